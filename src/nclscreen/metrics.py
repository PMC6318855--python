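"""Reliability and expression-context metrics for harmonized NCL events.

Given the per-tool junction read counts ``N_NCL(i)`` of an event across the
``n`` detectors compared (zeros for non-detecting tools):

* ``tau_ncl`` — heterogeneity of the counts,
  ``tau = sum_i(1 - log(N_i + 1)/log(Max + 1)) / (n - 1)``, in [0, 1];
  0 means all tools agree on a positive count, 1 means a single tool
  detected the event.
* ``ncl_score`` — ``log10((Median(N)^2 + kappa) / (tau + kappa))`` with the
  pseudocount ``kappa = 0.01``; larger median support with smaller
  between-tool variation gives a higher score.
* ``ncl_ratio`` (R) and ``circular_fraction`` (CF) — abundance of the NCL
  junction relative to co-linear splicing at the same boundaries:
  ``R = 2N / (2N + N_D + N_A)`` and ``CF = N / (N + N_D + N_A + 1)``;
  R > 0.5 (equivalently CF > ~1/3) indicates the NCL isoform is expressed
  above its co-linear counterpart.
* ``junction_usage`` — P_D = N_D / (all co-linear junction reads of the donor
  host gene), P_A symmetric, and P_median = the gene's median per-junction
  usage frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import EventKey

DEFAULT_KAPPA = 0.01


def tau_ncl(n_ncl_by_tool: Sequence[float], log_base: float | None = None) -> float:
    """Heterogeneity of junction read counts across the tools compared.

    ``n_ncl_by_tool`` is the full n-vector with zeros for tools that did not
    detect the event.  The log base is irrelevant (the terms are ratios of
    logarithms); ``log_base`` exists to make that property checkable.
    Returns 0.0 for a single-tool comparison (n < 2), where the statistic is
    undefined.
    """
    counts = np.asarray(n_ncl_by_tool, dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("counts must be a non-empty vector of non-negative values")
    mx = counts.max()
    if mx <= 0:
        raise ValueError("tau_ncl requires at least one positive count")
    n = counts.size
    if n < 2:
        return 0.0
    log = np.log if log_base is None else (lambda x: np.log(x) / math.log(log_base))
    terms = 1.0 - log(counts + 1.0) / log(mx + 1.0)
    return float(terms.sum() / (n - 1))


def ncl_score(
    n_ncl_by_tool: Sequence[float],
    kappa: float = DEFAULT_KAPPA,
    tau: float | None = None,
) -> float:
    """Reliability score combining median support and between-tool variation."""
    counts = np.asarray(n_ncl_by_tool, dtype=float)
    if tau is None:
        tau = tau_ncl(counts)
    med = float(np.median(counts))
    return float(np.log10((med * med + kappa) / (tau + kappa)))


def ncl_ratio(n_ncl: float, n_d: float, n_a: float) -> float | None:
    """R = 2N / (2N + N_D + N_A); None when no reads support either isoform."""
    if min(n_ncl, n_d, n_a) < 0:
        raise ValueError("counts must be non-negative")
    denom = 2.0 * n_ncl + n_d + n_a
    if denom == 0:
        return None
    return 2.0 * n_ncl / denom


def circular_fraction(n_ncl: float, n_d: float, n_a: float) -> float:
    """CF = N / (N + N_D + N_A + 1); the +1 pseudocount makes it total."""
    if min(n_ncl, n_d, n_a) < 0:
        raise ValueError("counts must be non-negative")
    return float(n_ncl) / (n_ncl + n_d + n_a + 1.0)


def junction_usage_side(
    n_side: float, junction_counts: Mapping[tuple, float] | Sequence[float]
) -> tuple[float | None, float | None]:
    """(P_side, P_median) for one host gene.

    ``junction_counts`` holds the read count of every annotated junction of
    the gene.  P_side = n_side / gene total; P_median = median over the
    gene's junctions of count/total.  Both are None when the gene total is 0.
    """
    values = (
        list(junction_counts.values())
        if isinstance(junction_counts, Mapping)
        else list(junction_counts)
    )
    total = float(sum(values))
    if total <= 0:
        return None, None
    p_side = n_side / total
    p_median = float(np.median([v / total for v in values]))
    return p_side, p_median


def junction_usage(
    n_d: float,
    n_a: float,
    donor_junction_counts: Mapping[tuple, float] | Sequence[float],
    acceptor_junction_counts: Mapping[tuple, float] | Sequence[float] | None = None,
) -> tuple[float | None, float | None, float | None, float | None]:
    """(P_D, P_A, P_median donor side, P_median acceptor side).

    For intragenic events both sides share the host gene, so pass the same
    counts (or omit the acceptor's) and the two medians coincide; for
    intergenic events each side is computed within its own host gene.
    """
    if acceptor_junction_counts is None:
        acceptor_junction_counts = donor_junction_counts
    p_d, p_med_d = junction_usage_side(n_d, donor_junction_counts)
    p_a, p_med_a = junction_usage_side(n_a, acceptor_junction_counts)
    return p_d, p_a, p_med_d, p_med_a


def sce_flags(
    key: EventKey, sce_trees: Mapping[str, IntervalTree] | None
) -> tuple[bool | None, bool | None]:
    """Whether the donor / acceptor junction base lies within an SCE interval.

    Returns (None, None) when no SCE annotation was provided.
    """
    if sce_trees is None:
        return None, None

    def hit(chrom: str, pos: int) -> bool:
        tree = sce_trees.get(chrom)
        return bool(tree is not None and tree[pos])

    return hit(key.donor_chrom, key.donor_pos), hit(key.acceptor_chrom, key.acceptor_pos)


@dataclass
class MetricsRow:
    """All per-event metrics, ready for the result tables.

    ``median_n_ncl`` is the median over the full n-vector (zeros included,
    as in the score); ``n_ncl_detected`` is the median over the tools that
    detected the event and feeds the expression-oriented quantities
    (R, CF, RPM).
    """

    key: EventKey
    n_tools: int
    single_tool_comparison: bool
    median_n_ncl: float
    n_ncl_detected: float
    tau_ncl: float
    ncl_score: float
    r_ncl: float | None
    cf: float
    p_d: float | None
    p_a: float | None
    p_median_donor: float | None
    p_median_acceptor: float | None
    rpm_raw: float
    rpm_mapped: float
    tpm_donor: float | None
    fpkm_donor: float | None
    tpm_acceptor: float | None
    fpkm_acceptor: float | None
    sce_donor: bool | None
    sce_acceptor: bool | None


def build_metrics_row(
    event,
    tool_order: Sequence[str],
    evidence,
    quant: Mapping[str, tuple[float, float]],
    sce_trees: Mapping[str, IntervalTree] | None,
    total_raw_reads: int,
    total_mapped_reads: int,
    kappa: float = DEFAULT_KAPPA,
) -> MetricsRow:
    """Assemble the metrics of one event.

    ``tool_order`` is the panel of tools whose scope covers the event's locus
    class (n of the tau/score equations is fixed per locus class, not per
    event); ``evidence`` is a :class:`nclscreen.evidence.JunctionEvidence`.
    """
    from .evidence import compute_rpm  # local import to avoid a cycle

    vector = [float(event.per_tool_n_ncl.get(t, 0)) for t in tool_order]
    if not any(v > 0 for v in vector):
        # event reported only by tools outside the class panel: fall back to
        # the detecting tools so tau/score remain defined
        vector = [float(event.per_tool_n_ncl[t]) for t in sorted(event.per_tool_n_ncl)]
    n = len(vector)
    single = n < 2
    tau = tau_ncl(vector)
    score = ncl_score(vector, kappa=kappa, tau=tau)
    detected = [v for v in vector if v > 0]
    n_det = float(np.median(detected)) if detected else 0.0
    r = ncl_ratio(n_det, evidence.n_d, evidence.n_a)
    cf = circular_fraction(n_det, evidence.n_d, evidence.n_a)
    p_d, p_a, p_med_d, p_med_a = junction_usage(
        evidence.n_d,
        evidence.n_a,
        evidence.donor_gene_junction_counts,
        evidence.acceptor_gene_junction_counts,
    )
    rpm_raw, rpm_mapped = compute_rpm(n_det, total_raw_reads, total_mapped_reads)
    tpm_d, fpkm_d = quant.get(evidence.donor_gene or "", (None, None))
    tpm_a, fpkm_a = quant.get(evidence.acceptor_gene or "", (None, None))
    sce_d, sce_a = sce_flags(event.key, sce_trees)
    return MetricsRow(
        key=event.key,
        n_tools=n,
        single_tool_comparison=single,
        median_n_ncl=float(np.median(vector)),
        n_ncl_detected=n_det,
        tau_ncl=tau,
        ncl_score=score,
        r_ncl=r,
        cf=cf,
        p_d=p_d,
        p_a=p_a,
        p_median_donor=p_med_d,
        p_median_acceptor=p_med_a,
        rpm_raw=rpm_raw,
        rpm_mapped=rpm_mapped,
        tpm_donor=tpm_d,
        fpkm_donor=fpkm_d,
        tpm_acceptor=tpm_a,
        fpkm_acceptor=fpkm_a,
        sce_donor=sce_d,
        sce_acceptor=sce_a,
    )
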