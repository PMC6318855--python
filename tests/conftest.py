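"""Shared fixtures: a tiny hand-built annotation/genome and simulated trees."""

from __future__ import annotations

import numpy as np
import pytest

from nclscreen import io_formats as io
from nclscreen import pipeline, synthetic

TINY_GTF = """\
chr1\ttest\texon\t100\t200\t.\t+\t.\tgene_id "GA"; transcript_id "TA"; gene_name "geneA";
chr1\ttest\texon\t300\t400\t.\t+\t.\tgene_id "GA"; transcript_id "TA"; gene_name "geneA";
chr1\ttest\texon\t500\t600\t.\t+\t.\tgene_id "GA"; transcript_id "TA"; gene_name "geneA";
chr1\ttest\texon\t300\t400\t.\t+\t.\tgene_id "GA"; transcript_id "TA2"; gene_name "geneA";
chr1\ttest\texon\t550\t650\t.\t+\t.\tgene_id "GA"; transcript_id "TA2"; gene_name "geneA";
chr1\ttest\texon\t4801\t4900\t.\t+\t.\tgene_id "GB"; transcript_id "TB"; gene_name "geneB";
chr1\ttest\texon\t4951\t5000\t.\t+\t.\tgene_id "GB"; transcript_id "TB"; gene_name "geneB";
chr2\ttest\texon\t100\t200\t.\t-\t.\tgene_id "GC"; transcript_id "TC"; gene_name "geneC";
chr2\ttest\texon\t300\t400\t.\t-\t.\tgene_id "GC"; transcript_id "TC"; gene_name "geneC";
chr2\ttest\texon\t1000\t1059\t.\t+\t.\tgene_id "GD"; transcript_id "TD"; gene_name "geneD";
chr2\ttest\texon\t1200\t1259\t.\t+\t.\tgene_id "GD"; transcript_id "TD"; gene_name "geneD";
"""


@pytest.fixture(scope="session")
def tiny_annotation(tmp_path_factory) -> io.AnnotationIndex:
    path = tmp_path_factory.mktemp("tiny") / "tiny.gtf"
    path.write_text(TINY_GTF)
    return io.read_annotation(path)


@pytest.fixture(scope="session")
def tiny_genome() -> dict[str, str]:
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    return {
        "chr1": "".join(bases[rng.integers(0, 4, 6000)]),
        "chr2": "".join(bases[rng.integers(0, 4, 3000)]),
    }


def _simulate_and_run(tmp_path_factory, name, config):
    out = tmp_path_factory.mktemp(name)
    truth = synthetic.simulate(config, out)
    run_config = pipeline.load_config(out / "config.yaml")
    result = pipeline.run(run_config, out / "out")
    return out, truth, result


@pytest.fixture(scope="session")
def default_tree(tmp_path_factory):
    """Default study conditions (noisy panel), simulated and screened."""
    return _simulate_and_run(tmp_path_factory, "default_sim", synthetic.SimConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_tree(tmp_path_factory):
    """Noise-free conditions: full detection, exact counts, no jitter."""
    cfg = synthetic.noiseless(synthetic.SimConfig(seed=5))
    return _simulate_and_run(tmp_path_factory, "noiseless_sim", cfg)
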