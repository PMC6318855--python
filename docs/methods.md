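# Methods

This note documents the model and procedure implemented by `nclscreen`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not demonstrate.

## Coordinates and junction model

All internal coordinates are 1-based inclusive; readers normalize at the
boundary. An NCL junction is keyed by `(donor_chrom, donor_pos,
donor_strand, acceptor_chrom, acceptor_pos, acceptor_strand)` where
`donor_pos` is the **last exonic base** of the donor segment and
`acceptor_pos` the **first exonic base** of the acceptor segment, both in
transcript direction. Minus-strand boundaries are stored as genomic
positions plus the strand flag; donor/acceptor roles follow transcript
direction, so a minus-strand donor boundary is a genomic exon *start*.
Detector dialects are declared per tool (`ToolConfig`): a column map plus a
coordinate base; 0-based position fields are declared *start-like* (shift
+1) or *end-like* (numerically equal to the 1-based base, no shift).

## Harmonization

A reported junction snaps to the nearest annotated boundary of the matching
type within `snap_dist = 5` bp (donor coordinates only to donor-type
boundaries, preventing role swaps). Choices where the underlying method is
silent:

* **Both** sides must snap or the record is rejected (reasons
  `unannotated_donor` / `unannotated_acceptor` / `unknown_chrom`;
  additionally `zero_count` for records reporting zero junction reads,
  since a merged event requires at least one supporting read per detecting
  tool).
* Ties at equal distance break toward the smaller genomic coordinate
  (deterministic).
* The two sides snap independently; no same-transcript constraint is
  imposed at this stage.
* A tool reporting the same snapped key twice has its counts summed, with a
  warning.
* An event is **intragenic** iff the donor and acceptor boundary gene-id
  sets intersect, which handles overlapping genes conservatively.

## Ambiguity screen

The junction-flanking sequence concatenates up to `flank = 100` nt of
*spliced transcript* sequence ending at the donor boundary with up to
100 nt starting at the acceptor boundary. Flanks walk across co-linear exon
junctions of an owning transcript (the transcript giving the longest flank
wins; ties break by lexicographic transcript id). When one transcript
carries both boundaries in circle orientation and the exonic circle length
L < 200, the full circle is used, split as donor side `L − ⌊L/2⌋` +
acceptor side `⌊L/2⌋`, so the emitted sequence has length L.

Alignment is consumed from externally produced PSL (genome and transcript
targets); scores use the web-BLAT convention `matches + repMatches −
misMatches − qNumInsert − tNumInsert`, identity is `(matches +
repMatches)/qSize` (query-wide). Classification:

* **alt_colinear** — some alignment crosses the junction midpoint with at
  least `side_margin = 10` query bases on each side and identity strictly
  above `identity_threshold = 0.80`. The margin guards against trivially
  clipped hits when the threshold is lowered; at the default threshold it is
  a pure safety net.
* **multi_hit** — among *genomic* alignments covering ≥ `min_coverage =
  0.5` of the query, at least two distinct target loci score within
  `(best − score_gap, best]`, `score_gap = 3`. Overlapping hits on one
  target collapse into one locus (so duplicated alignment lines cannot
  trigger the flag) and the event's own donor/acceptor loci count as a
  single self locus. Transcript-space hits feed only the alternative
  co-linear screen, because multi-mapping is a statement about genomic
  positions.
* Precedence: an event satisfying both is reported once, as `alt_colinear`;
  both boolean flags are retained in the output columns.
* A sequence with no alignments at all is classified `ok` with zero scores
  and a warning — the screen can only demote events for which evidence of
  ambiguity exists.

## Evidence counting

`N_D` sums the unique-read counts of every annotated intron whose
donor-side exonic boundary equals the event's donor position (deduplicated
by intron coordinates across transcripts); `N_A` symmetrically. Only the
uniquely-mapping count column of the splice-junction table is used,
matching the "per million uniquely mapped reads" normalization. Host-gene
junction totals sum over all annotated introns of the gene, with absent
junctions counted as zero (they still enter `P_median`).

Out-of-circle pairs require the mate interval **entirely** outside the
closed circle interval (or on another chromosome); straddling mates do not
count, and read ids are deduplicated. The chimeric-record reader takes the
STAR-style 14-column junction dialect: junction coordinates are intron-side
bases converted to exonic-side using the strand, and the mate alignment is
the second-segment position + CIGAR on the donor chromosome (the dialect
carries no separate mate chromosome; out-of-circle counting is defined for
intragenic events, where the two coincide).

## Metrics wiring

* `n` of τ/score is the number of tools configured for the event's locus
  class (fixed per class, not per event); non-detecting tools enter the τ
  sum and the median as zeros. This makes a single-tool event score ≈ −2,
  the natural screening floor for tool-specific events. Should an event be
  reported only by tools outside its class panel, the detecting tools form
  the vector instead so the statistics stay defined.
* Medians of even-length vectors are the mean of the two central values.
* Expression-oriented quantities (R, CF, RPM) use the median count over the
  tools that *detected* the event (`n_ncl_detected` column) rather than the
  zero-inflated panel median: they estimate the junction's abundance, for
  which a non-detection by a low-sensitivity tool is not a measurement of
  zero. Both medians are reported.
* `κ = 0.01` throughout; all thresholds (snap distance, flank, identity,
  score gap, κ) are CLI flags.
* For intergenic events `P_median` is computed per side (donor host gene
  and acceptor host gene) and both values are reported; intragenic events
  use the shared host gene (lexicographically smallest id if several genes
  share both boundaries) on both sides.
* TPM/FPKM are joined from the quantification table, never computed;
  library sizes come from configuration. Missing optional annotations
  render as `NA`, never as 0.

## Output determinism

Events are sorted by (donor_chrom, donor_pos, acceptor_chrom,
acceptor_pos); floats print with six decimals. Identical inputs give
byte-identical TSVs. The accounting identity *before = alt_colinear +
multi_hit + after* per locus class is asserted on every assembly.

## Synthetic fixtures

The generator emulates the input universe of a multi-detector comparison:
a random two-chromosome genome (~40 non-overlapping genes, 4–9 exons of
120–260 nt, introns 100–400 nt), single-transcript genes, and a detector
panel of 9 intragenic-scope + 6 intergenic-scope tools with detection
probabilities spread over 0.3–0.9, log-normal multiplicative count
dispersion (σ = 0.5) and ≤5 bp coordinate jitter on 30 % of reports — the
desk-scale defaults chosen once as representative of the large between-tool
discrepancies such comparisons show. Default event load: 24 circRNA, 8
*trans*-spliced (with 2–6 planted out-of-circle mates each), 12 fusions,
plus 6 planted alternative-co-linear events (a homolog single-exon gene
carries the junction sequence mutated to 85 % identity) and 6 planted
multi-hit events (the donor flank duplicated at a distant locus with one
mismatch, score gap 2).

Alignment and junction-count files are emitted directly in their text
dialects rather than by running an aligner, keeping tests hermetic: PSL
hits are written from the planted identities/scores, splice-junction counts
are drawn per annotated intron and the manifest records the resulting
N_D/N_A. To use real data, replace the PSL/SJ/chimeric paths in the run
configuration with BLAT output for `nclscreen seqs`' FASTA and the
aligner's junction/chimeric tables.

**What passing therefore shows** — exact recovery of planted counts,
classifications and classes through the full pipeline, including dialect
conversion, snapping and the classification rules. **What it does not
show** — robustness to real alignment noise: soft-clipped chimeric records,
repeat-driven partial hits, incomplete annotation, or detectors whose
reported coordinates are systematically shifted by more than 5 bp. The
generator plants no such pathologies, so real-data behavior at those
margins is untested here.

## Problem sizes

The default study (56 events, 15 detectors, ~120 kb genome) runs the whole
pipeline in a few seconds; the test suite's fixtures are shared per session
and the complete suite runs in seconds on one CPU.

## Known limitations

* No BAM support: junction evidence comes from the SJ/chimeric text
  dialects.
* Whether the junction-supporting read and its outside mate must share a
  strand is not enforced.
* Strand mis-assignments by detectors are not corrected — a junction
  reported on the wrong strand fails to snap and is rejected rather than
  rescued.
* BLAT itself is not run; the screen is only as good as the supplied PSL.
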