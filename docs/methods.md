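# Methods

## Model of the assay

The package assumes a targeted paired-end library in which each on-target
fragment spans the 3′ junction of an insertion of one of three active
human TE subfamilies (L1HS, AluYa5/8, AluYb8/9). Read 2 is anchored by the
subfamily's nested primer and reads through the TE 3′ end: primer, then a
short subfamily consensus stretch (the *TE-like* sequence), then the
poly-A tail added at retrotransposition, then — if the read is long
enough — unique downstream flank. Read 1 is sequenced from the opposite
(flank) end of the fragment and is the only mate whose alignment is
trusted: read 2 of a non-reference insertion has no template in the
reference and either fails to map or multi-maps onto one of the thousands
of near-identical older TE copies.

Two artifact classes of the enrichment chemistry are represented by their
read-level consequences rather than modeled kinetically: genomic
*background* fragments (read 2 lacks the primer) and *head-to-head*
inverted-repeat fragments (TE sequence at both ends, so read 1 itself is
repetitive and multi-maps).

## Parameters and defaults

All knobs live in `PipelineParams`; the defaults are the assay's published
operating point and are what the tests and acceptance script exercise.

| parameter | default | role |
| --- | --- | --- |
| `primer_partial_min_matches`/`primer_prefix_len` | 7/10 | a read-2 prefix matching ≥ 7 of the first 10 primer bases is a *partial* match: still rejected, but tallied separately from primer-less background because it indicates a discernible priming event |
| per-subfamily TE-like mismatch caps | 3, 10, 10 | maximum substitutions over the TE-like region (lengths 8, 37, 29 nt) for a read 2 to count as TE-derived |
| `min_report_mapq` | 1 | removes MAPQ-0 (multi-mapping) read-1 anchors |
| `cluster_gap_bp` | 200 | single-linkage join distance between read-1 start positions; retained clusters are therefore separated by > 200 bp |
| `min_read1_per_cluster`, `min_cluster_mapq` | 2, 3 | a call needs at least two flank-derived reads mapping with MAPQ ≥ 3 |
| `min_cluster_span_bp` | 100 | minimum cluster interval span, below the 151 bp footprint of a single intact read; rejects degenerate micro-clusters from clipped alignments |
| `annotation_window_bp` | 600 | distance from a cluster to an annotated TE 3′ end for classification and truth matching, matching the library fragment-size scale |
| `gap_flank_bp`, `satellite_window_bp` | 500, 1 Mb | masking margins around assembly gaps and centromere/sub-telomere annotations; chrY is excluded outright |
| `parental_window_bp` | 100 | trio co-location window |
| `primer_scan_max_mismatch` | 1 | genome primer scan tolerance; the base pairing the primer's 3′-ultimate position must always match exactly, since a mismatch there blocks extension |
| `target_pair_max_gap_bp`, `inverted_max_span_bp` | 200, 1000 | target/nested pairing distance for targetable loci; maximum 3′-end span of a head-to-head pair (the largest amplifiable fragment) |
| `polya_min_run`, `polya_max_nonA` | 8, 1 | poly-A detection: some window of ≥ 8 bases 3′ of the TE-like region with ≤ 1 non-A. These two are this package's own defaults — poly-A detection is annotation only and never changes a verdict |

Coordinates are 0-based half-open throughout; SAM input is converted at
the reader and BED output needs no conversion. Chromosome names are taken
verbatim from inputs (no chr-prefix normalization).

## Design choices where the design was open

- **Clustering linkage** is on read-1 *start* positions: the start is the
  amplification anchor on the flank side and is robust to variable 3′
  trimming. The 200 bp separation is thereby enforced between boundary
  read starts of neighbouring clusters (configurable via
  `cluster_gap_bp`).
- **MAPQ thresholds**: reads with 1 ≤ MAPQ < 3 remain cluster members
  (they contribute to span and totals) but do not count toward the ≥ 2
  high-quality requirement. This reconciles the reporting floor
  (remove MAPQ 0) with the call requirement (MAPQ ≥ 3).
- **Window geometry**: the 600 bp annotation window is measured from the
  cluster *edge* to the annotation's 3′ anchor (0 if the anchor lies
  inside the interval). Records without strand information contribute
  both interval ends as candidate anchors.
- **Classification precedence**: reference annotations of the targeted
  subfamily are tried before polyTEdb records; a same-window reference
  annotation of the *wrong* subfamily never produces a reference call —
  the cluster falls through to polyTEdb, then novel. Reference subfamily
  equality honours synonym groups (AluYa5 and AluYa8 both satisfy an
  AluYa5/8 library).
- **Truth matching** is greedy one-to-one by increasing distance, so one
  cluster cannot satisfy two truth records (and vice versa), preventing
  double counting. TP + FN always equals the truth-set size.
- **Trio de novo evidence** applies the full read filter to parental
  reads; a single passing parental read-1 within 100 bp rescues a proband
  novel call as inherited.
- **Long-read support** requires full containment of the cluster interval
  within the aligned footprint plus an exact TE-like substring in either
  orientation; clipping-pattern inspection is deliberately out of scope.
- **Reads too short to cover any TE-like base** after the primer are
  dropped under a dedicated reason (`TE_LIKE_UNCOVERED`) so the tally
  stays interpretable; they are neither background nor TE-confirmed.

## The simulator

`SimConfig` defaults define the standard verification experiment: a
100 kb uniform-random genome, 10 reference + 10 non-reference insertions
per subfamily, fragment length ~ Normal(300, 30) floored so the flank side
always accommodates a 151 bp read 1, 10 fragments per locus, 30%
background pairs, 5% head-to-head pairs, substitution error rate 0 and a
20 bp poly-A tail. Planted elements are `target primer + stuffer + nested
primer + TE-like + poly-A`; reference-kind elements appear in both genomes,
non-reference only in the donor. Loci are jitter-placed on a grid with a
guaranteed minimum spacing of 1500 bp — far above the 200 bp cluster-merge
scale plus fragment spread, and small enough that the standard 60-locus
experiment fits a 100 kb genome. Requesting more loci than the genome can
hold at that spacing is an input error. All randomness derives from one
seed; outputs are byte-identical across runs.

Idealized alignments are emitted directly (read 1 at its true flank
coordinate with MAPQ 60; read 2 unmapped for non-reference loci, mapped
with MAPQ 0–5 for reference loci; head-to-head read 1 at MAPQ 0), so the
pipeline is tested without an aligner. What the simulator does *not*
emulate — and what passing tests therefore do not demonstrate — includes
alignment ambiguity in genuinely repetitive flanks, indel and
quality-dependent sequencing errors, chimeric fragments, PCR duplicates
(assumed marked upstream), locus-to-locus amplification-efficiency
variation, and reference genomes with realistic repeat content. The
shipped subfamily profiles are synthetic stand-ins that reproduce the
assay's structural layout (TE-like lengths 8/37/29, caps 3/10/10), not the
proprietary primer sequences; analyses of real libraries must supply real
profiles via configuration.

## Numerical and degenerate-input conventions

Precision/recall with a zero denominator are undefined and reported as
NaN with a `*_defined` flag. Interval expansion clamps at coordinate 0;
intervals with start > end are input errors. Unknown chromosomes queried
against a mask are unmasked (logged once). Empty libraries, empty truth
sets and empty call lists all produce valid empty outputs. Ties in
annotation matching break by distance, then reference over polyTEdb, then
record id; cluster ordering is deterministic (chromosome, start).

## Verification scale

The test suite and `scripts/acceptance.py` run the standard experiment at
the sizes above (60 loci, ~900 read pairs, 1000 random clustering-oracle
trials, a 50 kb primer-scan oracle sequence), chosen so the whole suite
completes in seconds while every stage is exercised against an
independent brute-force oracle or planted ground truth.

## Known limitations

No breakpoint refinement beyond the cluster interval, no target-site
duplication detection, no genotyping (het/hom), no lift-over between
genome builds, and no significance testing on mismatch profiles (the
per-position densities are descriptive). Recall/precision of 1.0 on
simulator output reflects the idealized mapping model; on real data the
published operating point trades a ~5% false-negative rate driven by
mappability and coverage variance that the simulator does not model.
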