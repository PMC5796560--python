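# tescan

Calling active transposable-element (TE) insertions from targeted
paired-end sequencing libraries.

## The problem

The human genome still carries a handful of actively mobile
retrotransposon subfamilies — L1HS (LINE1 class) and the AluYa5/8 and
AluYb8/9 groups (Alu class). New insertions are rare (~1 per 20 births for
Alu, ~1 per 100 for LINE1) but can disrupt genes or their regulation, and
they are invisible to exome pipelines. Targeted assays enrich sequencing
libraries for fragments spanning the 3′ junction of an active TE: read 2
starts at a subfamily-diagnostic *nested primer*, runs through the
subfamily's *TE-like* consensus stretch and the poly-A tail; read 1 comes
from the unique 3′ flanking sequence and anchors the insertion site on the
reference genome.

`tescan` is the computational half of such an assay: given
coordinate-sorted, duplicate-marked alignments (one library per sample ×
subfamily), it filters read pairs, clusters read-1 anchors into candidate
loci, classifies each locus against reference TE annotations and a
polymorphic-TE database (polyTEdb), and evaluates call sets against truth
sets — including trio-based de novo classification and long-read
validation. A built-in simulator generates libraries with planted ground
truth so every stage is verifiable without external data.

## Method at a glance

Per read pair, in order: drop PCR duplicates; require read 2 to begin with
the full-length nested primer exactly (a *partial* match, ≥ 7 of the first
10 primer bases, is tallied separately as discernible-but-rejected); count
substitutions over the TE-like region and drop pairs above the subfamily
cap (3 for L1HS, 10 for AluYa5/8 and AluYb8/9, over TE-like lengths 8, 37
and 29 nt); require read 1 mapped with MAPQ > 0. Read 2 mapping is never
required — non-reference insertions routinely leave it unmapped.

Kept read-1 anchors are single-linkage clustered per chromosome (join gap
≤ 200 bp); retained clusters need ≥ 2 read-1 members at MAPQ ≥ 3 and a
span ≥ 100 bp, and must not overlap masked territory (assembly gaps ± 500
bp, centromere/sub-telomere regions ± 1 Mb, chrY). A cluster is
*reference* when a reference TE annotation of the targeted subfamily has
its 3′ end within 600 bp, *known non-reference* when a polyTEdb record of
the same class does, and *novel* otherwise.

Evaluation uses greedy one-to-one truth matching within the same 600 bp
window, with precision = TP/(TP+FP) and recall = TP/(TP+FN). For trios,
the truth set is the loci detected in both parents (within 100 bp); a
proband-only novel locus lacking even one parental read is a de novo
candidate and counted as a false positive. Long-read validation counts
reads spanning a call whose sequence contains the TE-like string exactly
in either orientation.

## Worked example

`examples/01_simulate_and_call.py` simulates a 100 kb genome with 10
reference + 10 non-reference insertions per subfamily (10 fragments per
locus, 30% background pairs, error rate 0) and runs the full pipeline:

```
simulated 923 read pairs over 60 planted loci
  L1HS: 299 pairs -> 20 calls {'reference': 10, 'known_non_reference': 0, 'novel': 10}
  AluYa5/8: 307 pairs -> 20 calls {'reference': 10, 'known_non_reference': 0, 'novel': 10}
  AluYb8/9: 317 pairs -> 20 calls {'reference': 10, 'known_non_reference': 0, 'novel': 10}
against planted truth: TP=60 FP=0 FN=0 precision=1.000 recall=1.000
```

Every planted reference insertion is recovered and classified `reference`;
every planted non-reference insertion appears as a `novel` call at its
junction; background and head-to-head artifact pairs are removed by the
primer and MAPQ filters. The other examples cover primer-site genomics
(`02`), trio analysis (`03`) and long-read validation (`04`).

The same pipeline is available as a thin CLI for shell use:

```bash
tescan simulate --out-dir fixture --seed 1
tescan call --manifest manifest.yaml
tescan evaluate --calls calls.tsv --truth fixture/truth.bed
```

## Scope

Alignment (BWA/Stampy), duplicate marking, demultiplexing and the wet-lab
protocol itself are upstream of this package; `tescan` consumes aligned,
duplicate-marked records. The simulator emits idealized alignments
directly so tests need no aligner.
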