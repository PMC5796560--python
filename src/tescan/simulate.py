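"""Synthetic targeted-library simulator with known ground truth.

The generator emulates the read architecture of the targeted assay: each
on-target fragment spans the 3' junction of a TE insertion, so read 2 is
``nested_primer + TE-like (with substitution errors) + poly-A`` running
into the downstream unique flank, while read 1 is sequenced from the far
(flank) end of the fragment back toward the element and aligns uniquely
just 3' of the junction. Reference insertions are planted in both the
reference and the donor genome; non-reference insertions only in the
donor, so their read 2 has nothing to align to (it is emitted unmapped,
while reference-locus read 2 maps onto the element with low MAPQ, which
near-identical TE copies cause in practice). Background fragments carry no
primer on read 2; head-to-head artifact fragments carry TE sequence on
both reads, which leaves read 1 multi-mapping (MAPQ 0).

All randomness flows from ``SimConfig.seed``; outputs are bit-identical
across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .core import (
    AlignedPair,
    InputError,
    Read1,
    Read2,
    SubfamilyProfile,
    revcomp,
)

#: Deterministic stuffer between target and nested primer inside the
#: synthetic element body (stands in for the consensus bases separating the
#: two priming sites).
_ELEMENT_FILLER = "GCTGAGGCAGGAGAATCGCTTGAACCCGGG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated experiment.

    Defaults encode the assay's library geometry (~300 bp sheared inserts,
    2 x 151 bp paired-end reads) and a verification-scale genome: 100 kb
    with 10 reference plus 10 non-reference insertions per subfamily at 10
    fragments per locus, 30% background fragments and 5% head-to-head
    artifacts.
    """

    genome_length_bp: int = 100_000
    chrom_name: str = "chr1"
    sample_id: str = "sim"
    n_reference_insertions: int = 10
    n_nonreference_insertions: int = 10
    fragment_mean_bp: int = 300
    fragment_sd_bp: float = 30.0
    read_length: int = 151
    fragments_per_locus: int = 10
    background_fraction: float = 0.3
    headtohead_fraction: float = 0.05
    substitution_error_rate: float = 0.0
    polya_tail_len: int = 20
    min_locus_spacing_bp: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.background_fraction, self.headtohead_fraction,
                     self.substitution_error_rate):
            if not 0.0 <= frac <= 1.0:
                raise InputError("fractions must lie in [0, 1]")
        if self.background_fraction + self.headtohead_fraction > 1.0:
            raise InputError("background + head-to-head fractions must sum to <= 1")
        if self.read_length > self.fragment_mean_bp + 4 * self.fragment_sd_bp:
            raise InputError("read_length exceeds the plausible fragment range")


@dataclass(frozen=True)
class TruthInsertion:
    """One planted insertion; ``anchor_pos`` is the reference coordinate of
    the first unique-flank base 3' of the element (the insertion junction)."""

    chrom: str
    anchor_pos: int
    subfamily: str
    kind: str  # "reference" or "nonreference"
    locus_id: str


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    insertions: list[TruthInsertion] = field(default_factory=list)
    background_ids: list[str] = field(default_factory=list)
    headtohead_ids: list[str] = field(default_factory=list)

    def by_kind(self, kind: str) -> list[TruthInsertion]:
        return [t for t in self.insertions if t.kind == kind]


@dataclass(frozen=True)
class SimulatedPair:
    """An emitted read pair: idealized alignment plus raw sequences."""

    pair: AlignedPair
    read1_seq: str
    read2_seq: str
    origin: str  # locus id, "background" or "headtohead"


def element_sequence(profile: SubfamilyProfile, config: SimConfig) -> str:
    """The planted element body: target primer, stuffer, nested primer,
    TE-like sequence, poly-A tail."""
    return (
        profile.target_primer
        + _ELEMENT_FILLER
        + profile.nested_primer
        + profile.te_like
        + "A" * config.polya_tail_len
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_genome_and_insertions(
    profiles: Mapping[str, SubfamilyProfile],
    config: SimConfig,
) -> tuple[str, str, SimTruth]:
    """Build a random reference genome, a donor genome and the truth set.

    Reference insertions are planted in both sequences; non-reference
    insertions only in the donor. Truth anchors are exact 3'-junction
    coordinates on the reference. Loci are spaced by at least
    ``min_locus_spacing_bp`` so that clusters cannot merge; requesting
    more insertions than the genome can hold at that spacing is an error.
    """
    rng = np.random.default_rng(config.seed)
    n_per = config.n_reference_insertions + config.n_nonreference_insertions
    n_total = n_per * len(profiles)
    margin = config.fragment_mean_bp + int(4 * config.fragment_sd_bp) + config.read_length
    usable = config.genome_length_bp - 2 * margin
    if n_total > 0:
        spacing = usable / n_total
        if spacing < config.min_locus_spacing_bp:
            raise InputError(
                f"{n_total} insertions exceed genome capacity at "
                f"{config.min_locus_spacing_bp} bp minimum spacing"
            )
    base = _random_dna(rng, config.genome_length_bp)

    assignments: list[tuple[str, str]] = []
    for name in profiles:
        assignments += [(name, "reference")] * config.n_reference_insertions
        assignments += [(name, "nonreference")] * config.n_nonreference_insertions
    order = rng.permutation(len(assignments))
    assignments = [assignments[i] for i in order]

    # insertion points in base-genome coordinates, jittered on a grid; the
    # jitter never exceeds spacing - min_locus_spacing_bp, so consecutive
    # junctions stay at least min_locus_spacing_bp apart
    points: list[int] = []
    for i in range(n_total):
        lo = margin + int(i * spacing)
        hi = lo + max(1, int(spacing) - config.min_locus_spacing_bp)
        points.append(int(rng.integers(lo, hi)))

    # splice reference-kind elements into the base genome, tracking offsets
    ref_parts: list[str] = []
    truth = SimTruth()
    cursor = 0
    offset = 0
    planned: list[tuple[int, str, str, str]] = []  # (base_pos, sub, kind, locus_id)
    for i, (pos, (sub, kind)) in enumerate(zip(points, assignments)):
        planned.append((pos, sub, kind, f"locus{i:03d}_{sub.replace('/', '')}_{kind}"))
    for pos, sub, kind, locus_id in planned:
        if kind != "reference":
            continue
        elem = element_sequence(profiles[sub], config)
        ref_parts.append(base[cursor:pos])
        ref_parts.append(elem)
        cursor = pos
        offset += len(elem)
    ref_parts.append(base[cursor:])
    reference = "".join(ref_parts)

    # recompute final reference coordinates of every junction
    offset = 0
    anchors: list[tuple[int, str, str, str]] = []
    for pos, sub, kind, locus_id in planned:
        if kind == "reference":
            elem_len = len(element_sequence(profiles[sub], config))
            anchors.append((pos + offset + elem_len, sub, kind, locus_id))
            offset += elem_len
        else:
            anchors.append((pos + offset, sub, kind, locus_id))
    for anchor, sub, kind, locus_id in anchors:
        truth.insertions.append(
            TruthInsertion(config.chrom_name, anchor, sub, kind, locus_id)
        )

    # donor: insert non-reference elements at their reference anchors
    donor_parts: list[str] = []
    cursor = 0
    for ins in sorted(truth.by_kind("nonreference"), key=lambda t: t.anchor_pos):
        elem = element_sequence(profiles[ins.subfamily], config)
        donor_parts.append(reference[cursor:ins.anchor_pos])
        donor_parts.append(elem)
        cursor = ins.anchor_pos
    donor_parts.append(reference[cursor:])
    donor = "".join(donor_parts)
    return reference, donor, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_library(
    reference: str,
    truth: SimTruth,
    profiles: Mapping[str, SubfamilyProfile],
    config: SimConfig,
) -> list[SimulatedPair]:
    """Emit read pairs with truth tags and idealized alignments.

    Per truth locus, ``fragments_per_locus`` fragments span the 3'
    junction; fragment lengths are normal(mean, sd), floored so that the
    flank side always accommodates read 1. Background and head-to-head
    pairs are added so that they form the configured fractions of the
    total library.
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom = config.chrom_name
    pairs: list[SimulatedPair] = []
    residual = 1.0 - config.background_fraction - config.headtohead_fraction
    on_target_loci = truth.insertions if residual > 0 else []
    for ins in on_target_loci:
        profile = profiles[ins.subfamily]
        te_side_len = (
            len(profile.nested_primer) + len(profile.te_like) + config.polya_tail_len
        )
        for j in range(config.fragments_per_locus):
            frag_len = int(round(rng.normal(config.fragment_mean_bp, config.fragment_sd_bp)))
            frag_len = max(frag_len, te_side_len + config.read_length)
            flank_len = frag_len - te_side_len
            # read 2: primer + (mutated) TE-like + poly-A, running into flank
            body = (
                profile.nested_primer
                + _mutate(profile.te_like, config.substitution_error_rate, rng)
                + "A" * config.polya_tail_len
                + reference[ins.anchor_pos: ins.anchor_pos + config.read_length]
            )
            read2_seq = body[: config.read_length]
            # read 1: far end of the fragment, reverse strand on the flank
            start1 = ins.anchor_pos + flank_len - config.read_length
            end1 = start1 + config.read_length
            read1_seq = revcomp(reference[start1:end1])
            if ins.kind == "nonreference":
                read2 = Read2(sequence=read2_seq, is_mapped=False, mapq=0)
            else:
                read2 = Read2(
                    sequence=read2_seq, is_mapped=True, mapq=int(rng.integers(0, 6))
                )
            pair_id = f"{ins.locus_id}_frag{j:03d}"
            pairs.append(
                SimulatedPair(
                    pair=AlignedPair(
                        sample_id=config.sample_id,
                        subfamily_name=ins.subfamily,
                        read1=Read1(chrom, start1, end1, "-", 60, True),
                        read2=read2,
                        pair_id=pair_id,
                    ),
                    read1_seq=read1_seq,
                    read2_seq=read2_seq,
                    origin=ins.locus_id,
                )
            )
    n_on = len(pairs)
    if residual > 0:
        total = n_on / residual if n_on else 0
    else:
        # pure background/artifact library: emit the nominal pair count
        total = config.fragments_per_locus * len(truth.insertions)
    n_bg = int(round(total * config.background_fraction))
    n_hh = int(round(total * config.headtohead_fraction))
    sub_names = list(profiles)
    L = len(reference)
    for i in range(n_bg):
        sub = sub_names[int(rng.integers(0, len(sub_names)))]
        pos = int(rng.integers(0, L - config.read_length))
        strand = "+" if rng.random() < 0.5 else "-"
        r1 = reference[pos: pos + config.read_length]
        read1_seq = r1 if strand == "+" else revcomp(r1)
        read2_seq = _random_dna(rng, config.read_length)
        pair_id = f"bg{i:04d}"
        truth.background_ids.append(pair_id)
        pairs.append(
            SimulatedPair(
                pair=AlignedPair(
                    sample_id=config.sample_id,
                    subfamily_name=sub,
                    read1=Read1(chrom, pos, pos + config.read_length, strand, 60, True),
                    read2=Read2(sequence=read2_seq, is_mapped=False),
                    pair_id=pair_id,
                ),
                read1_seq=read1_seq,
                read2_seq=read2_seq,
                origin="background",
            )
        )
    for i in range(n_hh):
        sub = sub_names[int(rng.integers(0, len(sub_names)))]
        profile = profiles[sub]
        pos = int(rng.integers(0, L - config.read_length))
        body = (
            profile.nested_primer
            + profile.te_like
            + "A" * config.polya_tail_len
            + _random_dna(rng, config.read_length)
        )
        read2_seq = body[: config.read_length]
        # read 1 is itself TE-derived -> multi-maps, MAPQ 0
        read1_seq = body[: config.read_length]
        pair_id = f"hh{i:04d}"
        truth.headtohead_ids.append(pair_id)
        pairs.append(
            SimulatedPair(
                pair=AlignedPair(
                    sample_id=config.sample_id,
                    subfamily_name=sub,
                    read1=Read1(chrom, pos, pos + config.read_length, "+", 0, True),
                    read2=Read2(sequence=read2_seq, is_mapped=False),
                    pair_id=pair_id,
                ),
                read1_seq=read1_seq,
                read2_seq=read2_seq,
                origin="headtohead",
            )
        )
    return pairs


def truth_records_for(
    truth: SimTruth, kind: str, source: str = "reference_truth"
) -> list:
    """Planted insertions of one kind as evaluation truth records."""
    from .evaluate import TruthRecord

    return [
        TruthRecord(
            chrom=t.chrom,
            anchor_pos=t.anchor_pos,
            subfamily=t.subfamily,
            te_class=None,
            source=source,
            record_id=t.locus_id,
        )
        for t in truth.by_kind(kind)
    ]


def annotation_records_for_reference(
    truth: SimTruth,
    profiles: Mapping[str, SubfamilyProfile],
    config: SimConfig,
) -> list:
    """Reference-TE annotation records matching the planted reference
    insertions (interval = element body, strand +, 3' end = junction)."""
    from .annotate import REFERENCE, AnnotationRecord

    records = []
    for t in truth.by_kind("reference"):
        elen = len(element_sequence(profiles[t.subfamily], config))
        records.append(
            AnnotationRecord(
                chrom=t.chrom,
                start=t.anchor_pos - elen,
                end=t.anchor_pos,
                strand="+",
                te_class=profiles[t.subfamily].te_class,
                subfamily=t.subfamily,
                source=REFERENCE,
                record_id=t.locus_id,
            )
        )
    return records


def write_fixture(
    sim_pairs: Sequence[SimulatedPair],
    reference: str,
    truth: SimTruth,
    config: SimConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the simulated experiment as plain-text files re-readable by
    the pipeline: reference FASTA, R1/R2 FASTQ, coordinate-sorted SAM,
    truth BED and a YAML config snapshot."""
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out_dir / "reference.fa",
        "r1": out_dir / "reads_R1.fastq",
        "r2": out_dir / "reads_R2.fastq",
        "sam": out_dir / "alignments.sam",
        "truth": out_dir / "truth.bed",
        "config": out_dir / "sim_config.yaml",
    }
    with open(paths["reference"], "w") as fh:
        fh.write(f">{config.chrom_name}\n")
        for i in range(0, len(reference), 80):
            fh.write(reference[i: i + 80] + "\n")
    with open(paths["r1"], "w") as f1, open(paths["r2"], "w") as f2:
        for sp in sim_pairs:
            q = "I" * len(sp.read1_seq)
            f1.write(f"@{sp.pair.pair_id}/1\n{sp.read1_seq}\n+\n{q}\n")
            q = "I" * len(sp.read2_seq)
            f2.write(f"@{sp.pair.pair_id}/2\n{sp.read2_seq}\n+\n{q}\n")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom_name, "LN": len(reference)}],
    }
    records = []
    with pysam.AlignmentFile(str(paths["sam"]), "w", header=header) as sam:
        for sp in sim_pairs:
            r1 = pysam.AlignedSegment(sam.header)
            r1.query_name = sp.pair.pair_id
            r1.flag = 0x1 | 0x40
            p1 = sp.pair.read1
            r1.reference_id = 0
            r1.reference_start = p1.start
            r1.mapping_quality = p1.mapq
            r1.cigarstring = f"{config.read_length}M"
            if p1.strand == "-":
                r1.flag |= 0x10
                r1.query_sequence = revcomp(sp.read1_seq)
            else:
                r1.query_sequence = sp.read1_seq
            r1.query_qualities = pysam.qualitystring_to_array("I" * config.read_length)

            r2 = pysam.AlignedSegment(sam.header)
            r2.query_name = sp.pair.pair_id
            r2.flag = 0x1 | 0x80
            r2.query_sequence = sp.read2_seq
            r2.query_qualities = pysam.qualitystring_to_array("I" * len(sp.read2_seq))
            if sp.pair.read2.is_mapped:
                r2.reference_id = 0
                r2.reference_start = max(0, p1.start - config.fragment_mean_bp)
                r2.mapping_quality = sp.pair.read2.mapq
                r2.cigarstring = f"{len(sp.read2_seq)}M"
            else:
                r2.flag |= 0x4
                r2.reference_id = 0
                r2.reference_start = p1.start
                r1.flag |= 0x8
            r1.next_reference_id = 0
            r1.next_reference_start = r2.reference_start
            r2.next_reference_id = 0
            r2.next_reference_start = r1.reference_start
            records.append(r1)
            records.append(r2)
        for rec in sorted(records, key=lambda r: (r.reference_start, r.query_name, r.flag)):
            sam.write(rec)

    with open(paths["truth"], "w") as fh:
        for t in sorted(truth.insertions, key=lambda t: (t.chrom, t.anchor_pos)):
            fh.write(
                f"{t.chrom}\t{t.anchor_pos}\t{t.anchor_pos + 1}\t"
                f"{t.subfamily}|{t.kind}|{t.locus_id}\t0\t+\n"
            )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return paths


def run_simulation(
    profiles: Mapping[str, SubfamilyProfile],
    config: SimConfig,
    out_dir: Optional[str | Path] = None,
) -> tuple[str, str, SimTruth, list[SimulatedPair]]:
    """Convenience wrapper: genome + truth + library (+ optional fixture)."""
    reference, donor, truth = simulate_genome_and_insertions(profiles, config)
    sim_pairs = simulate_library(reference, truth, profiles, config)
    if out_dir is not None:
        write_fixture(sim_pairs, reference, truth, config, out_dir)
    return reference, donor, truth, sim_pairs


__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedPair",
    "TruthInsertion",
    "annotation_records_for_reference",
    "element_sequence",
    "run_simulation",
    "simulate_genome_and_insertions",
    "simulate_library",
    "truth_records_for",
    "write_fixture",
]
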