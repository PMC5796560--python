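"""Orthogonal validation of calls with long reads.

A call lacking database annotation ("novel") gains support when a long
read spans its cluster interval and carries the subfamily's TE-like
sequence verbatim (either orientation).
"""

import random

from tescan import default_profiles
from tescan.annotate import TECall
from tescan.clustering import Cluster
from tescan.core import revcomp
from tescan.evaluate import LongRead, validate_with_long_reads

profile = default_profiles()["AluYb8/9"]
rnd = random.Random(3)

call = TECall(
    Cluster("s1", "AluYb8/9", "chr1", 10_050, 10_400,
            read1_count_hq=4, read1_total=4, read2_mapped_count=0,
            polya_count=4, member_ids=[]),
    "novel", None, None,
)

flank = lambda n: "".join(rnd.choice("ACGT") for _ in range(n))  # noqa: E731
supporting = LongRead("chr1", 9_000, 12_000,
                      flank(800) + profile.te_like + "A" * 30 + flank(800))
supporting_rc = LongRead("chr1", 9_000, 12_000, revcomp(supporting.sequence))
spanning_empty = LongRead("chr1", 9_000, 12_000, flank(1_600))
not_spanning = LongRead("chr1", 10_200, 12_000, flank(300) + profile.te_like)

for label, reads in (
    ("one supporting read", [supporting]),
    ("same read, reverse-complemented", [supporting_rc]),
    ("spanning read without TE sequence", [spanning_empty]),
    ("TE sequence but read does not span the cluster", [not_spanning]),
):
    n = validate_with_long_reads(call, reads, profile)
    print(f"{label}: support count {n} -> {'validated' if n >= 1 else 'not validated'}")
print("(support >= 1 rescues a 'novel' call as a likely true insertion that "
      "is simply missing from the annotation databases)")
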