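"""Primer-site genomics on a reference sequence.

Plants a target/nested primer pair (a targetable TE locus) and a
head-to-head primer pair (an amplification-artifact locus) in a random
genome, then recovers both with the mismatch-tolerant scanner.
"""

import random

from tescan import PipelineParams, default_profiles
from tescan.core import revcomp
from tescan.primers import build_target_set, find_inverted_repeats, scan_primer

rnd = random.Random(0)
genome = "".join(rnd.choice("ACGT") for _ in range(20_000))
profile = default_profiles()["AluYa5/8"]
params = PipelineParams()


def plant(seq, pos, site):
    return seq[:pos] + site + seq[pos + len(site):]


# a proper target locus: target primer, then nested primer 80 bp downstream
genome = plant(genome, 5_000, profile.target_primer)
genome = plant(genome, 5_080, profile.nested_primer)
# a head-to-head artifact: two target primers facing each other, 400 bp apart
genome = plant(genome, 12_000, profile.target_primer)
genome = plant(genome, 12_400, revcomp(profile.target_primer))

target_hits = scan_primer(genome, profile.target_primer, params, primer_id="target")
nested_hits = scan_primer(genome, profile.nested_primer, params, primer_id="nested")
print(f"target-primer matches: {[(m.pos, m.strand) for m in target_hits]}")
print(f"nested-primer matches: {[(m.pos, m.strand) for m in nested_hits]}")

loci = build_target_set(target_hits, nested_hits, None, None, params, profile.name)
for lo in loci:
    print(f"targetable locus {lo.chrom}:{lo.start}-{lo.end} ({lo.strand}) "
          "- both primers in proper order within 200 bp")

pairs = find_inverted_repeats(target_hits, params)
for pr in pairs:
    print(f"head-to-head pair at {pr.chrom}:{pr.match_a.pos}/{pr.match_b.pos}, "
          f"3'-end span {pr.span_bp} bp - would amplify exponentially and is "
          "removed by the exonuclease steps the assay models")
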