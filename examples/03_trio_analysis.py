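"""Trio inheritance analysis.

Both parents and the proband share one simulated experiment; withholding
one locus's reads from the parents makes the proband's call there a
candidate de novo insertion (counted as a false positive, since true de
novo retrotransposition is far rarer than inherited polymorphism).
"""

from tescan import PipelineParams, SimConfig, build_mask, default_profiles
from tescan.clustering import cluster_reads
from tescan.evaluate import evaluate_trio
from tescan.filtering import apply_filters
from tescan.pipeline import call_library
from tescan.simulate import run_simulation

profiles = default_profiles()
params = PipelineParams()
reference, donor, truth, pairs = run_simulation(profiles, SimConfig(seed=11))
withheld = truth.by_kind("nonreference")[0].locus_id


def clusters_for(exclude_locus=None):
    out = []
    for subfamily, profile in profiles.items():
        lib = [sp.pair for sp in pairs
               if sp.pair.subfamily_name == subfamily and sp.origin != exclude_locus]
        kept, _ = apply_filters(lib, profile, params)
        out += cluster_reads(kept, params)
    return out


mask = build_mask([], [], params)
proband_calls = []
for subfamily, profile in profiles.items():
    lib = [sp.pair for sp in pairs if sp.pair.subfamily_name == subfamily]
    proband_calls += call_library(lib, profile, params, mask, []).calls

for label, parents in (("full inheritance", clusters_for()),
                       (f"parents lack {withheld}", clusters_for(withheld))):
    res = evaluate_trio(proband_calls, parents, list(parents), params)
    print(f"{label}: parental truth {res.parental_truth_size} loci, "
          f"observed in proband {res.observed_in_proband}, "
          f"de novo {res.proband_de_novo}")
print("(a de novo call is a proband-only locus with no read-level evidence "
      "in either parent; expected 0 when everything is inherited, 1 when one "
      "locus is withheld from the parents)")
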