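"""Run the whole pipeline end to end and print the convergence report.

One call executes: simulate -> adjust -> effect maps (+ spin similarity) ->
8 signature ensembles -> transfer -> PheWAS -> convergence report, writing
all artifacts (TSV/JSON) plus a digest manifest to the output directory.
"""

import json
from pathlib import Path

from cnvsig import PipelineConfig, SignatureConfig, run_pipeline, validate_config

config = PipelineConfig(
    seed=7,
    n_regions=100,
    population_n=4000,
    signature=SignatureConfig(n_phenotypes=200, pheno_convergence=0.8),
    B=25,
    spin_perm=199,
    profile_perm=199,
)
assert validate_config(config) == []

out = Path("scratch/example_run")
manifest = run_pipeline(config, out)
s = manifest.summary

print("stages executed:", " -> ".join(manifest.stages))
print(f"artifacts written: {len(manifest.files)} files under {out}")
print(f"mean |map similarity|      = {s['mean_abs_map_similarity']:.2f}")
print(f"mean |profile similarity|  = {s['mean_abs_profile_similarity']:.2f}")
print(f"Lin's CCC (maps vs profiles) = {s['lin_ccc_maps_vs_profiles']:+.2f}")
print(f"pairs with phenotypic > volumetric similarity: "
      f"{s['n_pairs_pheno_gt_vol']}/28")
print("mean out-of-bag MCC per CNV:",
      json.dumps({k: round(v, 2) for k, v in s["mean_oob_mcc"].items()}))
# With convergent phenome couplings (pheno_convergence=0.8) the phenotypic
# profiles of the 8 CNVs align although their brain maps diverge: profile
# similarity far exceeds map similarity for most CNV pairs, and the low
# concordance coefficient quantifies the dissociation.
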