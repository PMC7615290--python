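"""Transfer the fitted signatures to the population cohort and run a PheWAS.

Scores every population subject's expression of each intermediate phenotype,
validates the transfer by a two-sample bootstrap mean test (carriers versus
non-carriers), then scans all phenotypes for associations with the signature
expressions and summarizes the convergence of the 8 phenotypic profiles.
"""

import numpy as np

from cnvsig import (
    CNV_GROUPS,
    adjust_confounds,
    bootstrap_mean_test,
    cohens_d_map,
    fit_ensemble,
    make_atlas,
    make_signatures,
    profile_similarity,
    run_phewas,
    score_expressions,
    shared_hits,
    simulate_clinical,
    simulate_population,
    zscore_columns,
)
from cnvsig.preprocess import POPULATION_DESIGN

atlas = make_atlas(100, 7, seed=0)
truth = make_signatures(atlas, seed=1)
clinical = simulate_clinical(truth, atlas, seed=2)
adj_clin, _ = adjust_confounds(clinical.volumes, clinical.confounds)
controls = clinical.group.index[clinical.group == "control"]

signatures = []
for k, g in enumerate(CNV_GROUPS):
    carriers = clinical.group.index[clinical.group == g]
    subset = carriers.append(controls)
    z = zscore_columns(adj_clin.values.loc[subset], over_subjects=subset)
    d = cohens_d_map(z, carriers, controls, group=g)
    y = np.r_[np.ones(len(carriers)), np.zeros(len(controls))]
    signatures.append(
        fit_ensemble(adj_clin.values.loc[subset], y, B=25, seed=10 + k,
                     d_map=d, group=g)
    )

population = simulate_population(truth, atlas, N=4000, seed=3)
adj_pop, _ = adjust_confounds(population.volumes, population.confounds,
                              POPULATION_DESIGN)
scores = score_expressions(adj_pop.values, signatures)
print(f"outlier filter removed {scores.n_flagged} of {len(scores.values)} "
      "subjects (Tukey fences, union over the 8 expressions)")

g = "15q11.2dup"  # the largest population carrier group
x = scores.values.loc[population.carrier_status == g, g]
y = scores.values.loc[population.carrier_status == "non-carrier", g]
res = bootstrap_mean_test(x, y, B=10000, seed=4)
print(f"{g}: carrier vs non-carrier expression difference = "
      f"{res.observed_difference:.2f} (bootstrap p = {res.p_value:.4f})")

profiles = run_phewas(scores, population.phenome)
for g in CNV_GROUPS:
    print(f"  {g:11s} Bonferroni hits: {profiles[g].n_bonferroni:3d}  "
          f"FDR hits: {profiles[g].n_fdr:3d}")
shared, top = shared_hits(profiles, min_k=6)
print(f"phenotypes significant in >= 6 of 8 scans: {len(shared)}")
sim = profile_similarity(profiles, n_perm=199, seed=5)
print(f"average PheWAS-profile similarity: {sim.mean_abs_offdiag:.2f}")
# Carriers express "their" signature more strongly than non-carriers, and
# the phenome profiles of different CNVs resemble each other far more than
# their brain maps do.
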