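"""End-to-end reproducible pipeline: simulate -> adjust -> effect maps ->
signature ensembles -> transfer -> PheWAS -> convergence report.

Every stochastic stage draws its seed deterministically from the master seed,
so two runs with the same configuration produce digest-identical numeric
artifacts. All artifacts are plain text (TSV tables, JSON models) and each
output file is listed in the run manifest with a content digest.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import make_atlas, write_atlas_tsv
from .effects import cohens_d_map, similarity_matrix
from .ensemble import (
    DEFAULT_GRID,
    fit_ensemble,
    network_summary,
    permutation_null,
)
from .phewas import (
    bootstrap_mean_test,
    category_hit_ratio,
    category_profile_similarity,
    concordance_report,
    condition_out,
    profile_similarity,
    run_phewas,
    score_expressions,
    shared_hits,
)
from .preprocess import (
    CLINICAL_DESIGN,
    POPULATION_DESIGN,
    adjust_confounds,
    zscore_columns,
)
from .simulate import (
    CNV_GROUPS,
    CONTROL,
    NONCARRIER,
    POPULATION_DESIGN_CARRIERS,
    ConfoundConfig,
    NoiseConfig,
    PhenomeConfig,
    SignatureConfig,
    make_signatures,
    simulate_clinical,
    simulate_population,
    clinical_design_sizes,
    write_cohort,
)


@dataclass
class PipelineConfig:
    """Desk-scale defaults: 100 regions, the full clinical design, a 4,000-
    subject population slice with the standard carrier counts, 200 phenotypes."""

    seed: int = 0
    n_regions: int = 100
    n_networks: int = 7
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    confounds: ConfoundConfig = field(default_factory=ConfoundConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    phenome: PhenomeConfig = field(default_factory=PhenomeConfig)
    clinical_size_scale: float = 1.0
    population_n: int = 4000
    population_carrier_counts: dict = field(
        default_factory=lambda: dict(POPULATION_DESIGN_CARRIERS)
    )
    B: int = 25
    n_perm: int = 0  # label permutations per CNV; 0 skips the null stage
    B_null: int | None = None
    spin_perm: int = 199
    profile_perm: int = 199
    bootstrap_replicates: int = 10000
    alpha: float = 0.05
    grid: tuple = DEFAULT_GRID
    shared_hit_min_k: int = 6
    run_conditioned_scan: bool = True

    def clinical_sizes(self) -> dict[str, int]:
        return clinical_design_sizes(self.clinical_size_scale)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Range and cross-field checks; returns a list of violations (empty = valid)."""
    v: list[str] = []
    if config.n_regions < config.n_networks or config.n_networks < 1:
        v.append("n_regions must be >= n_networks >= 1")
    try:
        rho = config.signature.mirror_rho_array()
        if (rho < 0).any() or (rho > 1).any():
            v.append("signature.mirror_rho must lie in [0, 1]")
    except Exception:
        v.append("signature.mirror_rho must lie in [0, 1]")
    if not 0.0 <= config.signature.pheno_convergence <= 1.0:
        v.append("signature.pheno_convergence must lie in [0, 1]")
    sizes = config.clinical_sizes()
    bad = [g for g, n in sizes.items() if n < 2]
    if bad:
        v.append(f"clinical group sizes below 2: {bad}")
    counts = config.population_carrier_counts
    if set(counts) != set(CNV_GROUPS):
        v.append("population_carrier_counts must cover exactly the 8 CNV groups")
    elif sum(counts.values()) >= config.population_n:
        v.append(
            f"population carrier total {sum(counts.values())} must be below "
            f"population_n={config.population_n}"
        )
    if config.signature.n_phenotypes < config.phenome.n_categories:
        v.append("signature.n_phenotypes must cover every phenome category")
    if not 0.0 < config.alpha < 1.0:
        v.append("alpha must lie in (0, 1)")
    if config.B < 1:
        v.append("B must be >= 1")
    if config.spin_perm < 1 or config.profile_perm < 1:
        v.append("permutation counts must be >= 1")
    g = np.asarray(config.grid, dtype=float)
    if g.size == 0 or (g < 0).any() or (g > 1).any():
        v.append("grid values must lie in [0, 1]")
    if not 1 <= config.shared_hit_min_k <= 8:
        v.append("shared_hit_min_k must lie in 1..8")
    return v


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    files: dict = field(default_factory=dict)  # relative path -> sha256
    warnings: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master: int, names: tuple[str, ...]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    return {
        name: int(np.random.default_rng(child).integers(2**31))
        for name, child in zip(names, ss.spawn(len(names)))
    }


_STAGES = (
    "atlas",
    "truth",
    "clinical",
    "population",
    "effectmaps",
    "ensembles",
    "transfer",
    "phewas",
    "report",
)


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute all stages, writing artifacts under ``out_dir``.

    Any stage error aborts with the stage name; the partial manifest is
    persisted as ``manifest.json`` before the error propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_json_dict(), started=time.strftime("%Y-%m-%dT%H:%M:%S")
    )
    violations = validate_config(config)
    if violations:
        raise PipelineStageError("validate", ValueError("; ".join(violations)))
    seeds = _stage_seeds(config.seed, _STAGES)

    def _register(relpath: str):
        manifest.files[relpath] = _digest(out / relpath)

    def _write_tsv(df: pd.DataFrame, relpath: str, index=True):
        (out / relpath).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / relpath, sep="\t", index=index, float_format="%.12g")
        _register(relpath)

    def _write_json(payload, relpath: str):
        (out / relpath).parent.mkdir(parents=True, exist_ok=True)
        with open(out / relpath, "w") as fh:
            json.dump(payload, fh, indent=1)
        _register(relpath)

    stage = "setup"
    try:
        # --- simulate ---------------------------------------------------
        stage = "atlas"
        atlas = make_atlas(config.n_regions, config.n_networks, seeds["atlas"])
        write_atlas_tsv(atlas, out / "atlas.tsv")
        _register("atlas.tsv")
        manifest.stages.append(stage)

        stage = "truth"
        truth = make_signatures(atlas, config.signature, seeds["truth"])
        truth.to_json(out / "ground_truth.json")
        _register("ground_truth.json")
        manifest.stages.append(stage)

        stage = "clinical"
        clinical = simulate_clinical(
            truth,
            atlas,
            sizes=config.clinical_sizes(),
            confound_cfg=config.confounds,
            noise_cfg=config.noise,
            seed=seeds["clinical"],
        )
        for name in write_cohort(clinical, out / "clinical"):
            _register(f"clinical/{name}")
        manifest.stages.append(stage)

        stage = "population"
        population = simulate_population(
            truth,
            atlas,
            N=config.population_n,
            carrier_counts=config.population_carrier_counts,
            phenome_cfg=config.phenome,
            confound_cfg=config.confounds,
            noise_cfg=config.noise,
            seed=seeds["population"],
        )
        for name in write_cohort(population, out / "population"):
            _register(f"population/{name}")
        manifest.stages.append(stage)

        # --- preprocess --------------------------------------------------
        stage = "preprocess"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            clin_adj, _ = adjust_confounds(
                clinical.volumes, clinical.confounds, CLINICAL_DESIGN
            )
            pop_adj, _ = adjust_confounds(
                population.volumes, population.confounds, POPULATION_DESIGN
            )
        manifest.warnings.extend(str(w.message) for w in caught)

        # --- effect maps -------------------------------------------------
        stage = "effectmaps"
        group = clinical.group
        controls = group.index[group == CONTROL]
        d_maps = {}
        for g in CNV_GROUPS:
            carriers = group.index[group == g]
            subset = carriers.append(controls)
            z = zscore_columns(clin_adj.values.loc[subset], over_subjects=subset)
            d_maps[g] = cohens_d_map(z, carriers, controls, group=g)
        _write_tsv(
            pd.DataFrame(
                {g: d_maps[g].d for g in CNV_GROUPS},
                index=clinical.volumes.columns,
            ),
            "effect_maps.tsv",
        )
        map_sim = similarity_matrix(
            [d_maps[g] for g in CNV_GROUPS],
            atlas,
            n_perm=config.spin_perm,
            seed=seeds["effectmaps"],
            labels=CNV_GROUPS,
            alpha=config.alpha,
        )
        _write_tsv(
            pd.DataFrame(map_sim.r, index=CNV_GROUPS, columns=CNV_GROUPS),
            "map_similarity_r.tsv",
        )
        _write_tsv(
            pd.DataFrame(map_sim.p_fdr, index=CNV_GROUPS, columns=CNV_GROUPS),
            "map_similarity_p_fdr.tsv",
        )
        manifest.stages.append(stage)

        # --- ensembles ---------------------------------------------------
        stage = "ensembles"
        ens_seeds = np.random.SeedSequence(seeds["ensembles"]).spawn(len(CNV_GROUPS))
        signatures = []
        recovery = {}
        for k, (g, child) in enumerate(zip(CNV_GROUPS, ens_seeds)):
            carriers = group.index[group == g]
            subset = carriers.append(controls)
            Xg = clin_adj.values.loc[subset]
            yg = np.concatenate([np.ones(len(carriers)), np.zeros(len(controls))])
            rng = np.random.default_rng(child)
            sig = fit_ensemble(
                Xg,
                yg,
                B=config.B,
                grid=config.grid,
                seed=int(rng.integers(2**31)),
                d_map=d_maps[g],
                group=g,
            )
            if sig.n_invalid:
                manifest.warnings.append(
                    f"{g}: {sig.n_invalid} bootstrap iterations excluded "
                    "(out-of-bag set missed a class)"
                )
            if config.n_perm > 0:
                null, thr = permutation_null(
                    Xg,
                    yg,
                    B=config.B,
                    n_perm=config.n_perm,
                    grid=config.grid,
                    seed=int(rng.integers(2**31)),
                    B_null=config.B_null,
                )
                sig.null_mcc = null
                sig.null_threshold = thr
            signatures.append(sig)
            b = truth.beta[k]
            recovery[g] = abs(float(np.corrcoef(sig.W, b)[0, 1]))
            _write_json(sig.to_json_dict(), f"signatures/{g}.json")
        _write_tsv(
            pd.concat(
                [network_summary(s, atlas).to_frame().assign(group=s.group)
                 for s in signatures],
                ignore_index=True,
            ),
            "network_summary.tsv",
            index=False,
        )
        sig_sim = similarity_matrix(
            [s.W for s in signatures],
            atlas,
            n_perm=config.spin_perm,
            seed=seeds["ensembles"],
            labels=CNV_GROUPS,
            alpha=config.alpha,
        )
        _write_tsv(
            pd.DataFrame(sig_sim.r, index=CNV_GROUPS, columns=CNV_GROUPS),
            "signature_similarity_r.tsv",
        )
        manifest.stages.append(stage)

        # --- transfer ----------------------------------------------------
        stage = "transfer"
        scores = score_expressions(
            pop_adj.values, signatures, adjustment="population-fit residualization"
        )
        manifest.warnings.append(
            f"outlier filter flagged {scores.n_flagged} of {len(scores.values)} subjects"
        )
        _write_tsv(
            scores.values.assign(outlier=scores.outlier.astype(int)),
            "expression_scores.tsv",
        )
        status = population.carrier_status
        tests = []
        trng = np.random.default_rng(seeds["transfer"])
        for g in CNV_GROUPS:
            x = scores.values.loc[status == g, g].to_numpy()
            yv = scores.values.loc[status == NONCARRIER, g].to_numpy()
            if len(x) < 2:
                manifest.warnings.append(
                    f"{g}: fewer than 2 population carriers; expression test skipped"
                )
                continue
            res = bootstrap_mean_test(
                x, yv, B=config.bootstrap_replicates, seed=int(trng.integers(2**31))
            )
            tests.append(
                {
                    "group": g,
                    "mean_difference": res.observed_difference,
                    "p": res.p_value,
                    "n_carriers": res.n_x,
                    "n_noncarriers": res.n_y,
                }
            )
        _write_tsv(pd.DataFrame(tests), "expression_tests.tsv", index=False)
        manifest.stages.append(stage)

        # --- phewas ------------------------------------------------------
        stage = "phewas"
        profiles = run_phewas(scores, population.phenome, alpha=config.alpha)
        hit_counts = {}
        for g, prof in profiles.items():
            n_untestable = int((~prof.table["testable"]).sum())
            if n_untestable:
                manifest.warnings.append(
                    f"{g}: {n_untestable} phenotypes untestable (insufficient pairs)"
                )
            hit_counts[g] = {"bonferroni": prof.n_bonferroni, "fdr": prof.n_fdr}
            _write_tsv(prof.table, f"phewas/{g}.tsv", index=False)
            _write_tsv(
                category_hit_ratio(prof, population.phenome.category_names),
                f"phewas/{g}_category_ratios.tsv",
                index=False,
            )
        shared, top = shared_hits(profiles, min_k=config.shared_hit_min_k)
        _write_tsv(shared, "shared_hits.tsv", index=False)
        _write_tsv(top, "top_phenotypes.tsv", index=False)
        conditioned_hits = None
        if config.run_conditioned_scan:
            cond_profiles = run_phewas(
                condition_out(scores), population.phenome, alpha=config.alpha
            )
            conditioned_hits = {
                g: int(p.table["bonferroni"].sum()) for g, p in cond_profiles.items()
            }
            _write_tsv(
                pd.concat(
                    [
                        category_hit_ratio(p, population.phenome.category_names)
                        .assign(group=g)
                        for g, p in cond_profiles.items()
                    ],
                    ignore_index=True,
                ),
                "conditioned_category_hits.tsv",
                index=False,
            )
        manifest.stages.append(stage)

        # --- report ------------------------------------------------------
        stage = "report"
        prof_sim = profile_similarity(
            profiles, n_perm=config.profile_perm, seed=seeds["report"],
            alpha=config.alpha,
        )
        cat_sim = category_profile_similarity(profiles)
        report = concordance_report(map_sim, prof_sim, cat_sim, shared)
        _write_tsv(
            pd.DataFrame(prof_sim.r, index=CNV_GROUPS, columns=CNV_GROUPS),
            "profile_similarity_r.tsv",
        )
        report_payload = {
            "mean_abs_map_similarity": report.mean_abs_map_similarity,
            "mean_abs_signature_similarity": sig_sim.mean_abs_offdiag,
            "mean_abs_profile_similarity": report.mean_abs_profile_similarity,
            "lin_ccc_maps_vs_profiles": report.lin_ccc,
            "n_pairs_pheno_gt_vol": report.n_pairs_pheno_gt_vol,
            "mean_oob_mcc": {s.group: s.mean_mcc for s in signatures},
            "null_threshold": {
                s.group: s.null_threshold for s in signatures
            },
            "signature_recovery_abs_corr": recovery,
            "bonferroni_hits": hit_counts,
            "conditioned_bonferroni_hits": conditioned_hits,
            "n_outliers_flagged": scores.n_flagged,
        }
        _write_json(report_payload, "report.json")
        manifest.summary = report_payload
        manifest.stages.append(stage)
    except Exception as exc:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.to_json(out / "manifest.json")
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    return manifest
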