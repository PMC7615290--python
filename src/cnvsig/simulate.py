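"""Synthetic clinical and population cohorts with planted CNV signatures.

The generator emulates the statistical structure the downstream analysis
assumes: a small multisite clinical cohort in which carriers of 8 recurrent
CNVs (deletion/duplication at 1q21.1, 15q11.2, 16p11.2, 22q11.2) deviate from
controls along spatially smooth, network-weighted whole-brain maps, and a
large population cohort whose subjects additionally carry a rich phenome whose
couplings to the latent brain signatures have a controllable cross-CNV
convergence level.

Planted structure
-----------------
Each locus has a deletion map ``beta_del`` (unit-norm, mean zero, built from
smooth spherical bumps) and a duplication map

    beta_dup = -mirror_rho * beta_del + sqrt(1 - mirror_rho^2) * orthogonal map

so the deletion/duplication anti-correlation ("mirror effect") equals
``-mirror_rho`` exactly by construction. Every subject ``i`` carries a latent
expression ``t_ik = u_ik + theta_k * 1[i carries k]`` with
``u_ik ~ N(0, latent_sd^2)``; regional volumes load these expressions on the
``beta_k`` directions, scaled so that ``theta`` is the root-mean-square
regional shift in units of the regional noise SD. Phenome values couple
linearly to the latent expressions through a coupling matrix ``gamma`` whose
rows share a common component controlled by ``pheno_convergence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasSpec, InvalidDesignError

CNV_LOCI = ("1q21.1", "15q11.2", "16p11.2", "22q11.2")

#: the 8 carrier groups, deletion before duplication within each locus
CNV_GROUPS = (
    "1q21.1del",
    "1q21.1dup",
    "15q11.2del",
    "15q11.2dup",
    "16p11.2del",
    "16p11.2dup",
    "22q11.2del",
    "22q11.2dup",
)

CONTROL = "control"

#: clinical carrier counts (and 312 controls): 534 carriers in total
CLINICAL_DESIGN_SIZES = {
    "1q21.1del": 24,
    "1q21.1dup": 15,
    "15q11.2del": 112,
    "15q11.2dup": 146,
    "16p11.2del": 80,
    "16p11.2dup": 69,
    "22q11.2del": 69,
    "22q11.2dup": 19,
    CONTROL: 312,
}

#: population-cohort carrier counts (361 carriers, 38,731 non-carriers)
POPULATION_DESIGN_CARRIERS = {
    "1q21.1del": 12,
    "1q21.1dup": 14,
    "15q11.2del": 117,
    "15q11.2dup": 155,
    "16p11.2del": 4,
    "16p11.2dup": 7,
    "22q11.2del": 5,
    "22q11.2dup": 47,
}

#: default population size: the sum of the printed per-group counts
POPULATION_DESIGN_N = 38731 + sum(POPULATION_DESIGN_CARRIERS.values())

NONCARRIER = "non-carrier"

ELEVEN_CATEGORIES = (
    "physical_measures_general",
    "blood_assays",
    "early_life_factors",
    "cognitive",
    "mental_health",
    "lifestyle",
    "sociodemographics",
    "medical_conditions",
    "bone_density_and_sizes",
    "cardiac_and_vascular",
    "diet",
)


def clinical_design_sizes(scale: float = 1.0) -> dict[str, int]:
    """Clinical design group sizes, optionally scaled (rounded, floor of 2)."""
    return {g: max(2, int(round(n * scale))) for g, n in CLINICAL_DESIGN_SIZES.items()}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SignatureConfig:
    """Settings for the planted effect maps and phenome couplings."""

    n_bumps: int = 6  # smooth bumps per map
    bump_concentration: float = 10.0  # vMF-like concentration; higher = more local
    network_gain_sd: float = 0.5  # log-normal per-network emphasis per locus
    mirror_rho: float | tuple = 0.5  # per-locus del/dup anti-correlation in [0, 1]
    theta: float | tuple = 1.0  # per-group effect scale (RMS shift in noise SDs)
    n_phenotypes: int = 200
    pheno_convergence: float = 0.5  # cross-CNV similarity of coupling rows in [0, 1]
    coupling_strength: float = 6.0  # L2 norm of each gamma row
    orthogonalize_loci: bool = False  # force cross-locus map correlations to 0

    def mirror_rho_array(self) -> np.ndarray:
        r = np.broadcast_to(np.asarray(self.mirror_rho, dtype=float), (4,)).copy()
        if (r < 0).any() or (r > 1).any():
            raise InvalidDesignError("mirror_rho must lie in [0, 1]")
        return r

    def theta_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.theta, dtype=float), (8,)).copy()


@dataclass
class ConfoundConfig:
    """Fixed-effect confound loadings shared by all regions."""

    icv_loading: float = 0.5
    age_loading: float = 0.02
    age2_loading: float = -4e-4
    sex_loading: float = 0.3
    bmi_loading: float = 0.1  # population cohort only
    motion_loading: float = 0.2  # population cohort only
    n_sites: int = 3
    site_sd: float = 0.5  # SD of per-site, per-region offsets


@dataclass
class NoiseConfig:
    noise_sd: float = 1.0  # regional measurement noise SD (volume units)
    latent_sd: float = 0.2  # SD of per-subject latent signature expressions
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0


@dataclass
class PhenomeConfig:
    frac_binary: float = 0.25
    frac_ordinal: float = 0.15
    ordinal_levels: int = 4
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    missing_max: float = 0.2
    n_categories: int = 11


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted maps, effect scales and phenome couplings."""

    beta: np.ndarray  # (8, n_regions), unit-norm mean-zero rows
    theta: np.ndarray  # (8,)
    mirror_rho: np.ndarray  # (4,)
    gamma: np.ndarray  # (8, n_phenotypes)
    pheno_convergence: float
    group_names: tuple[str, ...] = CNV_GROUPS

    @property
    def n_regions(self) -> int:
        return self.beta.shape[1]

    @property
    def n_phenotypes(self) -> int:
        return self.gamma.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.tolist(),
            "theta": self.theta.tolist(),
            "mirror_rho": self.mirror_rho.tolist(),
            "gamma": self.gamma.tolist(),
            "pheno_convergence": self.pheno_convergence,
            "group_names": list(self.group_names),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            beta=np.asarray(d["beta"]),
            theta=np.asarray(d["theta"]),
            mirror_rho=np.asarray(d["mirror_rho"]),
            gamma=np.asarray(d["gamma"]),
            pheno_convergence=d["pheno_convergence"],
            group_names=tuple(d["group_names"]),
        )


@dataclass
class PhenomeTable:
    """Subjects x phenotypes with per-phenotype metadata.

    ``values`` uses NaN for missing entries; binary phenotypes take {0, 1},
    ordinal phenotypes consecutive integer levels starting at 1.
    """

    values: pd.DataFrame
    var_type: np.ndarray  # per phenotype: continuous | binary | ordinal
    category: np.ndarray  # per phenotype: 1..n_categories
    category_names: tuple[str, ...] = ELEVEN_CATEGORIES

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phenotype": self.values.columns,
                "var_type": self.var_type,
                "category": self.category,
                "category_name": [self.category_names[c - 1] for c in self.category],
            }
        )


@dataclass
class ClinicalCohort:
    volumes: pd.DataFrame  # subjects x regions
    group: pd.Series  # per-subject label: CNV group or "control"
    confounds: pd.DataFrame  # icv, age, sex, site
    latent_expression: pd.DataFrame = None  # subjects x 8 true expressions

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]


@dataclass
class PopulationCohort:
    volumes: pd.DataFrame
    carrier_status: pd.Series  # "non-carrier" or CNV group
    confounds: pd.DataFrame  # icv, age, sex, site, bmi, motion
    phenome: PhenomeTable = None
    latent_expression: pd.DataFrame = None

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]


# ---------------------------------------------------------------------------
# signature construction
# ---------------------------------------------------------------------------


def _smooth_map(atlas: AtlasSpec, rng: np.random.Generator, cfg: SignatureConfig) -> np.ndarray:
    """Sum of spherical Gaussian bumps, giving spatial autocorrelation."""
    centers = rng.standard_normal((cfg.n_bumps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    weights = rng.standard_normal(cfg.n_bumps)
    # exp(kappa * (cos(angle) - 1)): a vMF-like bump peaking at its center
    cosang = atlas.centroid @ centers.T
    return (np.exp(cfg.bump_concentration * (cosang - 1.0)) * weights).sum(axis=1)


def random_smooth_map(
    atlas: AtlasSpec,
    seed: int | np.random.Generator = 0,
    n_bumps: int = 6,
    concentration: float = 10.0,
) -> np.ndarray:
    """A single spatially smooth random map (sum of spherical bumps), unit RMS.

    Useful on its own for calibrating spatial-null procedures on maps with
    realistic autocorrelation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = SignatureConfig(n_bumps=n_bumps, bump_concentration=concentration)
    v = _smooth_map(atlas, rng, cfg)
    v = v - v.mean()
    norm = np.linalg.norm(v)
    if norm == 0:
        raise InvalidDesignError("degenerate (constant) smooth map")
    return v / norm * np.sqrt(atlas.n_regions)


def _center_unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise InvalidDesignError("degenerate (constant) smooth map; increase n_regions")
    return v / n


def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        v = v - (v @ b) * b
    return v


def make_signatures(
    atlas: AtlasSpec, config: SignatureConfig | None = None, seed: int = 0
) -> GroundTruth:
    """Draw ground-truth effect maps and phenome couplings.

    Deletion maps are smooth, network-weighted, centered unit-norm vectors;
    the duplication map of each locus is an exact ``-mirror_rho`` mixture with
    an orthogonal smooth map, so the planted mirror anti-correlation is exact.
    Coupling rows are ``c * shared + (1 - c) * independent`` with
    ``c = pheno_convergence``, rescaled to ``coupling_strength``.
    """
    cfg = config or SignatureConfig()
    rho = cfg.mirror_rho_array()
    theta = cfg.theta_array()
    c = float(cfg.pheno_convergence)
    if not 0.0 <= c <= 1.0:
        raise InvalidDesignError("pheno_convergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    p = atlas.n_regions
    if cfg.orthogonalize_loci and p < 10:
        raise InvalidDesignError("orthogonalize_loci needs at least 10 regions")

    beta = np.zeros((8, p))
    basis: list[np.ndarray] = []
    for loc in range(4):
        gain = np.exp(cfg.network_gain_sd * rng.standard_normal(atlas.n_networks))
        net_w = gain[atlas.network_label - 1]
        g1 = _smooth_map(atlas, rng, cfg) * net_w
        g2 = _smooth_map(atlas, rng, cfg) * net_w
        g1 = g1 - g1.mean()
        g2 = g2 - g2.mean()
        if cfg.orthogonalize_loci:
            g1 = _orthogonalize(g1, basis)
        u1 = _center_unit(g1)
        g2 = _orthogonalize(g2, basis + [u1])
        u2 = _center_unit(g2)
        beta[2 * loc] = u1
        beta[2 * loc + 1] = -rho[loc] * u1 + np.sqrt(1.0 - rho[loc] ** 2) * u2
        basis.extend([u1, u2])

    shared = rng.standard_normal(cfg.n_phenotypes)
    gamma = np.zeros((8, cfg.n_phenotypes))
    for k in range(8):
        indep = rng.standard_normal(cfg.n_phenotypes)
        row = c * shared + (1.0 - c) * indep
        gamma[k] = row / np.linalg.norm(row) * cfg.coupling_strength

    return GroundTruth(
        beta=beta, theta=theta, mirror_rho=rho, gamma=gamma, pheno_convergence=c
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _simulate_volumes(
    truth: GroundTruth,
    atlas: AtlasSpec,
    group: np.ndarray,
    confound_matrix: np.ndarray,
    loadings: np.ndarray,
    site_idx: np.ndarray,
    noise: NoiseConfig,
    site_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Volumes = baseline + site offset + confound loadings + planted signal + noise.

    Returns (volumes, latent expressions t of shape (n, 8)).
    """
    n = group.shape[0]
    p = atlas.n_regions
    if truth.n_regions != p:
        raise InvalidDesignError("ground truth and atlas disagree on region count")
    baseline = noise.baseline_mean + noise.baseline_sd * rng.standard_normal(p)
    n_sites = int(site_idx.max()) + 1
    site_offsets = site_sd * rng.standard_normal((n_sites, p))

    t = noise.latent_sd * rng.standard_normal((n, 8))
    for k, g in enumerate(truth.group_names):
        t[group == g, k] += truth.theta[k]

    signal = np.sqrt(p) * (t @ truth.beta)
    eps = rng.standard_normal((n, p))
    vol = (
        baseline[None, :]
        + site_offsets[site_idx]
        + confound_matrix @ loadings
        + noise.noise_sd * (signal + eps)
    )
    return vol, t


def _check_sizes(sizes: dict[str, int]) -> None:
    expected = set(CNV_GROUPS) | {CONTROL}
    if set(sizes) != expected:
        raise InvalidDesignError(
            f"sizes must have 9 entries (8 CNV groups + control); got {sorted(sizes)}"
        )
    for g, n in sizes.items():
        if n < 2:
            raise InvalidDesignError(f"group {g!r} has size {n} < 2")


def simulate_clinical(
    truth: GroundTruth,
    atlas: AtlasSpec,
    sizes: dict[str, int] | None = None,
    confound_cfg: ConfoundConfig | None = None,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
) -> ClinicalCohort:
    """Simulate the multisite clinical cohort (default design: 534 carriers, 312 controls)."""
    sizes = dict(sizes) if sizes is not None else dict(CLINICAL_DESIGN_SIZES)
    _check_sizes(sizes)
    ccfg = confound_cfg or ConfoundConfig()
    ncfg = noise_cfg or NoiseConfig()
    if ccfg.n_sites < 2:
        raise InvalidDesignError("clinical cohort needs >= 2 sites")
    rng = np.random.default_rng(seed)

    group = np.concatenate(
        [np.repeat(g, sizes[g]) for g in (*CNV_GROUPS, CONTROL)]
    )
    n = group.shape[0]
    icv = rng.normal(1.4, 0.12, n)
    age = rng.uniform(6.0, 64.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    site_idx = rng.integers(0, ccfg.n_sites, n)

    X = np.column_stack([icv, age, age**2, sex])
    loads = np.array(
        [ccfg.icv_loading, ccfg.age_loading, ccfg.age2_loading, ccfg.sex_loading]
    )
    vol, t = _simulate_volumes(
        truth, atlas, group, X, np.outer(loads, np.ones(atlas.n_regions)),
        site_idx, ncfg, ccfg.site_sd, rng,
    )

    subjects = [f"clin{i:05d}" for i in range(n)]
    regions = [f"r{j:04d}" for j in range(atlas.n_regions)]
    return ClinicalCohort(
        volumes=pd.DataFrame(vol, index=subjects, columns=regions),
        group=pd.Series(group, index=subjects, name="group"),
        confounds=pd.DataFrame(
            {
                "icv": icv,
                "age": age,
                "sex": sex,
                "site": [f"site{s + 1:02d}" for s in site_idx],
            },
            index=subjects,
        ),
        latent_expression=pd.DataFrame(t, index=subjects, columns=list(CNV_GROUPS)),
    )


def simulate_population(
    truth: GroundTruth,
    atlas: AtlasSpec,
    N: int = POPULATION_DESIGN_N,
    carrier_counts: dict[str, int] | None = None,
    phenome_cfg: PhenomeConfig | None = None,
    confound_cfg: ConfoundConfig | None = None,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
) -> PopulationCohort:
    """Simulate the population cohort with carriers, confounds and a phenome.

    Default carrier counts follow the population-cohort design (361 carriers;
    at N = 39,085 this leaves 38,731 non-carriers).
    """
    counts = dict(carrier_counts) if carrier_counts is not None else dict(POPULATION_DESIGN_CARRIERS)
    if set(counts) != set(CNV_GROUPS):
        raise InvalidDesignError("carrier_counts must cover exactly the 8 CNV groups")
    n_carriers = sum(counts.values())
    if n_carriers >= N:
        raise InvalidDesignError(
            f"carrier total {n_carriers} must be < cohort size {N}"
        )
    pcfg = phenome_cfg or PhenomeConfig()
    ccfg = confound_cfg or ConfoundConfig()
    ncfg = noise_cfg or NoiseConfig()
    rng = np.random.default_rng(seed)

    status = np.concatenate(
        [np.repeat(g, counts[g]) for g in CNV_GROUPS]
        + [np.repeat(NONCARRIER, N - n_carriers)]
    )
    rng.shuffle(status)

    icv = rng.normal(1.4, 0.12, N)
    age = rng.normal(55.0, 7.5, N)
    sex = rng.integers(0, 2, N).astype(float)
    bmi = rng.normal(27.0, 4.0, N)
    motion = rng.gamma(2.0, 0.1, N)
    site_idx = rng.integers(0, ccfg.n_sites, N)

    X = np.column_stack([icv, age, age**2, sex, bmi, motion])
    loads = np.array(
        [
            ccfg.icv_loading,
            ccfg.age_loading,
            ccfg.age2_loading,
            ccfg.sex_loading,
            ccfg.bmi_loading,
            ccfg.motion_loading,
        ]
    )
    vol, t = _simulate_volumes(
        truth, atlas, status, X, np.outer(loads, np.ones(atlas.n_regions)),
        site_idx, ncfg, ccfg.site_sd, rng,
    )

    subjects = [f"pop{i:06d}" for i in range(N)]
    regions = [f"r{j:04d}" for j in range(atlas.n_regions)]
    phenome = _simulate_phenome(truth, t, pcfg, subjects, rng)

    return PopulationCohort(
        volumes=pd.DataFrame(vol, index=subjects, columns=regions),
        carrier_status=pd.Series(status, index=subjects, name="carrier_status"),
        confounds=pd.DataFrame(
            {
                "icv": icv,
                "age": age,
                "sex": sex,
                "site": [f"popsite{s + 1:02d}" for s in site_idx],
                "bmi": bmi,
                "motion": motion,
            },
            index=subjects,
        ),
        phenome=phenome,
        latent_expression=pd.DataFrame(t, index=subjects, columns=list(CNV_GROUPS)),
    )


def _simulate_phenome(
    truth: GroundTruth,
    t: np.ndarray,
    cfg: PhenomeConfig,
    subjects: list[str],
    rng: np.random.Generator,
) -> PhenomeTable:
    N = t.shape[0]
    P = truth.n_phenotypes
    if not 0.0 <= cfg.missing_rate <= cfg.missing_max <= 1.0:
        raise InvalidDesignError("need 0 <= missing_rate <= missing_max <= 1")

    latent = t @ truth.gamma + cfg.noise_sd * rng.standard_normal((N, P))

    # variable types and categories
    u = rng.random(P)
    var_type = np.where(
        u < cfg.frac_binary,
        "binary",
        np.where(u < cfg.frac_binary + cfg.frac_ordinal, "ordinal", "continuous"),
    )
    category = 1 + (np.arange(P) % cfg.n_categories)
    rng.shuffle(category)

    values = latent.copy()
    for q in range(P):
        if var_type[q] == "binary":
            prev = rng.uniform(0.2, 0.8)
            thr = np.quantile(latent[:, q], 1.0 - prev)
            values[:, q] = (latent[:, q] > thr).astype(float)
        elif var_type[q] == "ordinal":
            edges = np.quantile(
                latent[:, q], np.linspace(0, 1, cfg.ordinal_levels + 1)[1:-1]
            )
            values[:, q] = 1.0 + np.searchsorted(edges, latent[:, q])

    miss = rng.random((N, P)) < cfg.missing_rate
    values[miss] = np.nan

    names = [f"pheno{q:04d}" for q in range(P)]
    if cfg.n_categories == 11:
        cat_names = ELEVEN_CATEGORIES
    else:
        cat_names = tuple(f"category_{i + 1}" for i in range(cfg.n_categories))
    return PhenomeTable(
        values=pd.DataFrame(values, index=subjects, columns=names),
        var_type=var_type,
        category=category,
        category_names=cat_names,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_cohort(cohort, out_dir) -> list[str]:
    """Write a cohort's tables as TSV; returns the filenames written."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df, name):
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.12g")
        written.append(name)

    _w(cohort.volumes, "volumes.tsv")
    _w(cohort.confounds, "confounds.tsv")
    if isinstance(cohort, ClinicalCohort):
        _w(cohort.group.to_frame(), "labels.tsv")
    else:
        _w(cohort.carrier_status.to_frame(), "labels.tsv")
        if cohort.phenome is not None:
            _w(cohort.phenome.values, "phenome.tsv")
            meta = cohort.phenome.metadata().set_index("phenotype")
            _w(meta, "phenome_metadata.tsv")
    if cohort.latent_expression is not None:
        _w(cohort.latent_expression, "latent_expression.tsv")
    return written
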