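"""Regional effect sizes and spatially-aware brain-map comparison.

Per-region effect sizes between a carrier group and controls use Cohen's d
with the pooled-SD denominator

    d = (x1_bar - x2_bar) / sqrt((s1^2 + s2^2) / 2),

with sample SDs (n-1 divisor). Brain maps are compared with Pearson's r, and
the significance of a map-map correlation is assessed against a spin
permutation null: parcel centroids are rotated by Haar-uniform random 3-D
rotations and each parcel is reassigned the value of the parcel whose
original centroid lies nearest to the rotated position. The spin null
preserves the spatial autocorrelation of the maps, which a value-shuffling
null would destroy. Agreement between two sets of similarities is quantified
by Lin's concordance correlation coefficient

    rho_c = 2 * s12 / (s1^2 + s2^2 + (x1_bar - x2_bar)^2),

with population (n divisor) variances and covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._utils import bh_fdr, pearson_r
from .atlas import AtlasSpec


@dataclass
class EffectSizeMap:
    """Per-region Cohen's d with the group summaries behind it."""

    d: np.ndarray
    mean_carriers: np.ndarray
    mean_controls: np.ndarray
    sd_carriers: np.ndarray
    sd_controls: np.ndarray
    n_carriers: int
    n_controls: int
    group: str = ""


@dataclass
class ConcordanceResult:
    rho_c: float
    covariance: float  # s12, n divisor
    var_x: float
    var_y: float
    mean_x: float
    mean_y: float


@dataclass
class MapSimilarityMatrix:
    """Pairwise Pearson r between 8 maps with spin p-values."""

    r: np.ndarray  # (m, m) symmetric, unit diagonal
    p_spin: np.ndarray  # (m, m), NaN diagonal
    p_fdr: np.ndarray  # BH-adjusted across the off-diagonal pairs
    n_perm: int
    labels: tuple[str, ...] = ()

    @property
    def mean_abs_offdiag(self) -> float:
        """The 'average similarity': mean |r| over distinct pairs."""
        m = self.r.shape[0]
        iu = np.triu_indices(m, k=1)
        return float(np.abs(self.r[iu]).mean())

    def pair_values(self) -> np.ndarray:
        iu = np.triu_indices(self.r.shape[0], k=1)
        return self.r[iu]


def cohens_d_map(
    volumes, carriers, controls, group: str = ""
) -> EffectSizeMap:
    """Cohen's d per region between a carrier subset and a control subset.

    ``volumes`` is a subjects x regions DataFrame (typically confound-adjusted
    and z-scored across the two groups); ``carriers``/``controls`` are subject
    labels.
    """
    x1 = volumes.loc[carriers].to_numpy(dtype=float)
    x2 = volumes.loc[controls].to_numpy(dtype=float)
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("both groups need at least 2 subjects")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    s1, s2 = x1.std(axis=0, ddof=1), x2.std(axis=0, ddof=1)
    denom_sq = (s1**2 + s2**2) / 2.0
    if (denom_sq == 0).any():
        bad = list(np.asarray(volumes.columns)[denom_sq == 0])
        raise ValueError(f"both group variances are zero in regions: {bad}")
    d = (m1 - m2) / np.sqrt(denom_sq)
    return EffectSizeMap(
        d=d,
        mean_carriers=m1,
        mean_controls=m2,
        sd_carriers=s1,
        sd_controls=s2,
        n_carriers=x1.shape[0],
        n_controls=x2.shape[0],
        group=group,
    )


def lin_ccc(x, y) -> ConcordanceResult:
    """Lin's concordance correlation coefficient (population-form moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx = float(np.mean((x - mx) ** 2))
    vy = float(np.mean((y - my) ** 2))
    if vx == 0.0 and vy == 0.0:
        raise ValueError("concordance undefined: both vectors are constant")
    s12 = float(np.mean((x - mx) * (y - my)))
    rho_c = 2.0 * s12 / (vx + vy + (mx - my) ** 2)
    return ConcordanceResult(
        rho_c=float(rho_c), covariance=s12, var_x=vx, var_y=vy,
        mean_x=float(mx), mean_y=float(my),
    )


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform 3-D rotations: QR of a Gaussian matrix with sign fixing."""
    A = rng.standard_normal((n, 3, 3))
    Q, R = np.linalg.qr(A)
    # make the decomposition unique (R diagonal positive), then force det = +1
    sign = np.sign(np.einsum("nii->ni", R))
    sign[sign == 0] = 1.0
    Q = Q * sign[:, None, :]
    det = np.linalg.det(Q)
    Q[det < 0, :, 2] *= -1.0
    return Q


def spin_maps(
    values: np.ndarray, atlas: AtlasSpec, rotations: np.ndarray
) -> np.ndarray:
    """Apply parcel spins: value of the nearest original centroid to each rotated one.

    Nearest-centroid reassignment may map two rotated parcels to the same
    source parcel (values duplicated); this is the simplest well-defined
    parcel-level spin.
    """
    c = atlas.centroid
    rotated = np.einsum("nij,pj->npi", rotations, c)
    # nearest on the unit sphere == maximal dot product
    nearest = np.argmax(np.einsum("npi,qi->npq", rotated, c), axis=2)
    return np.asarray(values, dtype=float)[nearest]


def spin_test(
    map_a,
    map_b,
    atlas: AtlasSpec,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, np.ndarray]:
    """Two-sided spin-permutation test of the correlation between two maps.

    Returns (observed r, p-value, null r distribution). ``map_b`` is spun;
    p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != (atlas.n_regions,) or b.shape != (atlas.n_regions,):
        raise ValueError("maps must have one value per atlas region")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    r_obs = pearson_r(a, b)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rot = random_rotations(n_perm, rng)
    spun = spin_maps(b, atlas, rot)

    ac = a - a.mean()
    sc = spun - spun.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac @ ac) * np.einsum("np,np->n", sc, sc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_null = (sc @ ac) / denom
    r_null = np.where(np.isfinite(r_null), r_null, 0.0)
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (n_perm + 1.0)
    return r_obs, float(p), r_null


def similarity_matrix(
    maps,
    atlas: AtlasSpec,
    n_perm: int = 1000,
    seed: int = 0,
    labels: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> MapSimilarityMatrix:
    """Pairwise map similarity with spin p-values and BH-FDR across pairs.

    ``maps`` is a sequence of per-region vectors (e.g. the 8 CNV Cohen's d
    maps, or the 8 averaged signature vectors).
    """
    M = np.asarray(
        [m.d if isinstance(m, EffectSizeMap) else np.asarray(m, float) for m in maps]
    )
    m = M.shape[0]
    if M.shape[1] != atlas.n_regions:
        raise ValueError("maps must have one value per atlas region")

    r = np.eye(m)
    p = np.full((m, m), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(m), 2):
        r_ij, p_ij, _ = spin_test(M[i], M[j], atlas, n_perm=n_perm, seed=rng)
        r[i, j] = r[j, i] = r_ij
        p[i, j] = p[j, i] = p_ij

    iu = np.triu_indices(m, k=1)
    _, p_adj = bh_fdr(p[iu], alpha=alpha)
    p_fdr = np.full((m, m), np.nan)
    p_fdr[iu] = p_adj
    p_fdr.T[iu] = p_adj
    return MapSimilarityMatrix(
        r=r, p_spin=p, p_fdr=p_fdr, n_perm=n_perm, labels=tuple(labels)
    )
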