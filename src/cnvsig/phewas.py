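"""Signature transfer, phenome-wide scans and convergence reporting.

A fitted signature ``W_k`` is carried into a population cohort by scoring
each subject's confound-adjusted volumes as the dot product ``x_i . W_k``
("expression" of intermediate phenotype k). Downstream:

* Tukey's interquartile-range rule discards subjects with outlying
  expressions (union across the 8 signature columns) before any scan.
* A two-sample bootstrap mean test validates that carriers of CNV k express
  signature k more strongly than non-carriers.
* The PheWAS correlates each expression column with every phenotype
  (pairwise-complete Pearson, binary/ordinal phenotypes treated as numeric
  scores) under Bonferroni and Benjamini-Hochberg control.
* Profile similarity compares the 8 length-P vectors of PheWAS correlations
  across CNVs, and the concordance report contrasts this phenotypic
  similarity structure with the volumetric (Cohen's d map) similarity
  structure via Lin's concordance coefficient and a pairwise win count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import bh_fdr, pearson_p_from_r
from .effects import MapSimilarityMatrix, lin_ccc
from .simulate import PhenomeTable


@dataclass
class ExpressionScores:
    """Per-subject expressions of the 8 intermediate phenotypes."""

    values: pd.DataFrame  # subjects x CNV groups
    outlier: pd.Series  # bool per subject; flagged subjects leave all scans
    signature_version: str = ""
    adjustment: str = ""

    def filtered(self) -> pd.DataFrame:
        return self.values.loc[~self.outlier]

    @property
    def n_flagged(self) -> int:
        return int(self.outlier.sum())


@dataclass
class BootstrapTestResult:
    observed_difference: float
    n_replicates: int
    p_value: float
    n_x: int
    n_y: int


@dataclass
class PheWASProfile:
    """One CNV's phenome scan: per-phenotype r, p, n and multiplicity flags."""

    table: pd.DataFrame  # phenotype, category, r, p, n, testable, bonferroni, fdr
    group: str
    alpha: float
    n_tested: int

    @property
    def n_bonferroni(self) -> int:
        return int(self.table["bonferroni"].sum())

    @property
    def n_fdr(self) -> int:
        return int(self.table["fdr"].sum())

    def r_vector(self) -> pd.Series:
        return self.table.set_index("phenotype")["r"]


@dataclass
class ConvergenceReport:
    """Volumetric divergence versus phenotypic convergence, in one object."""

    profile_similarity: np.ndarray  # (8, 8)
    map_similarity: np.ndarray  # (8, 8)
    mean_abs_profile_similarity: float
    mean_abs_map_similarity: float
    lin_ccc: float  # between the 28 paired |r| values
    n_pairs_pheno_gt_vol: int  # of 28
    labels: tuple[str, ...] = ()
    category_similarity: dict = field(default_factory=dict)
    shared_hits: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# scoring and outlier handling
# ---------------------------------------------------------------------------


def score_expressions(
    adjusted_volumes: pd.DataFrame,
    signatures,
    flag_outliers: bool = True,
    adjustment: str = "",
) -> ExpressionScores:
    """Dot product of each subject's adjusted volumes with each signature W.

    ``signatures`` is a sequence of EnsembleSignature (region names, when
    present, must match the volume columns in order).
    """
    sigs = list(signatures)
    X = adjusted_volumes.to_numpy(dtype=float)
    cols = tuple(map(str, adjusted_volumes.columns))
    Wmat = []
    names = []
    for s in sigs:
        if s.region_names and tuple(s.region_names) != cols:
            raise ValueError(
                f"region identifiers of signature {s.group!r} do not match the "
                "volume columns (order matters)"
            )
        if len(s.W) != X.shape[1]:
            raise ValueError("signature length does not match region count")
        Wmat.append(s.W)
        names.append(s.group or f"sig{len(names)}")
    scores = pd.DataFrame(
        X @ np.asarray(Wmat).T, index=adjusted_volumes.index, columns=names
    )
    if flag_outliers and len(scores) >= 4:
        flags = tukey_filter(scores)
    else:
        flags = pd.Series(False, index=scores.index, name="outlier")
    return ExpressionScores(
        values=scores,
        outlier=flags,
        signature_version=",".join(names),
        adjustment=adjustment,
    )


def tukey_filter(scores) -> pd.Series:
    """Tukey IQR fences per column; a subject flagged on any column is out.

    Fences are Q1 - 1.5*IQR and Q3 + 1.5*IQR with linear-interpolation
    quartiles; values strictly outside the fences are flagged. A constant
    column flags nobody.
    """
    df = scores.values if isinstance(scores, ExpressionScores) else scores
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError("Tukey fences need at least 4 subjects")
    q1, q3 = np.percentile(X, [25, 75], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = (X < lo) | (X > hi)
    return pd.Series(flagged.any(axis=1), index=df.index, name="outlier")


def bootstrap_mean_test(
    x, y, B: int = 10000, seed: int = 0
) -> BootstrapTestResult:
    """Two-sample bootstrap test of a mean difference.

    The null is enforced by recentering both groups on the pooled mean;
    ``B`` within-group resamples give the null distribution of the mean
    difference and the two-sided p-value (floor 1/(B+1)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 values")
    obs = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y]).mean()
    xs = x - x.mean() + pooled
    ys = y - y.mean() + pooled
    rng = np.random.default_rng(seed)
    bx = xs[rng.integers(0, x.size, size=(B, x.size))].mean(axis=1)
    by = ys[rng.integers(0, y.size, size=(B, y.size))].mean(axis=1)
    t_null = bx - by
    p = (1.0 + np.sum(np.abs(t_null) >= abs(obs))) / (B + 1.0)
    return BootstrapTestResult(
        observed_difference=obs,
        n_replicates=B,
        p_value=float(p),
        n_x=x.size,
        n_y=y.size,
    )


# ---------------------------------------------------------------------------
# the phenome-wide scan
# ---------------------------------------------------------------------------


def _masked_pearson(
    s: np.ndarray, Y: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of one score vector against each column of Y on complete pairs."""
    n = mask.sum(axis=0).astype(float)
    Ym = np.where(mask, Y, 0.0)
    sy = Ym.sum(axis=0)
    syy = (Ym * Ym).sum(axis=0)
    ss = mask.T @ s
    sss = mask.T @ (s * s)
    ssy = Ym.T @ s
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * ssy - ss * sy
        var_s = n * sss - ss * ss
        var_y = n * syy - sy * sy
        r = cov / np.sqrt(var_s * var_y)
    return r, n


def run_phewas(
    scores: ExpressionScores | pd.DataFrame,
    phenome: PhenomeTable,
    alpha: float = 0.05,
    min_n: int = 10,
) -> dict[str, PheWASProfile]:
    """Correlate each signature expression with every phenotype.

    Outlier-flagged subjects are excluded up front. Correlations use
    pairwise-complete cases; a phenotype with fewer than ``min_n`` complete
    pairs (or no variance on them) is marked untestable and excluded from the
    multiplicity counts. Bonferroni uses alpha / (number testable);
    Benjamini-Hochberg runs across the testable phenotypes of each CNV's scan.
    """
    values = scores.filtered() if isinstance(scores, ExpressionScores) else scores
    common = values.index.intersection(phenome.values.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between scores and phenome")
    S = values.loc[common].to_numpy(dtype=float)
    Y = phenome.values.loc[common].to_numpy(dtype=float)
    mask = ~np.isnan(Y)
    profiles: dict[str, PheWASProfile] = {}
    pheno_names = np.asarray(phenome.values.columns)

    for k, grp in enumerate(values.columns):
        r, n = _masked_pearson(S[:, k], Y, mask)
        testable = (n >= min_n) & np.isfinite(r)
        m = int(testable.sum())
        p = np.full(r.shape, np.nan)
        p[testable] = pearson_p_from_r(r[testable], n[testable])
        bonf = np.zeros(r.shape, dtype=bool)
        if m > 0:
            bonf[testable] = p[testable] <= alpha / m
        fdr, _ = bh_fdr(np.where(testable, p, np.nan), alpha=alpha)
        table = pd.DataFrame(
            {
                "phenotype": pheno_names,
                "category": phenome.category,
                "var_type": phenome.var_type,
                "r": np.where(testable, r, np.nan),
                "p": p,
                "n": n.astype(int),
                "testable": testable,
                "bonferroni": bonf,
                "fdr": fdr,
            }
        )
        profiles[str(grp)] = PheWASProfile(
            table=table, group=str(grp), alpha=alpha, n_tested=m
        )
    return profiles


def category_hit_ratio(profile: PheWASProfile, category_names=None) -> pd.DataFrame:
    """Per category: Bonferroni hits / testable phenotypes (NaN when empty)."""
    t = profile.table[profile.table["testable"]]
    hits = t.groupby("category")["bonferroni"].sum()
    totals = t.groupby("category")["bonferroni"].count()
    cats = sorted(set(profile.table["category"]))
    rows = []
    for c in cats:
        n_tot = int(totals.get(c, 0))
        n_hit = int(hits.get(c, 0))
        rows.append(
            {
                "category": c,
                "category_name": (
                    category_names[c - 1] if category_names is not None else str(c)
                ),
                "n_phenotypes": n_tot,
                "n_hits": n_hit,
                "ratio": n_hit / n_tot if n_tot > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-CNV profile structure
# ---------------------------------------------------------------------------


def _profile_matrix(profiles: dict[str, PheWASProfile]) -> tuple[np.ndarray, list[str]]:
    groups = list(profiles)
    first = profiles[groups[0]].table["phenotype"]
    for g in groups[1:]:
        if not profiles[g].table["phenotype"].equals(first):
            raise ValueError("profiles must share the same phenotype set and order")
    R = np.vstack([profiles[g].table["r"].to_numpy() for g in groups])
    return R, groups


def profile_similarity(
    profiles: dict[str, PheWASProfile],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MapSimilarityMatrix:
    """Pairwise Pearson r between the CNVs' PheWAS correlation vectors.

    Untestable phenotypes are dropped pairwise. Significance comes from
    phenotype-label permutation (the P correlation entries are mutually
    dependent, so a t approximation would be anti-conservative); BH-FDR runs
    across the pairs.
    """
    R, groups = _profile_matrix(profiles)
    m = len(groups)
    rng = np.random.default_rng(seed)
    r = np.eye(m)
    p = np.full((m, m), np.nan)
    for i, j in combinations(range(m), 2):
        ok = np.isfinite(R[i]) & np.isfinite(R[j])
        xi, xj = R[i, ok], R[j, ok]
        if ok.sum() < 3 or np.ptp(xi) == 0 or np.ptp(xj) == 0:
            r[i, j] = r[j, i] = np.nan
            continue
        xic = xi - xi.mean()
        xjc = xj - xj.mean()
        denom = np.sqrt((xic @ xic) * (xjc @ xjc))
        r_obs = float(xic @ xjc / denom)
        perm_idx = np.array([rng.permutation(ok.sum()) for _ in range(n_perm)])
        r_null = (xjc[perm_idx] @ xic) / denom
        p_ij = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (n_perm + 1.0)
        r[i, j] = r[j, i] = r_obs
        p[i, j] = p[j, i] = p_ij
    iu = np.triu_indices(m, k=1)
    _, p_adj = bh_fdr(p[iu], alpha=alpha)
    p_fdr = np.full((m, m), np.nan)
    p_fdr[iu] = p_adj
    p_fdr.T[iu] = p_adj
    return MapSimilarityMatrix(
        r=r, p_spin=p, p_fdr=p_fdr, n_perm=n_perm, labels=tuple(groups)
    )


def category_profile_similarity(
    profiles: dict[str, PheWASProfile], n_perm: int = 0, seed: int = 0
) -> dict[int, np.ndarray]:
    """Profile similarity restricted to each phenotype category.

    A category with fewer than 2 testable phenotypes yields an all-NaN matrix
    (similarity undefined).
    """
    R, groups = _profile_matrix(profiles)
    cats = profiles[groups[0]].table["category"].to_numpy()
    m = len(groups)
    out: dict[int, np.ndarray] = {}
    for c in sorted(set(cats)):
        sel = cats == c
        mat = np.full((m, m), np.nan)
        np.fill_diagonal(mat, 1.0)
        for i, j in combinations(range(m), 2):
            ok = sel & np.isfinite(R[i]) & np.isfinite(R[j])
            if ok.sum() < 2:
                continue
            xi, xj = R[i, ok], R[j, ok]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            xic, xjc = xi - xi.mean(), xj - xj.mean()
            mat[i, j] = mat[j, i] = float(
                xic @ xjc / np.sqrt((xic @ xic) * (xjc @ xjc))
            )
        out[int(c)] = mat
    return out


def shared_hits(
    profiles: dict[str, PheWASProfile], min_k: int = 1, top_n: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotypes significant (Bonferroni) in at least ``min_k`` CNV scans.

    Returns (shared-hit table ordered by mean |r| across scans, top-``top_n``
    phenotypes by mean absolute correlation regardless of significance).
    """
    R, groups = _profile_matrix(profiles)
    if not 1 <= min_k <= len(groups):
        raise ValueError(f"min_k must lie in 1..{len(groups)}, got {min_k}")
    B = np.vstack([profiles[g].table["bonferroni"].to_numpy() for g in groups])
    t0 = profiles[groups[0]].table
    mean_abs_r = np.nanmean(np.abs(R), axis=0)
    base = pd.DataFrame(
        {
            "phenotype": t0["phenotype"],
            "category": t0["category"],
            "n_significant_cnvs": B.sum(axis=0),
            "mean_abs_r": mean_abs_r,
        }
    )
    shared = (
        base[base["n_significant_cnvs"] >= min_k]
        .sort_values("mean_abs_r", ascending=False)
        .reset_index(drop=True)
    )
    top = base.sort_values("mean_abs_r", ascending=False).head(top_n).reset_index(drop=True)
    return shared, top


def condition_out(scores: ExpressionScores) -> ExpressionScores:
    """Residualize each expression column on the other columns (OLS + intercept).

    Isolates each CNV signature's unique variation; rerunning the PheWAS on
    the residualized scores shows which associations are CNV-specific rather
    than shared.
    """
    V = scores.values.to_numpy(dtype=float)
    n, k = V.shape
    resid = np.empty_like(V)
    for j in range(k):
        others = np.delete(V, j, axis=1)
        X = np.column_stack([np.ones(n), others])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"expression columns are collinear; cannot condition out "
                f"column {scores.values.columns[j]!r}"
            )
        coef, *_ = np.linalg.lstsq(X, V[:, j], rcond=None)
        resid[:, j] = V[:, j] - X @ coef
    return ExpressionScores(
        values=pd.DataFrame(
            resid, index=scores.values.index, columns=scores.values.columns
        ),
        outlier=scores.outlier.copy(),
        signature_version=scores.signature_version + "|conditioned",
        adjustment=scores.adjustment,
    )


def concordance_report(
    map_similarity: MapSimilarityMatrix,
    profile_sim: MapSimilarityMatrix,
    category_similarity: dict | None = None,
    shared: pd.DataFrame | None = None,
) -> ConvergenceReport:
    """Contrast volumetric and phenotypic similarity structure across CNV pairs.

    Pairs the 28 off-diagonal |r| values of the two matrices, computes Lin's
    concordance between them, and counts pairs where phenotypic similarity
    exceeds volumetric similarity.
    """
    A, P = map_similarity.r, profile_sim.r
    if A.shape != P.shape:
        raise ValueError("similarity matrices must have matching dimensions")
    iu = np.triu_indices(A.shape[0], k=1)
    vol = np.abs(A[iu])
    phe = np.abs(P[iu])
    if (vol == 0).all() or (phe == 0).all():
        raise ValueError("concordance undefined: all similarities are zero in one matrix")
    ccc = lin_ccc(vol, phe)
    return ConvergenceReport(
        profile_similarity=P,
        map_similarity=A,
        mean_abs_profile_similarity=float(np.nanmean(phe)),
        mean_abs_map_similarity=float(np.nanmean(vol)),
        lin_ccc=ccc.rho_c,
        n_pairs_pheno_gt_vol=int(np.sum(phe > vol)),
        labels=profile_sim.labels or map_similarity.labels,
        category_similarity=category_similarity or {},
        shared_hits=shared,
    )
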