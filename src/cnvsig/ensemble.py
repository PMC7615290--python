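"""Bagged shrinkage-LDA intermediate phenotypes.

Each CNV's "intermediate phenotype" is the average of discriminant vectors
from an ensemble of regularized linear discriminant analyses fit to
bootstrap resamples of carriers-vs-controls. The pieces:

* **Shrunk covariance**: ``(1 - alpha) * S + alpha * (trace(S) / p) * I`` where
  ``S`` is the maximum-likelihood (n-divisor) pooled within-class covariance.
  Shrinkage stabilizes inversion when regions outnumber subjects.
* **Binary LDA**: ``w = Sigma(alpha)^{-1} (mu1 - mu0)``; classify to the
  carrier class when ``w'x > w'(mu0 + mu1)/2 - log(pi1/pi0)`` with empirical
  class priors.
* **Nested model selection**: per bootstrap, the shrinkage level is chosen on
  the in-bag set by exact leave-one-out, pooling all LOO predictions into one
  confusion matrix scored with the Matthews correlation coefficient (MCC);
  ties go to the smallest alpha. The LOO refits are exact but cheap: the
  pooled scatter is rank-one downdated per left-out subject and the shrunk
  systems for the whole alpha grid are solved in one batched call.
* **Bagging**: stratified bootstrap (class counts preserved), honest
  evaluation on the out-of-bag subjects via MCC, sign alignment of each
  discriminant to the group's Cohen's d map, unit-normalization, averaging,
  and per-region bootstrap percentile intervals giving a significance mask.
* **Permutation null**: the entire bagged procedure rerun under shuffled
  labels; the observed mean MCC is compared with the 97.5th percentile of the
  null mean-MCC distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from ._utils import pearson_r
from .atlas import AtlasSpec
from .effects import EffectSizeMap

#: the shrinkage search grid: 11 values between 0 and 1 in steps of 0.1
DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


class DegenerateEmbeddingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# covariance and binary LDA
# ---------------------------------------------------------------------------


@dataclass
class ShrunkCovariance:
    alpha: float
    matrix: np.ndarray


@dataclass
class BinaryLDAModel:
    w: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    alpha: float
    priors: tuple[float, float]
    threshold: float

    def decision(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w - self.threshold

    def predict(self, X) -> np.ndarray:
        return (self.decision(X) > 0).astype(int)


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"shrinkage alpha must lie in [0, 1], got {alpha}")
    return alpha


def shrunk_covariance(X, alpha: float) -> ShrunkCovariance:
    """Convex interpolation between the ML covariance of X and a scaled identity."""
    alpha = _check_alpha(alpha)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / X.shape[0]
    return ShrunkCovariance(alpha=alpha, matrix=_shrink(S, alpha))


def _shrink(S: np.ndarray, alpha: float) -> np.ndarray:
    p = S.shape[0]
    out = (1.0 - alpha) * S
    out[np.diag_indices(p)] += alpha * np.trace(S) / p
    return out


def _pooled_within(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled within-class ML covariance and the two class means."""
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Xc = np.concatenate([X0 - mu0, X1 - mu1])
    S = Xc.T @ Xc / X.shape[0]
    return S, mu0, mu1


def fit_binary_lda(X, y, alpha: float) -> BinaryLDAModel:
    """Shrinkage-regularized LDA for carriers (y=1) versus controls (y=0)."""
    alpha = _check_alpha(alpha)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    S, mu0, mu1 = _pooled_within(X, y)
    Sigma = _shrink(S, alpha)
    try:
        cho = sla.cho_factor(Sigma, check_finite=False)
        w = sla.cho_solve(cho, mu1 - mu0, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"shrunk covariance is singular at alpha={alpha} with "
            f"p={X.shape[1]} features and n={X.shape[0]} samples; "
            "use alpha > 0"
        ) from exc
    pi0, pi1 = n0 / len(y), n1 / len(y)
    threshold = float(w @ (mu0 + mu1) / 2.0 - np.log(pi1 / pi0))
    return BinaryLDAModel(
        w=w, mu0=mu0, mu1=mu1, alpha=alpha, priors=(pi0, pi1), threshold=threshold
    )


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Bounded in [-1, 1]; by convention 0 when any marginal is empty (e.g. all
    samples predicted as one class).
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn < 1:
        raise ValueError("confusion matrix is empty")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(float(denom)))


# ---------------------------------------------------------------------------
# exact leave-one-out shrinkage selection
# ---------------------------------------------------------------------------


def _loo_confusions(
    X: np.ndarray, y: np.ndarray, alphas: np.ndarray
) -> np.ndarray:
    """Pooled LOO confusion counts per alpha: returns (K, 4) = tp, tn, fp, fn.

    Exact per-left-out refits, computed cheaply: in the eigenbasis of the full
    pooled within-class scatter ``M``, dropping subject ``i`` changes the
    shrunk covariance to ``D - c v v'`` with ``D`` diagonal (the identity part
    of the shrinkage tracks the downdated trace exactly), so each LOO system
    over the whole alpha grid is solved by Sherman-Morrison in O(p).

    Raises LinAlgError if any left-out system is exactly singular (callers
    exclude alpha = 0 first when p is too large for the reduced sample).
    """
    n, p = X.shape
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    n0, n1 = len(idx0), len(idx1)
    mu0, mu1 = X[idx0].mean(axis=0), X[idx1].mean(axis=0)
    mu_own = np.where(y[:, None] == 1, mu1[None, :], mu0[None, :])
    U = X - mu_own
    M = U.T @ U  # pooled within-class scatter (n-divisor applied later)
    trM = float(np.trace(M))

    usable = np.where(y == 1, n1, n0) >= 2  # can't drop a class's only member
    Uu = U[usable]
    Xu = X[usable]
    yu = y[usable]
    nc = np.where(yu == 1, n1, n0).astype(float)
    f = nc / (nc - 1.0)
    # per-sample reduced-set class counts and prior log-odds
    n1_r = np.where(yu == 1, n1 - 1, n1).astype(float)
    n0_r = np.where(yu == 0, n0 - 1, n0).astype(float)
    logit = np.log(n1_r / n0_r)
    sgn = np.where(yu == 1, -1.0, 1.0)  # sign of the mean correction on dmu

    lam, Q = np.linalg.eigh(M)
    lam = np.maximum(lam, 0.0)
    V = Uu @ Q  # left-out scatter directions, eigenbasis
    Xt = Xu @ Q
    coef = (sgn / (nc - 1.0))[:, None] * V
    dmu = ((mu1 - mu0) @ Q)[None, :] + coef  # (m, p)
    mid = (((mu0 + mu1) / 2.0) @ Q)[None, :] - V / (2.0 * (nc - 1.0))[:, None]

    tau = (trM - f * np.einsum("ij,ij->i", Uu, Uu)) / ((n - 1.0) * p)  # (m,)
    # diagonal part per (sample, alpha, eigendirection) and rank-one weight c
    D = (1.0 - alphas)[None, :, None] * (lam / (n - 1.0))[None, None, :] + (
        alphas[None, :] * tau[:, None]
    )[:, :, None]
    c = (1.0 - alphas)[None, :] * (f / (n - 1.0))[:, None]  # (m, K)
    if (D <= 0.0).any():
        raise np.linalg.LinAlgError("singular shrunk covariance in LOO refit")
    Dv = V[:, None, :] / D  # D^-1 v
    denom = 1.0 - c * np.einsum("mp,mkp->mk", V, Dv)
    if (np.abs(denom) <= 1e-12).any():
        raise np.linalg.LinAlgError("singular downdated scatter in LOO refit")
    b = dmu[:, None, :] / D  # D^-1 dmu
    gain = c * np.einsum("mp,mkp->mk", dmu, Dv) / denom
    # w = D^-1 dmu + gain * D^-1 v  (Sherman-Morrison)
    score = np.einsum("mkp,mp->mk", b, Xt) + gain * np.einsum("mkp,mp->mk", Dv, Xt)
    thr = (
        np.einsum("mkp,mp->mk", b, mid)
        + gain * np.einsum("mkp,mp->mk", Dv, mid)
        - logit[:, None]
    )
    pred = score > thr  # predicted carrier
    truth = (yu == 1)[:, None]
    conf = np.stack(
        [
            (pred & truth).sum(axis=0),
            (~pred & ~truth).sum(axis=0),
            (pred & ~truth).sum(axis=0),
            (~pred & truth).sum(axis=0),
        ],
        axis=1,
    ).astype(np.int64)
    return conf


def loo_select_alpha(X, y, grid=DEFAULT_GRID) -> float:
    """Choose the shrinkage level by pooled leave-one-out MCC; ties -> smallest.

    A grid point whose shrunk covariance is singular for some left-out subject
    (alpha = 0 in the p >= n regime) scores -inf and can never be selected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if (y == 0).sum() == 0 or (y == 1).sum() == 0:
        raise ValueError("in-bag set must contain both classes")
    alphas = np.sort(np.asarray(grid, dtype=float))
    if (alphas < 0).any() or (alphas > 1).any():
        raise ValueError("grid values must lie in [0, 1]")

    n, p = X.shape
    scores = np.full(len(alphas), -np.inf)
    active = np.ones(len(alphas), dtype=bool)
    # the reduced pooled scatter has rank <= n - 3: alpha = 0 is then singular
    if p >= n - 2:
        active &= alphas > 0.0
    if not active.any():
        raise SingularCovarianceError(
            "no feasible shrinkage level: grid contains only alpha=0 and p >= n; "
            "use alpha > 0"
        )
    try:
        conf = _loo_confusions(X, y, alphas[active])
    except np.linalg.LinAlgError:
        # unexpected exact singularity (degenerate data); retry without alpha=0
        active &= alphas > 0.0
        conf = _loo_confusions(X, y, alphas[active])
    scores[active] = [mcc(*c) for c in conf]
    return float(alphas[int(np.argmax(scores))])


# ---------------------------------------------------------------------------
# bagged ensemble
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSignature:
    """A CNV-specific intermediate phenotype with its uncertainty and performance."""

    discriminants: np.ndarray  # (B_valid, p) sign-aligned, unit-norm
    W: np.ndarray  # averaged signature, mean of aligned discriminants
    ci_low: np.ndarray  # per-region 2.5% bootstrap percentile
    ci_high: np.ndarray  # per-region 97.5% bootstrap percentile
    significant: np.ndarray  # CI excludes zero
    oob_mcc: np.ndarray  # per valid iteration
    mean_mcc: float
    alphas: np.ndarray  # chosen shrinkage per valid iteration
    n_invalid: int
    group: str = ""
    region_names: tuple[str, ...] = ()
    null_mcc: np.ndarray | None = None
    null_threshold: float | None = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    @property
    def above_chance(self) -> bool | None:
        if self.null_threshold is None:
            return None
        return bool(self.mean_mcc > self.null_threshold)

    def to_json_dict(self) -> dict:
        d = {
            "group": self.group,
            "W": self.W.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "significant": self.significant.astype(int).tolist(),
            "oob_mcc": self.oob_mcc.tolist(),
            "mean_mcc": self.mean_mcc,
            "alphas": self.alphas.tolist(),
            "n_invalid": self.n_invalid,
            "region_names": list(self.region_names),
        }
        if self.null_mcc is not None:
            d["null_mcc"] = self.null_mcc.tolist()
            d["null_threshold"] = self.null_threshold
        return d


def _as_matrix(volumes) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(volumes, pd.DataFrame):
        return volumes.to_numpy(dtype=float), tuple(map(str, volumes.columns))
    return np.asarray(volumes, dtype=float), ()


def _oob_confusion(model: BinaryLDAModel, X: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    pred = model.predict(X)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return tp, tn, fp, fn


def fit_ensemble(
    volumes,
    y,
    B: int = 100,
    grid=DEFAULT_GRID,
    seed: int = 0,
    d_map: EffectSizeMap | np.ndarray | None = None,
    group: str = "",
    max_redraws: int = 10,
) -> EnsembleSignature:
    """Fit the bagged shrinkage-LDA signature for one CNV.

    Per iteration: stratified bootstrap preserving the dataset's class counts;
    LOO shrinkage selection on the in-bag set; LDA fit; out-of-bag MCC. An
    iteration whose out-of-bag set misses a class is redrawn up to
    ``max_redraws`` times and otherwise excluded (counted in ``n_invalid``).

    Discriminants are sign-aligned with the group's Cohen's d map (ties to
    +1), unit-L2-normalized and averaged into the signature ``W``; per-region
    2.5/97.5% percentiles of the aligned ensemble give the significance mask.
    """
    X, region_names = _as_matrix(volumes)
    y = np.asarray(y).astype(int)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    if len(idx1) < 2 or len(idx0) < 2:
        raise ValueError("need at least 2 carriers and 2 controls")
    if B < 1:
        raise ValueError("B must be >= 1")

    d_vec = None
    if d_map is not None:
        d_vec = d_map.d if isinstance(d_map, EffectSizeMap) else np.asarray(d_map, float)

    rng = np.random.default_rng(seed)
    ws, mccs, alphas = [], [], []
    n_invalid = 0
    all_idx = np.arange(len(y))
    for _ in range(B):
        ok = False
        for _try in range(max_redraws + 1):
            in_bag = np.concatenate(
                [rng.choice(idx1, size=len(idx1), replace=True),
                 rng.choice(idx0, size=len(idx0), replace=True)]
            )
            oob = np.setdiff1d(all_idx, in_bag, assume_unique=False)
            if len(oob) > 0 and (y[oob] == 1).any() and (y[oob] == 0).any():
                ok = True
                break
        if not ok:
            n_invalid += 1
            continue
        alpha = loo_select_alpha(X[in_bag], y[in_bag], grid)
        model = fit_binary_lda(X[in_bag], y[in_bag], alpha)
        mccs.append(mcc(*_oob_confusion(model, X[oob], y[oob])))
        alphas.append(alpha)
        ws.append(model.w)

    if not ws:
        raise RuntimeError("no valid bootstrap iteration produced a model")
    Wmat = np.asarray(ws)
    if d_vec is not None:
        signs = np.empty(len(Wmat))
        for i, w in enumerate(Wmat):
            try:
                c = pearson_r(w, d_vec)
            except ValueError:
                c = 0.0
            signs[i] = 1.0 if c >= 0 else -1.0
        Wmat = Wmat * signs[:, None]
    Wmat = Wmat / np.linalg.norm(Wmat, axis=1, keepdims=True)

    W = Wmat.mean(axis=0)
    lo, hi = np.percentile(Wmat, [2.5, 97.5], axis=0)
    significant = (lo > 0) | (hi < 0)
    return EnsembleSignature(
        discriminants=Wmat,
        W=W,
        ci_low=lo,
        ci_high=hi,
        significant=significant,
        oob_mcc=np.asarray(mccs),
        mean_mcc=float(np.mean(mccs)),
        alphas=np.asarray(alphas),
        n_invalid=n_invalid,
        group=group,
        region_names=region_names,
    )


def permutation_null(
    volumes,
    y,
    B: int = 100,
    n_perm: int = 100,
    grid=DEFAULT_GRID,
    seed: int = 0,
    B_null: int | None = None,
) -> tuple[np.ndarray, float]:
    """Label-permutation null for the bagged classifier's mean out-of-bag MCC.

    Each permutation shuffles the labels and reruns the full bagged procedure
    (including per-bootstrap shrinkage selection) with ``B_null`` iterations
    (default: same as ``B``). Returns the null mean-MCC distribution and its
    97.5th percentile; observed performance above that threshold is deemed
    above chance.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, _ = _as_matrix(volumes)
    y = np.asarray(y).astype(int)
    B_null = B if B_null is None else B_null
    ss = np.random.SeedSequence(seed).spawn(n_perm)
    null = np.empty(n_perm)
    for i, s in enumerate(ss):
        rng = np.random.default_rng(s)
        yp = rng.permutation(y)
        sig = fit_ensemble(
            X, yp, B=B_null, grid=grid, seed=rng.integers(2**31), d_map=None
        )
        null[i] = sig.mean_mcc
    return null, float(np.percentile(null, 97.5))


# ---------------------------------------------------------------------------
# inspection
# ---------------------------------------------------------------------------


@dataclass
class NetworkSummary:
    """Fraction of significant signature coefficients per network."""

    fraction: np.ndarray  # (K,)
    n_significant: np.ndarray  # (K,)
    n_regions: np.ndarray  # (K,)
    network_names: tuple[str, ...]
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "network": self.network_names,
                "n_regions": self.n_regions,
                "n_significant": self.n_significant,
                "fraction": self.fraction,
            }
        )


def network_summary(signature: EnsembleSignature, atlas: AtlasSpec) -> NetworkSummary:
    """Per-network share of regions with significant signature coefficients."""
    if signature.W.shape[0] != atlas.n_regions:
        raise ValueError("signature length must equal the atlas region count")
    K = atlas.n_networks
    n_regions = np.bincount(atlas.network_label, minlength=K + 1)[1:]
    n_sig = np.bincount(
        atlas.network_label[signature.significant], minlength=K + 1
    )[1:]
    return NetworkSummary(
        fraction=n_sig / n_regions,
        n_significant=n_sig,
        n_regions=n_regions,
        network_names=atlas.network_names,
        group=signature.group,
    )


def coeff_vs_performance(signatures) -> tuple[float, float]:
    """Pearson r (and two-sided p) between per-CNV significant-coefficient
    counts and mean out-of-bag MCC."""
    signatures = list(signatures)
    if len(signatures) < 3:
        raise ValueError("need at least 3 signatures")
    counts = np.array([s.n_significant for s in signatures], dtype=float)
    perf = np.array([s.mean_mcc for s in signatures])
    if np.ptp(counts) == 0 or np.ptp(perf) == 0:
        raise ValueError("correlation undefined: constant input")
    res = stats.pearsonr(counts, perf)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# 2-D embeddings
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # all subjects x dims
    loadings: np.ndarray  # (p, dims)
    explained_variance: np.ndarray | None
    fit_subjects: tuple[str, ...]
    projected_subjects: tuple[str, ...]
    kind: str = "pca"
    center: np.ndarray = field(default=None, repr=False)


def pca_embedding(volumes: pd.DataFrame, fit_subjects, project_subjects=()) -> EmbeddingResult:
    """Top-2 PCA of the fit population; other subjects projected post hoc."""
    fit_idx = pd.Index(fit_subjects)
    proj_idx = pd.Index(project_subjects)
    Xf = volumes.loc[fit_idx].to_numpy(dtype=float)
    if Xf.shape[0] < 3:
        raise ValueError("PCA fit population needs at least 3 subjects")
    center = Xf.mean(axis=0)
    Xc = Xf - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if (s > 1e-12 * s[0] if s[0] > 0 else s > 0).sum() < 2:
        raise DegenerateEmbeddingError("fewer than 2 non-degenerate components")
    V = Vt[:2].T
    # deterministic sign: largest-magnitude loading positive
    for j in range(2):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] *= -1
    var = s**2 / Xf.shape[0]
    evr = var[:2] / var.sum()

    everyone = fit_idx.append(proj_idx) if len(proj_idx) else pd.Index(fit_idx)
    coords = (volumes.loc[everyone].to_numpy(dtype=float) - center) @ V
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=everyone, columns=["PC1", "PC2"]),
        loadings=V,
        explained_variance=evr,
        fit_subjects=tuple(fit_idx),
        projected_subjects=tuple(proj_idx),
        kind="pca",
        center=center,
    )


def _loo_multiclass_accuracy(
    X: np.ndarray, y_codes: np.ndarray, alphas: np.ndarray
) -> np.ndarray:
    """Pooled LOO accuracy per alpha for shared-covariance Gaussian classification."""
    n, p = X.shape
    C = y_codes.max() + 1
    K = len(alphas)
    counts = np.bincount(y_codes, minlength=C).astype(float)
    mus = np.stack([X[y_codes == c].mean(axis=0) for c in range(C)])
    U = X - mus[y_codes]
    M = U.T @ U
    trM = float(np.trace(M))
    correct = np.zeros(K, dtype=np.int64)
    eye = np.eye(p)
    for i in range(n):
        c = y_codes[i]
        if counts[c] < 2:
            continue
        u = U[i]
        fct = counts[c] / (counts[c] - 1.0)
        S_minus = (M - fct * np.outer(u, u)) / (n - 1.0)
        tau = (trM - fct * (u @ u)) / ((n - 1.0) * p)
        mus_i = mus.copy()
        mus_i[c] = mus[c] - u / (counts[c] - 1.0)
        counts_i = counts.copy()
        counts_i[c] -= 1.0
        logpri = np.log(counts_i / (n - 1.0))
        A = (1.0 - alphas)[:, None, None] * S_minus[None] + (
            alphas * tau
        )[:, None, None] * eye[None]
        Wc = np.linalg.solve(A, np.broadcast_to(mus_i.T[None], (K, p, C)))  # (K, p, C)
        scores = X[i] @ Wc - 0.5 * np.einsum("pc,kpc->kc", mus_i.T, Wc) + logpri[None, :]
        correct += scores.argmax(axis=1) == c
    return correct / n


def multiclass_lda_embedding(
    volumes: pd.DataFrame,
    labels: pd.Series,
    project_subjects=(),
    grid=DEFAULT_GRID,
) -> EmbeddingResult:
    """Shrinkage-regularized multiclass LDA embedding (up to 2 discriminants).

    The shrinkage level is selected by leave-one-out pooled accuracy over the
    carrier classes; the embedding directions are the leading generalized
    eigenvectors of the between-class versus shrunk within-class scatter. The
    maximum number of discriminant dimensions is the number of classes minus
    one. Non-carrier subjects can be projected post hoc.
    """
    fit_idx = labels.index
    proj_idx = pd.Index(project_subjects)
    X = volumes.loc[fit_idx].to_numpy(dtype=float)
    classes, y_codes = np.unique(labels.to_numpy(), return_inverse=True)
    C = len(classes)
    if C < 2:
        raise ValueError("need at least 2 classes")
    if (np.bincount(y_codes) < 2).any():
        raise ValueError("every class needs at least 2 subjects")

    n, p = X.shape
    alphas = np.sort(np.asarray(grid, dtype=float))
    feasible = alphas > 0.0 if p >= n - C else np.ones(len(alphas), dtype=bool)
    acc = np.full(len(alphas), -np.inf)
    acc[feasible] = _loo_multiclass_accuracy(X, y_codes, alphas[feasible])
    alpha = float(alphas[int(np.argmax(acc))])

    counts = np.bincount(y_codes).astype(float)
    mus = np.stack([X[y_codes == c].mean(axis=0) for c in range(C)])
    grand = X.mean(axis=0)
    U = X - mus[y_codes]
    Sw = _shrink(U.T @ U / n, alpha)
    Md = mus - grand
    Sb = (Md * counts[:, None]).T @ Md / n
    if np.abs(Sb).max() <= 1e-12 * max(np.abs(Sw).max(), 1e-30):
        raise DegenerateEmbeddingError(
            "between-class scatter is degenerate (class means coincide)"
        )
    evals, evecs = sla.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    n_dims = min(2, C - 1)
    keep = order[:n_dims]
    if evals[keep[0]] <= 1e-10:
        raise DegenerateEmbeddingError("no usable discriminant direction")
    V = evecs[:, keep]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] *= -1

    everyone = pd.Index(fit_idx).append(proj_idx) if len(proj_idx) else pd.Index(fit_idx)
    coords = (volumes.loc[everyone].to_numpy(dtype=float) - grand) @ V
    cols = [f"LD{i + 1}" for i in range(n_dims)]
    ev = evals[keep]
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=everyone, columns=cols),
        loadings=V,
        explained_variance=ev / ev.sum() if ev.sum() > 0 else None,
        fit_subjects=tuple(fit_idx),
        projected_subjects=tuple(proj_idx),
        kind="lda",
        center=grand,
    )
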