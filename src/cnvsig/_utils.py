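"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def spawn_rng(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators deterministically from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation; NaN-free inputs expected."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ValueError("correlation undefined: at least one input is constant")
    return float((xc @ yc) / denom)


def pearson_p_from_r(r: float | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    """Two-sided p-value for a Pearson correlation from the t distribution (df = n-2)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    n = np.asarray(n)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = np.where(df > 0, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan)
    # |r| == 1 with df > 0 gives an infinite t statistic -> p = 0
    p = np.where((np.abs(r) >= 1.0) & (df > 0), 0.0, p)
    if p.ndim == 0:
        return float(p)
    return p


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values).

    NaN entries are passed through untouched and never rejected.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out_rej = np.zeros(p.shape, dtype=bool)
    out_adj = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        rej, adj, _, _ = multipletests(p[mask], alpha=alpha, method="fdr_bh")
        out_rej[mask] = rej
        out_adj[mask] = adj
    return out_rej, out_adj
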