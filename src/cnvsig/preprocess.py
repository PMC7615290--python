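"""Confound residualization and normalization of parcel volumes.

Regional volumes are adjusted for nuisance variables (intracranial volume,
age, age^2, sex, acquisition site for the clinical recipe; additionally body
mass index and head motion for the population recipe) by per-region ordinary
least squares. Site enters as categorical indicator columns, i.e. as a fixed
effect; this gives a deterministic closed-form residualization and is
equivalent in expectation to a site random factor for balanced designs. The
interface accepts any confound list, so a different site handler can be
swapped in upstream.

Coefficients can be fit on one subject subset and applied to all subjects,
which is how signatures fit in a clinical cohort are scored on volumes from a
population cohort adjusted with that cohort's own confound model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CLINICAL_DESIGN = ("icv", "age", "age2", "sex", "site")
POPULATION_DESIGN = ("icv", "age", "age2", "sex", "site", "bmi", "motion")


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class ZeroVarianceError(ValueError):
    """A region has no variance over the normalization subset."""


@dataclass
class ConfoundModel:
    """Per-region OLS coefficients for a fixed-effect confound design."""

    coefficients: pd.DataFrame  # design columns x regions
    design: tuple[str, ...]  # confound names as requested
    columns: tuple[str, ...]  # expanded design-matrix column names
    fit_subjects: tuple[str, ...]

    def to_json_dict(self) -> dict:
        return {
            "design": list(self.design),
            "columns": list(self.columns),
            "n_fit_subjects": len(self.fit_subjects),
            "coefficients": {
                c: self.coefficients[c].tolist() for c in self.coefficients.columns
            },
            "coefficient_index": list(self.coefficients.index),
        }


@dataclass
class AdjustedVolumes:
    """Residualized (optionally z-scored) volumes plus provenance."""

    values: pd.DataFrame  # subjects x regions
    removed: tuple[str, ...]
    fit_subjects: tuple[str, ...]
    zscored: bool = False


def _build_design(
    confounds: pd.DataFrame, design: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Expand the confound list into a numeric design matrix with intercept."""
    cols: list[np.ndarray] = [np.ones(len(confounds))]
    names: list[str] = ["intercept"]
    for name in design:
        if name == "age2":
            cols.append(confounds["age"].to_numpy(dtype=float) ** 2)
            names.append("age2")
        elif name == "site":
            site = confounds["site"].astype(str)
            levels = sorted(site.unique())
            if len(levels) == 1:
                warnings.warn(
                    "single acquisition site: dropping site columns from the "
                    "confound design",
                    UserWarning,
                    stacklevel=3,
                )
                continue
            for lev in levels[1:]:  # first level absorbed by the intercept
                cols.append((site == lev).to_numpy(dtype=float))
                names.append(f"site[{lev}]")
        else:
            if name not in confounds.columns:
                raise KeyError(f"confound {name!r} not found in confound table")
            vals = confounds[name].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing values in confound {name!r}")
            cols.append(vals)
            names.append(name)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns via near-zero diagonal of R in a pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise CollinearityError(
            f"confound design is rank deficient; offending columns: {bad}"
        )


def adjust_confounds(
    volumes: pd.DataFrame,
    confounds: pd.DataFrame,
    design: tuple[str, ...] = CLINICAL_DESIGN,
    fit_subjects=None,
) -> tuple[AdjustedVolumes, ConfoundModel]:
    """Residualize each region on the confound design.

    The OLS fit uses ``fit_subjects`` (default: all subjects); residuals are
    returned for every subject using the fitted coefficients. The intercept is
    always included and removed with the confounds.
    """
    confounds = confounds.loc[volumes.index]
    X, names = _build_design(confounds, tuple(design))
    _check_rank(X, names)

    if fit_subjects is None:
        fit_mask = np.ones(len(volumes), dtype=bool)
    else:
        fit_mask = volumes.index.isin(pd.Index(fit_subjects))
        if fit_mask.sum() < X.shape[1]:
            raise ValueError(
                f"{int(fit_mask.sum())} fit subjects for {X.shape[1]} design columns"
            )
    Y = volumes.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("missing volume entries are not supported")
    coef, *_ = np.linalg.lstsq(X[fit_mask], Y[fit_mask], rcond=None)
    resid = Y - X @ coef

    model = ConfoundModel(
        coefficients=pd.DataFrame(coef, index=names, columns=volumes.columns),
        design=tuple(design),
        columns=tuple(names),
        fit_subjects=tuple(volumes.index[fit_mask]),
    )
    adjusted = AdjustedVolumes(
        values=pd.DataFrame(resid, index=volumes.index, columns=volumes.columns),
        removed=tuple(n for n in names if n != "intercept"),
        fit_subjects=model.fit_subjects,
    )
    return adjusted, model


def apply_confound_model(
    volumes: pd.DataFrame, confounds: pd.DataFrame, model: ConfoundModel
) -> AdjustedVolumes:
    """Residualize new subjects with previously fitted coefficients."""
    confounds = confounds.loc[volumes.index]
    X, names = _build_design(confounds, model.design)
    if tuple(names) != model.columns:
        raise ValueError(
            f"design columns {names} do not match fitted model columns "
            f"{list(model.columns)}"
        )
    resid = volumes.to_numpy(dtype=float) - X @ model.coefficients.to_numpy()
    return AdjustedVolumes(
        values=pd.DataFrame(resid, index=volumes.index, columns=volumes.columns),
        removed=tuple(n for n in names if n != "intercept"),
        fit_subjects=model.fit_subjects,
    )


def zscore_columns(volumes: pd.DataFrame, over_subjects=None) -> pd.DataFrame:
    """Z-score each region using the mean/SD of ``over_subjects`` (sample SD, n-1).

    Subjects outside the subset are transformed with the same parameters, so
    e.g. normalizing over carriers-of-one-CNV plus controls leaves other
    groups on the same scale.
    """
    if over_subjects is None:
        mask = np.ones(len(volumes), dtype=bool)
    else:
        mask = volumes.index.isin(pd.Index(over_subjects))
    if mask.sum() < 2:
        raise ValueError("z-scoring needs at least 2 subjects in the subset")
    sub = volumes.loc[mask]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    # scale-aware zero test: a constant column's SD is float noise, not signal
    zero = sd[sd <= (mu.abs() + 1.0) * 1e-12]
    if len(zero) > 0:
        raise ZeroVarianceError(
            f"zero variance over the subset in regions: {list(zero.index)}"
        )
    return (volumes - mu) / sd
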