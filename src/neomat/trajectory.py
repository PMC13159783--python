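"""Maturation-delay trajectories: ΔHRV, outlier fences, and the mixed model.

ΔHRV is defined as PMA − FMA, so positive values quantify a maturation
*delay* in weeks. Per-patient outliers in the FMA estimates are removed
with Tukey fences (1.5 × IQR beyond the quartiles, linear-interpolation
quartile convention). All retained observations between 32 and 36 weeks of
PMA then enter a linear mixed-effects model with a random intercept per
patient, fixed effects for PMA (centered at 34 weeks) and the perinatal
covariates IUGR, BPD, neurological lesions, and PDA, fitted by REML.
Each patient's ΔHRV at 34 weeks is the conditional (BLUP) prediction at
PMA = 34 using the patient's own covariates and estimated random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DeltaObservation",
    "DeltaAt34",
    "compute_delta",
    "remove_outliers",
    "filter_fma_outliers",
    "fit_mixed_model",
    "interpolate_at_34",
    "observations_frame",
    "TrajectoryModel",
]

DEFAULT_COVARIATES = ("iugr", "bpd", "neuro_lesions", "pda")
DEFAULT_WINDOW = (32.0, 36.0)
CENTER_PMA = 34.0


@dataclass
class DeltaObservation:
    """One (patient, PMA) maturation observation: ΔHRV = PMA − FMA."""

    patient_id: str
    pma_weeks: float
    fma_weeks: float
    delta_weeks: float


@dataclass
class DeltaAt34:
    """Model-interpolated ΔHRV at 34 weeks PMA for one patient."""

    patient_id: str
    delta34_weeks: float
    covariates: dict[str, int] = field(default_factory=dict)


def compute_delta(pma_weeks, fma_weeks):
    """ΔHRV = PMA − FMA (weeks); positive = maturation delay.

    Accepts scalars or arrays; raises on non-finite input.
    """
    pma = np.asarray(pma_weeks, dtype=float)
    fma = np.asarray(fma_weeks, dtype=float)
    if not (np.all(np.isfinite(pma)) and np.all(np.isfinite(fma))):
        raise ValueError("pma_weeks and fma_weeks must be finite")
    delta = pma - fma
    return float(delta) if delta.ndim == 0 else delta


def remove_outliers(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Tukey-fence outlier removal.

    Fences are computed once from the original values — Q1 − 1.5·IQR and
    Q3 + 1.5·IQR with linear-interpolation quartiles — so a second pass
    would remove nothing. Fewer than 4 values pass through unchanged with
    a warning. Returns ``(retained, removed)``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        if vals.size:
            warnings.warn(
                f"only {vals.size} values; outlier fences need at least 4",
                stacklevel=2,
            )
        return vals, np.array([])
    q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (vals >= lo) & (vals <= hi)
    return vals[keep], vals[~keep]


def filter_fma_outliers(
    df: pd.DataFrame,
    value_col: str = "fma_weeks",
    group_col: str = "patient_id",
) -> pd.DataFrame:
    """Apply :func:`remove_outliers` to ``value_col`` within each patient."""
    keep_idx: list = []
    for _, grp in df.groupby(group_col, sort=False):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < 4:
            keep_idx.extend(grp.index)
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        iqr = q3 - q1
        keep = (vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)
        keep_idx.extend(grp.index[keep])
    return df.loc[keep_idx]


@dataclass
class TrajectoryModel:
    """Fitted ΔHRV trajectory model over the 32–36-week PMA window."""

    fixed_effects: pd.Series
    fixed_se: pd.Series
    random_intercepts: dict[str, float]
    group_var: float
    residual_var: float
    covariates: tuple[str, ...]
    data: pd.DataFrame = field(repr=False)
    fallback_fixed_only: bool = False
    result: object = field(default=None, repr=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "low": self.fixed_effects - z * self.fixed_se,
                "high": self.fixed_effects + z * self.fixed_se,
            }
        )


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["pma_c"] = df["pma_weeks"].to_numpy(dtype=float) - CENTER_PMA
    for cov in covariates:
        X[cov] = df[cov].to_numpy(dtype=float)
    return X


def fit_mixed_model(
    df: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    window: tuple[float, float] = DEFAULT_WINDOW,
    reml: bool = True,
    random_slope: bool = False,
) -> TrajectoryModel:
    """Fit the covariate-adjusted random-intercept model of ΔHRV on PMA.

    ``df`` is long-format with columns ``patient_id``, ``pma_weeks``,
    ``delta_weeks`` and the covariate columns. Observations outside
    ``window`` (inclusive) are dropped. On a singular or non-converged fit
    the model falls back to fixed effects only (OLS) with a warning and
    ``fallback_fixed_only=True``.
    """
    covariates = tuple(c for c in covariates if c in df.columns)
    data = df[(df["pma_weeks"] >= window[0]) & (df["pma_weeks"] <= window[1])].copy()
    n_patients = data["patient_id"].nunique()
    if n_patients < 10:
        raise ValueError(
            f"mixed model needs at least 10 patients in the window, got {n_patients}"
        )
    X = _design(data, covariates)
    y = data["delta_weeks"].to_numpy(dtype=float)
    groups = data["patient_id"].to_numpy()
    exog_re = None
    if random_slope:
        exog_re = X[["intercept", "pma_c"]]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
            res = model.fit(reml=reml, method="lbfgs")
        if not np.all(np.isfinite(res.params)) or res.cov_re.values.min() < 0:
            raise np.linalg.LinAlgError("degenerate covariance")
        re = {str(k): float(v.iloc[0]) for k, v in res.random_effects.items()}
        return TrajectoryModel(
            fixed_effects=res.fe_params,
            fixed_se=res.bse_fe,
            random_intercepts=re,
            group_var=float(res.cov_re.values[0, 0]) if res.cov_re.size else 0.0,
            residual_var=float(res.scale),
            covariates=covariates,
            data=data,
            result=res,
        )
    except (np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(
            f"mixed model fit failed ({exc}); falling back to fixed effects only",
            stacklevel=2,
        )
        ols = sm.OLS(y, X).fit()
        return TrajectoryModel(
            fixed_effects=ols.params,
            fixed_se=ols.bse,
            random_intercepts={str(g): 0.0 for g in pd.unique(groups)},
            group_var=0.0,
            residual_var=float(ols.mse_resid),
            covariates=covariates,
            data=data,
            fallback_fixed_only=True,
            result=ols,
        )


def interpolate_at_34(
    model: TrajectoryModel,
    patient_id: str | None = None,
    marginal: bool = False,
    at: float = CENTER_PMA,
) -> DeltaAt34 | list[DeltaAt34]:
    """Conditional (BLUP) ΔHRV at PMA = ``at`` for one patient or all.

    The prediction combines the fixed effects evaluated at the patient's
    own covariates with the patient's estimated random intercept; with
    ``marginal=True`` the random effect is omitted (population line).
    ``at`` defaults to the 34-week landmark.
    """
    if patient_id is not None:
        return _interp_one(model, patient_id, marginal, at)
    return [_interp_one(model, pid, marginal, at) for pid in model.random_intercepts]


def _interp_one(
    model: TrajectoryModel, patient_id: str, marginal: bool, at: float
) -> DeltaAt34:
    if patient_id not in model.random_intercepts:
        raise KeyError(
            f"patient {patient_id!r} has no retained observations in the window"
        )
    rows = model.data[model.data["patient_id"] == patient_id]
    covs = {c: int(rows.iloc[0][c]) for c in model.covariates}
    value = float(model.fixed_effects["intercept"])
    value += float(model.fixed_effects["pma_c"]) * (at - CENTER_PMA)
    for c in model.covariates:
        value += float(model.fixed_effects[c]) * covs[c]
    if not marginal:
        value += model.random_intercepts[patient_id]
    return DeltaAt34(patient_id=patient_id, delta34_weeks=value, covariates=covs)


def observations_frame(observations: Sequence[DeltaObservation]) -> pd.DataFrame:
    """Long-format DataFrame from a list of :class:`DeltaObservation`."""
    return pd.DataFrame(
        {
            "patient_id": [o.patient_id for o in observations],
            "pma_weeks": [o.pma_weeks for o in observations],
            "fma_weeks": [o.fma_weeks for o in observations],
            "delta_weeks": [o.delta_weeks for o in observations],
        }
    )
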