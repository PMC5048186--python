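"""Energy adjustment of nutrient intakes.

Two standard devices for removing the dependence of nutrient intake on
total energy intake: the residual model (regress nutrient on energy,
keep residual plus the fitted value at the cohort mean energy) and the
energy density (nutrient per MJ). Because dietary variables are skewed,
each variable is first log- or square-root transformed, choosing the
transformation that leaves the smaller absolute sample skewness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ResidualFit", "residual_adjust", "energy_density",
           "choose_transformation", "apply_transformation", "adjust_table"]

NUTRIENT_COLUMNS = ("protein", "fat", "sfa", "mufa", "pufa",
                    "carbohydrate", "sucrose", "fibre", "alcohol")


class AdjustmentError(ValueError):
    pass


@dataclass
class ResidualFit:
    """Audit trail of one residual-model adjustment."""
    slope: float
    intercept: float
    mean_energy: float
    adjusted: np.ndarray


def residual_adjust(nutrient_values, energy_values) -> ResidualFit:
    """Residual-model energy adjustment of one nutrient series.

    OLS of nutrient on energy; the adjusted value is the residual plus the
    predicted intake at the cohort mean energy, so the adjusted series is
    uncorrelated with energy but keeps an interpretable level.
    """
    y = np.asarray(nutrient_values, dtype=float)
    x = np.asarray(energy_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 3:
        raise AdjustmentError("need equal-length 1-d series of length >= 3")
    if np.var(x) == 0:
        raise AdjustmentError("energy variance is zero")
    slope, intercept = np.polyfit(x, y, 1)
    mean_energy = float(np.mean(x))
    predicted_at_mean = intercept + slope * mean_energy
    residuals = y - (intercept + slope * x)
    return ResidualFit(float(slope), float(intercept), mean_energy,
                       residuals + predicted_at_mean)


def energy_density(nutrient_values, energy_values) -> np.ndarray:
    """Nutrient intake per MJ of energy (unit/MJ), elementwise."""
    y = np.asarray(nutrient_values, dtype=float)
    x = np.asarray(energy_values, dtype=float)
    if np.any(x <= 0):
        raise AdjustmentError("energy must be positive for density adjustment")
    return y / x


def _log_offset(values: np.ndarray) -> float:
    """Offset for log-transforming series containing zeros: half the
    smallest positive observation (0 when no zeros are present)."""
    if np.all(values > 0):
        return 0.0
    positive = values[values > 0]
    if len(positive) == 0:
        raise AdjustmentError("cannot log-transform an all-zero series")
    return float(positive.min()) / 2.0


def apply_transformation(values, transformation: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise AdjustmentError("intake values must be >= 0")
    if transformation == "log":
        return np.log(values + _log_offset(values))
    if transformation == "sqrt":
        return np.sqrt(values)
    if transformation == "none":
        return values
    raise ValueError(f"unknown transformation {transformation!r}")


def choose_transformation(values) -> str:
    """Pick 'log' or 'sqrt', whichever leaves smaller |skewness|.

    Ties break to log; a constant series returns sqrt with a warning since
    skewness is undefined.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise AdjustmentError("intake values must be >= 0")
    if np.ptp(values) == 0:
        warnings.warn("constant series: skewness undefined, using sqrt",
                      stacklevel=2)
        return "sqrt"
    skews = {}
    for name in ("log", "sqrt"):
        transformed = apply_transformation(values, name)
        skews[name] = abs(float(stats.skew(transformed)))
    return "log" if skews["log"] <= skews["sqrt"] else "sqrt"


def adjust_table(intakes: pd.DataFrame, subjects: pd.DataFrame | None = None,
                 method: str = "residual", by_sex: bool = True,
                 nutrients: tuple = NUTRIENT_COLUMNS) -> pd.DataFrame:
    """Energy-adjust every nutrient column of the intake table.

    Transformation is chosen per nutrient x instrument (pooled over
    strata, so both sexes share a scale), then the adjustment runs within
    sex strata by default. Residual adjustment operates on transformed
    values; density adjustment divides the raw intake by energy.
    Returns long-format rows: subject_id, instrument, nutrient, method,
    transformation, value.
    """
    if method not in ("residual", "density"):
        raise ValueError("method must be 'residual' or 'density'")
    df = intakes.copy()
    if by_sex:
        if subjects is None:
            raise AdjustmentError("by_sex adjustment needs the subject table")
        df = df.merge(subjects[["subject_id", "sex"]], on="subject_id")
        strata = [g for _, g in df.groupby("sex")]
    else:
        strata = [df]

    out = []
    for inst, inst_df in df.groupby("instrument"):
        trans_by_nutrient = {
            nut: ("none" if method == "density"
                  else choose_transformation(inst_df[nut].to_numpy()))
            for nut in nutrients}
        for stratum in strata:
            grp = stratum[stratum["instrument"] == inst]
            if grp.empty:
                continue
            energy = grp["energy"].to_numpy()
            for nut in nutrients:
                raw = grp[nut].to_numpy()
                trans = trans_by_nutrient[nut]
                if method == "density":
                    values = energy_density(raw, energy)
                else:
                    values = residual_adjust(
                        apply_transformation(raw, trans), energy).adjusted
                out.extend(
                    {"subject_id": sid, "instrument": inst, "nutrient": nut,
                     "method": method, "transformation": trans,
                     "value": float(v)}
                    for sid, v in zip(grp["subject_id"], values))
    return pd.DataFrame(out)
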