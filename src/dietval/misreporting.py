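"""Goldberg-type misreporting classification of reported energy intake.

In weight-stable adults, reported energy intake (EI) should equal measured
total energy expenditure (TEE), so EI:TEE is expected to be 1. The 95%
confidence limits around 1 combine the within-subject variation of the
intake instrument (CV_EI over d recording days) and of the TEE measurement
(CV_TEE):

    limits = 1 ± z * sqrt(CV_EI^2 / d + CV_TEE^2) / 100

with the CVs in percent and z = 2. For a food-frequency questionnaire d is
taken as infinite, leaving only the CV_TEE term. With CV_TEE = 8.4%,
CV_EI = 20.6% and d = 4 the limits round to (0.73, 1.27); at d = infinity
they round to (0.83, 1.17). Subjects below the lower limit are classified
as under-reporters, above the upper limit as over-reporters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CutoffParams", "GoldbergLimits", "ReporterStatus",
           "goldberg_limits", "classify_reporter", "reporting_accuracy",
           "accuracy_summary", "classify_table"]


@dataclass
class CutoffParams:
    """Inputs of the confidence-limit formula (CVs in percent)."""
    cv_tee: float = 8.4
    cv_ei: float = 20.6
    d: float = 4            # recording days; math.inf for an FFQ
    z: float = 2.0

    def __post_init__(self) -> None:
        if self.cv_tee < 0 or self.cv_ei < 0:
            raise ValueError("CVs must be >= 0")
        if not (self.d >= 1 or math.isinf(self.d)):
            raise ValueError("d must be >= 1 or infinite")
        if self.z <= 0:
            raise ValueError("z must be positive")


@dataclass
class GoldbergLimits:
    lower: float
    upper: float
    lower_rounded: float
    upper_rounded: float

    def as_pair(self, rounded: bool = True) -> tuple[float, float]:
        if rounded:
            return self.lower_rounded, self.upper_rounded
        return self.lower, self.upper


@dataclass
class ReporterStatus:
    subject_id: str
    instrument: str
    ratio: float    # EI:TEE
    status: str     # "under" | "plausible" | "over"


def goldberg_limits(params: CutoffParams) -> GoldbergLimits:
    """Confidence limits for EI:TEE around 1, unrounded and 2-decimal."""
    ei_term = 0.0 if math.isinf(params.d) else params.cv_ei ** 2 / params.d
    half_width = params.z * math.sqrt(ei_term + params.cv_tee ** 2) / 100.0
    lower, upper = 1.0 - half_width, 1.0 + half_width
    return GoldbergLimits(lower, upper, round(lower, 2), round(upper, 2))


def classify_reporter(ei: float, tee: float, limits: tuple[float, float],
                      subject_id: str = "", instrument: str = "") -> ReporterStatus:
    """Classify one subject by EI:TEE against (lower, upper) limits.

    Comparisons are strict, so a ratio exactly on a limit is plausible.
    """
    if ei <= 0 or tee <= 0:
        raise ValueError("ei and tee must be positive")
    lower, upper = limits
    ratio = ei / tee
    if ratio < lower:
        status = "under"
    elif ratio > upper:
        status = "over"
    else:
        status = "plausible"
    return ReporterStatus(subject_id, instrument, ratio, status)


def reporting_accuracy(ei, tee):
    """Reporting accuracy in percent: 100 * EI / TEE (elementwise)."""
    ei = np.asarray(ei, dtype=float)
    tee = np.asarray(tee, dtype=float)
    if np.any(tee <= 0):
        raise ValueError("tee must be positive")
    return 100.0 * ei / tee


def accuracy_summary(ei, tee, ddof: int = 1) -> dict:
    """Cohort mean and SD (sample denominator by default) of accuracy %."""
    acc = reporting_accuracy(ei, tee)
    return {"mean": float(np.mean(acc)),
            "sd": float(np.std(acc, ddof=ddof)),
            "n": int(np.size(acc))}


def classify_table(intakes: pd.DataFrame, dlw_results: pd.DataFrame,
                   params_by_instrument: dict[str, CutoffParams],
                   use_rounded_limits: bool = True) -> pd.DataFrame:
    """Per subject x instrument classification against DLW TEE.

    Joins the intake table (subject_id, instrument, energy) with DLW TEE;
    subjects without a valid TEE are dropped. Returns ratio, status and the
    limits used for every row.
    """
    tee = dlw_results.loc[np.isfinite(dlw_results["tee"]),
                          ["subject_id", "tee"]]
    merged = intakes.merge(tee, on="subject_id", how="inner")
    rows = []
    for _, r in merged.iterrows():
        params = params_by_instrument[r["instrument"]]
        limits = goldberg_limits(params).as_pair(rounded=use_rounded_limits)
        st = classify_reporter(r["energy"], r["tee"], limits,
                               subject_id=r["subject_id"],
                               instrument=r["instrument"])
        rows.append({
            "subject_id": st.subject_id, "instrument": st.instrument,
            "ratio": st.ratio, "status": st.status,
            "limit_lower": limits[0], "limit_upper": limits[1],
            "accuracy_pct": 100.0 * st.ratio,
        })
    return pd.DataFrame(rows)


def status_summary(classified: pd.DataFrame) -> dict:
    """Counts and percentages by reporter status for each instrument."""
    out = {}
    for inst, grp in classified.groupby("instrument"):
        n = len(grp)
        counts = grp["status"].value_counts().to_dict()
        out[inst] = {
            "n": n,
            "counts": {s: int(counts.get(s, 0))
                       for s in ("under", "plausible", "over")},
            "percent": {s: 100.0 * counts.get(s, 0) / n
                        for s in ("under", "plausible", "over")},
            "accuracy_mean": float(grp["accuracy_pct"].mean()),
            "accuracy_sd": float(grp["accuracy_pct"].std(ddof=1)),
        }
    return out
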