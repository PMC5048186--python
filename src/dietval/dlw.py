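"""Total energy expenditure from doubly-labelled-water enrichment series.

The multipoint method: each isotope's excess enrichment (above the
subject's own pre-dose background) decays as a single exponential, so
ordinary least squares of log(excess) on time gives the elimination
constant k (per day) and, by back-extrapolation, the zero-time intercept.
Dilution spaces follow from tracer dose over intercept atom-fraction
excess; CO2 production from the two-pool equation with fractionation
corrections; and energy expenditure from CO2 via the Weir expression at a
configured food quotient.

Quality control mirrors standard practice for this technique: the
2H-to-18O dilution-space ratio must fall in a physiological window,
pre/post body weight must agree within 1 kg, and elimination curves are
screened for diverging residuals on the log scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import DlwConstants

__all__ = [
    "DoseRecord", "EnrichmentSample", "EliminationFit", "DlwResult",
    "InsufficientDataError", "tracer_moles", "fit_elimination",
    "compute_dilution_space", "compute_tee", "qc_check",
    "process_subject", "process_tables",
]


class InsufficientDataError(ValueError):
    """Fewer than two usable enrichment samples for a fit."""


@dataclass
class DoseRecord:
    subject_id: str
    body_weight_pre: float      # kg
    body_weight_post: float     # kg
    dose_mass: float            # g of dose mixture
    h2_fraction: float          # mass fraction of 2H-labelled water in dose
    o18_fraction: float         # mass fraction of 18O-labelled water in dose
    h2_purity: float = 0.999    # atom fraction 2H in the labelled component
    o18_purity: float = 0.10    # atom fraction 18O in the labelled component

    def __post_init__(self) -> None:
        if self.dose_mass <= 0:
            raise ValueError("dose_mass must be positive")
        for name in ("h2_fraction", "o18_fraction", "h2_purity", "o18_purity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.body_weight_pre <= 0 or self.body_weight_post <= 0:
            raise ValueError("body weights must be positive")


@dataclass
class EnrichmentSample:
    subject_id: str
    time: float         # days since dose
    h2_excess: float    # ppm excess above background
    o18_excess: float   # ppm excess above background


@dataclass
class EliminationFit:
    isotope: str                # "h2" or "o18"
    k: float                    # elimination constant, per day
    intercept_excess: float     # ppm excess at t = 0
    r_squared: float
    n_points: int
    residuals: np.ndarray       # log-scale residuals, fitted order
    times: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class DlwResult:
    subject_id: str
    n_h: float          # 2H dilution space, mol water
    n_o: float          # 18O dilution space, mol water
    pool_ratio: float   # n_h / n_o
    k_h: float          # per day
    k_o: float          # per day
    r_co2: float        # mol/d
    tee: float          # MJ/d; nan when flagged invalid
    qc_flags: set = field(default_factory=set)


def tracer_moles(dose: DoseRecord, constants: DlwConstants) -> tuple[float, float]:
    """Moles of excess tracer atoms (2H, 18O) delivered by a dose.

    The labelled-water components are treated as purity-weighted mixtures
    for their molar mass; each 2H2O molecule carries two deuterium atoms,
    each H2-18O molecule one 18O atom.
    """
    m_h2o = constants.water_molar_mass
    m_h_comp = dose.h2_purity * constants.m_2h2o + (1 - dose.h2_purity) * m_h2o
    m_o_comp = dose.o18_purity * constants.m_h218o + (1 - dose.o18_purity) * m_h2o
    mol_h_water = dose.dose_mass * dose.h2_fraction / m_h_comp
    mol_o_water = dose.dose_mass * dose.o18_fraction / m_o_comp
    mol_2h = 2.0 * mol_h_water * dose.h2_purity
    mol_18o = mol_o_water * dose.o18_purity
    return mol_2h, mol_18o


def fit_elimination(samples: list[EnrichmentSample], isotope: str) -> EliminationFit:
    """Log-linear OLS fit of excess enrichment decay for one isotope.

    Samples with non-positive excess are excluded with a warning; at least
    two usable points with distinct times are required.
    """
    if isotope not in ("h2", "o18"):
        raise ValueError("isotope must be 'h2' or 'o18'")
    attr = "h2_excess" if isotope == "h2" else "o18_excess"
    times, excess = [], []
    n_dropped = 0
    for s in samples:
        e = getattr(s, attr)
        if e <= 0:
            n_dropped += 1
            continue
        times.append(s.time)
        excess.append(e)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} sample(s) with non-positive {isotope} excess excluded",
            stacklevel=2)
    t = np.asarray(times, dtype=float)
    y = np.log(np.asarray(excess, dtype=float))
    if len(t) < 2 or np.ptp(t) == 0:
        raise InsufficientDataError(
            f"need >= 2 usable samples at distinct times for {isotope} fit "
            f"(got {len(t)})")
    slope, intercept = np.polyfit(t, y, 1)
    fitted = intercept + slope * t
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return EliminationFit(
        isotope=isotope,
        k=-float(slope),
        intercept_excess=float(np.exp(intercept)),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=len(t),
        residuals=resid,
        times=t,
    )


def compute_dilution_space(dose: DoseRecord, fit: EliminationFit,
                           isotope: str,
                           constants: DlwConstants | None = None) -> float:
    """Dilution space (mol water) from dose and back-extrapolated intercept.

    N = excess tracer atoms / (atom-fraction excess at t=0 × atom sites per
    water molecule); the intercept is the multipoint back-extrapolation,
    not a plateau sample.
    """
    constants = constants or DlwConstants()
    if fit.intercept_excess <= 0:
        raise ValueError("non-positive intercept excess: QC failure")
    mol_2h, mol_18o = tracer_moles(dose, constants)
    afe = fit.intercept_excess * 1e-6      # ppm -> atom fraction excess
    if isotope == "h2":
        return mol_2h / (2.0 * afe)
    if isotope == "o18":
        return mol_18o / afe
    raise ValueError("isotope must be 'h2' or 'o18'")


def _externally_studentized(fit: EliminationFit) -> np.ndarray:
    """Leave-one-out studentized residuals of the log-linear fit.

    With four-point curves an internally studentized residual is bounded
    by sqrt(n-2) and can never flag, so the deleted version is used.
    """
    t, r = fit.times, fit.residuals
    n = len(t)
    if n < 4:
        return np.zeros(n)
    h = 1.0 / n + (t - t.mean()) ** 2 / np.sum((t - t.mean()) ** 2)
    sse = float(np.sum(r ** 2))
    out = np.zeros(n)
    for i in range(n):
        s2_i = (sse - r[i] ** 2 / (1 - h[i])) / (n - 3)
        if s2_i <= 0:
            out[i] = 0.0 if abs(r[i]) < 1e-12 else np.inf
        else:
            out[i] = r[i] / math.sqrt(s2_i * (1 - h[i]))
    return out


def compute_tee(dose: DoseRecord, fit_h: EliminationFit, fit_o: EliminationFit,
                food_quotient: float = 0.85,
                constants: DlwConstants | None = None) -> DlwResult:
    """CO2 production and energy expenditure from the two elimination fits.

    rCO2 = (N/2.078)·(1.007·kO − 1.041·kH) − 0.0246·rGf with
    rGf = 1.05·N·(1.007·kO − 1.041·kH) and N the 18O dilution space scaled
    by the two-pool convention; energy via Weir at the given food quotient.
    A non-positive turnover difference flags the result invalid.
    """
    constants = constants or DlwConstants()
    if not 0.7 <= food_quotient <= 1.0:
        raise ValueError("food_quotient must lie in [0.7, 1.0]")
    n_h = compute_dilution_space(dose, fit_h, "h2", constants)
    n_o = compute_dilution_space(dose, fit_o, "o18", constants)
    n_body = n_o / constants.o18_space_scale
    flux = constants.f_o * fit_o.k - constants.f_h * fit_h.k
    result = DlwResult(
        subject_id=dose.subject_id,
        n_h=n_h, n_o=n_o, pool_ratio=n_h / n_o,
        k_h=fit_h.k, k_o=fit_o.k,
        r_co2=float("nan"), tee=float("nan"),
    )
    if flux <= 0:
        result.qc_flags.add("invalid_turnover")
        return qc_check(result, dose, fit_h, fit_o, constants)
    r_gf = constants.gf_fraction * n_body * flux
    r_co2 = (n_body / constants.space_factor) * flux - constants.gf_loss * r_gf
    result.r_co2 = r_co2
    result.tee = r_co2 * constants.energy_per_mol_co2(food_quotient)
    return qc_check(result, dose, fit_h, fit_o, constants)


def qc_check(result: DlwResult, dose: DoseRecord,
             fit_h: EliminationFit | None = None,
             fit_o: EliminationFit | None = None,
             constants: DlwConstants | None = None) -> DlwResult:
    """Apply the quality-control screens, updating ``result.qc_flags``.

    Flags: ``pool_ratio_out_of_range`` when n_H/n_O leaves the configured
    window; ``weight_unstable`` when |post − pre| body weight exceeds the
    1 kg stability criterion; ``residual_outlier`` when any log-scale
    externally studentized residual exceeds the threshold in magnitude.
    """
    constants = constants or DlwConstants()
    if not constants.pool_ratio_low <= result.pool_ratio <= constants.pool_ratio_high:
        result.qc_flags.add("pool_ratio_out_of_range")
    if abs(dose.body_weight_post - dose.body_weight_pre) > constants.weight_change_limit:
        result.qc_flags.add("weight_unstable")
    for fit in (fit_h, fit_o):
        if fit is None or fit.n_points < 4:
            continue
        threshold = constants.residual_threshold
        if threshold is None:
            # Bonferroni outlier-test critical value; with a t(n-3)-
            # distributed deleted residual a fixed cut is far too eager
            # on 4-point curves
            threshold = float(stats.t.ppf(
                1.0 - constants.residual_alpha / (2 * fit.n_points),
                fit.n_points - 3))
        if np.any(np.abs(_externally_studentized(fit)) > threshold):
            result.qc_flags.add("residual_outlier")
    return result


def process_subject(dose: DoseRecord, samples: list[EnrichmentSample],
                    food_quotient: float = 0.85,
                    constants: DlwConstants | None = None) -> DlwResult:
    """Full per-subject pipeline: two elimination fits then TEE with QC."""
    fit_h = fit_elimination(samples, "h2")
    fit_o = fit_elimination(samples, "o18")
    return compute_tee(dose, fit_h, fit_o, food_quotient, constants)


def process_tables(isotopes: pd.DataFrame, doses: pd.DataFrame,
                   food_quotient: float = 0.85,
                   constants: DlwConstants | None = None) -> pd.DataFrame:
    """Run the DLW computation for every subject in the input tables.

    ``isotopes`` columns: subject_id, time, h2_excess, o18_excess.
    ``doses`` columns: the DoseRecord fields. Returns one row per subject
    with dilution spaces, rate constants, rCO2, TEE and semicolon-joined
    QC flags.
    """
    rows = []
    for _, d in doses.iterrows():
        dose = DoseRecord(
            subject_id=str(d["subject_id"]),
            body_weight_pre=float(d["body_weight_pre"]),
            body_weight_post=float(d["body_weight_post"]),
            dose_mass=float(d["dose_mass"]),
            h2_fraction=float(d["h2_fraction"]),
            o18_fraction=float(d["o18_fraction"]),
            h2_purity=float(d.get("h2_purity", 0.999)),
            o18_purity=float(d.get("o18_purity", 0.10)),
        )
        sub = isotopes[isotopes["subject_id"].astype(str) == dose.subject_id]
        samples = [
            EnrichmentSample(dose.subject_id, float(r["time"]),
                             float(r["h2_excess"]), float(r["o18_excess"]))
            for _, r in sub.iterrows()
        ]
        res = process_subject(dose, samples, food_quotient, constants)
        rows.append({
            "subject_id": res.subject_id, "n_h": res.n_h, "n_o": res.n_o,
            "pool_ratio": res.pool_ratio, "k_h": res.k_h, "k_o": res.k_o,
            "r_co2": res.r_co2, "tee": res.tee,
            "qc_flags": ";".join(sorted(res.qc_flags)),
        })
    return pd.DataFrame(rows)


def write_results(results: pd.DataFrame, out_dir: str | Path,
                  food_quotient: float, constants: DlwConstants) -> None:
    """Write dlw_results.csv plus a JSON sidecar of constants in force."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "dlw_results.csv", index=False)
    sidecar = {"food_quotient": food_quotient, "constants": vars(constants)}
    (out_dir / "dlw_constants.json").write_text(json.dumps(sidecar, indent=2))
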