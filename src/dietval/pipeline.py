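"""End-to-end orchestration: simulate → DLW → misreporting → adjustment →
agreement/ranking → report.

Each stage reads and writes delimited text files in the run directory, so
a run can be resumed or repeated from any intermediate product. The final
report collects the summaries a validation study tabulates: energy
expenditure vs reported intake, misreporting prevalence, calibration
slopes, correlations, Bland-Altman agreement and cross-classification
with weighted kappa — as machine JSON and a human-readable text file.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import adjust, agreement, cohort, dlw, misreporting
from .config import INSTRUMENTS, CohortConfig

logger = logging.getLogger("dietval")

STAGES = ("simulate", "dlw", "misreport", "adjust", "agree", "report")


class QCError(RuntimeError):
    """Raised in strict mode when any DLW result carries a QC flag."""


def _read(out_dir: Path, name: str) -> pd.DataFrame:
    path = out_dir / name
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return pd.read_csv(path)


def stage_simulate(config: CohortConfig, out_dir: Path) -> None:
    logger.info("[simulate] generating cohort (n=%d, seed=%d)",
                config.n_subjects, config.seed)
    tables = cohort.simulate(config)
    cohort.write_tables(tables, out_dir)


def stage_dlw(config: CohortConfig, out_dir: Path,
              strict_qc: bool = False) -> None:
    isotopes = _read(out_dir, "isotopes.csv")
    doses = _read(out_dir, "doses.csv")
    logger.info("[dlw] computing TEE for %d subjects", len(doses))
    results = dlw.process_tables(isotopes, doses, config.food_quotient,
                                 config.dlw_constants)
    dlw.write_results(results, out_dir, config.food_quotient,
                      config.dlw_constants)
    flagged = results[results["qc_flags"].fillna("").astype(str).str.len() > 0]
    if len(flagged):
        logger.warning("[dlw] %d subject(s) carry QC flags", len(flagged))
        if strict_qc:
            raise QCError(f"QC flags on subjects: "
                          f"{flagged['subject_id'].tolist()}")


def stage_misreport(config: CohortConfig, out_dir: Path) -> None:
    intakes = _read(out_dir, "intakes.csv")
    results = _read(out_dir, "dlw_results.csv")
    params = {
        "record": misreporting.CutoffParams(
            cv_tee=config.cv_within_tee, cv_ei=config.cv_within_ei,
            d=config.record_days),
        "ffq": misreporting.CutoffParams(
            cv_tee=config.cv_within_tee, cv_ei=config.cv_within_ei,
            d=math.inf),
    }
    logger.info("[misreport] classifying reporters")
    classified = misreporting.classify_table(intakes, results, params)
    classified.to_csv(out_dir / "misreporting.csv", index=False)
    summary = misreporting.status_summary(classified)
    for inst, p in params.items():
        lim = misreporting.goldberg_limits(p)
        summary[inst]["limits"] = {
            "lower": lim.lower_rounded, "upper": lim.upper_rounded,
            "lower_unrounded": lim.lower, "upper_unrounded": lim.upper}
    (out_dir / "misreporting_summary.json").write_text(
        json.dumps(summary, indent=2))


def stage_adjust(config: CohortConfig, out_dir: Path) -> None:
    intakes = _read(out_dir, "intakes.csv")
    subjects = _read(out_dir, "subjects.csv")
    logger.info("[adjust] residual and density energy adjustment")
    frames = [
        adjust.adjust_table(intakes, subjects, method="residual", by_sex=True),
        adjust.adjust_table(intakes, subjects, method="density", by_sex=False),
    ]
    pd.concat(frames).to_csv(out_dir / "adjusted_intakes.csv", index=False)


def _dlw_merged(out_dir: Path) -> pd.DataFrame:
    intakes = _read(out_dir, "intakes.csv")
    results = _read(out_dir, "dlw_results.csv")
    valid = results[np.isfinite(results["tee"])]
    return intakes.merge(valid[["subject_id", "tee"]], on="subject_id")


def stage_agree(config: CohortConfig, out_dir: Path,
                plots: bool = False) -> None:
    logger.info("[agree] agreement, calibration and ranking statistics")
    merged = _dlw_merged(out_dir)
    intakes = _read(out_dir, "intakes.csv")
    adjusted = _read(out_dir, "adjusted_intakes.csv")

    agree_rows, corr_rows, cross_rows = [], [], []

    # --- each instrument vs DLW (subsample): energy only -------------
    for inst in INSTRUMENTS:
        grp = merged[merged["instrument"] == inst]
        ei, tee = grp["energy"].to_numpy(), grp["tee"].to_numpy()
        ba = agreement.bland_altman(ei, tee)
        cal = agreement.calibration_slope(ei, tee)
        wil = agreement.paired_compare(ei, tee)
        pear = agreement.correlate(ei, tee, "adjusted_pearson",
                                   pair=f"{inst}_vs_dlw")
        agree_rows.append({
            "comparison": f"{inst}_vs_dlw", "variable": "energy",
            "mean_difference": ba.mean_difference,
            "sd_difference": ba.sd_difference,
            "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
            "pct_outside_loa": ba.pct_outside_loa,
            "trend_slope": ba.trend_slope, "trend_p": ba.trend_p,
            "calibration_slope": cal.slope,
            "calibration_ci_lower": cal.ci_lower,
            "calibration_ci_upper": cal.ci_upper,
            "wilcoxon_statistic": wil.statistic, "wilcoxon_p": wil.p_value,
            "n": ba.n})
        corr_rows.append({
            "comparison": f"{inst}_vs_dlw", "variable": "energy",
            "mode": "pearson_crude", "coefficient": pear.coefficient,
            "p_value": pear.p_value, "transformation": "none"})
        tert_ei = agreement.quantile_bins(ei, 3)
        tert_tee = agreement.quantile_bins(tee, 3)
        cc = agreement.cross_classify(tert_ei, tert_tee)
        cross_rows.append(_cross_row(f"{inst}_vs_dlw", "energy", cc))
        if plots:
            agreement.bland_altman_plot(
                ei, tee, labels=(f"EI ({inst})", "TEE (DLW)"),
                path=str(out_dir / f"bland_altman_{inst}_vs_dlw.png"))

    # --- instrument vs instrument (full cohort) ----------------------
    rec = intakes[intakes["instrument"] == "record"].set_index("subject_id")
    ffq = intakes[intakes["instrument"] == "ffq"].set_index("subject_id")
    common = rec.index.intersection(ffq.index)
    rec, ffq = rec.loc[common], ffq.loc[common]

    ba = agreement.bland_altman(rec["energy"], ffq["energy"])
    wil = agreement.paired_compare(rec["energy"].to_numpy(),
                                   ffq["energy"].to_numpy())
    agree_rows.append({
        "comparison": "record_vs_ffq", "variable": "energy",
        "mean_difference": ba.mean_difference,
        "sd_difference": ba.sd_difference,
        "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
        "pct_outside_loa": ba.pct_outside_loa,
        "trend_slope": ba.trend_slope, "trend_p": ba.trend_p,
        "calibration_slope": float("nan"),
        "calibration_ci_lower": float("nan"),
        "calibration_ci_upper": float("nan"),
        "wilcoxon_statistic": wil.statistic, "wilcoxon_p": wil.p_value,
        "n": ba.n})
    corr_rows.append({
        "comparison": "record_vs_ffq", "variable": "energy",
        "mode": "crude_spearman",
        "coefficient": agreement.correlate(
            rec["energy"], ffq["energy"], "crude_spearman").coefficient,
        "p_value": agreement.correlate(
            rec["energy"], ffq["energy"], "crude_spearman").p_value,
        "transformation": "none"})
    cc = agreement.cross_classify(
        agreement.quantile_bins(rec["energy"].to_numpy(), 3),
        agreement.quantile_bins(ffq["energy"].to_numpy(), 3))
    cross_rows.append(_cross_row("record_vs_ffq", "energy", cc))
    if plots:
        agreement.bland_altman_plot(
            rec["energy"].to_numpy(), ffq["energy"].to_numpy(),
            labels=("EI (record)", "EI (ffq)"),
            path=str(out_dir / "bland_altman_record_vs_ffq.png"))

    # nutrients: crude Spearman + adjusted Pearson + quartile ranking
    resid = adjusted[adjusted["method"] == "residual"]
    for nut in adjust.NUTRIENT_COLUMNS:
        corr_rows.append({
            "comparison": "record_vs_ffq", "variable": nut,
            "mode": "crude_spearman",
            "coefficient": agreement.correlate(
                rec[nut], ffq[nut], "crude_spearman").coefficient,
            "p_value": agreement.correlate(
                rec[nut], ffq[nut], "crude_spearman").p_value,
            "transformation": "none"})
        piv = resid[resid["nutrient"] == nut].pivot_table(
            index="subject_id", columns="instrument", values="value")
        piv = piv.dropna()
        if {"record", "ffq"} <= set(piv.columns) and len(piv) >= 4:
            r = agreement.correlate(piv["record"], piv["ffq"],
                                    "adjusted_pearson")
            trans = resid[resid["nutrient"] == nut]["transformation"].iloc[0]
            corr_rows.append({
                "comparison": "record_vs_ffq", "variable": nut,
                "mode": "adjusted_pearson", "coefficient": r.coefficient,
                "p_value": r.p_value, "transformation": trans})
            cc = agreement.cross_classify(
                agreement.quantile_bins(piv["record"].to_numpy(), 4),
                agreement.quantile_bins(piv["ffq"].to_numpy(), 4))
            cross_rows.append(_cross_row("record_vs_ffq", nut, cc))

    pd.DataFrame(agree_rows).to_csv(out_dir / "agreement.csv", index=False)
    pd.DataFrame(corr_rows).to_csv(out_dir / "correlations.csv", index=False)
    pd.DataFrame(cross_rows).to_csv(out_dir / "crossclass.csv", index=False)


def _cross_row(comparison: str, variable: str,
               cc: agreement.CrossClassResult) -> dict:
    return {"comparison": comparison, "variable": variable,
            "n_bins": cc.n_bins, "pct_same": cc.pct_same,
            "pct_adjacent": cc.pct_adjacent, "pct_opposite": cc.pct_opposite,
            "kappa_weighted": cc.kappa_weighted,
            "weight_scheme": cc.weight_scheme}


def _mean_ci(values: np.ndarray, alpha: float = 0.05) -> dict:
    n = len(values)
    mean = float(np.mean(values))
    half = stats.t.ppf(1 - alpha / 2, n - 1) * np.std(values, ddof=1) / np.sqrt(n)
    return {"mean": mean, "ci_lower": mean - float(half),
            "ci_upper": mean + float(half), "n": n}


def stage_report(config: CohortConfig, out_dir: Path) -> dict:
    logger.info("[report] assembling validation report")
    subjects = _read(out_dir, "subjects.csv")
    results = _read(out_dir, "dlw_results.csv")
    merged = _dlw_merged(out_dir)
    mis_summary = json.loads(
        (out_dir / "misreporting_summary.json").read_text())
    agreement_df = _read(out_dir, "agreement.csv")
    corr_df = _read(out_dir, "correlations.csv")
    cross_df = _read(out_dir, "crossclass.csv")
    meta = json.loads((out_dir / "cohort_metadata.json").read_text())

    bmi = subjects["bmi"]
    report = {
        "cohort": {
            "n_subjects": int(len(subjects)),
            "n_by_sex": subjects["sex"].value_counts().to_dict(),
            "n_dlw": int(len(results)),
            "bmi_class_counts": {
                "normal_or_under": int((bmi < 25).sum()),
                "overweight": int(((bmi >= 25) & (bmi < 30)).sum()),
                "obese": int((bmi >= 30).sum()),
            },
        },
        "tee": _mean_ci(results.loc[np.isfinite(results["tee"]),
                                    "tee"].to_numpy()),
        "energy_intake": {}, "misreporting": mis_summary,
        "agreement": agreement_df.to_dict(orient="records"),
        "correlations": corr_df.to_dict(orient="records"),
        "cross_classification": cross_df.to_dict(orient="records"),
        "qc": {"n_flagged": int((results["qc_flags"].fillna("").astype(str)
                                 .str.len() > 0).sum())},
        "metadata": {"seed": meta["seed"], "config_hash": meta["config_hash"],
                     "decisions": {
                         "kappa_weights": "linear",
                         "adjustment": "transform-then-residual, sex-stratified",
                         "quantile_ties": "boundary ties to lower bin"}},
    }
    for inst in INSTRUMENTS:
        grp = merged[merged["instrument"] == inst]
        diff = grp["energy"].to_numpy() - grp["tee"].to_numpy()
        report["energy_intake"][inst] = {
            **_mean_ci(grp["energy"].to_numpy()),
            "mean_difference_vs_tee": float(np.mean(diff)),
            "sd_difference_vs_tee": float(np.std(diff, ddof=1)),
        }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, default=float))
    (out_dir / "report.txt").write_text(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable summary; 1 decimal for MJ and %, 2 for r and kappa."""
    lines = []
    c = report["cohort"]
    lines.append("Dietary instrument validation report")
    lines.append("=" * 38)
    lines.append(f"Cohort: {c['n_subjects']} subjects "
                 f"({c['n_by_sex']}), DLW subsample n={c['n_dlw']}")
    t = report["tee"]
    lines.append(f"TEE (DLW): mean {t['mean']:.1f} MJ/d "
                 f"(95% CI {t['ci_lower']:.1f}, {t['ci_upper']:.1f})")
    for inst, e in report["energy_intake"].items():
        lines.append(
            f"EI {inst}: mean {e['mean']:.1f} MJ/d "
            f"(95% CI {e['ci_lower']:.1f}, {e['ci_upper']:.1f}); "
            f"EI-TEE {e['mean_difference_vs_tee']:.1f} "
            f"(SD {e['sd_difference_vs_tee']:.1f}) MJ/d")
    for inst, m in report["misreporting"].items():
        lim = m["limits"]
        pct = m["percent"]
        lines.append(
            f"Misreporting {inst}: limits ({lim['lower']:.2f}, "
            f"{lim['upper']:.2f}); under {pct['under']:.1f}%, "
            f"plausible {pct['plausible']:.1f}%, over {pct['over']:.1f}%; "
            f"accuracy {m['accuracy_mean']:.1f}% (SD {m['accuracy_sd']:.1f})")
    for row in report["agreement"]:
        if row["variable"] != "energy":
            continue
        lines.append(
            f"Bland-Altman {row['comparison']}: mean diff "
            f"{row['mean_difference']:.1f} (SD {row['sd_difference']:.1f}), "
            f"LoA ({row['loa_lower']:.1f}, {row['loa_upper']:.1f}), "
            f"trend P={row['trend_p']:.2f}")
        if np.isfinite(row["calibration_slope"]):
            lines.append(
                f"  calibration slope {row['calibration_slope']:.2f} "
                f"(95% CI {row['calibration_ci_lower']:.2f}, "
                f"{row['calibration_ci_upper']:.2f})")
    for row in report["cross_classification"]:
        if row["variable"] == "energy":
            lines.append(
                f"Ranking {row['comparison']} (energy, {row['n_bins']} bins): "
                f"same {row['pct_same']:.1f}%, opposite "
                f"{row['pct_opposite']:.1f}%, kappa_w "
                f"{row['kappa_weighted']:.2f}")
    md = report["metadata"]
    lines.append(f"Run: seed={md['seed']} config_hash={md['config_hash']}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: CohortConfig, out_dir: str | Path,
                 strict_qc: bool = False, plots: bool = False) -> dict:
    """Execute every stage in order and return the report dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, out_dir)
    stage_dlw(config, out_dir, strict_qc=strict_qc)
    stage_misreport(config, out_dir)
    stage_adjust(config, out_dir)
    stage_agree(config, out_dir, plots=plots)
    return stage_report(config, out_dir)
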