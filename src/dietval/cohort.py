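"""Seeded synthetic validation cohorts.

Generates subjects with a true total energy expenditure (TEE), two dietary
instruments' reported intakes (a multi-day record and a food-frequency
questionnaire), and — for a DLW subsample — dosing records and isotope
enrichment time series constructed by inverting the same two-pool CO2
model the engine uses, so that a noise-free cohort closes the loop
exactly.

Reported energy is true TEE times a subject-level reporting-accuracy
draw (truncated normal, matching the mean/SD structure of validation
studies of web-based instruments) times within-subject sampling noise.
Macronutrient grams are back-calculated from reported energy through
per-subject energy shares and standard energy conversion factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import INSTRUMENTS, CohortConfig
from .dlw import DoseRecord, EnrichmentSample, tracer_moles

__all__ = ["Subject", "CohortTables", "generate_cohort",
           "generate_isotope_series", "generate_dlw_tables",
           "simulate", "write_tables"]


@dataclass
class Subject:
    id: str
    sex: str                # "female" | "male"
    body_weight: float      # kg
    bmi: float              # kg/m2
    true_tee: float         # MJ/d
    weight_change: float    # kg over the DLW period


@dataclass
class CohortTables:
    """All simulated tables of one cohort plus the run metadata."""
    subjects: pd.DataFrame
    intakes: pd.DataFrame
    doses: pd.DataFrame
    isotopes: pd.DataFrame
    metadata: dict


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float = 0.0) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _subject_shares(rng: np.random.Generator, config: CohortConfig,
                    n: int) -> dict[str, np.ndarray]:
    """Per-subject energy shares: log-jittered means, zero-inflated
    alcohol, renormalised to sum to 1 row-wise. Vectorised over subjects."""
    means = config.macronutrient_share_means
    sigma = config.macronutrient_share_sd
    keys = list(means)
    raw = {k: means[k] * np.exp(rng.normal(0.0, sigma, n)) for k in keys}
    if "alcohol" in raw:
        nondrinker = rng.random(n) < config.alcohol_nonconsumer_prob
        raw["alcohol"] = np.where(nondrinker, 0.0, raw["alcohol"])
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def generate_cohort(config: CohortConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the subject table and the per-instrument intake table.

    Deterministic for a fixed config (the seed lives in the config); sexes
    are balanced; true TEE is truncated-normal positive; reported energy is
    true TEE x accuracy x within-subject noise, truncated above zero.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_subjects
    sexes = np.array(["female", "male"])[np.arange(n) % 2]
    height_mu = np.where(sexes == "male", config.height_mean["male"],
                         config.height_mean["female"])
    weight_mu = np.where(sexes == "male", config.body_weight_mean["male"],
                         config.body_weight_mean["female"])
    heights = rng.normal(height_mu, config.height_sd)
    weights = np.maximum(rng.normal(weight_mu, config.body_weight_sd), 40.0)
    true_tee = _truncated_normal(rng, config.tee_mean, config.tee_sd, n)
    weight_change = np.clip(
        rng.normal(0.0, config.weight_change_sd, n),
        -config.weight_change_max, config.weight_change_max)

    subjects = pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "sex": sexes,
        "body_weight": weights,
        "bmi": weights / heights ** 2,
        "true_tee": true_tee,
        "weight_change": weight_change,
    })

    noise_cv = {
        "record": config.cv_within_ei / 100.0 / np.sqrt(config.record_days),
        "ffq": config.cv_within_ei_ffq / 100.0,
    }
    shares_true = _subject_shares(rng, config, n)
    frames = []
    for inst in INSTRUMENTS:
        acc = _truncated_normal(
            rng, config.accuracy_mean_by_instrument[inst],
            config.accuracy_sd_by_instrument[inst], n)
        noise = (1.0 + rng.normal(0.0, noise_cv[inst], n)
                 if noise_cv[inst] > 0 else np.ones(n))
        energy = np.maximum(true_tee * acc * noise, 1e-9)
        frames.append(_intake_frame(rng, config, subjects["subject_id"],
                                    inst, energy, shares_true))
    intakes = pd.concat(frames, ignore_index=True)
    return subjects, intakes


def _intake_frame(rng: np.random.Generator, config: CohortConfig,
                  subject_ids: pd.Series, instrument: str,
                  energy: np.ndarray,
                  shares_true: dict[str, np.ndarray]) -> pd.DataFrame:
    n = len(energy)
    # small instrument-specific perturbation of the subject's true shares
    shares = {k: np.where(v > 0, v * np.exp(rng.normal(0.0, 0.05, n)), 0.0)
              for k, v in shares_true.items()}
    total = sum(shares.values())
    shares = {k: v / total for k, v in shares.items()}
    energy_kj = energy * 1000.0
    grams = {k: shares[k] * energy_kj / config.energy_factors[k]
             for k in shares}
    sub = {k: v * np.exp(rng.normal(0.0, 0.08, n))
           for k, v in config.fat_subshares.items()}
    sub_total = sum(sub.values())
    scale = np.where(sub_total > 0.98, 0.98 / sub_total, 1.0)
    sub = {k: v * scale for k, v in sub.items()}
    sucrose = np.minimum(
        grams["carbohydrate"],
        grams["carbohydrate"] * config.sucrose_share_of_carb
        * np.exp(rng.normal(0.0, 0.2, n)))
    fibre = config.fibre_g_per_mj * energy * np.exp(rng.normal(0.0, 0.2, n))
    return pd.DataFrame({
        "subject_id": subject_ids.to_numpy(), "instrument": instrument,
        "energy": energy,
        "protein": grams["protein"], "fat": grams["fat"],
        "sfa": grams["fat"] * sub["sfa"],
        "mufa": grams["fat"] * sub["mufa"],
        "pufa": grams["fat"] * sub["pufa"],
        "carbohydrate": grams["carbohydrate"],
        "sucrose": sucrose, "fibre": fibre,
        "alcohol": grams["alcohol"],
    })


def _dose_rate(sex: str, bmi: float) -> float:
    """g of dose mixture per kg body weight (reduced for BMI > 30)."""
    if bmi > 30.0:
        return 0.6 if sex == "male" else 0.5
    return 1.0


def generate_isotope_series(subject: Subject, config: CohortConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[DoseRecord, list[EnrichmentSample]]:
    """Dose record and enrichment samples consistent with the subject's TEE.

    Pool sizes come from a sex-specific total-body-water fraction of body
    weight; the elimination constants are obtained by inverting the
    two-pool rCO2 equation so the engine's forward computation returns
    ``subject.true_tee`` exactly when the enrichment noise is zero.
    """
    if subject.true_tee <= 0:
        raise ValueError("subject.true_tee must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    c = config.dlw_constants
    rate = _dose_rate(subject.sex, subject.bmi)
    dose = DoseRecord(
        subject_id=subject.id,
        body_weight_pre=subject.body_weight,
        body_weight_post=subject.body_weight + subject.weight_change,
        dose_mass=rate * subject.body_weight,
        h2_fraction=0.05, o18_fraction=0.10,
    )
    tbw_kg = config.tbw_fraction[subject.sex] * subject.body_weight
    n_body = tbw_kg * 1000.0 / c.water_molar_mass
    n_o = c.o18_space_scale * n_body
    n_h = c.h2_space_scale * n_body

    mol_2h, mol_18o = tracer_moles(dose, c)
    e_h0 = mol_2h / (2.0 * n_h) * 1e6     # ppm atom-fraction excess at t=0
    e_o0 = mol_18o / n_o * 1e6

    r_co2 = subject.true_tee / c.energy_per_mol_co2(config.food_quotient)
    flux = r_co2 / (n_body * (1.0 / c.space_factor - c.gf_loss * c.gf_fraction))
    k_h = flux / (c.f_o * config.ko_kh_ratio - c.f_h)
    k_o = config.ko_kh_ratio * k_h

    samples = []
    for t in config.sample_days:
        noise_h = np.exp(rng.normal(0.0, config.enrichment_noise_sd)) \
            if config.enrichment_noise_sd > 0 else 1.0
        noise_o = np.exp(rng.normal(0.0, config.enrichment_noise_sd)) \
            if config.enrichment_noise_sd > 0 else 1.0
        samples.append(EnrichmentSample(
            subject_id=subject.id, time=float(t),
            h2_excess=e_h0 * np.exp(-k_h * t) * noise_h,
            o18_excess=e_o0 * np.exp(-k_o * t) * noise_o,
        ))
    return dose, samples


def _dlw_subsample(subjects: pd.DataFrame, n_dlw: int) -> pd.DataFrame:
    """Sex-balanced DLW subsample: first n/2 of each sex in table order."""
    per_sex = n_dlw // 2
    parts = [subjects[subjects["sex"] == s].head(per_sex)
             for s in ("female", "male")]
    picked = pd.concat(parts)
    if len(picked) < n_dlw:   # odd n or not enough of one sex
        rest = subjects.drop(picked.index)
        picked = pd.concat([picked, rest.head(n_dlw - len(picked))])
    return picked.sort_index()


def generate_dlw_tables(subjects: pd.DataFrame, config: CohortConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Doses and isotope series for the DLW subsample, as flat tables."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    picked = _dlw_subsample(subjects, config.n_dlw_subjects)
    dose_rows, iso_rows = [], []
    for _, row in picked.iterrows():
        subj = Subject(
            id=row["subject_id"], sex=row["sex"],
            body_weight=row["body_weight"], bmi=row["bmi"],
            true_tee=row["true_tee"], weight_change=row["weight_change"])
        dose, samples = generate_isotope_series(subj, config, rng)
        dose_rows.append(vars(dose))
        iso_rows.extend(vars(s) for s in samples)
    return pd.DataFrame(dose_rows), pd.DataFrame(iso_rows)


def simulate(config: CohortConfig) -> CohortTables:
    """Generate the complete cohort: subjects, intakes, doses, isotopes."""
    ss = np.random.SeedSequence(config.seed)
    rng_cohort, rng_iso = (np.random.default_rng(s) for s in ss.spawn(2))
    subjects, intakes = generate_cohort(config, rng_cohort)
    doses, isotopes = generate_dlw_tables(subjects, config, rng_iso)
    metadata = {"seed": config.seed, "config_hash": config.config_hash(),
                "config": config.to_dict()}
    return CohortTables(subjects, intakes, doses, isotopes, metadata)


def write_tables(tables: CohortTables, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables.subjects.to_csv(out_dir / "subjects.csv", index=False)
    tables.intakes.to_csv(out_dir / "intakes.csv", index=False)
    tables.doses.to_csv(out_dir / "doses.csv", index=False)
    tables.isotopes.to_csv(out_dir / "isotopes.csv", index=False)
    (out_dir / "cohort_metadata.json").write_text(
        json.dumps(tables.metadata, indent=2, default=float))
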