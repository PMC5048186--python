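"""Configuration objects for the synthetic cohort and analysis pipeline.

All tunable parameters of the simulation and of the doubly-labelled-water
(DLW) calculation live here, so that a single YAML file fully determines a
pipeline run and its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

INSTRUMENTS = ("record", "ffq")

#: kJ per gram for back-calculating macronutrient grams from energy.
DEFAULT_ENERGY_FACTORS = {
    "protein": 17.0,
    "carbohydrate": 17.0,
    "fat": 37.0,
    "alcohol": 29.0,
}


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class DlwConstants:
    """Physical constants of the two-pool DLW calculation.

    The CO2-production equation is the Schoeller-type multipoint two-pool
    form, rCO2 = (N/space_factor)·(f_o·kO − f_h·kH) − gf_loss·rGf with
    rGf = gf_fraction·N·(f_o·kO − f_h·kH); energy from rCO2 via the Weir
    expression EE = VCO2·(weir_co2 + weir_o2/FQ).
    """

    f_o: float = 1.007          # fractionation factor on the 18O rate
    f_h: float = 1.041          # fractionation factor on the 2H rate
    space_factor: float = 2.078
    gf_loss: float = 0.0246     # fractionated-water loss term coefficient
    gf_fraction: float = 1.05
    weir_co2: float = 1.106     # kcal per litre CO2
    weir_o2: float = 3.941      # kcal per litre O2
    co2_litres_per_mol: float = 22.26
    mj_per_kcal: float = 4.184e-3
    water_molar_mass: float = 18.0153   # g/mol, body water
    m_2h2o: float = 20.0276             # g/mol, 2H2O
    m_h218o: float = 20.0148            # g/mol, H2-18O
    #: dilution-space scaling: N = n_O / o18_space_scale (two-pool convention)
    o18_space_scale: float = 1.01
    h2_space_scale: float = 1.04
    pool_ratio_low: float = 1.00
    pool_ratio_high: float = 1.07
    weight_change_limit: float = 1.0    # kg, acceptable pre/post difference
    #: hard cut on |externally studentized residual|; None = Bonferroni
    #: critical value t(n-3, 1 - residual_alpha/(2n)) per curve
    residual_threshold: float | None = None
    residual_alpha: float = 0.01

    def energy_per_mol_co2(self, food_quotient: float) -> float:
        """MJ of energy expenditure per mol of CO2 produced at a given FQ."""
        kcal_per_litre = self.weir_co2 + self.weir_o2 / food_quotient
        return self.co2_litres_per_mol * kcal_per_litre * self.mj_per_kcal


@dataclass
class CohortConfig:
    """Parameters of the synthetic validation cohort.

    Defaults mirror the study design this package emulates: ~200 subjects
    with two dietary instruments (a 4-day web record and an FFQ), a DLW
    subsample of 40, mean TEE 10.8 MJ/d, instrument reporting-accuracy
    distributions of 0.80 (SD 0.23) and 0.82 (SD 0.33), within-subject CVs
    of 20.6% for record EI and 8.4% for TEE, and urine sampling on days
    1, 3, 12 and 14 after the dose.
    """

    n_subjects: int = 200
    n_dlw_subjects: int = 40
    seed: int = 0
    tee_mean: float = 10.8              # MJ/d
    tee_sd: float = 2.7                 # MJ/d
    accuracy_mean_by_instrument: dict = field(
        default_factory=lambda: {"record": 0.80, "ffq": 0.82})
    accuracy_sd_by_instrument: dict = field(
        default_factory=lambda: {"record": 0.23, "ffq": 0.33})
    cv_within_ei: float = 20.6          # percent, record EI
    cv_within_ei_ffq: float = 0.0       # percent, FFQ EI (free parameter)
    cv_within_tee: float = 8.4          # percent
    record_days: int = 4                # d in the Goldberg formula
    macronutrient_share_means: dict = field(
        default_factory=lambda: {
            "protein": 0.17, "fat": 0.34, "carbohydrate": 0.45, "alcohol": 0.04})
    macronutrient_share_sd: float = 0.15    # log-scale per-subject jitter, renormalised
    alcohol_nonconsumer_prob: float = 0.15  # probability of zero alcohol intake
    fat_subshares: dict = field(
        default_factory=lambda: {"sfa": 0.42, "mufa": 0.38, "pufa": 0.16})
    sucrose_share_of_carb: float = 0.20
    fibre_g_per_mj: float = 2.2
    energy_factors: dict = field(
        default_factory=lambda: dict(DEFAULT_ENERGY_FACTORS))
    enrichment_noise_sd: float = 0.005  # relative (multiplicative, log-scale)
    sample_days: tuple = (1.0, 3.0, 12.0, 14.0)
    body_weight_mean: dict = field(
        default_factory=lambda: {"female": 70.0, "male": 85.0})
    body_weight_sd: float = 12.0
    height_mean: dict = field(
        default_factory=lambda: {"female": 1.66, "male": 1.80})
    height_sd: float = 0.06
    tbw_fraction: dict = field(
        default_factory=lambda: {"female": 0.50, "male": 0.58})
    weight_change_sd: float = 0.3       # kg
    weight_change_max: float = 1.0      # kg, clip
    food_quotient: float = 0.85
    ko_kh_ratio: float = 1.25           # kO/kH used when inverting the model
    dlw_constants: DlwConstants = field(default_factory=DlwConstants)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_dlw_subjects > self.n_subjects:
            raise ConfigurationError("n_dlw_subjects must be <= n_subjects")
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if self.tee_sd < 0 or self.tee_mean <= 0:
            raise ConfigurationError("tee_mean must be > 0 and tee_sd >= 0")
        for inst in INSTRUMENTS:
            if inst not in self.accuracy_mean_by_instrument:
                raise ConfigurationError(f"missing accuracy mean for {inst!r}")
            if self.accuracy_sd_by_instrument.get(inst, -1.0) < 0:
                raise ConfigurationError(f"accuracy SD for {inst!r} must be >= 0")
        if min(self.cv_within_ei, self.cv_within_tee, self.cv_within_ei_ffq) < 0:
            raise ConfigurationError("within-subject CVs must be >= 0")
        share_sum = sum(self.macronutrient_share_means.values())
        if not math.isclose(share_sum, 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"macronutrient share means must sum to 1 (got {share_sum})")
        if any(v < 0 for v in self.macronutrient_share_means.values()):
            raise ConfigurationError("macronutrient shares must be >= 0")
        if sum(self.fat_subshares.values()) > 1.0 + 1e-9:
            raise ConfigurationError("fat subshares must sum to <= 1")
        days = tuple(self.sample_days)
        if not days or days[0] <= 0 or any(
                b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError(
                "sample_days must be strictly increasing with first element > 0")
        if self.enrichment_noise_sd < 0:
            raise ConfigurationError("enrichment_noise_sd must be >= 0")
        if not 0.7 <= self.food_quotient <= 1.0:
            raise ConfigurationError("food_quotient must lie in [0.7, 1.0]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sample_days"] = list(self.sample_days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "dlw_constants" in d and isinstance(d["dlw_constants"], dict):
            d["dlw_constants"] = DlwConstants(**d["dlw_constants"])
        if "sample_days" in d:
            d["sample_days"] = tuple(float(t) for t in d["sample_days"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON parameter dump (run provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
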