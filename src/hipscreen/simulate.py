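"""Synthetic cohort generator.

Emulates the statistical structure the screening analysis assumes in a
single-centre multiethnic pregnancy cohort: OGTT glucose triplets from a
correlated trivariate normal with published means and SDs, maternal age/BMI
from truncated normals, risk-factor prevalences matching the published
baseline table, and Bernoulli pregnancy outcomes from per-outcome logistic
models driven by glucose z-scores and personal history of hyperglycemia in
pregnancy (HIP).

Two deliberate structural features:

* Women with a history of HIP have their glucose means shifted upwards
  (default one SD per value), reproducing the roughly 50% recurrence rate of
  HIP reported in the literature.
* Women who are reference-standard positive are assumed treated, so a
  treatment-attenuation factor shrinks the glucose terms of every outcome's
  linear predictor for them, mimicking the care such women received in the
  study setting.

All randomness flows from a single ``numpy`` Generator seeded from the
config; identical configs produce identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .diagnosis import Thresholds, DEFAULT_THRESHOLDS
from .model import (
    Ethnicity,
    GlucoseTriplet,
    HistoryStatus,
    OutcomeRecord,
    WomanRecord,
)

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True, slots=True)
class OutcomeModel:
    """Logistic model for one outcome.

    ``logit p = intercept + b_fpg*z_fpg + b_pg1h*z_pg1h + b_pg2h*z_pg2h
    + b_history*[history of HIP]`` where the z-scores are taken against the
    cohort-level glucose means/SDs; the glucose terms are multiplied by the
    treatment-attenuation factor for reference-positive (treated) women.
    """

    intercept: float
    b_fpg: float
    b_pg1h: float
    b_pg2h: float
    b_history: float


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    n: int
    seed: int
    glucose_mean: tuple[float, float, float]
    glucose_sd: tuple[float, float, float]
    #: common off-diagonal correlation of the glucose triplet
    glucose_corr: float
    #: additional glucose shift (in SD units, per value) for women with a
    #: personal history of HIP; drives the ~50% recurrence rate
    history_glucose_shift_sd: float
    prevalences: Mapping[str, float]
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    ga_mean: float
    ga_sd: float
    early_fpg_mean: float
    early_fpg_sd: float
    early_fpg_corr: float
    ethnicity_probs: Mapping[Ethnicity, float]
    outcome_model: Mapping[str, OutcomeModel]
    treatment_attenuation: float
    insulin_rate_treated: float
    thresholds: Thresholds = DEFAULT_THRESHOLDS

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(s <= 0 for s in self.glucose_sd) or min(
            self.age_sd, self.bmi_sd, self.ga_sd, self.early_fpg_sd
        ) <= 0:
            raise ValueError("all SDs must be > 0")
        if not -0.5 < self.glucose_corr < 1.0:
            # equicorrelation is positive-definite for rho in (-1/2, 1)
            raise ValueError("glucose_corr must lie in (-0.5, 1) for a valid matrix")
        total = sum(self.ethnicity_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ethnicity_probs must sum to 1, got {total}")
        if not 0.0 <= self.treatment_attenuation <= 1.0:
            raise ValueError("treatment_attenuation must be in [0, 1]")
        for k, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {k}={p} outside [0, 1]")

    def correlation_matrix(self) -> np.ndarray:
        m = np.full((3, 3), self.glucose_corr)
        np.fill_diagonal(m, 1.0)
        return m


@dataclass(frozen=True, slots=True)
class GeneratedCohort:
    records: tuple[WomanRecord, ...]
    config: SimulationConfig
    seed: int


#: marginal outcome rates of the emulated cohort (fractions of all women);
#: intercepts below were calibrated against these with
#: :func:`calibrate_intercepts` at n=200000
TARGET_OUTCOME_RATES: dict[str, float] = {
    "preeclampsia": 0.0167,
    "lga": 0.0942,
    "sga": 0.0982,
    "shoulder_dystocia": 0.0014,
    "neonatal_hypoglycemia": 0.0064,
    "cesarean": 0.2031,
    "preterm_delivery": 0.0539,
    "nicu_admission": 0.1913,
    "respiratory_distress": 0.0476,
    "perinatal_death": 0.0031,
}

# glucose/history log-odds slopes per outcome; intercepts are the calibrated
# values (see calibrate_intercepts)
_DEFAULT_OUTCOME_MODEL: dict[str, OutcomeModel] = {
    "preeclampsia": OutcomeModel(-4.0820, 0.15, 0.10, 0.10, 0.10),
    "lga": OutcomeModel(-2.3507, 0.35, 0.25, 0.15, 0.60),
    "sga": OutcomeModel(-2.2340, -0.10, -0.05, -0.05, -0.20),
    "shoulder_dystocia": OutcomeModel(-6.5844, 0.10, 0.10, 0.10, 0.30),
    "neonatal_hypoglycemia": OutcomeModel(-5.1959, 0.40, 0.30, 0.30, 0.20),
    "cesarean": OutcomeModel(-1.3723, 0.15, 0.10, 0.10, 0.30),
    "preterm_delivery": OutcomeModel(-2.8646, 0.10, 0.05, 0.10, 0.10),
    "nicu_admission": OutcomeModel(-1.4418, 0.10, 0.10, 0.10, 0.20),
    "respiratory_distress": OutcomeModel(-3.0006, 0.10, 0.05, 0.10, 0.20),
    "perinatal_death": OutcomeModel(-5.7821, 0.10, 0.10, 0.10, 0.20),
}


def default_config(n: int = 4245, seed: int = 20210121) -> SimulationConfig:
    """Defaults calibrated to the emulated cohort's baseline table.

    Glucose means/SDs (4.38/0.45, 6.76/1.76, 5.96/1.43 mmol/L), age
    30.25 (5.32) years, BMI 24.36 (4.48) kg/m2, risk-factor prevalences
    (history of HIP 3.6%, macrosomia 2.3%, fetal death 1.3%, family history
    of diabetes 19.4%, 41.7% first pregnancies) and the ethnicity mix are
    the published cohort values.  The glucose correlation (0.4) and the
    history glucose shift (1 SD) are generator choices, not published
    quantities; both are exposed here.
    """
    ethnicity_counts = {
        Ethnicity.NORTH_AFRICAN: 866,
        Ethnicity.EUROPEAN: 1509,
        Ethnicity.SUBSAHARAN_AFRICAN: 888,
        Ethnicity.INDIAN_PAKISTANI_SRILANKAN: 342,
        Ethnicity.CARIBBEAN: 281,
        Ethnicity.ASIAN: 72,
        Ethnicity.OTHER: 285,
    }
    total = sum(ethnicity_counts.values())
    return SimulationConfig(
        n=n,
        seed=seed,
        glucose_mean=(4.38, 6.76, 5.96),
        glucose_sd=(0.45, 1.76, 1.43),
        glucose_corr=0.4,
        history_glucose_shift_sd=1.0,
        prevalences={
            "history_hip": 0.036,
            "history_macrosomia": 0.023,
            "history_fetal_death": 0.013,
            "family_history": 0.194,
            "nulliparous_fraction": 0.417,
        },
        age_mean=30.25,
        age_sd=5.32,
        bmi_mean=24.36,
        bmi_sd=4.48,
        ga_mean=26.22,
        ga_sd=1.89,
        early_fpg_mean=4.25,
        early_fpg_sd=0.35,
        early_fpg_corr=0.5,
        ethnicity_probs={e: c / total for e, c in ethnicity_counts.items()},
        outcome_model=dict(_DEFAULT_OUTCOME_MODEL),
        treatment_attenuation=0.5,
        insulin_rate_treated=0.357,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, n: int
) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_glucose(
    config: SimulationConfig, rng: np.random.Generator, history_hip: np.ndarray
) -> np.ndarray:
    """Correlated glucose triplets; values below 1.0 mmol/L are resampled.

    The configured means are the *marginal* cohort means, so the base means
    are lowered by the population-expected history shift
    (prevalence x shift); women with a history of HIP then sit
    ``history_glucose_shift_sd`` SDs above the rest.
    """
    n = history_hip.size
    sd = np.asarray(config.glucose_sd)
    chol = np.linalg.cholesky(config.correlation_matrix())
    shift = config.history_glucose_shift_sd * sd
    mean = (
        np.asarray(config.glucose_mean)
        - config.prevalences["history_hip"] * shift
    )

    def draw(k: int) -> np.ndarray:
        z = rng.standard_normal((k, 3)) @ chol.T
        return mean + z * sd

    glucose = draw(n)
    glucose[history_hip] += shift
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = (glucose <= 1.0).any(axis=1)
        if not bad.any():
            return glucose
        k = int(bad.sum())
        redraw = draw(k)
        redraw[history_hip[bad]] += shift
        glucose[bad] = redraw
    raise RuntimeError("glucose resampling did not converge")  # pragma: no cover


def _draw_early_fpg(
    config: SimulationConfig, rng: np.random.Generator, z_fpg: np.ndarray
) -> np.ndarray:
    """First-trimester FPG correlated with the OGTT fasting value, truncated
    below the early-HIP eligibility cutoff (such women were excluded)."""
    n = z_fpg.size
    rho = config.early_fpg_corr
    cutoff = config.thresholds.early_fpg_cutoff - 0.05  # one-decimal rounding
    mix = rho * z_fpg + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    early = config.early_fpg_mean + config.early_fpg_sd * mix
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = (early >= cutoff) | (early <= 1.0)
        if not bad.any():
            return early
        k = int(bad.sum())
        mix = rho * z_fpg[bad] + math.sqrt(1.0 - rho * rho) * rng.standard_normal(k)
        early[bad] = config.early_fpg_mean + config.early_fpg_sd * mix
    raise ValueError(
        "early-pregnancy FPG truncation infeasible: distribution mass lies "
        "almost entirely at or above the eligibility cutoff"
    )


def _reference_positive(config: SimulationConfig, glucose: np.ndarray) -> np.ndarray:
    """Vectorized reference-standard HIP flag (one-decimal rounding)."""
    t = config.thresholds
    g = np.floor(glucose * 10.0 + 0.5) / 10.0
    dip = (g[:, 0] >= t.fpg_dip) | (g[:, 2] >= t.pg2h_dip)
    gdm = (g[:, 0] >= t.fpg_gdm) | (g[:, 1] >= t.pg1h_gdm) | (g[:, 2] >= t.pg2h_gdm)
    return dip | gdm


def _conditional(prevalence: float, nullip_frac: float) -> float:
    """Convert a cohort-marginal history prevalence to the conditional
    probability among parous women."""
    if nullip_frac >= 1.0:
        return 0.0
    p = prevalence / (1.0 - nullip_frac)
    if p > 1.0:
        raise ValueError(f"marginal prevalence {prevalence} infeasible at "
                         f"{nullip_frac:.0%} first pregnancies")
    return p


@dataclass(frozen=True, slots=True)
class _Arrays:
    """Vectorized intermediate representation of a cohort."""

    glucose: np.ndarray
    z_glucose: np.ndarray
    history_hip: np.ndarray
    history_macrosomia: np.ndarray
    history_fetal_death: np.ndarray
    nulliparous: np.ndarray
    family_history: np.ndarray
    ethnicity: np.ndarray
    age: np.ndarray
    bmi: np.ndarray
    ga: np.ndarray
    early_fpg: np.ndarray
    reference_positive: np.ndarray


def _simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> _Arrays:
    n = config.n
    prev = config.prevalences
    nullip_frac = prev["nulliparous_fraction"]
    nulliparous = rng.random(n) < nullip_frac
    parous = ~nulliparous

    def history(key: str) -> np.ndarray:
        flags = np.zeros(n, dtype=bool)
        flags[parous] = rng.random(int(parous.sum())) < _conditional(prev[key], nullip_frac)
        return flags

    history_hip = history("history_hip")
    history_macrosomia = history("history_macrosomia")
    history_fetal_death = history("history_fetal_death")
    family_history = rng.random(n) < prev["family_history"]
    eth_order = list(config.ethnicity_probs)
    ethnicity = rng.choice(
        len(eth_order), size=n, p=[config.ethnicity_probs[e] for e in eth_order]
    )
    t = config.thresholds
    age = _truncated_normal(rng, config.age_mean, config.age_sd, t.age_min, t.age_max, n)
    bmi = _truncated_normal(rng, config.bmi_mean, config.bmi_sd, 13.0, 60.0, n)
    ga = _truncated_normal(rng, config.ga_mean, config.ga_sd, t.ga_min, t.ga_max, n)
    glucose = _draw_glucose(config, rng, history_hip)
    z = (glucose - np.asarray(config.glucose_mean)) / np.asarray(config.glucose_sd)
    early_fpg = _draw_early_fpg(config, rng, z[:, 0])
    return _Arrays(
        glucose=glucose,
        z_glucose=z,
        history_hip=history_hip,
        history_macrosomia=history_macrosomia,
        history_fetal_death=history_fetal_death,
        nulliparous=nulliparous,
        family_history=family_history,
        ethnicity=np.asarray([eth_order[i] for i in ethnicity], dtype=object),
        age=age,
        bmi=bmi,
        ga=ga,
        early_fpg=early_fpg,
        reference_positive=_reference_positive(config, glucose),
    )


def _outcome_probability(
    model: OutcomeModel, arrays: _Arrays, attenuation: float
) -> np.ndarray:
    atten = np.where(arrays.reference_positive, attenuation, 1.0)
    glucose_term = (
        model.b_fpg * arrays.z_glucose[:, 0]
        + model.b_pg1h * arrays.z_glucose[:, 1]
        + model.b_pg2h * arrays.z_glucose[:, 2]
    )
    lp = model.intercept + atten * glucose_term + model.b_history * arrays.history_hip
    return expit(lp)


def _draw_outcomes(
    config: SimulationConfig, rng: np.random.Generator, arrays: _Arrays
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name in TARGET_OUTCOME_RATES:  # fixed draw order for determinism
        p = _outcome_probability(config.outcome_model[name], arrays, config.treatment_attenuation)
        out[name] = rng.random(config.n) < p
    out["insulin_therapy"] = arrays.reference_positive & (
        rng.random(config.n) < config.insulin_rate_treated
    )
    return out


def generate_cohort(config: Optional[SimulationConfig] = None) -> GeneratedCohort:
    """Generate a synthetic cohort of eligible pregnancies.

    Every record passes the study eligibility filter by construction
    (gestational-age/age truncation, singleton, no prior diabetes or
    bariatric surgery, early FPG below the cutoff, complete risk attributes).
    """
    if config is None:
        config = default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    arrays = _simulate_covariates(config, rng)
    outcomes = _draw_outcomes(config, rng, arrays)

    def hist(flags: np.ndarray, i: int) -> HistoryStatus:
        if arrays.nulliparous[i]:
            return HistoryStatus.FIRST_CHILD
        return HistoryStatus.YES if flags[i] else HistoryStatus.NO

    records = []
    for i in range(config.n):
        records.append(
            WomanRecord(
                id=f"sim-{config.seed}-{i:06d}",
                age_years=float(arrays.age[i]),
                bmi_pre=float(arrays.bmi[i]),
                early_fpg=float(arrays.early_fpg[i]),
                ogtt=GlucoseTriplet(
                    fpg=float(arrays.glucose[i, 0]),
                    pg1h=float(arrays.glucose[i, 1]),
                    pg2h=float(arrays.glucose[i, 2]),
                    ga_weeks=float(arrays.ga[i]),
                ),
                history_hip=hist(arrays.history_hip, i),
                history_macrosomia=hist(arrays.history_macrosomia, i),
                history_fetal_death=hist(arrays.history_fetal_death, i),
                family_history_diabetes=bool(arrays.family_history[i]),
                ethnicity=arrays.ethnicity[i],
                singleton=True,
                prior_diabetes=False,
                prior_bariatric_surgery=False,
                outcomes=OutcomeRecord(
                    **{k: bool(v[i]) for k, v in outcomes.items()}
                ),
            )
        )
    return GeneratedCohort(records=tuple(records), config=config, seed=config.seed)


def calibrate_intercepts(
    config: SimulationConfig,
    target_rates: Mapping[str, float],
    n_calibration: int = 200_000,
) -> SimulationConfig:
    """Adjust outcome intercepts so simulated marginal rates hit targets.

    For each named outcome the intercept is found by monotone root-finding
    on the expected marginal rate over a fixed simulated covariate draw of
    ``n_calibration`` women (the expectation of the Bernoulli draw, so the
    achieved rate is exact up to sampling noise in the covariates).  A
    ``"composite"`` target is met by adding a common offset to the four
    component intercepts after any individual calibration.
    """
    for k, r in target_rates.items():
        if not 0.0 < r < 1.0:
            raise ValueError(f"target rate {k}={r} must be in the open interval (0, 1)")
    config.validate()
    rng = np.random.default_rng(config.seed)
    arrays = _simulate_covariates(replace(config, n=n_calibration), rng)
    models = dict(config.outcome_model)

    def solve(name: str, target: float) -> float:
        base = models[name]

        def gap(b0: float) -> float:
            return float(
                _outcome_probability(
                    replace(base, intercept=b0), arrays, config.treatment_attenuation
                ).mean()
                - target
            )

        try:
            return brentq(gap, -20.0, 10.0, xtol=1e-10, maxiter=200)
        except ValueError as e:  # pragma: no cover - bracketing failure
            raise RuntimeError(
                f"calibration failed for {name}: achieved range does not bracket "
                f"{target} (endpoint rates {expit(-20.0):.2e}, {expit(10.0):.5f})"
            ) from e

    for name, target in target_rates.items():
        if name == "composite":
            continue
        if name not in models:
            raise KeyError(f"no outcome model named {name!r}")
        models[name] = replace(models[name], intercept=solve(name, target))

    if "composite" in target_rates:
        from .model import COMPOSITE_COMPONENTS

        target = target_rates["composite"]

        def composite_gap(delta: float) -> float:
            none = np.ones(n_calibration)
            for comp in COMPOSITE_COMPONENTS:
                m = models[comp]
                p = _outcome_probability(
                    replace(m, intercept=m.intercept + delta),
                    arrays,
                    config.treatment_attenuation,
                )
                none *= 1.0 - p
            return float(1.0 - none.mean() - target)

        delta = brentq(composite_gap, -10.0, 10.0, xtol=1e-10, maxiter=200)
        for comp in COMPOSITE_COMPONENTS:
            m = models[comp]
            models[comp] = replace(m, intercept=m.intercept + delta)

    return replace(config, outcome_model=models)
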