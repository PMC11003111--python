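"""Synthetic registry-style cohort generator with known ground truth.

Emulates the data structure of a Danish clinical-database adherence study:
premenopausal, hormone-receptor-positive breast-cancer patients diagnosed
over a ten-year window, semi-annual follow-up visits at which adjuvant
endocrine therapy (AET) use is registered, latent adherence-behaviour
groups with polynomial mean-PDC trajectories, covariate-dependent group
membership, cause-specific censoring, and a small amount of missingness in
stage / tumour size / nodal status.

All dates are integer day offsets from a common origin; a calendar month is
approximated as 30.4375 days.  Every sampling step is driven by a single
``numpy.random.Generator`` so that identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25
FOLLOW_UP_DAYS = int(round(5 * DAYS_PER_YEAR))  # five years post-diagnosis
INTERVAL_DAYS = 182

#: Marginal level probabilities for each baseline covariate.  The categorical
#: splits mirror the published cohort description of a premenopausal Danish
#: breast-cancer population (about nine in ten treated with chemotherapy,
#: a quarter stage I, one in nine with comorbidity, and so on).
COVARIATE_LEVELS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "age_group": (("<40", "40-49", "50-55"), (0.155, 0.620, 0.225)),
    "stage": (("I", "II", "III"), (0.257, 0.547, 0.196)),
    "tumor_size": (("<2cm", "2-5cm", ">5cm"), (0.577, 0.378, 0.045)),
    "positive_nodes": (("none", "one", "two_plus"), (0.371, 0.255, 0.374)),
    "grade": (("I", "II", "III", "unknown"), (0.209, 0.522, 0.204, 0.065)),
    "her2": (("negative", "positive", "unknown"), (0.629, 0.133, 0.238)),
    "chemotherapy": (("yes", "no"), (0.910, 0.090)),
    "surgery_rt": (
        ("mastectomy_no_rt", "mastectomy_rt", "lumpectomy"),
        (0.144, 0.299, 0.557),
    ),
    "income": (("low", "medium", "high"), (0.30, 0.40, 0.30)),
    "education": (("basic", "vocational", "higher"), (0.25, 0.45, 0.30)),
    "cohabitation": (("living_alone", "cohabiting"), (0.22, 0.78)),
}

#: Prior chronic-medication classes and their two-year-window use prevalence.
MEDICATION_CLASSES: dict[str, float] = {
    "psychoanaleptic": 0.04,
    "psycholeptic": 0.03,
    "thyroid": 0.03,
    "hormonal_contraceptive": 0.05,
    "analgesic": 0.08,
    "diuretic_antihypertensive": 0.05,
    "airway_antihistamine": 0.04,
}

CENSORING_CAUSES = ("recurrence", "death", "second_primary", "emigration")

MISSABLE_FIELDS = ("stage", "tumor_size", "positive_nodes")


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic cohort.

    Parameters
    ----------
    n_patients
        Cohort size.
    group_mixing
        Baseline membership probabilities of the latent adherence groups
        (length J, summing to one).  The default mirrors the observed
        three-group split of 57% high adherers, 36% slow decliners and
        7% rapid decliners.
    group_polynomials
        Per-group polynomial coefficients (intercept, slope, quadratic)
        of the mean PDC on scaled time s = t / (n_intervals - 1) in [0, 1].
    sigma
        Residual SD of the latent adherence propensity (PDC units).
    covariate_effects
        Map ``"covariate=level"`` -> length-J log-odds shifts added to the
        baseline multinomial-logit membership scores for patients at that
        level.  Entry for the reference group is conventionally 0.
    censoring_hazards
        Annual hazard per censoring cause (exponential waiting times).
    initiation_delay_months
        (median, log-scale SD) of a lognormal delay from diagnosis to the
        first AET registration.  Default median 6.3 months with a log-SD
        reproducing an interquartile range of roughly 5.5-8 months.
    missingness_rates
        MCAR missingness probability per missable field.
    prescription_window
        Month offsets before diagnosis delimiting the prior-medication
        look-back (default 3-27; sensitivity analyses use 12-36).
    ai_switch_prob
        Probability that a patient switches from tamoxifen to an aromatase
        inhibitor at some mid-follow-up visit (still counted as adherent).
    refill_jitter_days
        Maximum uniform delay (days) of each registration after its
        scheduled 182-day refill date.  Late refills open coverage gaps and
        give fractional interval PDC, as in real dispensing data; zero puts
        every registration exactly on the grid, making interval coverage
        binary.
    n_intervals
        Number of six-month intervals spanned by the group polynomials.
    seed
        Base RNG seed.
    """

    n_patients: int = 2000
    group_mixing: tuple[float, ...] = (0.57, 0.36, 0.07)
    group_polynomials: tuple[tuple[float, ...], ...] = (
        (0.96,),                    # high adherers: constant
        (0.95, -0.25, -0.22),       # slow decliners: gradual quadratic decline
        (0.85, -1.85, 0.90),        # rapid decliners: steep early decline
    )
    sigma: float = 0.15
    covariate_effects: Mapping[str, Sequence[float]] = field(default_factory=dict)
    censoring_hazards: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.01 for c in CENSORING_CAUSES}
    )
    initiation_delay_months: tuple[float, float] = (6.3, 0.278)
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: {f: 0.01 for f in MISSABLE_FIELDS}
    )
    prescription_window: tuple[float, float] = (3.0, 27.0)
    ai_switch_prob: float = 0.10
    refill_jitter_days: int = 45
    n_intervals: int = 9
    diagnosis_span_days: int = int(round(10 * DAYS_PER_YEAR))
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        mix = np.asarray(self.group_mixing, dtype=float)
        if mix.ndim != 1 or mix.size < 1 or np.any(mix < 0) or abs(mix.sum() - 1) > 1e-9:
            raise ValueError("group_mixing must be a probability vector summing to 1")
        if len(self.group_polynomials) != mix.size:
            raise ValueError("group_polynomials must have one coefficient vector per group")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        for key, eff in self.covariate_effects.items():
            if len(eff) != mix.size:
                raise ValueError(f"covariate_effects[{key!r}] must have length {mix.size}")
        for cause, rate in self.censoring_hazards.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"censoring hazard for {cause} must be in [0,1]")
        for fld, rate in self.missingness_rates.items():
            if fld not in MISSABLE_FIELDS:
                raise ValueError(f"missingness configured for non-missable field {fld}")
            if not 0 <= rate <= 1:
                raise ValueError("missingness rates must be in [0,1]")
        if self.n_intervals < 2:
            raise ValueError("n_intervals must be at least 2")
        if not 0 <= self.refill_jitter_days < INTERVAL_DAYS:
            raise ValueError("refill_jitter_days must be in [0, interval length)")

    @property
    def n_groups(self) -> int:
        return len(self.group_mixing)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_effects"] = {k: list(v) for k, v in self.covariate_effects.items()}
        return d


def default_config(**overrides) -> SimulationConfig:
    """Study-condition default: three groups with the headline covariate
    effects (stage I, no chemotherapy, comorbidity, prior medication use
    raising the odds of declining-adherence membership)."""
    effects = {
        # (high adherers [ref], slow decliners, rapid decliners)
        "stage=I": (0.0, np.log(1.4), np.log(1.9)),
        "chemotherapy=no": (0.0, np.log(3.4), np.log(4.3)),
        "cci=1+": (0.0, np.log(1.5), np.log(1.6)),
        "prior_med_any=yes": (0.0, np.log(1.2), np.log(1.3)),
        "positive_nodes=none": (0.0, np.log(1.3), np.log(1.9)),
    }
    params = dict(covariate_effects=effects)
    params.update(overrides)
    return SimulationConfig(**params)


def _poly_value(coefs: Sequence[float], s: np.ndarray) -> np.ndarray:
    out = np.zeros_like(s, dtype=float)
    for p, c in enumerate(coefs):
        out += c * s**p
    return out


def _effect_mask(key: str, patients: pd.DataFrame) -> np.ndarray:
    """Boolean mask of patients matching a ``"covariate=level"`` effect key."""
    cov, _, level = key.partition("=")
    if cov == "cci":
        return (patients["cci"].to_numpy() >= 1) == (level == "1+")
    if cov == "prior_med_any":
        return (patients["prior_med_any"].to_numpy() == 1) == (level == "yes")
    if cov not in patients.columns:
        raise KeyError(f"unknown covariate in effect key {key!r}")
    return (patients[cov] == level).to_numpy()


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw baseline covariates and latent group membership.

    Returns ``(patients, truth)``.  Group membership follows a multinomial
    logit: softmax(log mixing + sum of matching covariate log-odds shifts).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    J = config.n_groups

    cols: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i:06d}" for i in range(n)]),
        "diagnosis_date": rng.integers(0, config.diagnosis_span_days, size=n),
    }
    # numeric age consistent with the premenopausal 18-54 eligibility window
    age = rng.integers(25, 55, size=n)
    cols["age_at_diagnosis"] = age
    for cov, (levels, probs) in COVARIATE_LEVELS.items():
        if cov == "age_group":
            continue
        cols[cov] = rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))
    cols["age_group"] = np.select(
        [age < 40, age < 50], ["<40", "40-49"], default="50-55"
    )
    # Charlson score: mostly zero in a young cohort
    has_cci = rng.random(n) < 0.11
    cols["cci"] = np.where(has_cci, 1 + rng.poisson(0.4, size=n), 0)

    med_flags = {}
    for cls, prev in MEDICATION_CLASSES.items():
        med_flags[cls] = (rng.random(n) < prev).astype(int)
        cols[f"prior_med_{cls}"] = med_flags[cls]
    any_class = np.maximum.reduce(list(med_flags.values()))
    other_chronic = (rng.random(n) < 0.05).astype(int)
    cols["prior_med_any"] = np.maximum(any_class, other_chronic)

    patients = pd.DataFrame(cols)

    # multinomial-logit group membership
    scores = np.tile(np.log(np.asarray(config.group_mixing, dtype=float)), (n, 1))
    for key, eff in config.covariate_effects.items():
        scores[_effect_mask(key, patients)] += np.asarray(eff, dtype=float)
    scores -= scores.max(axis=1, keepdims=True)
    probs = np.exp(scores)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    true_group = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1) + 1  # 1..J

    truth = pd.DataFrame({"patient_id": patients["patient_id"], "true_group": true_group})
    for j in range(J):
        truth[f"true_prob_{j + 1}"] = probs[:, j]
    return patients, truth


def generate_follow_up(
    patients: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate visit registrations and censoring events.

    Each patient initiates AET after a lognormal delay from diagnosis, then
    has visits scheduled every 182 days until censoring or five years
    post-diagnosis.  At each scheduled visit the probability of attending
    and reporting AET use is the patient's true-group polynomial at that
    interval, perturbed by N(0, sigma) noise and clamped to [0, 1].
    """
    config.validate()
    if not patients["patient_id"].equals(truth["patient_id"]):
        raise ValueError("patients and truth must be aligned by patient_id")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    med_delay, log_sd = config.initiation_delay_months
    n = len(patients)
    delays = np.exp(rng.normal(np.log(med_delay), log_sd, size=n)) * DAYS_PER_MONTH
    delays = np.maximum(1, np.round(delays)).astype(int)

    hazards = dict(config.censoring_hazards)
    causes = list(hazards)
    cause_days = np.full((n, max(len(causes), 1)), np.inf)
    for k, cause in enumerate(causes):
        rate = hazards[cause]
        if rate > 0:
            cause_days[:, k] = rng.exponential(DAYS_PER_YEAR / rate, size=n)

    groups = truth["true_group"].to_numpy() - 1
    denom = max(config.n_intervals - 1, 1)

    visit_rows = []
    censor_rows = []
    for i in range(n):
        pid = patients["patient_id"].iloc[i]
        diag = int(patients["diagnosis_date"].iloc[i])
        init = diag + int(delays[i])
        end = diag + FOLLOW_UP_DAYS
        k_min = int(np.argmin(cause_days[i])) if causes else 0
        censor_day = cause_days[i, k_min] if causes else np.inf
        if np.isfinite(censor_day) and diag + censor_day < end:
            event_date = diag + int(np.ceil(censor_day))
            censor_rows.append((pid, event_date, causes[k_min]))
            end = min(end, event_date)

        coefs = config.group_polynomials[groups[i]]
        switch_visit = np.inf
        if config.ai_switch_prob > 0 and rng.random() < config.ai_switch_prob:
            switch_visit = rng.integers(1, config.n_intervals)
        t = 0
        sched = init
        while sched < end:
            s = t / denom
            mu = _poly_value(coefs, np.array(s))
            p = float(np.clip(mu + rng.normal(0.0, config.sigma), 0.0, 1.0))
            if rng.random() < p:
                # the first registration defines the diary grid; later refills
                # run late by up to refill_jitter_days, opening coverage gaps
                delay = 0 if t == 0 else int(rng.integers(0, config.refill_jitter_days + 1))
                date = sched + delay
                if date < end:
                    therapy = "AI" if t >= switch_visit else "TAM"
                    visit_rows.append((pid, date, 1, therapy))
            t += 1
            sched = init + t * INTERVAL_DAYS

    visits = pd.DataFrame(
        visit_rows, columns=["patient_id", "visit_date", "aet_reported", "therapy"]
    )
    censoring = pd.DataFrame(
        censor_rows, columns=["patient_id", "event_date", "reason"]
    )
    return visits, censoring


def inject_missingness(patients: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Set stage / tumour size / nodal status missing completely at random."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out = patients.copy()
    for fld in MISSABLE_FIELDS:
        rate = config.missingness_rates.get(fld, 0.0)
        if rate > 0:
            mask = rng.random(len(out)) < rate
            out.loc[mask, fld] = pd.NA
    return out


def simulate_panels(
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw PDC panels directly from the censored-normal trajectory model.

    Bypasses the visit/diary machinery: each patient's interval PDC is
    ``clip(poly_g(s_t) + N(0, sigma), 0, 1)``.  This is the generating
    process the trajectory fitter assumes, used for parameter-recovery
    studies.  Returns ``(panel, truth)`` with the panel in long format
    (patient_id, t, covered_days, denominator_days, pdc).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, T, J = config.n_patients, config.n_intervals, config.n_groups
    mix = np.asarray(config.group_mixing, dtype=float)
    groups = rng.choice(J, size=n, p=mix)
    s = np.arange(T) / max(T - 1, 1)
    mu = np.stack([_poly_value(c, s) for c in config.group_polynomials])  # (J, T)
    y = np.clip(mu[groups] + rng.normal(0.0, config.sigma, size=(n, T)), 0.0, 1.0)

    pids = np.repeat([f"P{i:06d}" for i in range(n)], T)
    panel = pd.DataFrame(
        {
            "patient_id": pids,
            "t": np.tile(np.arange(T), n),
            "covered_days": np.round(y.ravel() * INTERVAL_DAYS).astype(int),
            "denominator_days": INTERVAL_DAYS,
            "pdc": y.ravel(),
        }
    )
    truth = pd.DataFrame(
        {"patient_id": [f"P{i:06d}" for i in range(n)], "true_group": groups + 1}
    )
    return panel, truth


def write_cohort(
    out_dir,
    patients: pd.DataFrame,
    truth: pd.DataFrame,
    visits: pd.DataFrame,
    censoring: pd.DataFrame,
    config: SimulationConfig,
) -> None:
    """Persist the generated tables plus the generating config."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients.to_csv(out / "patients.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    visits.to_csv(out / "visits.csv", index=False)
    censoring.to_csv(out / "censoring.csv", index=False)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
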