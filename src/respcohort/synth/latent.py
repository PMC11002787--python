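"""Latent population generator.

Draws a population of latent persons with exact dates and known truth:
demographics, disease status and onset, practice-move histories,
smoking/BMI/spirometry trajectories with GP observation schedules, and
prescription histories.  Coarsening (year/week/month of birth), coding
and dialect-specific availability rules all happen later at render
time, so imputation and harmonisation error can be quantified exactly
against this truth.

Default parameters are the study conditions: UK-plausible prevalences
(asthma 10%, COPD 4%, ILD 1%), onset-age distributions with childhood-
peaked asthma and late-adult COPD/ILD, a 20% practice-mover fraction,
and zero injected missingness/noise (the noise knobs exist but default
off).  Onset-age truncation keeps at least a two-year margin above the
COPD/ILD cohort age thresholds so that birth-date imputation error
(at most ~one year) can never flip a threshold decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from ..errors import ValidationError
from . import vocab

__all__ = ["GenerationParams", "LatentPerson", "generate_population"]


_DAY = timedelta(days=1)


@dataclass(frozen=True)
class GenerationParams:
    """Knobs of the latent-population generator.

    ``missingness`` holds per-variable Bernoulli drop rates applied at
    render time (keys: diagnosis, smoking, bmi, spirometry, ethnicity,
    prescription, deprivation).  ``rerecord_prob`` is the probability
    that a pre-existing diagnosis is re-recorded when the patient joins
    a new practice — the mechanism by which prevalent disease enters a
    fresh registration's record.
    """

    n: int = 1000
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"asthma": 0.10, "copd": 0.04, "ild": 0.01}
    )
    mover_fraction: float = 0.2
    sex_unknown_rate: float = 0.005
    rerecord_prob: float = 1.0
    missingness: dict[str, float] = field(default_factory=dict)
    smoking_miscode_rate: float = 0.0
    bmi_outlier_rate: float = 0.0
    quality_invalid_rate: float = 0.0
    ons_death_date_missing_rate: float = 0.0
    birth_window: tuple[date, date] = (date(1920, 1, 1), date(2017, 12, 31))
    horizon: date = date(2022, 3, 7)
    observation_era_start: date = date(2002, 1, 1)
    prescription_era_start: date = date(2006, 1, 1)
    post_2016_drug_start: date = date(2017, 1, 1)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for name, p in {
            **self.prevalence,
            "mover_fraction": self.mover_fraction,
            "sex_unknown_rate": self.sex_unknown_rate,
            "rerecord_prob": self.rerecord_prob,
            **{f"missingness[{k}]": v for k, v in self.missingness.items()},
            "smoking_miscode_rate": self.smoking_miscode_rate,
            "bmi_outlier_rate": self.bmi_outlier_rate,
            "quality_invalid_rate": self.quality_invalid_rate,
            "ons_death_date_missing_rate": self.ons_death_date_missing_rate,
        }.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {p!r}")
        if self.birth_window[0] >= self.birth_window[1]:
            raise ValidationError("birth_window must be an increasing date pair")

    def missing_rate(self, variable: str) -> float:
        return self.missingness.get(variable, 0.0)


@dataclass
class LatentPerson:
    """One latent person with exact ground truth."""

    person_id: str
    true_birth_date: date
    sex: str  # male | female | unknown
    true_death_date: date | None
    disease_status: dict[str, bool]
    true_onset_date: dict[str, date | None]
    height: float | None
    ethnicity_broad: str
    ethnicity_concept: str
    deprivation_level: int  # canonical 1..5, 5 = most deprived
    practice_moves: list[date]
    registrations: list[tuple[date, date | None]]
    # GP-observable truth (rendered into coded events per dialect):
    diagnosis_events: list[tuple[date, str, str]]  # (date, disease, concept)
    smoking_observations: list[tuple[date, str]]
    bmi_observations: list[tuple[date, float]]
    height_observation: tuple[date, float] | None
    spirometry_observations: list[tuple[date, float, float | None, str | None]]
    ethnicity_gp_date: date | None
    ethnicity_hospital_date: date | None
    prescriptions: list[tuple[date, str]]  # (date, drug key)
    quality_valid: bool = True

    @property
    def end_of_records(self) -> date | None:
        return self.true_death_date

    def alive_on(self, when: date) -> bool:
        return self.true_death_date is None or self.true_death_date >= when


_ONSET_DISTS = {  # mean, sd, truncation (years)
    "asthma": (8.0, 9.0, 2.0, 70.0),
    "copd": (65.0, 10.0, 40.0, 90.0),
    "ild": (72.0, 8.0, 45.0, 92.0),
}

_ILD_SUBTYPE_WEIGHTS = {
    "ild_ipf_narrow": 0.30,
    "ild_ipf_broad": 0.20,
    "ild_hp": 0.08,
    "ild_pneumoconiosis": 0.05,
    "ild_sarcoid": 0.15,
    "ild_ra": 0.08,
    "ild_drug": 0.04,
    "ild_other": 0.10,
}

#: per-disease regimen: drug key -> probability of being on it.
_REGIMENS = {
    "asthma": {
        "salbutamol": 1.0,
        "beclometasone": 0.5,
        "laba_ics_combo": 0.3,
        "saba_sama_combo": 0.05,
        "prednisolone": 0.15,
        "theophylline": 0.03,
    },
    "copd": {
        "salbutamol": 0.8,
        "ipratropium": 0.3,
        "salmeterol": 0.2,
        "tiotropium": 0.5,
        "laba_ics_combo": 0.3,
        "laba_lama_combo": 0.2,
        "triple_combo": 0.25,
        "prednisolone": 0.3,
        "theophylline": 0.05,
        "roflumilast": 0.05,
        "azithromycin": 0.2,
    },
    "ild": {"prednisolone": 0.4},
}


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def _years(days: float) -> timedelta:
    return timedelta(days=round(days * 365.25))


def generate_population(params: GenerationParams, seed: int) -> list[LatentPerson]:
    """Generate ``params.n`` latent persons, reproducibly for a seed."""
    rng = np.random.default_rng(seed)
    birth_lo, birth_hi = params.birth_window
    birth_span = (birth_hi - birth_lo).days
    horizon = params.horizon
    predict_coeffs = {"male": (4.30, -0.029, -2.49), "female": (3.95, -0.025, -2.60)}

    population: list[LatentPerson] = []
    for i in range(params.n):
        person_id = f"p{i:06d}"
        birth = birth_lo + timedelta(days=int(rng.integers(0, birth_span + 1)))
        u = rng.random()
        if u < params.sex_unknown_rate:
            sex = "unknown"
        else:
            sex = "male" if rng.random() < 0.5 else "female"

        death_age = _trunc_normal(rng, 81.0, 12.0, 2.0, 105.0)
        death: date | None = birth + _years(death_age)
        if death > horizon:
            death = None
        end = death or horizon

        # -------------------------------------------------- diseases
        disease_status: dict[str, bool] = {}
        onsets: dict[str, date | None] = {}
        for disease in vocab.DISEASES:
            diseased = rng.random() < params.prevalence.get(disease, 0.0)
            onset = None
            if diseased:
                mean, sd, lo, hi = _ONSET_DISTS[disease]
                # onset must fall inside the observable lifetime; persons
                # whose lifetime never reaches the onset-age range cannot
                # develop the disease
                max_age = min(hi, (end - birth).days / 365.25 - 0.05)
                if max_age < lo:
                    diseased = False
                else:
                    onset = birth + _years(_trunc_normal(rng, mean, sd, lo, max_age))
                    if onset >= end:
                        onset = end - _DAY
            disease_status[disease] = diseased
            onsets[disease] = onset

        # -------------------------------------- practice registrations
        moves: list[date] = []
        if rng.random() < params.mover_fraction and death_age > 20:
            k = int(rng.integers(1, 4))
            max_age = min(death_age, 80.0)
            ages = sorted(rng.uniform(18.0, max_age, size=k))
            for age in ages:
                move = birth + _years(age)
                if birth < move < end and (not moves or move > moves[-1]):
                    moves.append(move)
        starts = [birth] + moves
        registrations: list[tuple[date, date | None]] = []
        for j, start in enumerate(starts):
            if j + 1 < len(starts):
                registrations.append((start, starts[j + 1] - _DAY))
            else:
                registrations.append((start, death))

        # ---------------------------------------- diagnosis events
        diagnosis_events: list[tuple[date, str, str]] = []
        ild_concept = None
        for disease in vocab.DISEASES:
            onset = onsets[disease]
            if onset is None:
                continue
            if disease == "ild":
                keys = list(_ILD_SUBTYPE_WEIGHTS)
                weights = np.array(list(_ILD_SUBTYPE_WEIGHTS.values()))
                ild_concept = keys[rng.choice(len(keys), p=weights / weights.sum())]
                onset_concept = ild_concept
            else:
                dx = vocab.diagnostic_concepts(disease)
                onset_concept = dx[int(rng.integers(0, len(dx)))]
            diagnosis_events.append((onset, disease, onset_concept))
            # re-recording when joining a new practice after onset
            for start, reg_end in registrations:
                if start <= onset:
                    continue
                if rng.random() < params.rerecord_prob:
                    when = start + timedelta(days=14)
                    for bound in (reg_end, death, horizon):
                        if bound is not None and when > bound:
                            when = bound
                    if when >= start:
                        diagnosis_events.append((when, disease, onset_concept))
            # annual management reviews
            mgmt = vocab.management_concepts(disease)
            review_end = min(end, onset + _years(40.0))
            year_mark = onset + _years(1.0)
            while year_mark <= review_end:
                if rng.random() < 0.6:
                    when = year_mark + timedelta(days=int(rng.integers(0, 120)))
                    if when <= review_end:
                        concept = mgmt[int(rng.integers(0, len(mgmt)))]
                        if disease == "ild" and rng.random() < 0.2:
                            # a second subtype mention over the disease course
                            concept = keys[int(rng.integers(0, len(keys)))]
                        diagnosis_events.append((when, disease, concept))
                year_mark += _years(1.0)

        # ------------------------------------------------ body habitus
        if sex == "female":
            height = float(np.clip(rng.normal(1.62, 0.065), 1.45, 2.05))
        else:
            height = float(np.clip(rng.normal(1.76, 0.07), 1.45, 2.10))

        obs_start = max(params.observation_era_start, birth + _years(20.0))
        bmi_observations: list[tuple[date, float]] = []
        height_observation = None
        if obs_start <= end:
            bmi = float(np.clip(rng.normal(27.0, 4.5), 16.0, 48.0))
            when = obs_start + timedelta(days=int(rng.integers(0, 365)))
            while when <= end:
                bmi = float(np.clip(bmi + rng.normal(0.0, 0.5), 12.0, 60.0))
                value = bmi
                if rng.random() < params.bmi_outlier_rate:
                    value = bmi * 10.0  # keystroke-style outlier
                bmi_observations.append((when, value))
                if height_observation is None:
                    height_observation = (when, height)
                when += timedelta(days=int(rng.integers(700, 1100)))

        # --------------------------------------------------- smoking
        smoking_observations: list[tuple[date, str]] = []
        p_ever = 0.85 if disease_status["copd"] else 0.40
        ever = rng.random() < p_ever
        start_smoking = birth + _years(_trunc_normal(rng, 17.0, 2.5, 12.0, 40.0)) if ever else None
        quit_smoking = None
        if ever and rng.random() < 0.5:
            quit_smoking = start_smoking + _years(float(rng.uniform(2.0, 35.0)))
            if quit_smoking >= end:
                quit_smoking = None
        def smoking_status_at(when: date) -> str:
            if not ever or when < start_smoking:
                return "never"
            if quit_smoking is not None and when >= quit_smoking:
                return "ex"
            return "current"

        smoke_start = max(params.observation_era_start, birth + _years(18.0))
        if smoke_start <= end:
            when = smoke_start + timedelta(days=int(rng.integers(0, 365)))
            while when <= end:
                status = smoking_status_at(when)
                if status != "never" and rng.random() < params.smoking_miscode_rate:
                    status = "never"  # miscoding the cleaner must repair
                smoking_observations.append((when, status))
                when += timedelta(days=int(rng.integers(800, 1300)))

        # new-patient health check: joining a practice re-records smoking
        # status and BMI early in the fresh registration
        for move in moves:
            when = move + timedelta(days=7)
            if when > end:
                continue
            if when >= smoke_start:
                smoking_observations.append((when, smoking_status_at(when)))
            if when >= obs_start and bmi_observations:
                prior = [v for d, v in bmi_observations if d <= when]
                value = prior[-1] if prior else bmi_observations[0][1]
                bmi_observations.append((when, value))
        smoking_observations.sort()
        bmi_observations.sort()

        # ------------------------------------------------ spirometry
        spirometry_observations: list[tuple[date, float, float | None, str | None]] = []
        if disease_status["copd"] and onsets["copd"] is not None:
            frac = float(rng.uniform(0.40, 0.75))
            when = max(onsets["copd"], params.observation_era_start)
            while when <= end:
                age = (when - birth).days / 365.25
                coeffs = predict_coeffs.get(sex)
                if coeffs is None:
                    coeffs = predict_coeffs["male"]
                predicted = coeffs[0] * height + coeffs[1] * age + coeffs[2]
                years_on = (when - onsets["copd"]).days / 365.25
                fev1 = max(0.3, frac * predicted * (0.985 ** years_on))
                gp_pct = None
                if sex in predict_coeffs and rng.random() < 0.5:
                    gp_pct = round(fev1 / predicted * 100.0, 1)
                bd = None
                u_bd = rng.random()
                if u_bd < 0.25:
                    bd = "pre"
                elif u_bd < 0.30:
                    bd = "post"
                spirometry_observations.append((when, round(fev1, 3), gp_pct, bd))
                when += timedelta(days=int(rng.integers(400, 700)))

        # ------------------------------------------------- ethnicity
        broad = ["White", "Asian", "Black", "Mixed", "Other"][
            int(rng.choice(5, p=[0.85, 0.07, 0.04, 0.02, 0.02]))
        ]
        options = vocab.ETHNICITY_BY_BROAD[broad]
        concept = options[int(rng.integers(0, len(options)))]
        eth_window_start = max(params.observation_era_start, birth)
        eth_span = max((end - eth_window_start).days, 1)
        ethnicity_gp_date = None
        ethnicity_hospital_date = None
        if eth_window_start <= end:
            ethnicity_gp_date = eth_window_start + timedelta(days=int(rng.integers(0, eth_span)))
            if rng.random() < 0.3:
                ethnicity_hospital_date = eth_window_start + timedelta(
                    days=int(rng.integers(0, eth_span))
                )

        # ---------------------------------------------- prescriptions
        prescriptions: list[tuple[date, str]] = []
        on_drugs: set[str] = set()
        for disease in vocab.DISEASES:
            if not disease_status[disease]:
                continue
            for drug_key, p in _REGIMENS[disease].items():
                if rng.random() < p:
                    on_drugs.add(drug_key)
        for drug_key in sorted(on_drugs):
            drug_start = params.prescription_era_start
            if vocab.DRUGS[drug_key].post_2016:
                drug_start = max(drug_start, params.post_2016_drug_start)
            first_onset = min(
                (d for d in onsets.values() if d is not None), default=None
            )
            if first_onset is None:
                continue
            when = max(drug_start, first_onset) + timedelta(days=int(rng.integers(0, 60)))
            while when <= end:
                prescriptions.append((when, drug_key))
                when += timedelta(days=int(rng.integers(120, 180)))

        population.append(
            LatentPerson(
                person_id=person_id,
                true_birth_date=birth,
                sex=sex,
                true_death_date=death,
                disease_status=disease_status,
                true_onset_date=onsets,
                height=height,
                ethnicity_broad=broad,
                ethnicity_concept=concept,
                deprivation_level=int(rng.integers(1, 6)),
                practice_moves=moves,
                registrations=registrations,
                diagnosis_events=sorted(diagnosis_events),
                smoking_observations=smoking_observations,
                bmi_observations=bmi_observations,
                height_observation=height_observation,
                spirometry_observations=spirometry_observations,
                ethnicity_gp_date=ethnicity_gp_date,
                ethnicity_hospital_date=ethnicity_hospital_date,
                prescriptions=prescriptions,
                quality_valid=not (rng.random() < params.quality_invalid_rate),
            )
        )
    return population
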