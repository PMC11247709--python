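"""Synthetic cohorts emulating a population-based aging-study design.

The generator reproduces the structural features of the study design that
the estimators depend on: a baseline cohort of ~2631 persons aged 60-101
sampled at the ages 60/66/72/78/81/84/87/90, ~61% female, ~27% APOE-e4
carriers; a latent composite CR score (mean 0, SD 1.26, truncated to
[-4.25, 3.46]) that drives a four-indicator battery through a one-factor
model; a six-test cognitive battery correlated with CR from which baseline
CIND is classified; continuous-time four-state trajectories with log-linear
covariate effects on each transition intensity; exams every 6 years below
attained age 78 and every 3 years from 78 on, administrative censoring at
15 years, and exactly observed death times.

Every cohort comes with a :class:`TruthRecord` carrying the generating
parameters and the latent jump paths, so downstream estimates can be scored
against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cind as cind_mod
from . import cr as cr_mod
from .msm import DEFAULT_STRUCTURE, IntensityModel, TransitionStructure, build_intensity_matrix
from .panel import DEATH, Cohort, StateObservation, Subject

#: baseline-age sampling weights, chosen to give a mean baseline age near the
#: study's 72.3 years with the youngest cohorts largest.
DEFAULT_AGE_WEIGHTS = {60: 0.24, 66: 0.18, 72: 0.15, 78: 0.13,
                       81: 0.10, 84: 0.09, 87: 0.06, 90: 0.05}

#: age at which the exam interval switches from 6 to 3 years.
SCHEDULE_SWITCH_AGE = 78.0


def default_truth(structure: TransitionStructure = DEFAULT_STRUCTURE) -> IntensityModel:
    """Generating intensities of the default synthetic cohort.

    Baseline rates (per year, at age 72, male, CR 0, no e4 allele) are set so
    that a 15-year follow-up of ~2500 subjects produces transition counts of
    the same order as the study's (hundreds of normal->CIND and CIND->death
    interval pairs, tens of direct normal->dementia pairs).  The per-point CR
    log hazard ratios default to the study's reported point estimates on the
    three transitions where an effect was found; age (centered at 72), sex
    and APOE-e4 carry conventional epidemiological effect sizes.
    """
    log_q0 = {
        (1, 2): np.log(0.090), (2, 1): np.log(0.200),
        (1, 3): np.log(0.006), (2, 3): np.log(0.050),
        (1, 4): np.log(0.020), (2, 4): np.log(0.060),
        (3, 4): np.log(0.300),
    }
    beta = {
        (1, 2): {"cr": np.log(0.78), "age_c": 0.04},
        (2, 1): {"age_c": -0.02},
        (1, 3): {"age_c": 0.09, "apoe4": 0.40},
        (2, 3): {"age_c": 0.07, "apoe4": 0.40},
        (1, 4): {"cr": np.log(0.85), "age_c": 0.09, "female": -0.25},
        (2, 4): {"cr": np.log(0.82), "age_c": 0.08, "female": -0.25},
        (3, 4): {"age_c": 0.05, "female": -0.20},
    }
    return IntensityModel(structure=structure, log_q0=log_q0, beta=beta)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults emulate the study design."""

    n: int = 2631
    seed: int = 0
    age_cohorts: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_AGE_WEIGHTS))
    p_female: float = 0.61
    p_apoe4: float = 0.27
    cr_sd: float = 1.26
    cr_range: tuple[float, float] = (-4.25, 3.46)
    loadings: tuple[float, ...] = (0.7, 0.6, 0.5, 0.4)
    horizon: float = 15.0
    dropout_per_exam: float = 0.0
    truth: IntensityModel | None = None

    def __post_init__(self) -> None:
        for p in (self.p_female, self.p_apoe4, self.dropout_per_exam):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        w = sum(self.age_cohorts.values())
        if not w > 0:
            raise ValueError("age-cohort weights must have positive sum")
        if self.truth is None:
            self.truth = default_truth()

    def with_truth(self, beta_updates: dict) -> "SimulationConfig":
        """Copy of the config with selected beta entries of the truth replaced.

        ``beta_updates`` maps transition -> {covariate: log-HR}; entries merge
        over the existing truth.
        """
        truth = self.truth
        beta = {tr: dict(truth.beta[tr]) for tr in truth.structure.allowed}
        for tr, upd in beta_updates.items():
            beta[tr].update(upd)
        new = IntensityModel(structure=truth.structure, log_q0=dict(truth.log_q0), beta=beta)
        return replace(self, truth=new)


@dataclass
class TruthRecord:
    """Everything needed to score estimates against the generator."""

    config: SimulationConfig
    paths: dict[str, list[tuple[float, int]]]
    baseline_states: dict[str, int]
    latent_cr: dict[str, float]

    def to_json(self) -> str:
        truth = self.config.truth
        payload = {
            "n": self.config.n, "seed": self.config.seed,
            "horizon": self.config.horizon,
            "log_q0": {f"{r}->{s}": v for (r, s), v in truth.log_q0.items()},
            "beta": {f"{r}->{s}": dict(b) for (r, s), b in truth.beta.items()},
            "baseline_states": self.baseline_states,
            "paths": {k: [[t, s] for t, s in v] for k, v in self.paths.items()},
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# baseline population


# raw-scale anchors for the CR indicator battery (study baseline table)
_EDU_MEAN, _EDU_SD = 12.32, 4.00
_WORK_MEAN, _WORK_SD = 5.00, 1.81

# cognitive-test reference scales (plausible raw-score anchors; sign -1 for
# the timed trail-making test where longer = worse)
_TEST_SCALES = {
    "free_recall": (10.0, 3.0, +1),
    "trail_making_b_seconds": (120.0, 40.0, -1),
    "verbal_fluency": (45.0, 12.0, +1),
    "mental_rotations": (15.0, 5.0, +1),
    "digit_cancellation": (30.0, 8.0, +1),
    "pattern_comparison": (20.0, 6.0, +1),
}

# cross-domain correlation of cognitive abilities: a general factor at
# loading sqrt(0.4) gives exchangeable correlation ~0.4, under which the
# any-domain-below-threshold rule classifies ~23% of a baseline wave as CIND.
_GENERAL_LOADING = np.sqrt(0.4)
_CR_ON_GENERAL = 0.45


def sample_baseline_population(config: SimulationConfig,
                               rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Draw baseline covariates, latent CR, CR indicators, cognitive battery.

    Returns a dict of frames indexed by subject id: ``covariates`` (age,
    female, apoe4, latent cr and derived columns), ``indicators`` (the
    four-indicator CR battery inputs) and ``battery`` (six raw cognitive
    tests).  Draws are reproducible given the generator state.
    """
    n = config.n
    ids = [f"s{i:05d}" for i in range(n)]

    ages = np.array(sorted(config.age_cohorts))
    w = np.array([config.age_cohorts[a] for a in ages], dtype=float)
    age = rng.choice(ages, size=n, p=w / w.sum()).astype(float)
    female = (rng.random(n) < config.p_female).astype(float)
    apoe4 = (rng.random(n) < config.p_apoe4).astype(float)

    lo, hi = config.cr_range
    cr = stats.truncnorm.rvs(lo / config.cr_sd, hi / config.cr_sd,
                             scale=config.cr_sd, size=n, random_state=rng)
    eta = cr / config.cr_sd  # unit-variance latent factor

    # CR indicator battery from the one-factor model
    lam = np.asarray(config.loadings, dtype=float)
    z_ind = lam * eta[:, None] + np.sqrt(1 - lam ** 2) * rng.standard_normal((n, 4))
    education = np.clip(_EDU_MEAN + _EDU_SD * z_ind[:, 0], 0, None)
    work = np.clip(_WORK_MEAN + _WORK_SD * z_ind[:, 1], 0.7, 10.0)

    # leisure components: counts/frequency discretized from the leisure factor
    zl = z_ind[:, 2]
    mental = np.clip(np.round(2.6 + 1.8 * (zl + 0.5 * rng.standard_normal(n))), 0, 26)
    social = np.clip(np.round(2.2 + 1.8 * (zl + 0.5 * rng.standard_normal(n))), 0, 26)
    phys_lat = zl + 0.7 * rng.standard_normal(n)
    physical = np.digitize(phys_lat, [-0.43, 0.43])  # roughly equal thirds

    # social-network indicators: 4 size + 3 support measures on arbitrary
    # pre-coded numeric scales, all loading on the network factor
    zs = z_ind[:, 3]
    size_cols = {f"social_size_{k}": 0.6 * zs + 0.8 * rng.standard_normal(n)
                 for k in ("marital", "living", "children", "contacts")}
    support_cols = {f"social_support_{k}": 0.6 * zs + 0.8 * rng.standard_normal(n)
                    for k in ("material", "psychosocial", "belonging")}

    indicators = pd.DataFrame({
        "education_years": education,
        "work_complexity": work,
        "leisure_mental_count": mental.astype(int),
        "leisure_social_count": social.astype(int),
        "leisure_physical_freq": physical.astype(int),
        **size_cols, **support_cols,
    }, index=ids)

    # cognitive battery: five domain abilities sharing a general factor that
    # is itself correlated with CR, then test scores on raw scales
    g = _CR_ON_GENERAL * eta + np.sqrt(1 - _CR_ON_GENERAL ** 2) * rng.standard_normal(n)
    domain_ability = {}
    for d in cind_mod.DOMAINS:
        domain_ability[d] = (_GENERAL_LOADING * g
                             + np.sqrt(1 - _GENERAL_LOADING ** 2) * rng.standard_normal(n))
    battery = {}
    for d, tests in cind_mod.DEFAULT_BATTERY.items():
        for test, _sign in tests:
            mean, sd, sign = _TEST_SCALES[test]
            noise = 0.5 * rng.standard_normal(n)
            battery[test] = mean + sd * sign * (0.85 * domain_ability[d] + noise)
    battery = pd.DataFrame(battery, index=ids)

    covariates = pd.DataFrame({
        "age": age,
        "age_c": age - 72.0,
        "female": female,
        "apoe4": apoe4,
        "cr": cr,
        "old": (age >= SCHEDULE_SWITCH_AGE).astype(float),
    }, index=ids)
    covariates["cr_x_old"] = covariates["cr"] * covariates["old"]
    return {"covariates": covariates, "indicators": indicators, "battery": battery}


def _classify_baseline_states(covariates: pd.DataFrame, battery: pd.DataFrame) -> pd.Series:
    """Baseline state (1/2) from the cognitive battery via the CIND rule."""
    ref = cind_mod.TestReference(
        mean={t: float(battery[t].mean()) for t in battery.columns},
        sd={t: float(battery[t].std(ddof=1)) for t in battery.columns})
    profiles = {}
    for sid, row in battery.iterrows():
        group = cind_mod.age_group_label(covariates.loc[sid, "age"])
        profiles[sid] = cind_mod.cognitive_z_scores(row, ref, group)
    group_ref = cind_mod.GroupReference.from_profiles(list(profiles.values()))
    states = {}
    for sid, prof in profiles.items():
        is_cind = cind_mod.classify_cind(prof, group_ref)
        states[sid] = cind_mod.assemble_state(dementia=False, cind=is_cind, dead=False)
    return pd.Series(states)


# ---------------------------------------------------------------------------
# trajectories and observation design


def simulate_trajectory(Q: np.ndarray, start_state: int, horizon: float,
                        rng: np.random.Generator) -> list[tuple[float, int]]:
    """Exact jump path of the CTMC by competing exponentials.

    Returns [(0, start_state), (t1, s1), ...]; the path ends at absorption
    (death) or at the horizon, whichever comes first.  Starting in the
    absorbing state yields the empty path.
    """
    if start_state == DEATH:
        return []
    path = [(0.0, int(start_state))]
    t, s = 0.0, int(start_state)
    while True:
        rate = -Q[s - 1, s - 1]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        probs = Q[s - 1].copy()
        probs[s - 1] = 0.0
        probs = np.clip(probs, 0, None) / rate
        s = int(rng.choice(np.arange(1, 5), p=probs / probs.sum()))
        path.append((t, s))
        if s == DEATH:
            break
    return path


def exam_times(baseline_age: float, horizon: float) -> list[float]:
    """Scheduled exam offsets: 6-year steps below attained age 78, then 3."""
    times = [0.0]
    t = 0.0
    while True:
        step = 3.0 if baseline_age + t >= SCHEDULE_SWITCH_AGE else 6.0
        t += step
        if t > horizon + 1e-9:
            break
        times.append(t)
    return times


def _state_at(path: list[tuple[float, int]], t: float) -> int:
    s = path[0][1]
    for tj, sj in path:
        if tj <= t:
            s = sj
        else:
            break
    return s


def apply_observation_design(path: list[tuple[float, int]], baseline_age: float,
                             config: SimulationConfig,
                             rng: np.random.Generator) -> list[StateObservation]:
    """Panel observations of a latent path under the age-dependent schedule.

    Living states are recorded at attended exams (optional permanent Bernoulli
    dropout after baseline); death is recorded at its exact time whenever it
    occurs before administrative censoring, regardless of exam attendance.
    """
    death_time = next((t for t, s in path if s == DEATH), None)
    obs: list[StateObservation] = []
    attending = True
    for te in exam_times(baseline_age, config.horizon):
        if death_time is not None and death_time <= te:
            break
        if te > 0 and attending and config.dropout_per_exam > 0 \
                and rng.random() < config.dropout_per_exam:
            attending = False
        if attending:
            obs.append(StateObservation(te, _state_at(path, te)))
    if death_time is not None and death_time <= config.horizon:
        obs.append(StateObservation(float(death_time), DEATH, exact=True))
    return obs


# ---------------------------------------------------------------------------
# full cohort


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, TruthRecord]:
    """Sample a full synthetic cohort plus its truth record.

    Composes baseline sampling, baseline CIND classification from the
    cognitive battery, subject-specific intensity matrices from the truth
    model, exact trajectory simulation, and the observation design.  Frames
    from :func:`sample_baseline_population` are attached to the returned
    cohort as ``cohort.tables``.
    """
    rng = np.random.default_rng(config.seed)
    tables = sample_baseline_population(config, rng)
    cov = tables["covariates"]
    states0 = _classify_baseline_states(cov, tables["battery"])

    truth = config.truth
    needed = sorted({name for bs in truth.beta.values() for name in bs})
    subjects: list[Subject] = []
    paths: dict[str, list[tuple[float, int]]] = {}
    for sid in cov.index:
        x = {name: float(cov.loc[sid, name]) for name in needed}
        Q = build_intensity_matrix(truth, x)
        path = simulate_trajectory(Q, int(states0[sid]), config.horizon, rng)
        obs = apply_observation_design(path, float(cov.loc[sid, "age"]), config, rng)
        paths[sid] = path
        subjects.append(Subject(id=sid, observations=obs,
                                covariates={c: float(cov.loc[sid, c]) for c in cov.columns}))
    cohort = Cohort(subjects=subjects, covariate_names=list(cov.columns))
    cohort.tables = tables  # baseline frames for the scoring/classification stages
    record = TruthRecord(config=config, paths=paths,
                         baseline_states={sid: int(states0[sid]) for sid in cov.index},
                         latent_cr={sid: float(cov.loc[sid, "cr"]) for sid in cov.index})
    return cohort, record


def write_cohort_dir(cohort: Cohort, record: TruthRecord, outdir) -> None:
    """Write panel.csv, covariates.csv, indicators.csv, battery.csv, truth.json."""
    from pathlib import Path

    from .panel import write_panel

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel(cohort, out / "panel.csv", out / "covariates.csv")
    tables = getattr(cohort, "tables", None)
    if tables is not None:
        tables["indicators"].rename_axis("subject_id").to_csv(out / "indicators.csv")
        tables["battery"].rename_axis("subject_id").to_csv(out / "battery.csv")
    (out / "truth.json").write_text(record.to_json())
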