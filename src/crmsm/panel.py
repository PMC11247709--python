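"""Long-format panel observations of cognitive states and death.

A *panel* observation scheme records each subject's cognitive state only at
scheduled examinations, so transitions between exams are interval-censored;
death is recorded at its exact date.  States are coded

    1 = normal cognition, 2 = CIND, 3 = dementia, 4 = death (absorbing).

This module reads, validates and summarizes such data.  It knows nothing
about models; the likelihood lives in :mod:`crmsm.msm`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMAL, CIND, DEMENTIA, DEATH = 1, 2, 3, 4
STATES = (NORMAL, CIND, DEMENTIA, DEATH)
LIVING_STATES = (NORMAL, CIND, DEMENTIA)

PANEL_COLUMNS = ["subject_id", "time_years", "state", "exact_death"]


class PanelFormatError(ValueError):
    """A panel or covariate file is structurally malformed."""


class PanelValidationError(ValueError):
    """Panel rows violate the observation-scheme invariants."""


@dataclass(frozen=True)
class StateObservation:
    """One examination record: state occupied at ``time`` years past baseline.

    ``exact`` is True only for death, whose time is known exactly (register
    linkage); living states are panel-observed at exam dates.
    """

    time: float
    state: int
    exact: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise PanelValidationError(f"observation time must be finite and >= 0, got {self.time}")
        if self.state not in STATES:
            raise PanelValidationError(f"unknown state code {self.state}")
        if self.state == DEATH and not self.exact:
            raise PanelValidationError("death (state 4) must be recorded as exact")


@dataclass
class Subject:
    """A subject's time-ordered observations plus baseline covariates."""

    id: str
    observations: list[StateObservation]
    covariates: dict[str, float] = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    @property
    def states(self) -> np.ndarray:
        return np.array([o.state for o in self.observations], dtype=int)


@dataclass
class Cohort:
    """A set of subjects sharing a covariate schema."""

    subjects: list[Subject]
    covariate_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subjects)

    def covariate_frame(self) -> pd.DataFrame:
        """Baseline covariates as a DataFrame indexed by subject id."""
        rows = {s.id: {k: s.covariates.get(k, np.nan) for k in self.covariate_names}
                for s in self.subjects}
        df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
        df.index.name = "subject_id"
        return df.reindex(columns=self.covariate_names)


@dataclass
class ValidationIssue:
    subject_id: str
    kind: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def kinds(self) -> set[str]:
        return {i.kind for i in self.issues}

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "cohort valid"
        return "\n".join(f"[{i.kind}] subject {i.subject_id}: {i.message}" for i in self.issues)


@dataclass
class TransitionCountTable:
    """Observed interval transitions between consecutive exams.

    ``counts[r-1, s-1]`` counts pairs observed in state ``r`` at one exam and
    ``s`` at the next (or death); the diagonal counts unchanged pairs.
    ``person_time[r-1]`` attributes each whole interval to its origin state —
    a descriptive convention feeding crude initial rates only.
    """

    counts: np.ndarray
    person_time: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = ["normal", "cind", "dementia", "death"]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# reading / writing


def read_panel(path, covariate_path=None) -> Cohort:
    """Read a long-format panel CSV (and optional baseline covariate CSV).

    The panel file must have columns ``subject_id,time_years,state,exact_death``;
    the covariate file has ``subject_id`` plus one column per covariate (empty
    cell = missing).  Rows are grouped by subject and sorted by time; sorting
    is canonicalization, not an error.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file {path} is missing column(s): {', '.join(missing)}")

    bad_state = ~df["state"].isin(STATES)
    if bad_state.any():
        row = int(np.flatnonzero(bad_state.to_numpy())[0])
        raise PanelValidationError(
            f"unknown state code {df['state'].iloc[row]!r} at data row {row + 1}")
    dup = df.duplicated(subset=["subject_id", "time_years"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise PanelValidationError(
            f"duplicate (subject_id, time) at data row {row + 1}: "
            f"({df['subject_id'].iloc[row]}, {df['time_years'].iloc[row]})")

    cov: dict[str, dict[str, float]] = {}
    covariate_names: list[str] = []
    if covariate_path is not None:
        cdf = pd.read_csv(covariate_path, dtype={"subject_id": str})
        if "subject_id" not in cdf.columns:
            raise PanelFormatError(f"covariate file {covariate_path} is missing column: subject_id")
        covariate_names = [c for c in cdf.columns if c != "subject_id"]
        for _, r in cdf.iterrows():
            cov[r["subject_id"]] = {k: r[k] for k in covariate_names}

    subjects = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("time_years")
        obs = [StateObservation(float(t), int(s), bool(e))
               for t, s, e in zip(g["time_years"], g["state"], g["exact_death"])]
        subjects.append(Subject(id=str(sid), observations=obs, covariates=cov.get(str(sid), {})))

    n_single = sum(1 for s in subjects if len(s.observations) < 2)
    if n_single:
        logger.info("%d subject(s) have a single observation and contribute no "
                    "likelihood terms", n_single)
    return Cohort(subjects=subjects, covariate_names=covariate_names)


def write_panel(cohort: Cohort, path, covariate_path=None) -> None:
    """Write a cohort back to the panel CSV layout (RFC-4180, header row)."""
    rows = [(s.id, o.time, o.state, int(o.exact))
            for s in cohort.subjects for o in s.observations]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)
    if covariate_path is not None:
        cdf = cohort.covariate_frame().reset_index()
        cdf.to_csv(covariate_path, index=False)


# ---------------------------------------------------------------------------
# validation


def _reachable(allowed: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Transitive closure over the 4 states (multi-step paths allowed)."""
    reach = {(r, r) for r in STATES} | set(allowed)
    changed = True
    while changed:
        changed = False
        for a, b in list(reach):
            for c, d in list(reach):
                if b == c and (a, d) not in reach:
                    reach.add((a, d))
                    changed = True
    return reach


def validate_cohort(cohort: Cohort, structure=None) -> ValidationReport:
    """Check the observation-scheme invariants; report every violation.

    With a :class:`~crmsm.msm.TransitionStructure` given, consecutive observed
    pairs must also be reachable under the structure's transitive closure
    (e.g. dementia followed by a living cognitive state is flagged under the
    default no-recovery structure).
    """
    reach = None
    if structure is not None:
        reach = _reachable(set(structure.allowed))

    report = ValidationReport()

    def add(sid, kind, msg):
        report.issues.append(ValidationIssue(sid, kind, msg))

    for s in cohort.subjects:
        t = s.times
        st = s.states
        if len(t) == 0:
            add(s.id, "empty", "subject has no observations")
            continue
        if np.any(np.diff(t) < 0):
            add(s.id, "nonmonotone_time", "observation times are not increasing")
        if np.any(np.diff(t) == 0):
            add(s.id, "duplicate_time", "duplicate observation times (panel intervals "
                                        "must have positive length)")
        dead = np.flatnonzero(st == DEATH)
        if dead.size > 1:
            add(s.id, "multiple_deaths", "more than one death record")
        if dead.size >= 1 and dead[0] != len(st) - 1:
            add(s.id, "observation_after_death", "observation recorded after death")
        for o in s.observations:
            if o.state == DEATH and not o.exact:
                add(s.id, "death_not_exact", "state 4 must carry exact_death = 1")
        if reach is not None:
            for k in range(len(st) - 1):
                r, q = int(st[k]), int(st[k + 1])
                if (r, q) not in reach:
                    add(s.id, "forbidden_transition",
                        f"observed pair {r}->{q} at times {t[k]:g}->{t[k + 1]:g} is "
                        "unreachable under the transition structure"
                        + (" (transition out of dementia to a living cognitive state)"
                           if r == DEMENTIA and q in (NORMAL, CIND) else ""))
    return report


# ---------------------------------------------------------------------------
# summaries


def transition_count_table(cohort: Cohort, structure=None) -> TransitionCountTable:
    """Tabulate observed interval transitions and origin-state person-time.

    Raises :class:`PanelValidationError` if the cohort fails validation.
    """
    report = validate_cohort(cohort, structure=structure)
    if not report.ok:
        raise PanelValidationError(f"cohort failed validation:\n{report}")
    counts = np.zeros((4, 4), dtype=int)
    person_time = np.zeros(4)
    for s in cohort.subjects:
        t, st = s.times, s.states
        for k in range(len(t) - 1):
            counts[st[k] - 1, st[k + 1] - 1] += 1
            person_time[st[k] - 1] += t[k + 1] - t[k]
    return TransitionCountTable(counts=counts, person_time=person_time)
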