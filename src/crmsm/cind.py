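"""Cognitive-domain z-scores and CIND classification.

Five cognitive domains are assessed: episodic memory (free recall),
executive function (trail making B), language (verbal fluency),
visuospatial ability (mental rotations), and perceptual speed (digit
cancellation and pattern comparison).  Raw test scores are standardized
against baseline means/SDs (timed tests sign-flipped so that higher always
means better); a domain with several tests takes the mean of its available
test z-scores.

CIND (cognitive impairment, no dementia) is scoring at least 1.5 SD below
the *age-group-specific* mean in any of the five domains.  A subject can be
classified non-CIND only when all five domains are scoreable; with a partial
battery the rule can still fire (any one qualifying domain suffices) but a
negative call is withheld as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CIND, DEATH, DEMENTIA, NORMAL

DOMAINS = ["episodic_memory", "executive_function", "language",
           "visuospatial", "perceptual_speed"]

#: default test battery: domain -> test columns; sign -1 flips timed tests
#: (longer completion time = worse performance).
DEFAULT_BATTERY = {
    "episodic_memory": [("free_recall", +1)],
    "executive_function": [("trail_making_b_seconds", -1)],
    "language": [("verbal_fluency", +1)],
    "visuospatial": [("mental_rotations", +1)],
    "perceptual_speed": [("digit_cancellation", +1), ("pattern_comparison", +1)],
}

#: age bands matching the cohort's sampling design.
DEFAULT_AGE_GROUPS = (60, 66, 72, 78, 81, 84, 87, 90)


class UnknownAgeGroupError(KeyError):
    pass


def age_group_label(age: float, bands: tuple[int, ...] = DEFAULT_AGE_GROUPS) -> int:
    """Assign an age to its sampling band (the largest band <= age)."""
    if age < bands[0]:
        raise UnknownAgeGroupError(f"age {age} below the youngest band {bands[0]}")
    return int(max(b for b in bands if b <= age))


@dataclass(frozen=True)
class TestReference:
    """Baseline mean/SD per raw test, for the test-level z-scores."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.sd.items():
            if not v > 0:
                raise ValueError(f"reference SD for test {k!r} must be > 0")


@dataclass
class DomainZProfile:
    """Per-domain z-scores (NaN = unscoreable) and the subject's age band."""

    z: dict[str, float]
    age_group: int


@dataclass(frozen=True)
class GroupReference:
    """Age-group-specific mean/SD of each domain z-score.

    ``mean[(age_group, domain)]`` and ``sd[(age_group, domain)]``; built from
    baseline data with :meth:`from_profiles`.
    """

    mean: dict[tuple[int, str], float]
    sd: dict[tuple[int, str], float]

    @classmethod
    def from_profiles(cls, profiles: list[DomainZProfile]) -> "GroupReference":
        """Estimate per-band references; bands too sparse to yield an SD
        (fewer than two observations) fall back to the pooled all-ages
        mean/SD of the domain."""
        groups: dict[tuple[int, str], list[float]] = {}
        pooled: dict[str, list[float]] = {}
        bands = set()
        for p in profiles:
            bands.add(p.age_group)
            for d, z in p.z.items():
                if np.isfinite(z):
                    groups.setdefault((p.age_group, d), []).append(z)
                    pooled.setdefault(d, []).append(z)
        mean = {k: float(np.mean(v)) for k, v in groups.items() if len(v) > 1}
        sd = {k: float(np.std(v, ddof=1)) for k, v in groups.items() if len(v) > 1}
        for g in bands:
            for d, vals in pooled.items():
                if (g, d) not in sd and len(vals) > 1:
                    mean[(g, d)] = float(np.mean(vals))
                    sd[(g, d)] = float(np.std(vals, ddof=1))
        return cls(mean=mean, sd=sd)


def cognitive_z_scores(battery: dict[str, float] | pd.Series,
                       reference: TestReference,
                       age_group: int,
                       battery_config: dict = None) -> DomainZProfile:
    """Standardize raw test scores and average them within each domain.

    Tests are oriented so that higher = better before averaging (timed tests
    carry sign -1 in the battery configuration).  A domain's z is the mean of
    its available test z-scores; NaN when no test of the domain is present.
    """
    config = battery_config or DEFAULT_BATTERY
    if isinstance(battery, pd.Series):
        battery = battery.to_dict()
    z: dict[str, float] = {}
    for domain, tests in config.items():
        zs = []
        for test, sign in tests:
            x = battery.get(test, np.nan)
            if np.isfinite(x):
                zs.append(sign * (x - reference.mean[test]) / reference.sd[test])
        z[domain] = float(np.mean(zs)) if zs else np.nan
    return DomainZProfile(z=z, age_group=age_group)


def classify_cind(profile: DomainZProfile, group_reference: GroupReference,
                  threshold: float = 1.5) -> bool | None:
    """CIND if any scoreable domain sits >= ``threshold`` SD below its
    age-group mean (inclusive).

    Returns False only when all five domains are scoreable and none crosses
    the threshold; with a partial battery and no qualifying domain the result
    is None (insufficient information).
    """
    n_scoreable = 0
    for domain, z in profile.z.items():
        if not np.isfinite(z):
            continue
        key = (profile.age_group, domain)
        if key not in group_reference.mean or key not in group_reference.sd:
            raise UnknownAgeGroupError(f"no group reference for age group "
                                       f"{profile.age_group}, domain {domain!r}")
        zg = (z - group_reference.mean[key]) / group_reference.sd[key]
        if zg <= -threshold:
            return True
        n_scoreable += 1
    if n_scoreable == len(profile.z):
        return False
    return None


def assemble_state(dementia: bool, cind: bool | None, dead: bool) -> int | None:
    """Combine vital status, clinical dementia and CIND into the state code.

    Death overrides everything; dementia overrides CIND (the states are
    mutually exclusive); otherwise CIND status decides between codes 2 and 1,
    and a missing CIND classification propagates (the exam is unusable).
    """
    if dead:
        return DEATH
    if dementia:
        return DEMENTIA
    if cind is None:
        return None
    return CIND if cind else NORMAL
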