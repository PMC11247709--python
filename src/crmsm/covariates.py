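"""Design-matrix preparation: transforms, interactions, missing-data policy.

The adjustment set of the transition models mixes continuous risk factors
(age in years, body-mass index), binary conditions (current smoking, heavy
alcohol drinking, hypertension, high total cholesterol, diabetes, atrial
fibrillation, ischemic heart disease, heart failure), and -- in the MRI
subsample -- structural brain markers: ICV-adjusted gray-matter, white-matter
and hippocampal volumes, log-transformed white-matter-hyperintensity volume,
lacunes dichotomized to presence/absence, and a perivascular-space count.
Missing covariates are handled by complete-case exclusion per fitted model;
no imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

VALID_TRANSFORMS = {"none", "log", "icv_adjust", "dichotomize_presence"}


class CollinearityError(ValueError):
    pass


@dataclass
class CovariateSpec:
    """Names, transforms, interactions and centering of the design matrix.

    ``transforms`` maps a column to one of ``none`` (default), ``log``,
    ``icv_adjust`` (regression adjustment for intracranial volume) or
    ``dichotomize_presence`` (0 stays 0, any positive count becomes 1).
    Interaction product columns are appended last, named ``a:b``.
    """

    continuous: list[str] = field(default_factory=list)
    binary: list[str] = field(default_factory=list)
    transforms: dict[str, str] = field(default_factory=dict)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    center: dict[str, bool] = field(default_factory=dict)
    icv_column: str = "icv"

    def __post_init__(self) -> None:
        for name, tag in self.transforms.items():
            if tag not in VALID_TRANSFORMS:
                raise ValueError(f"unknown transform {tag!r} for {name!r}")
        names = set(self.continuous) | set(self.binary)
        for a, b in self.interactions:
            for m in (a, b):
                if m not in names:
                    raise ValueError(f"interaction member {m!r} is not a spec column")

    @property
    def columns(self) -> list[str]:
        return list(self.continuous) + list(self.binary)


def icv_adjust_volume(volume: np.ndarray, icv: np.ndarray) -> np.ndarray:
    """Adjust a brain volume for total intracranial volume by OLS.

    Returns residual + mean(volume) on complete cases (preserving the scale
    of the original volume); incomplete rows stay missing.  The adjusted
    vector is uncorrelated with ICV by construction.
    """
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if volume.shape != icv.shape:
        raise ValueError("volume and icv must have equal length")
    ok = np.isfinite(volume) & np.isfinite(icv)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete (volume, icv) pairs")
    if np.ptp(icv[ok]) == 0:
        raise CollinearityError("icv is constant; cannot adjust")
    fit = sm.OLS(volume[ok], sm.add_constant(icv[ok])).fit()
    out = np.full_like(volume, np.nan)
    out[ok] = fit.resid + volume[ok].mean()
    return out


def prepare_covariates(raw: pd.DataFrame,
                       spec: CovariateSpec) -> tuple[pd.DataFrame, dict]:
    """Build the design matrix from a raw covariate table.

    Applies per-column transforms, optional centering, and appends
    interaction product columns (spec order first, interactions last).
    Returns the design frame and an inclusion log with per-column missing
    counts; complete-case filtering is left to the model fit, which sees the
    per-fit covariate subset.
    """
    missing = [c for c in spec.columns if c not in raw.columns]
    if missing:
        raise KeyError(f"spec column(s) absent from table: {missing}")

    design = pd.DataFrame(index=raw.index)
    log: dict[str, dict] = {"n_rows": len(raw), "columns": {}}
    for c in spec.columns:
        x = raw[c].astype(float)
        tag = spec.transforms.get(c, "none")
        n_warn = 0
        if tag == "log":
            nonpos = x <= 0
            n_warn = int((nonpos & x.notna()).sum())
            if n_warn:
                logger.warning("log transform of %r: %d non-positive value(s) set missing",
                               c, n_warn)
            x = x.where(~nonpos, np.nan)
            x = np.log(x)
        elif tag == "icv_adjust":
            if spec.icv_column not in raw.columns:
                raise KeyError(f"icv_adjust for {c!r} needs column {spec.icv_column!r}")
            x = pd.Series(icv_adjust_volume(x.to_numpy(), raw[spec.icv_column].to_numpy()),
                          index=raw.index)
        elif tag == "dichotomize_presence":
            x = (x > 0).astype(float).where(x.notna(), np.nan)
        if spec.center.get(c, False):
            x = x - x.mean()
        design[c] = x
        log["columns"][c] = {"transform": tag, "n_missing": int(x.isna().sum()),
                             "n_invalid": n_warn}
    for a, b in spec.interactions:
        design[f"{a}:{b}"] = design[a] * design[b]
    log["n_complete"] = int(design.notna().all(axis=1).sum())
    return design, log
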