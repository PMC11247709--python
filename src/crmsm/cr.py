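"""Composite cognitive-reserve (CR) scoring.

Cognitive reserve is proxied by four lifespan indicators: years of formal
education (early life), substantive complexity of the longest-held
occupations (midlife, continuous 0.7-10), a late-life leisure-activity score
(0-6, summing mental/social/physical components each scored 0/1/2), and a
late-life social-network score (mean of standardized size and support
blocks).  The four indicators are z-standardized and combined through a
one-factor confirmatory factor model fitted by maximum likelihood; the
composite score of a subject is the weighted sum of their standardized
indicators using regression-method factor-score weights w = Sigma^-1 lambda.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import optimize

INDICATORS = ["education_years", "work_complexity", "leisure_score", "social_network_score"]


class DomainError(ValueError):
    pass


class DegenerateIndicatorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# component scores


class PhysicalFrequency(IntEnum):
    """Frequency band of physical leisure engagement; the band is the score."""

    LESS_THAN_WEEKLY = 0
    WEEKLY = 1
    MORE_THAN_WEEKLY = 2


_FREQ_ALIASES = {"less_than_weekly": 0, "weekly": 1, "more_than_weekly": 2}


@dataclass(frozen=True)
class LeisureInputs:
    mental_count: int
    social_count: int
    physical_frequency: PhysicalFrequency | str | int

    def __post_init__(self) -> None:
        for name in ("mental_count", "social_count"):
            v = getattr(self, name)
            if v < 0:
                raise DomainError(f"{name} must be non-negative, got {v}")
            if v > 26:
                raise DomainError(f"{name} exceeds the 26 listed activities: {v}")


def _count_band(count: int) -> int:
    # low (<=1) / moderate (2-3) / high (>=4) engagement -> 0 / 1 / 2
    if count <= 1:
        return 0
    return 1 if count <= 3 else 2


def leisure_activity_score(inputs: LeisureInputs) -> int:
    """Sum of the mental, social and physical component scores (0-6).

    Mental and social components are banded by the number of activities
    (<=1 -> 0, 2-3 -> 1, >=4 -> 2); the physical component by participation
    frequency (less than weekly / weekly / more than weekly -> 0/1/2).
    """
    freq = inputs.physical_frequency
    if isinstance(freq, str):
        try:
            freq = _FREQ_ALIASES[freq]
        except KeyError:
            raise DomainError(f"unknown physical frequency {freq!r}") from None
    freq = int(freq)
    if freq not in (0, 1, 2):
        raise DomainError(f"physical frequency band must be 0/1/2, got {freq}")
    return _count_band(inputs.mental_count) + _count_band(inputs.social_count) + freq


@dataclass(frozen=True)
class Reference:
    """Per-indicator standardization constants (baseline mean and SD)."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.sd.items():
            if not v > 0:
                raise DegenerateIndicatorError(f"reference SD for {k!r} must be > 0, got {v}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Reference":
        sd = df.std(ddof=1)
        bad = sd[~(sd > 0)].index.tolist()
        if bad:
            raise DegenerateIndicatorError(f"zero-variance indicator column(s): {bad}")
        return cls(mean=df.mean().to_dict(), sd=sd.to_dict())


@dataclass(frozen=True)
class SocialNetworkInputs:
    """Pre-coded numeric indicators of network size and perceived support."""

    size_indicators: dict[str, float]
    support_indicators: dict[str, float]


def social_network_score(inputs: SocialNetworkInputs, reference: Reference) -> float:
    """(mean size z-score + mean support z-score) / 2, ignoring missing.

    Each raw indicator is standardized against the reference; if every
    indicator of a block is missing the score is missing (NaN).
    """
    def block(values: dict[str, float]) -> float:
        zs = [(v - reference.mean[k]) / reference.sd[k]
              for k, v in values.items() if np.isfinite(v)]
        return float(np.mean(zs)) if zs else np.nan
    size = block(inputs.size_indicators)
    support = block(inputs.support_indicators)
    return (size + support) / 2.0


def standardize_indicators(table: pd.DataFrame, reference: Reference | None = None) -> pd.DataFrame:
    """Column-wise z = (x - mean)/SD; missing values stay missing.

    Without an explicit reference the table's own mean/SD are used (baseline
    standardization).
    """
    if reference is None:
        reference = Reference.from_frame(table)
    z = table.copy().astype(float)
    for c in table.columns:
        if c not in reference.mean:
            raise KeyError(f"no reference mean/SD for column {c!r}")
        z[c] = (table[c] - reference.mean[c]) / reference.sd[c]
    return z


# ---------------------------------------------------------------------------
# one-factor confirmatory factor model


@dataclass
class CfaFit:
    """ML one-factor model: S approx lambda lambda' + diag(theta).

    ``weights`` are regression-method factor-score coefficients
    w = Sigma_hat^-1 lambda_hat, the weights of the composite weighted sum.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    weights: np.ndarray
    chi2: float
    df: int
    cfi: float
    rmsea: float
    n: int
    converged: bool
    heywood: bool
    indicator_names: list[str]

    @property
    def implied_covariance(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.uniquenesses)


def _discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p."""
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def compute_fit_indices(F_ml: float, n: int, df: int,
                        F_baseline: float, df_baseline: int) -> tuple[float, float, float]:
    """Likelihood-ratio chi2, CFI and RMSEA from ML discrepancies.

    chi2 = (n-1) F; CFI compares the excess of chi2 over its df with that of
    the independence baseline; RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))).
    A better-than-expected fit (chi2 <= df) gives CFI = 1 and RMSEA = 0.
    """
    if n < 2 or df < 1:
        raise DomainError("need n >= 2 and df >= 1")
    if F_ml < 0 or F_baseline < 0:
        raise DomainError("discrepancy values must be non-negative")
    chi2 = (n - 1) * F_ml
    chi2_b = (n - 1) * F_baseline
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    return float(chi2), float(cfi), rmsea


_THETA_FLOOR = 1e-6


def fit_one_factor_model(z: pd.DataFrame | np.ndarray | None = None, *,
                         cov: np.ndarray | None = None,
                         n: int | None = None) -> CfaFit:
    """Fit the one-factor model to the complete-case sample covariance.

    The factor variance is fixed at 1 and the first loading is constrained
    positive (resolving the sign indeterminacy).  Free parameters: 4 loadings
    and 4 uniquenesses, leaving df = 10 - 8 = 2.  Heywood cases are bounded
    at a small positive uniqueness and flagged.

    Instead of raw data ``z``, a sample covariance may be supplied directly
    via ``cov`` together with its sample size ``n``.
    """
    if cov is not None:
        if n is None:
            raise ValueError("a sample size n is required with cov")
        S = np.asarray(cov, dtype=float)
        p = S.shape[0]
        names = [f"x{j + 1}" for j in range(p)]
    else:
        if isinstance(z, pd.DataFrame):
            names = list(z.columns)
            arr = z.to_numpy(dtype=float)
        else:
            arr = np.asarray(z, dtype=float)
            names = [f"x{j + 1}" for j in range(arr.shape[1])]
        arr = arr[np.all(np.isfinite(arr), axis=1)]
        n, p = arr.shape
        if n < p:
            raise ValueError(f"need at least {p} complete rows, got {n}")
        S = np.cov(arr, rowvar=False, ddof=1)
    if np.any(np.linalg.eigvalsh(S) <= 0):
        raise np.linalg.LinAlgError("sample covariance is not positive definite")

    # principal-axis start: first eigenvector scaled by sqrt(eigenvalue)
    w_eig, v_eig = np.linalg.eigh(S)
    lam0 = v_eig[:, -1] * np.sqrt(w_eig[-1])
    if lam0[0] < 0:
        lam0 = -lam0
    theta0 = np.clip(np.diag(S) - lam0 ** 2, 0.05, None)

    def objective(params):
        lam = params[:p]
        theta = np.exp(params[p:])
        return _discrepancy(S, np.outer(lam, lam) + np.diag(theta))

    res = optimize.minimize(objective, np.concatenate([lam0, np.log(theta0)]),
                            method="L-BFGS-B",
                            bounds=[(None, None)] * p + [(np.log(_THETA_FLOOR), None)] * p,
                            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 2000})
    lam = res.x[:p]
    theta = np.exp(res.x[p:])
    if lam[0] < 0:
        lam = -lam
    heywood = bool(np.any(theta <= _THETA_FLOOR * (1 + 1e-9)))
    if heywood:
        import warnings
        warnings.warn("Heywood case: uniqueness bounded at the floor", stacklevel=2)

    Sigma = np.outer(lam, lam) + np.diag(theta)
    F_ml = _discrepancy(S, Sigma)
    # independence baseline: free variances, zero covariances (ML solution
    # sets the variances to the sample variances)
    F_base = _discrepancy(S, np.diag(np.diag(S)))
    df = p * (p + 1) // 2 - 2 * p
    df_base = p * (p + 1) // 2 - p
    chi2, cfi, rmsea = compute_fit_indices(F_ml, n, df, F_base, df_base)
    weights = np.linalg.solve(Sigma, lam)

    return CfaFit(loadings=lam, uniquenesses=theta, weights=weights,
                  chi2=chi2, df=df, cfi=cfi, rmsea=rmsea, n=n,
                  converged=bool(res.success), heywood=heywood,
                  indicator_names=names)


# ---------------------------------------------------------------------------
# composite scores


def composite_cr_scores(fit: CfaFit, z: pd.DataFrame | np.ndarray,
                        min_indicators: int = 3) -> pd.DataFrame:
    """Composite CR score per row: sum of weights times standardized indicators.

    Rows with some (but >= ``min_indicators``) indicators present use the
    available weights rescaled so they sum to the full-weight total; rows
    below the minimum get a missing score.  Returns columns
    ``cr_score`` and ``n_indicators_used``.
    """
    if not fit.converged:
        raise RuntimeError("factor model did not converge; refusing to score")
    if isinstance(z, pd.DataFrame):
        index = z.index
        arr = z.to_numpy(dtype=float)
    else:
        arr = np.asarray(z, dtype=float)
        index = pd.RangeIndex(arr.shape[0])
    w = fit.weights
    present = np.isfinite(arr)
    n_used = present.sum(axis=1)
    total = w.sum()
    scores = np.full(arr.shape[0], np.nan)
    for i in range(arr.shape[0]):
        if n_used[i] < min_indicators:
            continue
        wi = w[present[i]]
        scale = total / wi.sum() if n_used[i] < arr.shape[1] else 1.0
        scores[i] = float(np.nansum(wi * scale * arr[i, present[i]]))
    return pd.DataFrame({"cr_score": scores, "n_indicators_used": n_used}, index=index)
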