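"""Continuous-time Markov multistate model for panel-observed cognitive states.

The model follows the classical panel-data formulation for Markov processes
observed at arbitrary exam times: a four-state process (normal cognition,
CIND, dementia, death) with transition intensity matrix

    q_rs(x) = q0_rs * exp(beta_rs' x)        for allowed transitions r -> s,

time-homogeneous on the follow-up-time scale given baseline covariates x.
Living states are interval-censored (the likelihood contribution of an exam
pair r at t, s at t+dt is the matrix-exponential entry P_rs(dt)); death is
exactly observed and contributes sum_s P_rs(dt) * q_s4(x), summing over the
living state occupied just before death.

Maximum likelihood uses a quasi-Newton optimizer.  Gradients are analytic by
default, computed from the eigendecomposition form of the directional
derivative of the matrix exponential, which makes cohort-scale fits fast; a
central-difference gradient is available (``gradient="numeric"``) and the two
agree to optimizer tolerance (cross-checked in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import expm

from .panel import (
    DEATH,
    LIVING_STATES,
    Cohort,
    PanelValidationError,
    Subject,
    TransitionCountTable,
    validate_cohort,
)

logger = logging.getLogger(__name__)

N_STATES = 4

#: transitions of the default structure: bidirectional normal<->CIND, onward
#: progression to dementia, death reachable from every living state; no
#: recovery from dementia.
DEFAULT_ALLOWED = ((1, 2), (2, 1), (1, 3), (2, 3), (1, 4), (2, 4), (3, 4))


class StructureError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class TransitionStructure:
    """The set of directed instantaneous transitions the model allows."""

    allowed: tuple[tuple[int, int], ...] = DEFAULT_ALLOWED

    def __post_init__(self) -> None:
        for r, s in self.allowed:
            if r == DEATH:
                raise StructureError("no transitions out of the absorbing death state")
            if r == s or r not in range(1, 5) or s not in range(1, 5):
                raise StructureError(f"invalid transition ({r}, {s})")
        # death must be reachable (possibly indirectly) from every living
        # state that participates in the structure
        reach = {r: {r} for r in range(1, 5)}
        changed = True
        while changed:
            changed = False
            for r, s in self.allowed:
                new = reach[s] - reach[r]
                if new:
                    reach[r] |= new
                    changed = True
        participating = {r for tr in self.allowed for r in tr}
        for r in participating & set(LIVING_STATES):
            if DEATH not in reach[r]:
                raise StructureError(f"death is unreachable from state {r}")

    def __len__(self) -> int:
        return len(self.allowed)

    def index(self, r: int, s: int) -> int:
        return self.allowed.index((r, s))


DEFAULT_STRUCTURE = TransitionStructure()


@dataclass
class IntensityModel:
    """Baseline log-intensities and per-transition covariate coefficients.

    ``log_q0[(r, s)]`` is the log baseline intensity (1/year) of transition
    r -> s at covariates 0; ``beta[(r, s)]`` maps covariate name -> log hazard
    ratio per covariate unit for that specific transition.
    """

    structure: TransitionStructure
    log_q0: dict[tuple[int, int], float]
    beta: dict[tuple[int, int], dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tr in self.structure.allowed:
            if tr not in self.log_q0:
                raise ValueError(f"log_q0 missing for allowed transition {tr}")
        self.beta = {tr: dict(self.beta.get(tr, {})) for tr in self.structure.allowed}

    def rate(self, r: int, s: int, x: dict[str, float]) -> float:
        lin = self.log_q0[(r, s)]
        for name, b in self.beta[(r, s)].items():
            if name not in x:
                raise KeyError(f"missing covariate '{name}' for transition ({r}, {s})")
            lin += b * x[name]
        return float(np.exp(lin))

    def hazard_ratios(self) -> dict[tuple[int, int], dict[str, float]]:
        return {tr: {k: float(np.exp(b)) for k, b in bs.items()} for tr, bs in self.beta.items()}


def build_intensity_matrix(model: IntensityModel, x: dict[str, float] | None = None) -> np.ndarray:
    """Assemble the 4x4 generator Q at covariate vector ``x``.

    Off-diagonals are ``exp(log_q0 + beta'x)`` on allowed transitions and 0
    elsewhere; each diagonal is minus its row sum, so rows sum to zero.
    """
    x = x or {}
    Q = np.zeros((N_STATES, N_STATES))
    for r, s in model.structure.allowed:
        Q[r - 1, s - 1] = model.rate(r, s, x)
    Q[np.arange(N_STATES), np.arange(N_STATES)] = -Q.sum(axis=1)
    return Q


def transition_probability(Q: np.ndarray, dt: float) -> np.ndarray:
    """P(dt) = expm(Q*dt), by scaling-and-squaring with Pade approximation.

    Entries are clipped into [0, 1] only within 1e-12 numerical slack; rows
    sum to 1 within 1e-10 for any valid generator.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    Q = np.asarray(Q, dtype=float)
    offdiag = Q[~np.eye(Q.shape[0], dtype=bool)]
    if np.any(offdiag < -1e-12) or np.any(np.abs(Q.sum(axis=1)) > 1e-10):
        raise ValueError("Q is not a valid generator (negative off-diagonal or nonzero row sum)")
    P = expm(Q * dt)
    if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
        raise FloatingPointError("transition probabilities outside [0,1] beyond numerical slack")
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# likelihood


def subject_loglik(subject: Subject, model: IntensityModel,
                   x: dict[str, float] | None = None) -> float:
    """Log-likelihood contribution of one subject (reference implementation).

    Panel pairs contribute ln P_rs(dt); an exactly observed death from last
    living exam state r contributes ln sum_s P_rs(dt) q_s4.  A pair that is
    impossible under the structure yields -inf with a diagnostic log message.
    """
    x = dict(x or subject.covariates)
    Q = build_intensity_matrix(model, x)
    t, st = subject.times, subject.states
    total = 0.0
    for k in range(len(t) - 1):
        r, s = int(st[k]), int(st[k + 1])
        dt = float(t[k + 1] - t[k])
        P = transition_probability(Q, dt)
        if s == DEATH:
            contrib = sum(P[r - 1, u - 1] * Q[u - 1, DEATH - 1] for u in LIVING_STATES)
        else:
            contrib = P[r - 1, s - 1]
        if contrib <= 0:
            logger.warning("subject %s: observed pair %d->%d over %.3g years has zero "
                           "probability under the transition structure", subject.id, r, s, dt)
            return -np.inf
        total += np.log(contrib)
    return float(total)


@dataclass
class _IntervalData:
    """Vectorized interval arrays for one cohort under one design."""

    X: np.ndarray                 # (n_subjects, p) covariate matrix, design column order
    columns: list[str]
    # panel pairs (both endpoints living, observed at exams)
    p_subj: np.ndarray            # subject index per interval
    p_from: np.ndarray            # 0-based origin state
    p_to: np.ndarray              # 0-based destination state
    p_dt: np.ndarray
    # exactly observed death pairs
    d_subj: np.ndarray
    d_from: np.ndarray
    d_dt: np.ndarray
    n_subjects: int
    n_pairs: int


def _collect_intervals(cohort: Cohort, columns: list[str]) -> tuple[_IntervalData, int]:
    """Flatten a cohort into interval arrays; complete-case on ``columns``."""
    X_rows, p_subj, p_from, p_to, p_dt = [], [], [], [], []
    d_subj, d_from, d_dt = [], [], []
    n_excluded = 0
    i = 0
    for s in cohort.subjects:
        if len(s.observations) < 2:
            continue
        xs = [s.covariates.get(c, np.nan) for c in columns]
        if any(not np.isfinite(v) for v in xs):
            n_excluded += 1
            continue
        t, st = s.times, s.states
        X_rows.append(xs)
        for k in range(len(t) - 1):
            r, q = int(st[k]), int(st[k + 1])
            dt = float(t[k + 1] - t[k])
            if q == DEATH:
                d_subj.append(i); d_from.append(r - 1); d_dt.append(dt)
            else:
                p_subj.append(i); p_from.append(r - 1); p_to.append(q - 1); p_dt.append(dt)
        i += 1
    if i == 0:
        raise FitError("no subjects with >= 2 observations and complete covariates")
    data = _IntervalData(
        X=np.asarray(X_rows, dtype=float).reshape(i, len(columns)),
        columns=list(columns),
        p_subj=np.asarray(p_subj, dtype=int), p_from=np.asarray(p_from, dtype=int),
        p_to=np.asarray(p_to, dtype=int), p_dt=np.asarray(p_dt, dtype=float),
        d_subj=np.asarray(d_subj, dtype=int), d_from=np.asarray(d_from, dtype=int),
        d_dt=np.asarray(d_dt, dtype=float),
        n_subjects=i, n_pairs=len(p_subj) + len(d_subj),
    )
    return data, n_excluded


class _ParameterMap:
    """Pack/unpack the free parameter vector.

    Layout: free log baseline intensities first (structure order), then beta
    coefficients transition-by-transition in design order.  Frozen baselines
    hold their initial value; frozen betas are fixed at zero (absent).
    """

    def __init__(self, structure: TransitionStructure,
                 design: dict[tuple[int, int], list[str]],
                 frozen_q0: dict[tuple[int, int], float]):
        self.structure = structure
        self.design = design
        self.frozen_q0 = dict(frozen_q0)
        self.free_q0 = [tr for tr in structure.allowed if tr not in frozen_q0]
        self.names: list[tuple[tuple[int, int], str]] = []
        self.names += [(tr, "log_q0") for tr in self.free_q0]
        for tr in structure.allowed:
            self.names += [(tr, c) for c in design.get(tr, [])]
        self.n = len(self.names)

    def pack(self, model: IntensityModel) -> np.ndarray:
        theta = np.empty(self.n)
        for j, (tr, name) in enumerate(self.names):
            theta[j] = model.log_q0[tr] if name == "log_q0" else model.beta[tr].get(name, 0.0)
        return theta

    def unpack(self, theta: np.ndarray) -> IntensityModel:
        log_q0 = dict(self.frozen_q0)
        beta: dict[tuple[int, int], dict[str, float]] = {tr: {} for tr in self.structure.allowed}
        for j, (tr, name) in enumerate(self.names):
            if name == "log_q0":
                log_q0[tr] = float(theta[j])
            else:
                beta[tr][name] = float(theta[j])
        return IntensityModel(structure=self.structure, log_q0=log_q0, beta=beta)


_TINY = 1e-250


class _PanelLikelihood:
    """Cohort log-likelihood and analytic gradient, vectorized over subjects.

    All subjects' generators are eigendecomposed in one batched call; interval
    probabilities and the directional derivatives of expm follow from the
    spectral identity dP = V (W o (V^-1 dQ V)) V^-1 with
    W_ab = (e^{la t} - e^{lb t}) / (la - lb) and W_aa = t e^{la t}.
    Falls back to a dense expm evaluation (with central-difference gradient)
    when an eigenvector matrix is ill-conditioned.
    """

    def __init__(self, data: _IntervalData, pmap: _ParameterMap):
        self.data = data
        self.pmap = pmap
        self.trans = pmap.structure.allowed
        self.n_trans = len(self.trans)
        # per-transition design column indices into data.X
        col = {c: k for k, c in enumerate(data.columns)}
        self.design_cols = {tr: [col[c] for c in pmap.design.get(tr, [])] for tr in self.trans}
        self.fallbacks = 0

    # -- rate matrix assembly ------------------------------------------------

    def _rates(self, model: IntensityModel) -> np.ndarray:
        """(n_subjects, n_trans) intensity of each transition per subject."""
        X = self.data.X
        R = np.empty((self.data.n_subjects, self.n_trans))
        for j, tr in enumerate(self.trans):
            lin = model.log_q0[tr]
            cols = self.design_cols[tr]
            if cols:
                b = np.array([model.beta[tr][self.pmap.design[tr][k]] for k in range(len(cols))])
                R[:, j] = np.exp(lin + X[:, cols] @ b)
            else:
                R[:, j] = np.exp(lin)
        return R

    def _generators(self, R: np.ndarray) -> np.ndarray:
        n = self.data.n_subjects
        Q = np.zeros((n, N_STATES, N_STATES))
        for j, (r, s) in enumerate(self.trans):
            Q[:, r - 1, s - 1] = R[:, j]
        Q[:, np.arange(N_STATES), np.arange(N_STATES)] = -Q.sum(axis=2)
        return Q

    # -- main entry -----------------------------------------------------------

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        model = self.pmap.unpack(theta)
        R = self._rates(model)
        Q = self._generators(R)
        lam, V = np.linalg.eig(Q)
        with np.errstate(all="ignore"):
            Vinv = np.linalg.inv(V)
            cond = (np.abs(V).sum(axis=(1, 2)) * np.abs(Vinv).sum(axis=(1, 2)))
        if not np.all(np.isfinite(cond)) or np.max(cond) > 1e10:
            self.fallbacks += 1
            return self._value_expm(theta), self._grad_numeric(theta)

        ll = 0.0
        grad = np.zeros(self.pmap.n)
        d = self.data

        if d.p_subj.size:
            ll += self._panel_block(d, lam, V, Vinv, R, grad)
        if d.d_subj.size:
            ll += self._death_block(d, lam, V, Vinv, R, grad)
        if not np.isfinite(ll):
            return -np.inf, grad
        return float(ll), grad

    # -- spectral helpers ------------------------------------------------------

    @staticmethod
    def _frechet_W(lam_i: np.ndarray, ex: np.ndarray, dt: np.ndarray) -> np.ndarray:
        diff = lam_i[:, :, None] - lam_i[:, None, :]
        num = ex[:, :, None] - ex[:, None, :]
        small = np.abs(diff) < 1e-9
        W = np.where(small, dt[:, None, None] * ex[:, :, None],
                     num / np.where(small, 1.0, diff))
        return W

    def _accumulate(self, grad, subj, weight, E, R):
        """Add per-interval, per-transition gradient contributions.

        ``E[i, u, v]`` is d(contribution_i)/d(q_uv) / contribution_i scaled by
        ``weight``; chain rule through q_uv = exp(log_q0 + beta'x) multiplies
        by q_uv (and by the covariate for beta terms).
        """
        X = self.data.X
        pos = 0
        free = set(self.pmap.free_q0)
        for j, tr in enumerate(self.trans):
            u, v = tr[0] - 1, tr[1] - 1
            g = weight * R[subj, j] * E[:, u, v]
            if tr in free:
                k = self.pmap.free_q0.index(tr)
                grad[k] += g.sum()
        pos = len(self.pmap.free_q0)
        for tr in self.trans:
            cols = self.design_cols[tr]
            if not cols:
                continue
            j = self.trans.index(tr)
            u, v = tr[0] - 1, tr[1] - 1
            g = weight * R[subj, j] * E[:, u, v]
            for k in cols:
                grad[pos] += (g * X[subj, k]).sum()
                pos += 1

    def _panel_block(self, d, lam, V, Vinv, R, grad) -> float:
        idx, r, s, dt = d.p_subj, d.p_from, d.p_to, d.p_dt
        lam_i, V_i, Vinv_i = lam[idx], V[idx], Vinv[idx]
        ex = np.exp(lam_i * dt[:, None])
        L = V_i[np.arange(idx.size), r, :]
        Rv = Vinv_i[np.arange(idx.size), :, s]
        P = np.einsum("ma,ma,ma->m", L, ex, Rv).real
        P = np.clip(P, _TINY, None)
        W = self._frechet_W(lam_i, ex, dt)
        S = np.einsum("ma,mau,mab->mub", L, Vinv_i, W)
        F = np.einsum("mub,mb,mvb->muv", S, Rv, V_i)
        E = (F - np.diagonal(F, axis1=1, axis2=2)[:, :, None]).real
        self._accumulate(grad, idx, 1.0 / P, E, R)
        return float(np.log(P).sum())

    def _death_block(self, d, lam, V, Vinv, R, grad) -> float:
        idx, r, dt = d.d_subj, d.d_from, d.d_dt
        m = idx.size
        lam_i, V_i, Vinv_i = lam[idx], V[idx], Vinv[idx]
        ex = np.exp(lam_i * dt[:, None])
        L = V_i[np.arange(m), r, :]
        # q_{s,DEATH} per living state s, per interval
        qd = np.zeros((m, N_STATES))
        for j, tr in enumerate(self.trans):
            if tr[1] == DEATH:
                qd[:, tr[0] - 1] = R[idx, j]
        # P_{r,s}(dt) for all s simultaneously
        Prow = np.einsum("ma,ma,mas->ms", L, ex, Vinv_i).real
        D = np.clip((Prow * qd).sum(axis=1), _TINY, None)
        # part A: derivative through P, with the death rates folded into R~
        Rtilde = np.einsum("mas,ms->ma", Vinv_i, qd)
        W = self._frechet_W(lam_i, ex, dt)
        S = np.einsum("ma,mau,mab->mub", L, Vinv_i, W)
        F = np.einsum("mub,mb,mvb->muv", S, Rtilde, V_i)
        E = (F - np.diagonal(F, axis1=1, axis2=2)[:, :, None]).real
        self._accumulate(grad, idx, 1.0 / D, E, R)
        # part B: derivative through the death intensity q_{s4} itself
        pos = len(self.pmap.free_q0)
        X = self.data.X
        free = self.pmap.free_q0
        for j, tr in enumerate(self.trans):
            if tr[1] == DEATH:
                gB = Prow[:, tr[0] - 1] * R[idx, j] / D
                if tr in free:
                    grad[free.index(tr)] += gB.sum()
        for tr in self.trans:
            cols = self.design_cols[tr]
            for k in cols:
                if tr[1] == DEATH:
                    j = self.trans.index(tr)
                    gB = Prow[:, tr[0] - 1] * R[idx, j] / D
                    grad[pos] += (gB * X[idx, k]).sum()
                pos += 1
        return float(np.log(D).sum())

    # -- dense fallback --------------------------------------------------------

    def _value_expm(self, theta: np.ndarray) -> float:
        model = self.pmap.unpack(theta)
        R = self._rates(model)
        Q = self._generators(R)
        d = self.data
        ll = 0.0
        for i, r, s, dt in zip(d.p_subj, d.p_from, d.p_to, d.p_dt):
            P = expm(Q[i] * dt)
            ll += np.log(max(P[r, s], _TINY))
        for i, r, dt in zip(d.d_subj, d.d_from, d.d_dt):
            P = expm(Q[i] * dt)
            contrib = sum(P[r, u - 1] * Q[i][u - 1, DEATH - 1] for u in LIVING_STATES)
            ll += np.log(max(contrib, _TINY))
        return float(ll)

    def _grad_numeric(self, theta: np.ndarray) -> np.ndarray:
        grad = np.empty(self.pmap.n)
        for j in range(self.pmap.n):
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            grad[j] = (self._value_expm(tp) - self._value_expm(tm)) / (2 * h)
        return grad


# ---------------------------------------------------------------------------
# initial values


def crude_initial_values(table: TransitionCountTable,
                         structure: TransitionStructure = DEFAULT_STRUCTURE,
                         floor: float = 1e-4) -> IntensityModel:
    """Occurrence/exposure starting rates: count_rs / person_time_r, floored.

    These equal the exact MLE for fully observed single-transition data and
    serve as the specified initial values of the transition matrix; all
    covariate effects start at zero.
    """
    log_q0 = {}
    for r, s in structure.allowed:
        pt = table.person_time[r - 1]
        rate = table.counts[r - 1, s - 1] / pt if pt > 0 else 0.0
        if rate < floor:
            logger.info("transition %d->%d has crude rate %.3g below floor; using %.3g",
                        r, s, rate, floor)
            rate = floor
        log_q0[(r, s)] = float(np.log(rate))
    return IntensityModel(structure=structure, log_q0=log_q0)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedModel:
    """MLE result: estimates, covariance, and bookkeeping."""

    estimates: IntensityModel
    covariance: np.ndarray | None
    param_names: list[tuple[tuple[int, int], str]]
    loglik: float
    n_subjects: int
    n_transitions: int
    convergence: dict
    frozen: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    n_excluded: int = 0

    def param_index(self, transition: tuple[int, int], name: str) -> int:
        try:
            return self.param_names.index((transition, name))
        except ValueError:
            raise KeyError(f"parameter {name!r} on transition {transition} not in fitted model")

    def se(self, transition: tuple[int, int], name: str) -> float:
        if self.covariance is None:
            return np.nan
        j = self.param_index(transition, name)
        return float(np.sqrt(self.covariance[j, j]))


def _transition_support(cohort: Cohort, structure: TransitionStructure) -> dict:
    """Observed interval pairs backing each allowed transition (incl. death)."""
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    for s in cohort.subjects:
        st = s.states
        for k in range(len(st) - 1):
            counts[st[k] - 1, st[k + 1] - 1] += 1
    return {tr: int(counts[tr[0] - 1, tr[1] - 1]) for tr in structure.allowed}


def fit_multistate(cohort: Cohort,
                   structure: TransitionStructure = DEFAULT_STRUCTURE,
                   covariates: list[str] | dict[tuple[int, int], list[str]] | None = None,
                   init: IntensityModel | None = None,
                   *,
                   min_covariate_support: int = 10,
                   rate_floor: float = 1e-4,
                   gradient: str = "analytic",
                   maxiter: int = 500,
                   gtol: float = 1e-4,
                   compute_covariance: bool = True,
                   validate: bool = True) -> FittedModel:
    """Maximum-likelihood fit of the panel multistate model.

    Parameters
    ----------
    covariates
        Either one list of covariate names applied to every allowed
        transition, or a mapping transition -> names for per-transition
        designs.  Subjects missing any required covariate are excluded
        (complete-case), with the count logged and recorded on the result.
    min_covariate_support
        Covariate effects on transitions backed by fewer observed interval
        pairs than this are frozen at zero and flagged (mirroring analyses
        that do not estimate parameters for very sparse transitions).
    gradient
        ``"analytic"`` (spectral derivative of expm, default) or
        ``"numeric"`` (central differences; slower, kept as a cross-check).
    """
    if validate:
        report = validate_cohort(cohort, structure=structure)
        if not report.ok:
            raise PanelValidationError(f"cohort failed validation:\n{report}")

    if covariates is None:
        design: dict[tuple[int, int], list[str]] = {tr: [] for tr in structure.allowed}
    elif isinstance(covariates, dict):
        design = {tr: list(covariates.get(tr, [])) for tr in structure.allowed}
    else:
        design = {tr: list(covariates) for tr in structure.allowed}

    support = _transition_support(cohort, structure)
    frozen: list[tuple[tuple[int, int], str]] = []
    frozen_q0: dict[tuple[int, int], float] = {}
    for tr in structure.allowed:
        if support[tr] == 0:
            frozen_q0[tr] = float(np.log(rate_floor))
            frozen.append((tr, "log_q0"))
            if design[tr]:
                frozen += [(tr, c) for c in design[tr]]
                design[tr] = []
            logger.warning("transition %s has no observed interval pairs; baseline "
                           "rate frozen at floor %.1e", tr, rate_floor)
        elif design[tr] and support[tr] < min_covariate_support:
            frozen += [(tr, c) for c in design[tr]]
            logger.warning("transition %s has only %d observed pairs (< %d); covariate "
                           "effects frozen at 0", tr, support[tr], min_covariate_support)
            design[tr] = []

    columns = sorted({c for cols in design.values() for c in cols})
    data, n_excluded = _collect_intervals(cohort, columns)
    if n_excluded:
        logger.info("excluded %d subject(s) with missing covariates (complete-case)",
                    n_excluded)

    pmap = _ParameterMap(structure, design, frozen_q0)
    like = _PanelLikelihood(data, pmap)

    if init is None:
        kept = Cohort([s for s in cohort.subjects if len(s.observations) >= 2],
                      cohort.covariate_names)
        table = TransitionCountTable(
            counts=np.array([[support.get((r, s), 0) if r != s else 0
                              for s in range(1, 5)] for r in range(1, 5)]),
            person_time=_person_time(kept))
        init = crude_initial_values(table, structure, floor=rate_floor)
    theta0 = pmap.pack(init)
    if not np.all(np.isfinite(theta0)):
        raise FitError("non-finite initial parameter values")

    if pmap.n == 0:
        # every parameter frozen (no observed transitions at all)
        return FittedModel(
            estimates=pmap.unpack(theta0), covariance=None, param_names=[],
            loglik=like._value_expm(theta0), n_subjects=data.n_subjects,
            n_transitions=0,
            convergence={"converged": True, "iterations": 0, "grad_norm": 0.0,
                         "message": "no free parameters", "fallback_evaluations": 0},
            frozen=frozen, n_excluded=n_excluded)

    if gradient == "analytic":
        def negll(theta):
            ll, g = like.value_and_grad(theta)
            return -ll, -g
        res = optimize.minimize(negll, theta0, jac=True, method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
    elif gradient == "numeric":
        res = optimize.minimize(lambda th: -like._value_expm(th), theta0,
                                jac=lambda th: -like._grad_numeric(th), method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
    else:
        raise ValueError(f"unknown gradient mode {gradient!r}")

    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success) or grad_norm < 10 * gtol
    if not converged:
        logger.warning("optimizer did not converge: %s (|grad|_inf = %.3g after %d iterations)",
                       res.message, grad_norm, res.nit)
    convergence = {"converged": converged, "iterations": int(res.nit),
                   "grad_norm": grad_norm, "message": str(res.message),
                   "fallback_evaluations": like.fallbacks}

    covariance = None
    if compute_covariance and pmap.n > 0:
        H = _numeric_hessian(like, res.x)
        try:
            covariance = np.linalg.inv(H)
            if not np.all(np.isfinite(covariance)) or np.any(np.diag(covariance) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            logger.warning("observed information is singular; covariance unavailable")
            covariance = None

    return FittedModel(
        estimates=pmap.unpack(res.x),
        covariance=covariance,
        param_names=list(pmap.names),
        loglik=float(-res.fun),
        n_subjects=data.n_subjects,
        n_transitions=int(sum(v for tr, v in support.items() if tr[0] != tr[1])),
        convergence=convergence,
        frozen=frozen,
        n_excluded=n_excluded,
    )


def _person_time(cohort: Cohort) -> np.ndarray:
    pt = np.zeros(N_STATES)
    for s in cohort.subjects:
        t, st = s.times, s.states
        for k in range(len(t) - 1):
            pt[st[k] - 1] += t[k + 1] - t[k]
    return pt


def _numeric_hessian(like: _PanelLikelihood, theta: np.ndarray) -> np.ndarray:
    """Observed information: central differences of the analytic gradient."""
    n = theta.size
    H = np.empty((n, n))
    for j in range(n):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = like.value_and_grad(tp)
        _, gm = like.value_and_grad(tm)
        H[j] = -(gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# inference


def hazard_ratio_table(fitted: FittedModel, level: float = 0.95) -> pd.DataFrame:
    """Per-transition, per-covariate hazard ratios with Wald CIs and p-values.

    Frozen covariate effects appear with ``frozen=True`` and missing HR
    (the 'not estimated' dashes of sparse transitions).
    """
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    frozen_set = set(fitted.frozen)
    covnames = {tr: list(fitted.estimates.beta[tr]) for tr in fitted.estimates.structure.allowed}
    for tr in fitted.estimates.structure.allowed:
        for name in covnames[tr]:
            b = fitted.estimates.beta[tr][name]
            se = fitted.se(tr, name)
            with np.errstate(over="ignore"):  # near-singular information: huge but valid CI
                rows.append({"transition": f"{tr[0]}->{tr[1]}", "covariate": name,
                             "hr": np.exp(b), "lo": np.exp(b - z * se), "hi": np.exp(b + z * se),
                             "se_log": se,
                             "p": 2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan,
                             "frozen": False})
        for name in {c for t2, c in frozen_set if t2 == tr and c != "log_q0"}:
            rows.append({"transition": f"{tr[0]}->{tr[1]}", "covariate": name,
                         "hr": np.nan, "lo": np.nan, "hi": np.nan, "se_log": np.nan,
                         "p": np.nan, "frozen": True})
    return pd.DataFrame(rows, columns=["transition", "covariate", "hr", "lo", "hi",
                                       "se_log", "p", "frozen"])


def wald_interaction(fitted: FittedModel, term: str,
                     transition: tuple[int, int]) -> tuple[float, float]:
    """Wald z statistic and two-sided p-value for one coefficient.

    Used for product terms (e.g. CR x age-group) on a specific transition.
    """
    j = fitted.param_index(transition, term)
    if fitted.covariance is None:
        raise FitError("covariance unavailable; cannot form the Wald statistic")
    b = fitted.estimates.beta[transition][term]
    se = float(np.sqrt(fitted.covariance[j, j]))
    z = b / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def stratified_fit(cohort: Cohort, stratum: str, levels=None,
                   **fit_kwargs) -> dict[object, FittedModel]:
    """Independent fits per level of a baseline stratifying covariate.

    The stratifying variable is removed from every transition's covariate set
    (a constant within stratum is inestimable).  Sparse transitions within a
    stratum follow the usual freezing policy, so a stratum with, say, no
    CIND -> death transitions yields a flagged frozen parameter, not a crash.
    """
    values = {s.id: s.covariates.get(stratum, np.nan) for s in cohort.subjects}
    if levels is None:
        levels = sorted({v for v in values.values() if np.isfinite(v)})
    out: dict[object, FittedModel] = {}
    covariates = fit_kwargs.pop("covariates", None)
    for lev in levels:
        subs = [s for s in cohort.subjects if values[s.id] == lev]
        if not subs:
            raise FitError(f"stratum {stratum}={lev} is empty")
        sub_cohort = Cohort(subs, cohort.covariate_names)
        if isinstance(covariates, dict):
            cov = {tr: [c for c in cols if c != stratum] for tr, cols in covariates.items()}
        elif covariates is not None:
            cov = [c for c in covariates if c != stratum]
        else:
            cov = None
        out[lev] = fit_multistate(sub_cohort, covariates=cov, **fit_kwargs)
    return out
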