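"""Generators for longitudinal treatment/confounder/time-to-event cohorts.

The observational generator draws, sequentially per visit k = 0..K,

* a frailty ``U ~ N(0, u_sd^2)`` (once, before visit 0),
* the confounder ``L_k`` from a normal with mean
  ``rho * L_{k-1} + theta_a * A_{k-1} + theta_k * k + theta_u * U``
  (``L_0`` has mean ``l0_u_coef * U``),
* the treatment ``A_k ~ Bernoulli(expit(gamma0 + gammaL * L_k + gammaA * A_{k-1}))``,
* an event time in ``[k, k+1)`` from the conditional hazard
  ``lambda(t | A, L, U)``, by inverse transform of the (piecewise) exponential
  within the interval; survivors continue to visit k + 1,

with administrative censoring at ``K + 1``.  The default parameters give the
conditional additive hazard ``0.7 - 0.2 A + 0.05 L + 0.05 U``.  Negative
additive hazards are floored at 0 at evaluation time and the number of floored
evaluations is logged.

The intervention-trial generator bypasses the treatment model and assigns a
fixed regime to every person, sharing the baseline draws ``(U, L_0)`` across
regimes within a replicate; this is what defines the "true" marginal estimands
by randomization.

Random-number discipline: a master seed spawns named substreams (frailty,
covariates, treatment, event, censoring), and every stream draws full-length
vectors at each visit regardless of risk status, so that toggling one model
component does not shift the draws of any other component.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit

from .trajectories import CohortPanel

logger = logging.getLogger(__name__)

STREAM_NAMES = ("frailty", "covariates", "treatment", "event", "censoring")


class ConfigurationError(ValueError):
    """A generator specification is invalid."""


def _named_streams(seed, stream_seeds: Mapping[str, int] | None = None):
    """One independent Generator per named substream, spawned from the seed."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STREAM_NAMES))
    streams = {name: np.random.default_rng(c) for name, c in zip(STREAM_NAMES, children)}
    if stream_seeds:
        for name, s in stream_seeds.items():
            if name not in streams:
                raise ConfigurationError(f"unknown stream name {name!r}")
            streams[name] = np.random.default_rng(s)
    return streams


# ---------------------------------------------------------------------------
# Piecewise-constant coefficient functions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PiecewiseConstant:
    """Right-continuous step function on ``[breakpoints[0], breakpoints[-1]]``."""

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.breakpoints) != len(self.values) + 1:
            raise ConfigurationError("need len(breakpoints) == len(values) + 1")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ConfigurationError("breakpoints must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("piecewise values must be finite")

    def __call__(self, t):
        idx = np.clip(
            np.searchsorted(self.breakpoints, t, side="right") - 1,
            0, len(self.values) - 1,
        )
        return self.values[idx]

    def interior_knots_within(self, a: float, b: float) -> np.ndarray:
        k = self.breakpoints
        return k[(k > a) & (k < b)]


def as_piecewise(x, domain: tuple[float, float]) -> PiecewiseConstant:
    """Coerce a scalar or PiecewiseConstant to a PiecewiseConstant on domain."""
    if isinstance(x, PiecewiseConstant):
        return x
    return PiecewiseConstant(np.array(domain, dtype=float), np.array([float(x)]))


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConditionalHazardSpec:
    """Conditional hazard of the event given treatment/confounder history and U.

    ``family='additive'``:
        ``lambda(t) = alpha0(t) + sum_j alphaA[j](t) A_{k-j}
        + sum_j alphaL[j](t) L_{k-j} + alphaU(t) U`` with ``k = floor(t)``;
        negative values are floored at 0 at evaluation time.
    ``family='cox'``:
        ``lambda(t) = lambda0(t) * exp(sum_j betaA[j] A_{k-j}
        + sum_j betaL[j] L_{k-j} + betaU U)`` with piecewise-constant baseline.

    Coefficients may be scalars (constant in time) or
    :class:`PiecewiseConstant` on ``[0, K+1]``; per-lag sequences give
    dependence on earlier visits (lag 0 = current value).  Defaults are the
    additive generator ``0.7 - 0.2 A + 0.05 L + 0.05 U`` with K = 4.
    """

    family: str = "additive"
    baseline: object = 0.7
    treatment: Sequence = (-0.2,)
    confounder: Sequence = (0.05,)
    frailty: object = 0.05
    K: int = 4

    def __post_init__(self) -> None:
        if self.family not in ("additive", "cox"):
            raise ConfigurationError(f"unknown hazard family {self.family!r}")
        dom = (0.0, self.K + 1.0)
        self.baseline = as_piecewise(self.baseline, dom)
        self.treatment = tuple(as_piecewise(c, dom) for c in np.atleast_1d(self.treatment))
        self.confounder = tuple(as_piecewise(c, dom) for c in np.atleast_1d(self.confounder))
        self.frailty = as_piecewise(self.frailty, dom)

    @classmethod
    def cox_illustration(cls, K: int = 4) -> "ConditionalHazardSpec":
        """A documented Cox-family illustration (not a published scenario)."""
        return cls(family="cox", baseline=0.7, treatment=(-0.3,),
                   confounder=(0.1,), frailty=0.1, K=K)

    def _interval_grid(self, k: int) -> np.ndarray:
        """Merged coefficient breakpoints within [k, k+1]."""
        a, b = float(k), float(k + 1)
        knots = [f.interior_knots_within(a, b)
                 for f in (self.baseline, self.frailty, *self.treatment, *self.confounder)]
        return np.unique(np.concatenate([[a, b], *knots]))

    def interval_rates(self, k: int, A: np.ndarray, L: np.ndarray, U: np.ndarray):
        """Hazard as a step function on [k, k+1) for each person.

        Returns ``(bounds, rates, n_floored)`` where bounds has shape (P+1,)
        and rates (n, P); additive rates are already floored at 0 and
        ``n_floored`` counts the floored entries.
        """
        bounds = self._interval_grid(k)
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        n = A.shape[0]
        P = len(mids)
        if self.family == "additive":
            lin = np.tile(self.baseline(mids), (n, 1))
        else:
            lin = np.zeros((n, P))
        for j, coef in enumerate(self.treatment):
            if k - j >= 0:
                lin += A[:, k - j, None] * coef(mids)[None, :]
        for j, coef in enumerate(self.confounder):
            if k - j >= 0:
                lin += L[:, k - j, None] * coef(mids)[None, :]
        lin += U[:, None] * self.frailty(mids)[None, :]
        if self.family == "additive":
            n_floored = int(np.count_nonzero(lin < 0))
            rates = np.maximum(lin, 0.0)
        else:
            n_floored = 0
            rates = self.baseline(mids)[None, :] * np.exp(lin)
        return bounds, rates, n_floored


@dataclasses.dataclass
class CovariateProcessSpec:
    """Normal confounder process and frailty distribution.

    ``U ~ N(0, u_sd^2)``; ``L_0 ~ N(l0_u_coef * U, l0_sd^2)``;
    ``L_k ~ N(rho L_{k-1} + theta_a A_{k-1} + theta_k k + theta_u U, l_sd^2)``.
    """

    u_sd: float = 0.1
    l0_u_coef: float = 1.0
    l0_sd: float = 1.0
    rho: float = 0.8
    theta_a: float = -1.0
    theta_k: float = 0.1
    theta_u: float = 1.0
    l_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.u_sd > 0 and self.l0_sd > 0 and self.l_sd > 0):
            raise ConfigurationError("standard deviations must be strictly positive")


@dataclasses.dataclass
class TreatmentAssignmentSpec:
    """Pooled logistic treatment-initiation/continuation model.

    ``logit P(A_k = 1 | past) = gamma0 + gammaL * L_k + gammaA * A_{k-1}``
    (the ``gammaA`` term is absent at k = 0).
    """

    gamma0: float = -2.0
    gammaL: float = 0.5
    gammaA: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.gamma0, self.gammaL, self.gammaA):
            if not math.isfinite(v):
                raise ConfigurationError("treatment-model coefficients must be finite")


@dataclasses.dataclass(frozen=True)
class TreatmentRegime:
    """A fixed treatment vector (a_0, ..., a_K), each entry 0/1."""

    a: tuple

    def __post_init__(self) -> None:
        a = tuple(int(x) for x in self.a)
        if any(x not in (0, 1) for x in a):
            raise ConfigurationError("regime entries must be binary")
        object.__setattr__(self, "a", a)

    @property
    def K(self) -> int:
        return len(self.a) - 1

    @property
    def label(self) -> str:
        return "".join(str(x) for x in self.a)

    @classmethod
    def coerce(cls, x, K: int | None = None) -> "TreatmentRegime":
        if isinstance(x, cls):
            return x
        if isinstance(x, str):
            return cls(tuple(int(c) for c in x))
        return cls(tuple(x))


def never_treated(K: int = 4) -> TreatmentRegime:
    return TreatmentRegime((0,) * (K + 1))


def always_treated(K: int = 4) -> TreatmentRegime:
    return TreatmentRegime((1,) * (K + 1))


def single_visit_regime(m: int, K: int = 4) -> TreatmentRegime:
    """Treated at visit m only."""
    a = [0] * (K + 1)
    a[m] = 1
    return TreatmentRegime(tuple(a))


def all_regimes(K: int = 4) -> list[TreatmentRegime]:
    """All 2^(K+1) static treatment regimes, in binary order."""
    out = []
    for code in range(2 ** (K + 1)):
        bits = tuple((code >> (K - j)) & 1 for j in range(K + 1))
        out.append(TreatmentRegime(bits))
    return out


# ---------------------------------------------------------------------------
# Event-time draws (inverse-transform, exponential within intervals)
# ---------------------------------------------------------------------------

def draw_event_time_constant(hazard: float, interval_length: float, uniform_draw: float) -> float:
    """Offset of the event within an interval under a constant hazard.

    Returns ``T* = -log(V)/hazard``; the event occurs iff the returned offset
    is strictly less than ``interval_length``, otherwise the person survives
    the interval.  A hazard <= 0 is treated as 0 (returns ``inf``: no event).
    """
    if not (0.0 < uniform_draw < 1.0):
        raise ValueError("uniform_draw must lie strictly in (0, 1)")
    if not interval_length > 0:
        raise ValueError("interval_length must be positive")
    if hazard <= 0:
        return math.inf
    return -math.log(uniform_draw) / hazard


def draw_event_time_piecewise(breakpoints, values, uniform_draw: float) -> float:
    """Offset of the event under a piecewise-constant hazard on [0, delta).

    Inverts the piecewise-linear cumulative hazard at ``-log(V)``.  Negative
    step values are floored at 0.  Returns ``inf`` (survives) when the total
    cumulative hazard over the interval is below ``-log(V)``.
    """
    if not (0.0 < uniform_draw < 1.0):
        raise ValueError("uniform_draw must lie strictly in (0, 1)")
    bounds = np.asarray(breakpoints, dtype=float)
    rates = np.maximum(np.asarray(values, dtype=float), 0.0)
    if len(bounds) != len(rates) + 1 or np.any(np.diff(bounds) <= 0):
        raise ValueError("breakpoints must be sorted with one more entry than values")
    out = _draw_piecewise(bounds - bounds[0], rates[None, :], np.array([uniform_draw]))
    return float(out[0])


def _draw_piecewise(bounds: np.ndarray, rates: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Vectorized inverse-transform draw; bounds (P+1,) from 0, rates (n, P)."""
    durations = np.diff(bounds)
    cum = np.cumsum(rates * durations[None, :], axis=1)  # (n, P)
    target = -np.log(V)
    idx = np.sum(cum < target[:, None], axis=1)          # first piece with cum >= target
    out = np.full(len(V), np.inf)
    hit = idx < rates.shape[1]
    if np.any(hit):
        i = idx[hit]
        prev = np.where(i > 0, cum[hit, np.maximum(i - 1, 0)], 0.0)
        r = rates[hit, i]
        out[hit] = bounds[i] + (target[hit] - prev) / r
    return out


# ---------------------------------------------------------------------------
# Cohort simulators
# ---------------------------------------------------------------------------

def _simulate_engine(n, K, hazard, covariates, treatment, streams,
                     fixed_A: np.ndarray | None = None) -> CohortPanel:
    """Shared sequential generator; fixed_A (n, K+1) bypasses the treatment model."""
    cov = covariates
    U = streams["frailty"].normal(0.0, cov.u_sd, size=n)
    L = np.zeros((n, K + 1))
    A = np.zeros((n, K + 1), dtype=np.int8)
    atrisk = np.zeros((n, K + 1), dtype=bool)
    T = np.full(n, np.nan)
    alive = np.ones(n, dtype=bool)
    n_floored = 0
    for k in range(K + 1):
        atrisk[:, k] = alive
        if k == 0:
            mean = cov.l0_u_coef * U
            sd = cov.l0_sd
        else:
            mean = (cov.rho * L[:, k - 1] + cov.theta_a * A[:, k - 1]
                    + cov.theta_k * k + cov.theta_u * U)
            sd = cov.l_sd
        L[:, k] = mean + sd * streams["covariates"].standard_normal(n)
        if fixed_A is not None:
            A[:, k] = fixed_A[:, k]
            streams["treatment"].random(n)  # keep the stream aligned
        else:
            eta = treatment.gamma0 + treatment.gammaL * L[:, k]
            if k > 0:
                eta = eta + treatment.gammaA * A[:, k - 1]
            A[:, k] = streams["treatment"].random(n) < expit(eta)
        V = streams["event"].random(n)
        V = np.clip(V, np.finfo(float).tiny, 1.0 - np.finfo(float).eps)
        bounds, rates, nf = hazard.interval_rates(k, A, L, U)
        n_floored += nf
        offset = _draw_piecewise(bounds - bounds[0], rates, V)
        dies = alive & (offset < 1.0)
        T[dies] = k + offset[dies]
        alive = alive & ~dies
    if n_floored:
        logger.info("floored %d negative hazard evaluations", n_floored)
    C = np.full(n, K + 1.0)
    event = ~np.isnan(T)
    L[~atrisk] = np.nan
    A[~atrisk] = 0
    return CohortPanel(
        ids=np.arange(n), A=A, L=L, atrisk=atrisk, U=U,
        T=T, event=event, C=C,
    )


def simulate_observational(
    n: int,
    K: int = 4,
    hazard: ConditionalHazardSpec | None = None,
    covariates: CovariateProcessSpec | None = None,
    treatment: TreatmentAssignmentSpec | None = None,
    seed=None,
    stream_seeds: Mapping[str, int] | None = None,
) -> CohortPanel:
    """Simulate an observational cohort with time-dependent confounding.

    Defaults reproduce the additive generator with hazard
    ``0.7 - 0.2 A + 0.05 L + 0.05 U``, confounder process
    ``L_k ~ N(0.8 L_{k-1} - A_{k-1} + 0.1 k + U, 1)`` and treatment model
    ``logit P(A_k=1) = -2 + 0.5 L_k + A_{k-1}``, with administrative
    censoring at K + 1 = 5.  Deterministic given the seed.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    hazard = hazard or ConditionalHazardSpec(K=K)
    if hazard.family != "additive":
        raise ConfigurationError("simulate_observational expects an additive hazard; "
                                 "use simulate_conditional_cox for the Cox family")
    covariates = covariates or CovariateProcessSpec()
    treatment = treatment or TreatmentAssignmentSpec()
    streams = _named_streams(seed, stream_seeds)
    return _simulate_engine(n, K, hazard, covariates, treatment, streams)


def simulate_conditional_cox(
    n: int,
    K: int = 4,
    hazard: ConditionalHazardSpec | None = None,
    covariates: CovariateProcessSpec | None = None,
    treatment: TreatmentAssignmentSpec | None = None,
    seed=None,
    stream_seeds: Mapping[str, int] | None = None,
) -> CohortPanel:
    """Observational cohort whose conditional hazard is a Cox model.

    Within a visit interval the hazard is constant given covariates (or
    piecewise-constant for a piecewise baseline), so event times are drawn by
    the same exponential inverse transform.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    hazard = hazard or ConditionalHazardSpec.cox_illustration(K=K)
    if hazard.family != "cox":
        raise ConfigurationError("simulate_conditional_cox requires family='cox'")
    covariates = covariates or CovariateProcessSpec()
    treatment = treatment or TreatmentAssignmentSpec()
    streams = _named_streams(seed, stream_seeds)
    return _simulate_engine(n, K, hazard, covariates, treatment, streams)


def simulate_under_regimes(
    regimes: Sequence,
    m: int,
    hazard: ConditionalHazardSpec | None = None,
    covariates: CovariateProcessSpec | None = None,
    seed=None,
    share_baseline: bool = True,
    K: int = 4,
) -> CohortPanel:
    """Simulate an intervention trial: m persons per fixed treatment regime.

    The treatment-assignment model is bypassed; A_k is set by intervention.
    With ``share_baseline`` (default), the frailty U and the baseline
    confounder L_0 are drawn once per replicate and reused across all regimes,
    so regimes differ only through treatment effects downstream of visit 0.
    The confounder evolution and event generation are identical to the
    observational simulator.  Output persons carry regime labels.
    """
    if len(regimes) == 0:
        raise ConfigurationError("need at least one regime")
    regimes = [TreatmentRegime.coerce(r, K) for r in regimes]
    K = regimes[0].K
    if any(r.K != K for r in regimes):
        raise ConfigurationError("all regimes must have the same length")
    labels = [r.label for r in regimes]
    if len(set(labels)) < len(labels):
        warnings.warn("duplicate regimes supplied", stacklevel=2)
    hazard = hazard or ConditionalHazardSpec(K=K)
    covariates = covariates or CovariateProcessSpec()
    streams = _named_streams(seed)

    shared_U = streams["frailty"].normal(0.0, covariates.u_sd, size=m)
    shared_eps0 = streams["covariates"].standard_normal(m)

    panels = []
    for regime in regimes:
        # per-regime draws come from the shared streams in regime order
        if share_baseline:
            U = shared_U
            eps0 = shared_eps0
        else:
            U = streams["frailty"].normal(0.0, covariates.u_sd, size=m)
            eps0 = streams["covariates"].standard_normal(m)
        panel = _simulate_regime_arm(m, K, regime, hazard, covariates, U, eps0, streams)
        panel.regime = np.repeat(regime.label, m)
        panels.append(panel)
    return _concat_panels(panels)


def _simulate_regime_arm(m, K, regime, hazard, covariates, U, eps0, streams) -> CohortPanel:
    cov = covariates
    A = np.tile(np.asarray(regime.a, dtype=np.int8), (m, 1))
    L = np.zeros((m, K + 1))
    atrisk = np.zeros((m, K + 1), dtype=bool)
    T = np.full(m, np.nan)
    alive = np.ones(m, dtype=bool)
    for k in range(K + 1):
        atrisk[:, k] = alive
        if k == 0:
            L[:, 0] = cov.l0_u_coef * U + cov.l0_sd * eps0
        else:
            mean = (cov.rho * L[:, k - 1] + cov.theta_a * A[:, k - 1]
                    + cov.theta_k * k + cov.theta_u * U)
            L[:, k] = mean + cov.l_sd * streams["covariates"].standard_normal(m)
        V = streams["event"].random(m)
        V = np.clip(V, np.finfo(float).tiny, 1.0 - np.finfo(float).eps)
        bounds, rates, _ = hazard.interval_rates(k, A, L, U)
        offset = _draw_piecewise(bounds - bounds[0], rates, V)
        dies = alive & (offset < 1.0)
        T[dies] = k + offset[dies]
        alive = alive & ~dies
    C = np.full(m, K + 1.0)
    L[~atrisk] = np.nan
    A_out = A.copy()
    A_out[~atrisk] = 0
    return CohortPanel(ids=np.arange(m), A=A_out, L=L, atrisk=atrisk, U=U,
                       T=T, event=~np.isnan(T), C=C)


def _concat_panels(panels: list[CohortPanel]) -> CohortPanel:
    offset = 0
    ids = []
    for p in panels:
        ids.append(p.ids + offset)
        offset += p.n
    return CohortPanel(
        ids=np.concatenate(ids),
        A=np.concatenate([p.A for p in panels]),
        L=np.concatenate([p.L for p in panels]),
        atrisk=np.concatenate([p.atrisk for p in panels]),
        U=np.concatenate([p.U for p in panels]),
        T=np.concatenate([p.T for p in panels]),
        event=np.concatenate([p.event for p in panels]),
        C=np.concatenate([p.C for p in panels]),
        regime=np.concatenate([p.regime for p in panels]),
    )


# ---------------------------------------------------------------------------
# Optional non-administrative censoring
# ---------------------------------------------------------------------------

def apply_random_censoring(
    panel: CohortPanel,
    censoring: float | Callable,
    seed=None,
) -> CohortPanel:
    """Overlay random censoring with a per-interval censoring hazard.

    ``censoring`` is either a constant hazard or a callable
    ``c(k, A_k, L_k) -> array`` giving the censoring hazard within
    ``[k, k+1)``; a censoring time is drawn per interval by exponential
    inverse transform and ``C`` becomes the minimum of the administrative
    time and the first drawn censoring time.  The event indicator and at-risk
    pattern are updated; censoring times are strictly positive.
    """
    rng = _named_streams(seed)["censoring"]
    K = panel.K
    n = panel.n
    C_new = panel.C.copy()
    censored_at = np.full(n, np.inf)
    for k in range(K + 1):
        V = np.clip(rng.random(n), np.finfo(float).tiny, 1 - np.finfo(float).eps)
        if callable(censoring):
            rate = np.asarray(censoring(k, panel.A[:, k], panel.L[:, k]), dtype=float)
            rate = np.broadcast_to(rate, (n,)).copy()
            rate[~panel.atrisk[:, k]] = 0.0
        else:
            rate = np.full(n, float(censoring))
        rate = np.maximum(rate, 0.0)
        with np.errstate(divide="ignore"):
            offset = np.where(rate > 0, -np.log(V) / rate, np.inf)
        hit = panel.atrisk[:, k] & np.isinf(censored_at) & (offset < 1.0)
        censored_at[hit] = k + offset[hit]
    C_new = np.minimum(C_new, censored_at)
    t_ev = np.where(np.isnan(panel.T), np.inf, panel.T)
    event = t_ev <= C_new
    fu = np.minimum(t_ev, C_new)
    atrisk = fu[:, None] > np.arange(K + 1)[None, :]
    L = panel.L.copy()
    A = panel.A.copy()
    L[~atrisk] = np.nan
    A[~atrisk] = 0
    return CohortPanel(ids=panel.ids, A=A, L=L, atrisk=atrisk, U=panel.U,
                       T=panel.T, event=event, C=C_new, regime=panel.regime)


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def specs_from_config(cfg: Mapping) -> dict:
    """Build generator specs from a config mapping.

    Recognized keys: ``n``, ``K``, ``seed``, ``hazard.{family, alpha0, alphaA,
    alphaL, alphaU}``, ``covariates.{u_sd, l0_u_coef, l0_sd, rho, theta_a,
    theta_k, theta_u, l_sd}``, ``treatment.{gamma0, gammaL, gammaA}``,
    ``censoring.rate``.
    """
    K = int(cfg.get("K", 4))
    h = dict(cfg.get("hazard", {}) or {})
    hazard = ConditionalHazardSpec(
        family=h.get("family", "additive"),
        baseline=h.get("alpha0", h.get("lambda0", 0.7)),
        treatment=h.get("alphaA", h.get("betaA", (-0.2,))),
        confounder=h.get("alphaL", h.get("betaL", (0.05,))),
        frailty=h.get("alphaU", h.get("betaU", 0.05)),
        K=K,
    )
    c = dict(cfg.get("covariates", {}) or {})
    covariates = CovariateProcessSpec(**c)
    t = dict(cfg.get("treatment", {}) or {})
    treatment = TreatmentAssignmentSpec(**t)
    out = {
        "n": int(cfg.get("n", 5000)),
        "K": K,
        "seed": cfg.get("seed"),
        "hazard": hazard,
        "covariates": covariates,
        "treatment": treatment,
    }
    if "censoring" in cfg and cfg["censoring"]:
        out["censoring"] = float(cfg["censoring"].get("rate", 0.0))
    return out
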