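"""Weighted Aalen least-squares fitting of additive-hazard MSMs.

The marginal structural model is the additive hazard
``lambda(t; a) = alpha~_0(t) + g(a_hist(t); alpha~_A(t))`` where ``g`` is one
of these treatment-history summaries:

* ``intercept``: no treatment terms (the fit reduces to Nelson-Aalen)
* ``current``:  ``alpha~_A(t) * a_{floor(t)}``
* ``duration``: ``alpha~_A(t) * sum_{j <= floor(t)} a_j``
* ``history``:  ``sum_j alpha~_Aj(t) * a_{floor(t)-j}`` (main effect per lag)

Estimation is by the classical Aalen least-squares increment: at each distinct
event time ``t_e`` the cumulative-coefficient increment is
``(X' W X)^{-1} X' W dN`` over the risk set at ``t_e-``, where X stacks the
design vectors, W the (IPTW) weights and dN the event indicators.  Cumulative
coefficients ``B(t)`` are the running sums, right-continuous step functions
with ``B(0) = 0``; for the history form the fit runs interval by interval with
design dimension ``k + 2`` on ``[k, k+1)``, so the lag-j coefficient is
identically zero on ``[0, j]``.

Counterfactual survival curves follow from the cumulative coefficients via
``S(t; a) = exp(-B_0(t) - integral of g along the regime)``; additive fits can
produce values above 1 and these are not clamped by default.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .trajectories import CountingProcessData

logger = logging.getLogger(__name__)

MSM_FORMS = ("intercept", "current", "duration", "history")


class SingularDesignError(np.linalg.LinAlgError):
    """Raised in strict mode when X'WX is singular at an event time."""


# ---------------------------------------------------------------------------
# MSM design
# ---------------------------------------------------------------------------

class MSMDesign:
    """Maps (treatment history, time) to the MSM design vector.

    The Cox MSM form is intentionally not supported: requesting ``form='cox'``
    fails loudly rather than silently fitting the wrong model.
    """

    def __init__(self, form: str, K: int):
        if form == "cox":
            raise NotImplementedError(
                "Cox MSM fitting is not implemented; use an additive form "
                f"from {MSM_FORMS}"
            )
        if form not in MSM_FORMS:
            raise ValueError(f"unknown MSM form {form!r}; choose from {MSM_FORMS}")
        self.form = form
        self.K = int(K)

    @property
    def ncols(self) -> int:
        if self.form == "history":
            return self.K + 2
        return 1 if self.form == "intercept" else 2

    @property
    def column_names(self) -> list[str]:
        if self.form == "history":
            return ["alpha0"] + [f"alphaA{j}" for j in range(self.K + 1)]
        if self.form == "intercept":
            return ["alpha0"]
        return ["alpha0", {"current": "alphaA_current", "duration": "alphaA_duration"}[self.form]]

    def active_columns(self, k: int) -> np.ndarray:
        """Design columns identified on interval [k, k+1)."""
        if self.form == "history":
            return np.arange(k + 2)
        return np.arange(self.ncols)

    def matrix_at(self, A: np.ndarray, k: int, rows=None) -> np.ndarray:
        """Design rows for interval [k, k+1) from the treatment matrix A (n, K+1)."""
        A = np.asarray(A)
        if rows is None:
            rows = slice(None)
        Ak = A[rows, : k + 1]
        n = Ak.shape[0]
        X = np.zeros((n, self.ncols))
        X[:, 0] = 1.0
        if self.form == "current":
            X[:, 1] = Ak[:, k]
        elif self.form == "duration":
            X[:, 1] = Ak.sum(axis=1)
        elif self.form == "history":
            for j in range(k + 1):
                X[:, 1 + j] = Ak[:, k - j]
        return X

    def regime_rows(self, regime) -> np.ndarray:
        """(K+1, ncols) design vectors of a fixed regime, one row per interval."""
        a = np.asarray(getattr(regime, "a", regime), dtype=float)
        if a.shape != (self.K + 1,):
            raise ValueError(f"regime must have length K+1 = {self.K + 1}")
        return np.vstack([self.matrix_at(a[None, :], k)[0] for k in range(self.K + 1)])


# ---------------------------------------------------------------------------
# Cumulative coefficients
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CumulativeCoefficients:
    """Right-continuous step functions of cumulative MSM coefficients.

    ``values[t_idx, col]`` holds ``B(t)`` evaluated just after ``times[t_idx]``;
    ``B(0) = 0`` and steps occur only at the stored times.
    """

    times: np.ndarray      # increasing, in (0, K+1]
    values: np.ndarray     # (T, p) cumulative coefficient values
    design: MSMDesign
    K: int

    @property
    def columns(self) -> list[str]:
        return self.design.column_names

    def at(self, times) -> np.ndarray:
        """Evaluate B(t) (right-continuous) at the given times -> (len(times), p)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t < 0) or np.any(t > self.K + 1):
            raise ValueError(f"evaluation times must lie in [0, {self.K + 1}]")
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.zeros((len(t), self.values.shape[1]))
        has = idx >= 0
        out[has] = self.values[idx[has]]
        return out

    def increments(self) -> np.ndarray:
        """Per-event-time increments dB, same shape as ``values``."""
        return np.diff(self.values, axis=0, prepend=np.zeros((1, self.values.shape[1])))


def cumulative_coefficients_at(cc: CumulativeCoefficients, times) -> np.ndarray:
    """Module-level alias for :meth:`CumulativeCoefficients.at`."""
    return cc.at(times)


# ---------------------------------------------------------------------------
# Weighted Aalen least-squares fit
# ---------------------------------------------------------------------------

def fit_weighted_aalen(
    data: CountingProcessData,
    strict_singular: bool = False,
) -> CumulativeCoefficients:
    """Fit the (weighted) additive-hazard MSM on counting-process data.

    At each distinct event time the increment ``(X'WX)^{-1} X'W dN`` is
    computed over the risk set ``t_start < t_e <= t_stop`` (left-limit
    convention); tied event times are processed as a single time with a
    multi-event dN.  A singular ``X'WX`` falls back to the Moore-Penrose
    pseudo-inverse with a logged warning, or raises
    :class:`SingularDesignError` when ``strict_singular`` is set.

    With an intercept-only design and unit weights this reduces to the
    Nelson-Aalen estimator.
    """
    design = data.msm_design
    p = design.ncols
    kvals = data.tstart.astype(int)
    cum = np.zeros(p)
    all_times: list[np.ndarray] = []
    all_values: list[np.ndarray] = []
    for k in np.unique(kvals):
        rows = kvals == k
        active = design.active_columns(k)
        X = data.design[rows][:, active]
        w = data.weight[rows]
        stop = data.tstop[rows]
        ev = data.event[rows]
        if not np.any(ev):
            continue
        uniq_t, inv = np.unique(stop[ev], return_inverse=True)
        E = len(uniq_t)
        # Designs are functions of binary treatment history, so rows fall in
        # few distinct groups; risk-set cross-products come from group sums.
        Xg, gidx = np.unique(X, axis=0, return_inverse=True)
        G = Xg.shape[0]
        W = np.empty((E, G))
        for g in range(G):
            sel = gidx == g
            order = np.argsort(stop[sel], kind="stable")
            ss = stop[sel][order]
            cw = np.concatenate([[0.0], np.cumsum(w[sel][order])])
            pos = np.searchsorted(ss, uniq_t, side="left")  # stops < t_e leave the risk set
            W[:, g] = cw[-1] - cw[pos]
        S = np.einsum("eg,gi,gj->eij", W, Xg, Xg)
        rhs = np.zeros((E, len(active)))
        np.add.at(rhs, inv, w[ev, None] * X[ev])
        dB = _solve_increments(S, rhs, uniq_t, [design.column_names[c] for c in active],
                               strict_singular)
        vals = np.tile(cum, (E, 1))
        vals[:, active] += np.cumsum(dB, axis=0)
        all_times.append(uniq_t)
        all_values.append(vals)
        cum = vals[-1].copy()
    if not all_times:
        times = np.empty(0)
        values = np.empty((0, p))
    else:
        times = np.concatenate(all_times)
        values = np.vstack(all_values)
    return CumulativeCoefficients(times=times, values=values, design=design, K=data.K)


def _solve_increments(S, rhs, times, colnames, strict):
    try:
        return np.linalg.solve(S, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        pass
    out = np.empty_like(rhs)
    for e in range(S.shape[0]):
        try:
            out[e] = np.linalg.solve(S[e], rhs[e])
        except np.linalg.LinAlgError:
            if strict:
                col = _deficient_column(S[e], colnames)
                raise SingularDesignError(
                    f"singular design at event time {times[e]:.6g} (column {col})"
                ) from None
            logger.warning(
                "singular design at event time %.6g; using pseudo-inverse", times[e]
            )
            out[e] = np.linalg.pinv(S[e]) @ rhs[e]
    return out


def _deficient_column(S, colnames):
    _, _, vt = np.linalg.svd(S)
    return colnames[int(np.argmax(np.abs(vt[-1])))]


# ---------------------------------------------------------------------------
# Survival transform
# ---------------------------------------------------------------------------

def survival_from_cumcoef(
    cc: CumulativeCoefficients,
    regime,
    times,
    clamp: bool = False,
) -> np.ndarray:
    """Counterfactual survival under a fixed regime from cumulative coefficients.

    ``S(t) = exp(-sum over event times t_e <= t of x_k(a)' dB(t_e))`` where
    ``x_k(a)`` is the regime's design vector on the interval containing
    ``t_e``.  Values above 1 are possible for additive fits and are only
    clamped to [0, 1] when ``clamp`` is set.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0) or np.any(t > cc.K + 1):
        raise ValueError(f"times must lie in [0, {cc.K + 1}]")
    if len(cc.times) == 0:
        out = np.ones(len(t))
        return out
    reg = cc.design.regime_rows(regime)          # (K+1, p)
    interval = np.ceil(cc.times).astype(int) - 1  # event in (k, k+1] -> k
    interval = np.clip(interval, 0, cc.K)
    dB = cc.increments()
    contrib = np.einsum("tp,tp->t", dB, reg[interval])
    cumulative = np.cumsum(contrib)
    idx = np.searchsorted(cc.times, t, side="right") - 1
    neglog = np.where(idx >= 0, cumulative[np.maximum(idx, 0)], 0.0)
    S = np.exp(-neglog)
    if clamp:
        S = np.clip(S, 0.0, 1.0)
    return S
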