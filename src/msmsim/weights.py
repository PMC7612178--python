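"""Stabilized inverse-probability-of-treatment weights.

The stabilized weight at visit k is the cumulative product

    SW_k = prod_{j=0..k} P_num(A_j | past) / P_den(A_j | past)

where both probabilities are evaluated at the treatment actually received.
The numerator model conditions on previous treatment only (intercept-only at
visit 0, where no previous treatment exists) and the denominator additionally
on the current confounder:

    numerator:    logit P(A_k = 1 | A_{k-1}, T >= k) = gamma0 + gammaA A_{k-1}
    denominator:  logit P(A_k = 1 | A_{k-1}, L_k, T >= k)
                      = gamma0 + gammaA A_{k-1} + gammaL L_k

Both are fitted by pooled maximum-likelihood logistic regression over visits
k = 1..K, with a separate pair of fits at k = 0.  Weights are constant within
each interval [k, k+1) and are applied to all counting-process rows there.
No truncation is applied by default; an optional symmetric percentile
truncation is available and logged.

Only the observed data (A, L) are used -- never the frailty U.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .trajectories import CohortPanel

logger = logging.getLogger(__name__)

_ALLOWED_PREDICTORS = ("prev_A", "L")


class EstimationError(RuntimeError):
    """A propensity model failed to fit (separation or non-convergence)."""


class PositivityError(ValueError):
    """An observed treatment value has estimated probability zero."""


@dataclasses.dataclass
class WeightModelSpec:
    """Predictor sets for the numerator and denominator treatment models.

    Predictors are drawn from ``{"prev_A", "L"}``; the numerator set must be
    a subset of the denominator set.  At visit 0 the ``prev_A`` term is
    dropped (no previous treatment exists), so the default numerator is
    intercept-only there.
    """

    numerator: tuple = ("prev_A",)
    denominator: tuple = ("prev_A", "L")

    def __post_init__(self) -> None:
        self.numerator = tuple(self.numerator)
        self.denominator = tuple(self.denominator)
        for p in self.numerator + self.denominator:
            if p not in _ALLOWED_PREDICTORS:
                raise ValueError(f"unknown predictor {p!r}; allowed: {_ALLOWED_PREDICTORS}")
        if not set(self.numerator) <= set(self.denominator):
            raise ValueError("numerator predictors must be a subset of the denominator's")


@dataclasses.dataclass
class LogisticFit:
    """Coefficients of one pooled logistic model, keyed by predictor name."""

    name: str
    params: dict        # e.g. {"const": -2.0, "prev_A": 1.0, "L": 0.5}
    converged: bool
    llf: float
    bse: dict

    def probability(self, features: dict) -> np.ndarray:
        """P(A = 1) given feature arrays keyed like ``params``."""
        keys = [k for k in self.params if k != "const"]
        n = len(np.asarray(next(iter(features.values())))) if features else 1
        eta = np.full(n, self.params["const"])
        for k in keys:
            eta = eta + self.params[k] * np.asarray(features[k], dtype=float)
        return expit(eta)


@dataclasses.dataclass
class TreatmentModelFits:
    """The four fitted propensity models (visit-0 and pooled later-visit pairs)."""

    visit0_num: LogisticFit
    visit0_den: LogisticFit
    later_num: LogisticFit
    later_den: LogisticFit
    spec: WeightModelSpec


def _fit_logit(y: np.ndarray, X: pd.DataFrame, name: str) -> LogisticFit:
    import warnings

    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=100)
    except PerfectSeparationWarning as exc:
        raise EstimationError(f"perfect separation in model {name!r}") from exc
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise EstimationError(f"logistic fit failed for model {name!r}: {exc}") from exc
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged or not np.all(np.isfinite(res.params)):
        raise EstimationError(f"logistic fit did not converge for model {name!r}")
    # separation shows up as fitted probabilities of exactly 0/1
    fitted = res.predict(X)
    if np.any(fitted <= 0) or np.any(fitted >= 1):
        raise EstimationError(f"perfect separation detected in model {name!r}")
    return LogisticFit(
        name=name,
        params=dict(res.params),
        converged=converged,
        llf=float(res.llf),
        bse=dict(res.bse),
    )


def _design(df: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(df))})
    for p in predictors:
        X[p] = df[p].to_numpy()
    return X


def fit_treatment_models(
    panel: CohortPanel,
    spec: WeightModelSpec | None = None,
) -> TreatmentModelFits:
    """Fit the numerator and denominator propensity models.

    Person-visits at risk are pooled over k = 1..K for one pair of fits (the
    printed single-coefficient model forms hold across visits); visit 0 gets
    its own pair, with the ``prev_A`` predictor dropped.
    """
    spec = spec or WeightModelSpec()
    K = panel.K
    i, k = np.nonzero(panel.atrisk)
    df = pd.DataFrame(
        {
            "visit": k,
            "A": panel.A[i, k].astype(float),
            "L": panel.L[i, k],
            "prev_A": np.where(k > 0, panel.A[i, np.maximum(k - 1, 0)], 0).astype(float),
        }
    )
    at0 = df[df["visit"] == 0]
    later = df[df["visit"] > 0]
    drop0 = lambda preds: tuple(p for p in preds if p != "prev_A")
    fits = TreatmentModelFits(
        visit0_num=_fit_logit(at0["A"].to_numpy(), _design(at0, drop0(spec.numerator)),
                              "numerator (visit 0)"),
        visit0_den=_fit_logit(at0["A"].to_numpy(), _design(at0, drop0(spec.denominator)),
                              "denominator (visit 0)"),
        later_num=_fit_logit(later["A"].to_numpy(), _design(later, spec.numerator),
                             "numerator (visits 1..K)"),
        later_den=_fit_logit(later["A"].to_numpy(), _design(later, spec.denominator),
                             "denominator (visits 1..K)"),
        spec=spec,
    )
    logger.debug(
        "propensity fits: llf num=%.2f den=%.2f (later visits)",
        fits.later_num.llf, fits.later_den.llf,
    )
    return fits


@dataclasses.dataclass
class StabilizedWeights:
    """Cumulative stabilized weights per person-visit.

    ``sw[i, k]`` applies to all counting-process rows of person i in
    ``[k, k+1)``; NaN where the person is not at risk.  The visit-k ratio
    ``sw[:, k] / sw[:, k-1]`` equals the single-visit probability ratio
    exactly.
    """

    ids: np.ndarray
    sw: np.ndarray       # (n, K+1)
    p_num: np.ndarray    # (n, K+1) probability of the observed treatment
    p_den: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n, kp1 = self.sw.shape
        i, k = np.nonzero(~np.isnan(self.sw))
        return pd.DataFrame(
            {"id": self.ids[i], "visit": k, "p_num": self.p_num[i, k],
             "p_den": self.p_den[i, k], "sw": self.sw[i, k]}
        )


def compute_stabilized_weights(
    panel: CohortPanel,
    fits: TreatmentModelFits,
    truncate_percentile: float | None = None,
) -> StabilizedWeights:
    """Cumulative stabilized weights SW_k from fitted propensity models.

    The probability of the *observed* treatment is used (p if A_k = 1, 1 - p
    otherwise).  A denominator probability of zero raises
    :class:`PositivityError` naming the person and visit.  Optional symmetric
    percentile truncation (e.g. 1 -> clip at the 1st/99th percentiles) is off
    by default and logged when used.
    """
    K = panel.K
    n = panel.n
    p_num = np.full((n, K + 1), np.nan)
    p_den = np.full((n, K + 1), np.nan)
    for k in range(K + 1):
        at = panel.atrisk[:, k]
        if not np.any(at):
            continue
        feats = {
            "L": panel.L[at, k],
            "prev_A": panel.A[at, k - 1].astype(float) if k > 0 else np.zeros(at.sum()),
        }
        num_fit = fits.visit0_num if k == 0 else fits.later_num
        den_fit = fits.visit0_den if k == 0 else fits.later_den
        p1_num = num_fit.probability({key: feats[key] for key in num_fit.params if key != "const"})
        p1_den = den_fit.probability({key: feats[key] for key in den_fit.params if key != "const"})
        a = panel.A[at, k]
        p_num[at, k] = np.where(a == 1, p1_num, 1.0 - p1_num)
        p_den[at, k] = np.where(a == 1, p1_den, 1.0 - p1_den)
    bad = np.argwhere(p_den == 0)
    if len(bad):
        i, k = bad[0]
        raise PositivityError(
            f"estimated probability of observed treatment is 0 for person "
            f"{panel.ids[i]} at visit {k}"
        )
    ratio = p_num / p_den
    sw = np.where(panel.atrisk, np.nancumprod(np.where(panel.atrisk, ratio, 1.0), axis=1), np.nan)
    if truncate_percentile is not None:
        vals = sw[~np.isnan(sw)]
        lo, hi = np.percentile(vals, [truncate_percentile, 100 - truncate_percentile])
        logger.info("truncating stabilized weights to [%.4g, %.4g]", lo, hi)
        sw = np.clip(sw, lo, hi)
    return StabilizedWeights(ids=panel.ids, sw=sw, p_num=p_num, p_den=p_den)


# ---------------------------------------------------------------------------
# Optional inverse-probability-of-censoring weights
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CensoringModelFits:
    """Pooled logistic models for remaining uncensored through an interval."""

    num: LogisticFit
    den: LogisticFit


def fit_censoring_models(panel: CohortPanel) -> CensoringModelFits:
    """Fit discrete-time models for non-administrative censoring.

    Outcome: the person remains uncensored through interval [k, k+1) (or has
    an event there first).  The denominator conditions on current (A_k, L_k);
    the numerator is intercept-only, giving stabilized censoring weights.
    """
    K = panel.K
    i, k = np.nonzero(panel.atrisk)
    C = panel.C[i]
    cens_in_k = (C > k) & (C <= k + 1) & (C < K + 1) & ~panel.event[i]
    y = (~cens_in_k).astype(float)
    df = pd.DataFrame({"A": panel.A[i, k].astype(float), "L": panel.L[i, k]})
    num = _fit_logit(y, _design(df, ()), "censoring numerator")
    den = _fit_logit(y, _design(df, ("A", "L")), "censoring denominator")
    return CensoringModelFits(num=num, den=den)


def compute_censoring_weights(panel: CohortPanel, fits: CensoringModelFits) -> np.ndarray:
    """Cumulative stabilized censoring weights per person-visit (n, K+1).

    Returns all ones when the panel has no non-administrative censoring.
    Combined IPTW x IPCW weights are the elementwise product with ``sw``.
    """
    K = panel.K
    n = panel.n
    if np.all(panel.C >= K + 1):
        return np.where(panel.atrisk, 1.0, np.nan)
    cw = np.full((n, K + 1), np.nan)
    for k in range(K + 1):
        at = panel.atrisk[:, k]
        if not np.any(at):
            continue
        feats = {"A": panel.A[at, k].astype(float), "L": panel.L[at, k]}
        p_num = fits.num.probability({key: feats[key] for key in fits.num.params if key != "const"})
        p_den = fits.den.probability({key: feats[key] for key in fits.den.params if key != "const"})
        if np.any(p_den == 0):
            raise PositivityError(f"zero probability of remaining uncensored at visit {k}")
        cw[at, k] = p_num / p_den
    return np.where(panel.atrisk, np.nancumprod(np.where(panel.atrisk, cw, 1.0), axis=1), np.nan)
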