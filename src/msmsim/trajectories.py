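"""Longitudinal survival-data containers, counting-process expansion, and CSV I/O.

The central container is :class:`CohortPanel`: person-visit records of a binary
treatment ``A_k`` and a continuous confounder ``L_k`` observed at regular visits
``k = 0..K``, together with a per-person frailty ``U`` (unmeasured in the
"observed" view), an event time ``T`` in continuous time, and a censoring time
``C`` (administrative default ``K + 1``).

For hazard regression the panel is expanded into the standard start-stop
(counting-process) format: one row per person per at-risk interval
``[k, min(k + 1, T, C))`` carrying the MSM design vector evaluated from the
treatment history at visit ``k``.

Conventions
-----------
* Visits sit at the integers ``0..K``; intervals are half-open ``[k, k + 1)``.
* A person is at risk at visit ``k`` iff ``min(T, C) > k``; visit records exist
  exactly for at-risk visits.
* The event indicator is 1 iff ``T <= C``; for persons without an event ``T``
  is stored as NaN.
* CSV files are comma-separated, UTF-8, header row, '.' decimal, floats with
  10 significant digits.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Long-format column order for panel CSV files.
PANEL_COLUMNS = ["id", "visit", "A", "L", "atrisk", "U", "T", "event", "C"]

#: Columns that must be present when reading a panel (U may be withheld).
REQUIRED_PANEL_COLUMNS = ["id", "visit", "A", "L", "atrisk", "T", "event", "C"]

FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A CSV file does not have the declared long-format columns."""


class PanelValidationError(ValueError):
    """A panel violates a structural invariant (e.g. non-consecutive visits)."""


# ---------------------------------------------------------------------------
# CohortPanel
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CohortPanel:
    """Wide-format longitudinal cohort.

    Arrays are aligned on persons (axis 0) and visits (axis 1, length K+1).
    ``A`` and ``L`` are meaningful only where ``atrisk`` is True.  ``U`` is
    ``None`` in observed views.  ``regime`` optionally labels each person with
    the treatment regime they were assigned to (intervention trials).
    """

    ids: np.ndarray          # (n,) int
    A: np.ndarray            # (n, K+1) int, 0/1
    L: np.ndarray            # (n, K+1) float, NaN off risk
    atrisk: np.ndarray       # (n, K+1) bool
    U: np.ndarray | None     # (n,) float or None (observed view)
    T: np.ndarray            # (n,) float, NaN if no event
    event: np.ndarray        # (n,) bool
    C: np.ndarray            # (n,) float
    regime: np.ndarray | None = None   # (n,) str labels, optional

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.A = np.asarray(self.A, dtype=np.int8)
        self.L = np.asarray(self.L, dtype=float)
        self.atrisk = np.asarray(self.atrisk, dtype=bool)
        self.T = np.asarray(self.T, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        self.C = np.asarray(self.C, dtype=float)
        if self.U is not None:
            self.U = np.asarray(self.U, dtype=float)

    # -- basic properties ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def K(self) -> int:
        return self.A.shape[1] - 1

    def followup(self) -> np.ndarray:
        """min(T, C) per person (observed follow-up time)."""
        t = np.where(np.isnan(self.T), np.inf, self.T)
        return np.minimum(t, self.C)

    # -- views ----------------------------------------------------------------

    def observed(self) -> "CohortPanel":
        """Return the observed-data view: the frailty U is withheld.

        Estimation modules (weights, MSM fitting) must work from this view;
        only the simulator and the g-formula oracle may read U.
        """
        return dataclasses.replace(self, U=None)

    # -- validation -----------------------------------------------------------

    def validate(self) -> "CohortPanel":
        """Check structural invariants; raise PanelValidationError on failure."""
        n, kp1 = self.A.shape
        if self.L.shape != (n, kp1) or self.atrisk.shape != (n, kp1):
            raise PanelValidationError("A, L, atrisk must share shape (n, K+1)")
        fu = self.followup()
        expect = fu[:, None] > np.arange(kp1)[None, :]
        if not np.array_equal(self.atrisk, expect):
            bad = int(self.ids[np.argmax((self.atrisk != expect).any(axis=1))])
            raise PanelValidationError(
                f"at-risk pattern inconsistent with min(T, C) for person {bad}"
            )
        has_t = ~np.isnan(self.T)
        if np.any(self.event & ~has_t):
            raise PanelValidationError("event indicator set without an event time")
        if np.any(self.event != (has_t & (np.where(has_t, self.T, np.inf) <= self.C))):
            raise PanelValidationError("event indicator must be 1 iff T <= C")
        if np.any(self.T[has_t] <= 0) or np.any(self.C <= 0):
            raise PanelValidationError("event and censoring times must be positive")
        if np.any(np.isnan(self.L[self.atrisk])):
            raise PanelValidationError("L missing at an at-risk visit")
        return self

    # -- long-format conversion ------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long person-visit DataFrame with one row per at-risk visit."""
        i, k = np.nonzero(self.atrisk)
        df = pd.DataFrame(
            {
                "id": self.ids[i],
                "visit": k,
                "A": self.A[i, k],
                "L": self.L[i, k],
                "atrisk": np.ones(len(i), dtype=int),
                "U": self.U[i] if self.U is not None else np.nan,
                "T": self.T[i],
                "event": self.event[i].astype(int),
                "C": self.C[i],
            }
        )
        if self.regime is not None:
            df["regime"] = self.regime[i]
        return df

    @classmethod
    def from_long(cls, df: pd.DataFrame, K: int | None = None) -> "CohortPanel":
        missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"panel file missing required column(s): {missing}")
        df = df.sort_values(["id", "visit"], kind="stable")
        ids, start = np.unique(df["id"].to_numpy(), return_index=True)
        order = np.argsort(start)
        ids = ids[order]
        counts = df.groupby("id", sort=False)["visit"].agg(["min", "max", "count"])
        counts = counts.loc[ids]
        bad = counts.index[(counts["min"] != 0) | (counts["count"] != counts["max"] + 1)]
        if len(bad):
            raise PanelValidationError(
                f"visits must be consecutive integers starting at 0; person {bad[0]}"
            )
        if K is None:
            K = int(df["visit"].max())
        n = len(ids)
        A = np.zeros((n, K + 1), dtype=np.int8)
        L = np.full((n, K + 1), np.nan)
        atrisk = np.zeros((n, K + 1), dtype=bool)
        idx = {pid: j for j, pid in enumerate(ids)}
        rows = df["id"].map(idx).to_numpy()
        visits = df["visit"].to_numpy(dtype=int)
        A[rows, visits] = df["A"].to_numpy()
        L[rows, visits] = df["L"].to_numpy()
        atrisk[rows, visits] = True
        per = df.drop_duplicates("id").set_index("id").loc[ids]
        U = per["U"].to_numpy(dtype=float) if "U" in df.columns else None
        if U is not None and np.all(np.isnan(U)):
            U = None
        regime = per["regime"].to_numpy() if "regime" in df.columns else None
        return cls(
            ids=ids,
            A=A,
            L=L,
            atrisk=atrisk,
            U=U,
            T=per["T"].to_numpy(dtype=float),
            event=per["event"].to_numpy(dtype=bool),
            C=per["C"].to_numpy(dtype=float),
            regime=regime,
        )


def read_panel(path) -> CohortPanel:
    """Read a long-format panel CSV and validate it."""
    df = pd.read_csv(path)
    panel = CohortPanel.from_long(df)
    return panel.validate()


def write_panel(panel: CohortPanel, path) -> None:
    """Write a panel to long-format CSV (10 significant digits)."""
    panel.validate().to_long().to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Counting-process expansion
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CountingProcessData:
    """Start-stop rows with MSM design columns and weights.

    Rows for one person are disjoint and contiguous from 0 to ``min(T, C)``;
    interval boundaries occur only at visit times or at ``min(T, C)``; the
    event flag is set on the terminal row iff ``T <= C``.
    """

    ids: np.ndarray        # (R,) person id per row
    tstart: np.ndarray     # (R,) = visit k
    tstop: np.ndarray      # (R,) min(k+1, T, C)
    event: np.ndarray      # (R,) bool
    design: np.ndarray     # (R, p) design vector, constant on the interval
    weight: np.ndarray     # (R,) positive
    msm_design: object     # the MSMDesign that produced the columns
    K: int

    @property
    def columns(self) -> list[str]:
        return list(self.msm_design.column_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"id": self.ids, "tstart": self.tstart, "tstop": self.tstop,
             "event": self.event.astype(int)}
        )
        for j, name in enumerate(self.columns):
            df[f"d{j}"] = self.design[:, j]
        df["weight"] = self.weight
        return df


def write_counting_process(data: CountingProcessData, path) -> None:
    data.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def expand_to_counting_process(
    panel: CohortPanel,
    design,
    weights=None,
) -> CountingProcessData:
    """Expand a panel into weighted start-stop rows under an MSM design.

    Parameters
    ----------
    panel : CohortPanel
    design : MSMDesign
        Maps treatment history at visit k to the design vector (see
        :mod:`msmsim.additive_msm`).
    weights : StabilizedWeights, (n, K+1) array, or None
        Per person-visit weights, constant within ``[k, k+1)``; default 1.
    """
    panel.validate()
    K = panel.K
    sw = None
    if weights is not None:
        sw = getattr(weights, "sw", weights)
        sw = np.asarray(sw, dtype=float)
        if sw.shape != (panel.n, K + 1):
            raise ValueError("weights must have shape (n, K+1)")
    i, k = np.nonzero(panel.atrisk)
    fu = panel.followup()
    tstop = np.minimum(k + 1.0, fu[i])
    t_ev = np.where(np.isnan(panel.T), np.inf, panel.T)
    ev = panel.event[i] & (t_ev[i] > k) & (t_ev[i] <= k + 1)
    X = np.zeros((len(i), design.ncols))
    for kk in range(K + 1):
        sel = k == kk
        if np.any(sel):
            X[sel] = design.matrix_at(panel.A, kk, rows=i[sel])
    w = np.ones(len(i)) if sw is None else sw[i, k]
    if np.any(~(w > 0)):
        raise ValueError("weights must be strictly positive on at-risk rows")
    return CountingProcessData(
        ids=panel.ids[i],
        tstart=k.astype(float),
        tstop=tstop,
        event=ev,
        design=X,
        weight=w,
        msm_design=design,
        K=K,
    )
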