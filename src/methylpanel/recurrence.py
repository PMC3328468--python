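"""Recurrence association: 2x2 odds ratios with Woolf CIs, Kaplan-Meier
curves and the log-rank test.

Exposure is promoter methylation of a marker; the event is tumour
recurrence.  The univariate association is the cross-product odds ratio of
the exposure-by-recurrence 2x2 table with the Woolf log-scale interval
exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); a univariate logistic
regression of recurrence on a single binary exposure estimates exactly
this quantity.  Follow-up analyses use the product-limit (Kaplan-Meier)
estimator per exposure stratum and the standard observed-minus-expected
log-rank statistic with hypergeometric variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RecurrenceTable",
    "ORResult",
    "FollowUpCohort",
    "KMCurve",
    "LogrankResult",
    "odds_ratio",
    "km_estimate",
    "km_by_exposure",
    "logrank",
]

Z95 = 1.96  # conventional two-sided 95% quantile; configurable per call


@dataclass(frozen=True)
class RecurrenceTable:
    """Exposure (methylated) x event (recurrence) 2x2 counts.

    a = exposed with event, b = exposed without, c = unexposed with event,
    d = unexposed without.
    """

    exposed_events: int
    exposed_nonevents: int
    unexposed_events: int
    unexposed_nonevents: int

    def __post_init__(self) -> None:
        for label in (
            "exposed_events",
            "exposed_nonevents",
            "unexposed_events",
            "unexposed_nonevents",
        ):
            v = getattr(self, label)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{label} must be a non-negative integer, got {v!r}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.exposed_events,
            self.exposed_nonevents,
            self.unexposed_events,
            self.unexposed_nonevents,
        )

    @property
    def total(self) -> int:
        return sum(self.cells)

    def transposed_exposure(self) -> "RecurrenceTable":
        """Swap exposed and unexposed rows (label inversion)."""
        a, b, c, d = self.cells
        return RecurrenceTable(c, d, a, b)


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float | None
    ci: tuple[float, float] | None
    p_value: float | None
    corrected: bool  # Haldane-Anscombe +0.5 applied (zero cell)
    defined: bool
    z: float = Z95


def odds_ratio(table: RecurrenceTable, z: float = Z95) -> ORResult:
    """Cross-product odds ratio with Woolf CI and Wald p-value.

    A single zero cell triggers the Haldane-Anscombe +0.5 correction on
    all cells (flagged).  Two zero cells in one margin leave the OR
    undefined (flagged, no numbers invented).
    """
    a, b, c, d = table.cells
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (
        b == 0 and d == 0
    ):
        return ORResult(
            odds_ratio=None, ci=None, p_value=None, corrected=False,
            defined=False, z=z,
        )
    corrected = 0 in (a, b, c, d)
    fa, fb, fc, fd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    or_ = (fa * fd) / (fb * fc)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    log_or = math.log(or_)
    ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return ORResult(
        odds_ratio=or_, ci=ci, p_value=float(p), corrected=corrected,
        defined=True, z=z,
    )


@dataclass
class FollowUpCohort:
    """Per-patient binary exposure, follow-up time (months) and event flag."""

    exposure: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.exposure)
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("exposure, time and event must be aligned")
        if not np.all(self.time > 0):
            raise ValueError("follow-up times must be positive")
        for name, arr in (("exposure", self.exposure), ("event", self.event)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.time)

    def table(self) -> RecurrenceTable:
        """Collapse to the exposure-by-event 2x2 table."""
        e, v = self.exposure, self.event
        return RecurrenceTable(
            exposed_events=int(((e == 1) & (v == 1)).sum()),
            exposed_nonevents=int(((e == 1) & (v == 0)).sum()),
            unexposed_events=int(((e == 0) & (v == 1)).sum()),
            unexposed_nonevents=int(((e == 0) & (v == 0)).sum()),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "patient": [f"p{i:04d}" for i in range(len(self))],
                "exposure": self.exposure,
                "time_months": self.time,
                "event": self.event,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FollowUpCohort":
        df = pd.read_csv(path, sep="\t")
        return cls(
            exposure=df["exposure"].to_numpy(),
            time=df["time_months"].to_numpy(),
            event=df["event"].to_numpy(),
        )


@dataclass
class KMCurve:
    """Product-limit survival estimate: step function over event times."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    n_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); S(0) = 1, non-increasing, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one stratum.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    where n_i counts subjects with follow-up >= t_i — i.e. subjects
    censored exactly at an event time are still at risk there (events
    precede censorings at tied times).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("km_estimate needs at least one subject")
    evt_times = np.unique(time[event == 1])
    sorted_all = np.sort(time)
    n_risk = len(time) - np.searchsorted(sorted_all, evt_times, side="left")
    evt_sorted = np.sort(time[event == 1])
    n_events = np.searchsorted(evt_sorted, evt_times, side="right") - np.searchsorted(
        evt_sorted, evt_times, side="left"
    )
    survival = np.cumprod(1.0 - n_events / n_risk)
    return KMCurve(
        times=evt_times,
        survival=survival,
        n_risk=n_risk,
        n_events=n_events,
    )


def km_by_exposure(cohort: FollowUpCohort) -> dict[int, KMCurve]:
    """KM curve per exposure stratum; errors on an empty stratum."""
    out: dict[int, KMCurve] = {}
    for stratum in (0, 1):
        mask = cohort.exposure == stratum
        if not mask.any():
            raise ValueError(f"empty exposure stratum {stratum}")
        out[stratum] = km_estimate(cohort.time[mask], cohort.event[mask])
    return out


@dataclass(frozen=True)
class LogrankResult:
    statistic: float | None
    p_value: float | None
    defined: bool


def logrank(cohort: FollowUpCohort) -> LogrankResult:
    """Two-group log-rank test over the joint event-time grid.

    chi^2 = (sum_j (d_1j - E_1j))^2 / sum_j V_j with the hypergeometric
    variance V_j = d_j (n_1j/n_j)(n_0j/n_j)(n_j - d_j)/(n_j - 1); 1 df.
    Tied event times use the standard hypergeometric variance; undefined
    (flagged) when there are no events or no variance.
    """
    t, e, g = cohort.time, cohort.event, cohort.exposure
    if not (g == 0).any() or not (g == 1).any():
        raise ValueError("logrank needs subjects in both exposure strata")
    evt_times = np.unique(t[e == 1])
    if len(evt_times) == 0:
        return LogrankResult(statistic=None, p_value=None, defined=False)

    def risk_and_events(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ts = np.sort(t[mask])
        n_at = len(ts) - np.searchsorted(ts, evt_times, side="left")
        te = np.sort(t[mask & (e == 1)])
        d_at = np.searchsorted(te, evt_times, side="right") - np.searchsorted(
            te, evt_times, side="left"
        )
        return n_at.astype(float), d_at.astype(float)

    n1, d1 = risk_and_events(g == 1)
    n0, d0 = risk_and_events(g == 0)
    n = n1 + n0
    d = d1 + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        expected1 = d * n1 / n
        var = np.where(
            n > 1, d * (n1 / n) * (n0 / n) * (n - d) / (n - 1), 0.0
        )
    observed_minus_expected = float(np.sum(d1 - expected1))
    total_var = float(np.sum(var))
    if total_var <= 0:
        return LogrankResult(statistic=None, p_value=None, defined=False)
    chi2 = observed_minus_expected**2 / total_var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(statistic=chi2, p_value=p, defined=True)
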