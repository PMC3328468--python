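"""Diagnostic panel evaluation: confusion tables, SN/SP/PPV/NPV, panel search.

A marker panel under the any-positive rule calls a sample positive when at
least ``m`` member loci are methylated (default ``m = 1``).  Binary-marker
discriminative ability is summarised as ``(sensitivity + specificity) / 2``
— the area under the single-operating-point ROC polygon — which is the
objective used by the exhaustive panel search.

Percentages are rounded half-away-from-zero to two decimals; 95% CIs for
proportions use the Wilson score interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionTable",
    "Proportion",
    "DiagnosticMetrics",
    "PanelDefinition",
    "DiagnosticsResult",
    "SearchResult",
    "GroupTestResult",
    "ConcordanceResult",
    "PairedResult",
    "round_pct",
    "wilson_ci",
    "call_panel",
    "diagnostics",
    "search_panel",
    "group_test",
    "concordance",
    "paired_prepost",
]

Z95 = 1.96  # conventional two-sided 95% normal quantile


def round_pct(fraction: float | None, ndigits: int = 2) -> float | None:
    """Express a fraction as a percentage, rounded half-away-from-zero."""
    if fraction is None:
        return None
    quantum = Decimal(1).scaleb(-ndigits)
    return float(
        Decimal(repr(float(fraction) * 100)).quantize(quantum, rounding=ROUND_HALF_UP)
    )


def wilson_ci(k: int, n: int, z: float = Z95) -> tuple[float, float] | None:
    """Wilson score 95% interval for a binomial proportion ``k/n``."""
    if n <= 0:
        return None
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a binary diagnostic against truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for label in ("tp", "fp", "tn", "fn"):
            v = getattr(self, label)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{label} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, pred: Sequence[float], truth: Sequence[float]
    ) -> "ConfusionTable":
        """Tabulate aligned binary vectors; pairs with a missing prediction
        are excluded."""
        pred = np.asarray(pred, dtype=float)
        truth = np.asarray(truth, dtype=float)
        if pred.shape != truth.shape:
            raise ValueError(
                f"prediction/truth length mismatch: {pred.shape} vs {truth.shape}"
            )
        keep = ~np.isnan(pred) & ~np.isnan(truth)
        pred, truth = pred[keep], truth[keep]
        return cls(
            tp=int(((pred == 1) & (truth == 1)).sum()),
            fp=int(((pred == 1) & (truth == 0)).sum()),
            tn=int(((pred == 0) & (truth == 0)).sum()),
            fn=int(((pred == 0) & (truth == 1)).sum()),
        )

    @classmethod
    def from_marginals(
        cls, case_pos: int, case_total: int, control_neg: int, control_total: int
    ) -> "ConfusionTable":
        """Build from study-report style marginals: positives among cases
        (pos./total) and negatives among controls (neg./total)."""
        if case_pos > case_total or control_neg > control_total:
            raise ValueError("counts exceed totals")
        return cls(
            tp=case_pos,
            fn=case_total - case_pos,
            tn=control_neg,
            fp=control_total - control_neg,
        )


@dataclass(frozen=True)
class Proportion:
    """A proportion metric with its CI; ``value is None`` means the
    denominator was zero and the metric is undefined (flagged, not NaN)."""

    value: float | None
    numerator: int
    denominator: int
    ci: tuple[float, float] | None
    method: str = "Wilson score"

    @property
    def defined(self) -> bool:
        return self.value is not None

    @property
    def percent(self) -> float | None:
        return round_pct(self.value)

    @property
    def ci_percent(self) -> tuple[float, float] | None:
        if self.ci is None:
            return None
        return (round_pct(self.ci[0]), round_pct(self.ci[1]))


def _proportion(k: int, n: int) -> Proportion:
    if n == 0:
        return Proportion(value=None, numerator=k, denominator=0, ci=None)
    return Proportion(value=k / n, numerator=k, denominator=n, ci=wilson_ci(k, n))


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    accuracy: Proportion
    auc_binary: Proportion

    def as_percent_dict(self) -> dict:
        out = {}
        for label in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                      "auc_binary"):
            m: Proportion = getattr(self, label)
            out[label] = {
                "percent": m.percent,
                "ci_percent": m.ci_percent,
                "numerator": m.numerator,
                "denominator": m.denominator,
                "method": m.method,
            }
        return out


class DiagnosticsResult(NamedTuple):
    table: ConfusionTable
    metrics: DiagnosticMetrics


def diagnostics(
    pred: Sequence[float] | None = None,
    truth: Sequence[float] | None = None,
    *,
    table: ConfusionTable | None = None,
) -> DiagnosticsResult:
    """Compute SN/SP/PPV/NPV/accuracy and binary AUC from predictions or
    directly from a 2x2 table.

    Zero-denominator metrics are flagged undefined rather than propagated
    as NaN.  Binary AUC = (SN + SP) / 2 with a normal-approximation CI
    treating SN and SP as independent binomials.
    """
    if table is None:
        if pred is None or truth is None:
            raise ValueError("provide pred and truth, or a ConfusionTable")
        table = ConfusionTable.from_predictions(pred, truth)
    if table.total == 0:
        raise ValueError("empty confusion table")
    t = table
    sn = _proportion(t.tp, t.tp + t.fn)
    sp = _proportion(t.tn, t.tn + t.fp)
    ppv = _proportion(t.tp, t.tp + t.fp)
    npv = _proportion(t.tn, t.tn + t.fn)
    acc = _proportion(t.tp + t.tn, t.total)
    if sn.defined and sp.defined:
        auc = (sn.value + sp.value) / 2
        var = (
            sn.value * (1 - sn.value) / sn.denominator
            + sp.value * (1 - sp.value) / sp.denominator
        ) / 4
        half = Z95 * math.sqrt(var)
        auc_m = Proportion(
            value=auc,
            numerator=t.tp + t.tn,
            denominator=t.total,
            ci=(max(0.0, auc - half), min(1.0, auc + half)),
            method="normal approximation (independent SN, SP)",
        )
    else:
        auc_m = Proportion(
            value=None, numerator=0, denominator=0, ci=None,
            method="undefined (zero margin)",
        )
    metrics = DiagnosticMetrics(
        sensitivity=sn, specificity=sp, ppv=ppv, npv=npv, accuracy=acc,
        auc_binary=auc_m,
    )
    return DiagnosticsResult(table=table, metrics=metrics)


@dataclass(frozen=True)
class PanelDefinition:
    """A marker panel with the >=m-positive decision rule (default any-positive)."""

    members: tuple[str, ...]
    min_positive: int = 1

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a panel needs at least one member")
        if not 1 <= self.min_positive <= len(self.members):
            raise ValueError(
                f"min_positive must be in [1, {len(self.members)}], "
                f"got {self.min_positive}"
            )


def call_panel(matrix, panel: PanelDefinition) -> pd.Series:
    """Per-sample panel prediction: 1.0 positive, 0.0 negative, NaN when
    every member call is missing.

    A sample is positive iff at least ``min_positive`` member calls are
    positive; missing member calls count neither way.
    """
    unknown = [t for t in panel.members if t not in matrix.calls.columns]
    if unknown:
        raise KeyError(f"panel members not in matrix: {unknown}")
    sub = matrix.calls[list(panel.members)]
    n_pos = (sub == 1.0).sum(axis=1)
    n_obs = sub.notna().sum(axis=1)
    pred = (n_pos >= panel.min_positive).astype(float)
    pred[n_obs == 0] = np.nan
    return pred


@dataclass
class SearchResult:
    best: PanelDefinition
    score: float
    trace: pd.DataFrame  # one row per evaluated subset


def search_panel(
    matrix,
    candidates: Sequence[str],
    max_size: int | None = None,
    cases: str = "BC",
    controls: str = "normal_control",
    objective: str = "auc_binary",
    min_positive: int = 1,
) -> SearchResult:
    """Exhaustively search marker subsets for the best panel.

    Enumerates every non-empty subset of ``candidates`` up to ``max_size``
    (so the candidate list is capped at 20), scores each with the chosen
    objective on the case/control split, and returns the best panel with a
    full score trace.  Deterministic tie-break: higher score, then fewer
    members, then lexicographic member order.
    """
    candidates = sorted(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("no candidate targets supplied")
    if len(candidates) > 20:
        raise ValueError(
            f"{len(candidates)} candidates: exhaustive enumeration is "
            "capped at 20"
        )
    if objective not in ("auc_binary", "sensitivity", "specificity", "accuracy"):
        raise ValueError(f"unknown objective {objective!r}")
    max_size = len(candidates) if max_size is None else min(max_size, len(candidates))

    case_mask = matrix.sample_mask(cases)
    ctrl_mask = matrix.sample_mask(controls)
    if not case_mask.any() or not ctrl_mask.any():
        raise ValueError(f"empty case ({cases}) or control ({controls}) group")
    keep = case_mask | ctrl_mask
    truth = case_mask[keep].astype(float)

    rows = []
    best_key: tuple | None = None
    best_panel: PanelDefinition | None = None
    best_score = -math.inf
    for size in range(1, max_size + 1):
        for members in itertools.combinations(candidates, size):
            panel = PanelDefinition(members=members, min_positive=min_positive)
            pred = call_panel(matrix, panel)[keep]
            res = diagnostics(pred.to_numpy(), truth.to_numpy())
            metric: Proportion = getattr(res.metrics, objective)
            score = metric.value if metric.defined else -math.inf
            rows.append(
                {
                    "members": ",".join(members),
                    "size": size,
                    objective: score,
                    "sensitivity": res.metrics.sensitivity.value,
                    "specificity": res.metrics.specificity.value,
                }
            )
            key = (-score, size, members)
            if best_key is None or key < best_key:
                best_key, best_panel, best_score = key, panel, score
    trace = pd.DataFrame(rows)
    assert best_panel is not None
    return SearchResult(best=best_panel, score=best_score, trace=trace)


@dataclass
class GroupTestResult:
    method: str
    statistic: float | None
    p_value: float | None
    table: np.ndarray
    defined: bool


def group_test(matrix, target: str, group_a: str, group_b: str) -> GroupTestResult:
    """Test a target's positive-call frequency between two sample groups.

    Pearson chi-square without continuity correction by default; Fisher's
    exact test (two-sided, point-probability rule) when any expected cell
    count is below 5.  Degenerate tables (a zero margin) are flagged with
    an undefined p-value.
    """
    if target not in matrix.calls.columns:
        raise KeyError(f"unknown target {target!r}")
    cells = []
    for group in (group_a, group_b):
        mask = matrix.sample_mask(group)
        if not mask.any():
            raise ValueError(f"no samples in group {group!r}")
        col = matrix.calls.loc[mask, target]
        cells.append([int((col == 1.0).sum()), int((col == 0.0).sum())])
    table = np.array(cells, dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return GroupTestResult(
            method="degenerate", statistic=None, p_value=None, table=table,
            defined=False,
        )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupTestResult(
            method="fisher_exact", statistic=None, p_value=float(p),
            table=table, defined=True,
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupTestResult(
        method="chi2", statistic=float(chi2), p_value=float(p), table=table,
        defined=True,
    )


@dataclass
class ConcordanceResult:
    n: int
    agreement: float  # fraction of samples where both procedures agree
    both_positive: int
    both_negative: int
    pred_pos_ref_neg: int
    pred_neg_ref_pos: int

    @property
    def agreement_percent(self) -> float:
        return round_pct(self.agreement)


def concordance(pred: Sequence[float], reference: Sequence[float]) -> ConcordanceResult:
    """Agreement between a panel and a reference procedure (e.g. cystoscopy)."""
    pred = np.asarray(pred, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pred.shape != reference.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions vs "
            f"{reference.shape[0]} reference calls"
        )
    both_pos = int(((pred == 1) & (reference == 1)).sum())
    both_neg = int(((pred == 0) & (reference == 0)).sum())
    return ConcordanceResult(
        n=len(pred),
        agreement=(both_pos + both_neg) / len(pred),
        both_positive=both_pos,
        both_negative=both_neg,
        pred_pos_ref_neg=int(((pred == 1) & (reference == 0)).sum()),
        pred_neg_ref_pos=int(((pred == 0) & (reference == 1)).sum()),
    )


@dataclass
class PairedResult:
    n: int
    pre_positive: int
    post_positive: int
    pre_rate: float
    post_rate: float
    n_discordant: int
    p_value: float  # exact binomial McNemar on discordant pairs


def paired_prepost(pre: Sequence[float], post: Sequence[float]) -> PairedResult:
    """Paired pre/post-surgery comparison of panel positivity.

    Exact McNemar: the discordant count in the minority direction is
    referred to Binomial(b + c, 1/2); two-sided p doubled and capped at 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(
            f"length mismatch: {pre.shape[0]} pre vs {post.shape[0]} post"
        )
    b = int(((pre == 1) & (post == 0)).sum())  # positive -> negative
    c = int(((pre == 0) & (post == 1)).sum())  # negative -> positive
    nd = b + c
    if nd == 0:
        p = 1.0
    else:
        p = min(1.0, 2 * stats.binom.cdf(min(b, c), nd, 0.5))
    return PairedResult(
        n=len(pre),
        pre_positive=int((pre == 1).sum()),
        post_positive=int((post == 1).sum()),
        pre_rate=float((pre == 1).mean()),
        post_rate=float((post == 1).mean()),
        n_discordant=nd,
        p_value=float(p),
    )
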