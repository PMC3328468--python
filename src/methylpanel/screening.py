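"""Binary MSP call matrices and the multi-round marker screening cascade.

Methylation-specific PCR (MSP) on urine sediment DNA yields one binary
methylated/unmethylated call per locus per sample.  Candidate loci coming
out of the DMR profiler are winnowed through successive screening rounds:
each round keeps a target only if it is methylated in enough case samples
and in few enough control samples, and later rounds see only the survivors
of earlier ones — so the sample count grows while the target count shrinks.

Bisulfite-sequencing (BSP) clone patterns are summarised here too, as the
orthogonal confirmation assay for MSP calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GROUPS",
    "MSPCallMatrix",
    "ScreeningRule",
    "RuleResult",
    "CascadeResult",
    "BSPCloneSet",
    "apply_rule",
    "run_cascade",
    "bsp_percentage",
    "load_rules",
]

#: Closed vocabulary of sample group labels.
GROUPS = frozenset(
    {
        "cell_line",
        "normal_control",
        "BC",
        "nontumor_lesion",
        "pre_surgery",
        "post_surgery",
        "suspected",
    }
)


class MSPCallMatrix:
    """Samples x targets binary methylation calls with sample metadata.

    ``calls`` is a float DataFrame (sample index, target columns) with
    entries 1.0 (methylated), 0.0 (unmethylated) or NaN (failed PCR /
    missing).  Missing entries are tracked and reported, never silently
    coerced.  ``groups`` labels each sample with one of :data:`GROUPS`;
    ``batches`` optionally sub-labels samples (e.g. the two distinct
    normal-control groups used in successive screening rounds).
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        groups: pd.Series,
        batches: pd.Series | None = None,
    ) -> None:
        calls = calls.astype(float)
        values = calls.to_numpy()
        ok = np.isnan(values) | (values == 0.0) | (values == 1.0)
        if not ok.all():
            bad = sorted(set(values[~ok].tolist()))
            raise ValueError(f"calls must be 0, 1 or NA; found {bad}")
        if not calls.index.equals(groups.index):
            groups = groups.reindex(calls.index)
            if groups.isna().any():
                raise ValueError("every sample needs a group label")
        unknown = set(groups.unique()) - GROUPS
        if unknown:
            raise ValueError(
                f"unknown group labels {sorted(unknown)}; "
                f"allowed: {sorted(GROUPS)}"
            )
        if batches is None:
            batches = pd.Series("", index=calls.index)
        else:
            batches = batches.reindex(calls.index).fillna("").astype(str)
        self.calls = calls
        self.groups = groups
        self.batches = batches

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def targets(self) -> list[str]:
        return list(self.calls.columns)

    def sample_mask(self, group: str, batch: str | None = None) -> pd.Series:
        mask = self.groups == group
        if batch is not None:
            mask &= self.batches == batch
        return mask

    def subset_targets(self, targets: Sequence[str]) -> "MSPCallMatrix":
        missing = [t for t in targets if t not in self.calls.columns]
        if missing:
            raise KeyError(f"unknown targets {missing}")
        return MSPCallMatrix(self.calls[list(targets)], self.groups, self.batches)

    # ---- TSV round trip ------------------------------------------------
    # Layout: sample <tab> group [<tab> batch] <tab> target columns; call
    # entries are 1, 0 or NA.

    def to_tsv(self, path: str | Path) -> None:
        df = self.calls.copy()
        out = pd.DataFrame(index=df.index)
        out["group"] = self.groups
        if (self.batches != "").any():
            out["batch"] = self.batches
        for col in df.columns:
            out[col] = df[col].map(
                lambda v: "NA" if pd.isna(v) else str(int(v))
            )
        out.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MSPCallMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample", dtype=str)
        df.index.name = None
        if "group" not in df.columns:
            raise ValueError(f"{path}: missing 'group' column")
        groups = df.pop("group")
        batches = df.pop("batch") if "batch" in df.columns else None
        calls = df.replace({"NA": np.nan}).astype(float)
        return cls(calls, groups, batches)


@dataclass(frozen=True)
class ScreeningRule:
    """One screening round: positivity thresholds for a case/control pair.

    A target is retained iff its positive-call count in the case group is
    at least ``min_case_positives`` AND its positive-call count in the
    control group is at most ``max_control_positives``.  Optional batch
    filters address a sub-cohort (e.g. the second batch of normal
    controls recruited for a later round).
    """

    case_group: str
    control_group: str
    min_case_positives: int
    max_control_positives: int
    case_batch: str | None = None
    control_batch: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.min_case_positives < 0 or self.max_control_positives < 0:
            raise ValueError("screening thresholds must be >= 0")
        for g in (self.case_group, self.control_group):
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; allowed: {sorted(GROUPS)}")

    @property
    def label(self) -> str:
        return self.name or (
            f">={self.min_case_positives} {self.case_group} / "
            f"<={self.max_control_positives} {self.control_group}"
        )


@dataclass
class RuleResult:
    rule: ScreeningRule
    retained: list[str]
    removed: list[str]
    counts: pd.DataFrame  # per-target case/control positives, observed, missing


@dataclass
class CascadeResult:
    rounds: list[RuleResult]

    @property
    def survivors(self) -> list[str]:
        return self.rounds[-1].retained if self.rounds else []

    def audit(self) -> pd.DataFrame:
        """Per-round funnel: targets in, retained, removed."""
        rows = []
        for i, res in enumerate(self.rounds, start=1):
            n_in = len(res.retained) + len(res.removed)
            rows.append(
                {
                    "round": i,
                    "rule": res.rule.label,
                    "n_in": n_in,
                    "n_retained": len(res.retained),
                    "n_removed": len(res.removed),
                }
            )
        return pd.DataFrame(
            rows, columns=["round", "rule", "n_in", "n_retained", "n_removed"]
        )

    def to_dict(self) -> dict:
        return {
            "rounds": self.audit().to_dict(orient="records"),
            "survivors": self.survivors,
        }


def _group_counts(
    matrix: MSPCallMatrix,
    group: str,
    batch: str | None,
    targets: Sequence[str],
    role: str,
) -> pd.DataFrame:
    mask = matrix.sample_mask(group, batch)
    if not mask.any():
        where = f"group {group!r}" + (f" batch {batch!r}" if batch else "")
        raise ValueError(f"no samples in {where} ({role} group of the rule)")
    sub = matrix.calls.loc[mask, list(targets)]
    return pd.DataFrame(
        {
            f"{role}_pos": (sub == 1.0).sum(),
            f"{role}_obs": sub.notna().sum(),
            f"{role}_missing": sub.isna().sum(),
        }
    )


def apply_rule(
    matrix: MSPCallMatrix,
    rule: ScreeningRule,
    targets: Sequence[str] | None = None,
) -> RuleResult:
    """Apply one screening rule, partitioning targets into retained/removed.

    Missing calls are excluded from both numerator and denominator
    (complete-case per target) and reported in the counts table.
    """
    targets = list(targets) if targets is not None else matrix.targets
    case = _group_counts(matrix, rule.case_group, rule.case_batch, targets, "case")
    ctrl = _group_counts(
        matrix, rule.control_group, rule.control_batch, targets, "control"
    )
    counts = case.join(ctrl)
    counts["retained"] = (counts["case_pos"] >= rule.min_case_positives) & (
        counts["control_pos"] <= rule.max_control_positives
    )
    retained = [t for t in targets if counts.loc[t, "retained"]]
    removed = [t for t in targets if not counts.loc[t, "retained"]]
    return RuleResult(rule=rule, retained=retained, removed=removed, counts=counts)


def run_cascade(
    matrix: MSPCallMatrix, rules: Sequence[ScreeningRule]
) -> CascadeResult:
    """Run an ordered cascade of screening rules.

    Round ``r`` sees only the targets that survived round ``r - 1``
    (the funnel: samples increase, targets decrease).
    """
    if not rules:
        raise ValueError("run_cascade needs at least one rule")
    survivors: Sequence[str] = matrix.targets
    rounds: list[RuleResult] = []
    for i, rule in enumerate(rules, start=1):
        res = apply_rule(matrix, rule, targets=survivors)
        rounds.append(res)
        survivors = res.retained
        if not survivors and i < len(rules):
            warnings.warn(
                f"screening cascade: no surviving targets after round {i}; "
                "remaining rounds operate on an empty set",
                stacklevel=2,
            )
    return CascadeResult(rounds=rounds)


@dataclass
class BSPCloneSet:
    """Per-clone CpG methylation patterns from bisulfite sequencing.

    Each clone is a string over {M, U}, one symbol per CpG position; all
    clones of a locus cover the same positions.
    """

    locus: str
    clones: list[str]

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("BSPCloneSet needs at least one clone")
        length = len(self.clones[0])
        if length < 1:
            raise ValueError("clone patterns must be non-empty")
        for clone in self.clones:
            if len(clone) != length:
                raise ValueError(
                    f"clone length mismatch: {len(clone)} != {length}"
                )
            bad = set(clone) - {"M", "U"}
            if bad:
                raise ValueError(
                    f"invalid symbols {sorted(bad)} in clone pattern; "
                    "allowed: M (methylated), U (unmethylated)"
                )


def bsp_percentage(clones: BSPCloneSet) -> float:
    """Methylated-cytosine fraction across all sequenced clones.

    Number of M symbols divided by the total number of symbols, pooled
    over clones; in [0, 1].
    """
    total = sum(len(c) for c in clones.clones)
    methylated = sum(c.count("M") for c in clones.clones)
    return methylated / total


def load_rules(path: str | Path) -> list[ScreeningRule]:
    """Load an ordered list of screening rules from YAML.

    The file is a list of mappings with keys matching
    :class:`ScreeningRule` fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of rules")
    return [ScreeningRule(**entry) for entry in raw]
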