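"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylpanel.intervals import GenomicInterval
from methylpanel.screening import MSPCallMatrix


def naive_overlap_flags(query, subject, min_bp=1):
    """All-pairs overlap oracle: the definition, applied literally."""
    return [
        any(
            q.chrom == s.chrom
            and min(q.end, s.end) - max(q.start, s.start) >= min_bp
            for s in subject
        )
        for q in query
    ]


def random_intervals(rng, n, chroms=("chr1", "chr2", "chr3"), span=20_000,
                     max_len=300, with_fields=False):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        if with_fields:
            iv = GenomicInterval.make(
                chrom, start, start + length,
                name=f"iv{i}", score=f"{rng.uniform(0, 100):.2f}",
                strand="+" if rng.random() < 0.5 else "-",
            )
        else:
            iv = GenomicInterval(chrom, start, start + length)
        out.append(iv)
    return out


def make_matrix(calls_by_target, groups, batches=None):
    """Build an MSPCallMatrix from {target: list-of-calls} and group labels."""
    index = [f"s{i:03d}" for i in range(len(groups))]
    calls = pd.DataFrame(
        {t: pd.array(v, dtype=float) for t, v in calls_by_target.items()},
        index=index,
    )
    batch_series = pd.Series(batches, index=index) if batches else None
    return MSPCallMatrix(calls, pd.Series(list(groups), index=index),
                         batch_series)


@pytest.fixture
def rng():
    return np.random.default_rng(20120417)
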