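"""Differentially methylated region (DMR) calling and genomic-context profiling.

Two MBD-capture libraries (e.g. a tumour cell-line pool and a normal mucosa
pool) each contribute a set of hypermethylation peaks.  Peaks present in
both libraries carry no differential signal and are set aside; peaks unique
to one library are the DMRs.  DMRs are then tabulated down a narrowing
genomic-context hierarchy:

    all DMRs -> gene-body DMRs -> gene & CpG-island DMRs -> promoter DMRs

Promoter-CGI hypermethylation is the classic tumour-suppressor silencing
signal, so the final tier is where diagnostic marker candidates come from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import pandas as pd

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    PeakSet,
    overlap_flags,
)

__all__ = [
    "DMRSet",
    "DMRProfile",
    "DmrCalls",
    "call_dmrs",
    "make_promoters",
    "profile_dmrs",
    "rank_promoter_targets",
    "PROFILE_CATEGORIES",
]

PROFILE_CATEGORIES = (
    "all_DMR",
    "gene_DMR",
    "CGI_DMR",
    "gene_and_CGI_DMR",
    "promoter_DMR",
)


@dataclass
class DMRSet:
    """Peaks unique to one library at the configured overlap threshold."""

    source_library: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


class DmrCalls(NamedTuple):
    common_a: PeakSet
    dmr_a: DMRSet
    common_b: PeakSet
    dmr_b: DMRSet


def call_dmrs(lib_a: PeakSet, lib_b: PeakSet, min_bp: int = 1) -> DmrCalls:
    """Split each library's peaks into common peaks and library-unique DMRs.

    A peak of A is *common* when it overlaps at least one peak of B by
    ``min_bp`` or more, else it is a DMR of A (and symmetrically for B).
    Conservation holds by construction: ``|common| + |dmr| == |library|``.
    """
    if len(lib_a) == 0 or len(lib_b) == 0:
        warnings.warn(
            "call_dmrs: empty peak library "
            f"({lib_a.name}: {len(lib_a)}, {lib_b.name}: {len(lib_b)})",
            stacklevel=2,
        )
    flags_a = overlap_flags(lib_a.intervals, lib_b.intervals, min_bp=min_bp)
    flags_b = overlap_flags(lib_b.intervals, lib_a.intervals, min_bp=min_bp)
    common_a = [iv for iv, f in zip(lib_a.intervals, flags_a) if f]
    unique_a = [iv for iv, f in zip(lib_a.intervals, flags_a) if not f]
    common_b = [iv for iv, f in zip(lib_b.intervals, flags_b) if f]
    unique_b = [iv for iv, f in zip(lib_b.intervals, flags_b) if not f]
    return DmrCalls(
        common_a=PeakSet(name=f"{lib_a.name}:common", intervals=common_a),
        dmr_a=DMRSet(source_library=lib_a.name, intervals=unique_a),
        common_b=PeakSet(name=f"{lib_b.name}:common", intervals=common_b),
        dmr_b=DMRSet(source_library=lib_b.name, intervals=unique_b),
    )


def make_promoters(
    tss: AnnotationSet, upstream: int = 2000, downstream: int = 500
) -> AnnotationSet:
    """Build strand-aware promoter windows around transcription start sites.

    For a ``+`` strand TSS at position ``t`` the window is
    ``[t - upstream, t + downstream)``; for ``-`` strand it is mirrored,
    ``[t - downstream, t + upstream)``.  Windows are clipped at position 0.
    Every TSS record must carry a strand.
    """
    if tss.track_name != "TSS":
        raise ValueError(f"expected a TSS track, got {tss.track_name!r}")
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    out: list[GenomicInterval] = []
    for iv in tss:
        if iv.strand not in ("+", "-"):
            raise ValueError(
                f"TSS record {iv.chrom}:{iv.start} has no strand; "
                "promoter windows require stranded TSS records"
            )
        t = iv.start
        if iv.strand == "+":
            start, end = t - upstream, t + downstream
        else:
            start, end = t - downstream, t + upstream
        start = max(0, start)
        if end <= start:  # fully clipped away
            continue
        out.append(
            GenomicInterval.make(
                iv.chrom, start, end, name=iv.name, strand=iv.strand
            )
        )
    return AnnotationSet(track_name="promoter", intervals=out)


@dataclass
class DMRProfile:
    """Per-library DMR counts down the genomic-context hierarchy.

    ``counts`` maps library name -> {category -> count}; ``config`` echoes
    the parameters the profile was computed under so results are
    self-describing; ``table`` holds per-DMR membership flags for
    downstream target ranking.
    """

    counts: dict[str, dict[str, int]]
    config: dict
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {"counts": self.counts, "config": self.config}


def _empty(track_name: str, ann: AnnotationSet | None) -> AnnotationSet:
    return ann if ann is not None else AnnotationSet(track_name, [])


def profile_dmrs(
    dmr_a: DMRSet,
    dmr_b: DMRSet,
    cgi: AnnotationSet | None,
    genes: AnnotationSet | None,
    promoters: AnnotationSet | None,
    min_bp: int = 1,
    promoter_tier: str = "nested",
    promoter_window: tuple[int, int] | None = None,
) -> DMRProfile:
    """Tabulate DMRs of both libraries by genomic context.

    A DMR counts once per category regardless of how many annotation
    intervals it touches (set semantics).  The final ``promoter_DMR`` tier
    is controlled by ``promoter_tier``:

    - ``"nested"`` (default): promoter window AND CpG island AND gene body,
      the fully narrowing hierarchy;
    - ``"cgi"``: promoter window AND CpG island;
    - ``"window"``: promoter window only.
    """
    if promoter_tier not in ("nested", "cgi", "window"):
        raise ValueError(f"unknown promoter_tier {promoter_tier!r}")
    cgi = _empty("CGI", cgi)
    genes = _empty("gene_body", genes)
    promoters = _empty("promoter", promoters)

    counts: dict[str, dict[str, int]] = {}
    rows: list[dict] = []
    for dmrs in (dmr_a, dmr_b):
        in_gene = overlap_flags(dmrs.intervals, genes.intervals, min_bp=min_bp)
        in_cgi = overlap_flags(dmrs.intervals, cgi.intervals, min_bp=min_bp)
        in_win = overlap_flags(dmrs.intervals, promoters.intervals, min_bp=min_bp)
        lib_counts = dict.fromkeys(PROFILE_CATEGORIES, 0)
        lib_counts["all_DMR"] = len(dmrs)
        for iv, g, c, w in zip(dmrs.intervals, in_gene, in_cgi, in_win):
            if promoter_tier == "nested":
                prom = g and c and w
            elif promoter_tier == "cgi":
                prom = c and w
            else:
                prom = w
            lib_counts["gene_DMR"] += g
            lib_counts["CGI_DMR"] += c
            lib_counts["gene_and_CGI_DMR"] += g and c
            lib_counts["promoter_DMR"] += prom
            rows.append(
                {
                    "library": dmrs.source_library,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "name": iv.name,
                    "score": iv.score,
                    "in_gene": bool(g),
                    "in_CGI": bool(c),
                    "in_gene_and_CGI": bool(g and c),
                    "in_promoter_window": bool(w),
                    "promoter_DMR": bool(prom),
                }
            )
        counts[dmrs.source_library] = lib_counts

    config = {"min_bp": min_bp, "promoter_tier": promoter_tier}
    if promoter_window is not None:
        config["promoter_upstream"] = promoter_window[0]
        config["promoter_downstream"] = promoter_window[1]
    columns = [
        "library", "chrom", "start", "end", "name", "score",
        "in_gene", "in_CGI", "in_gene_and_CGI", "in_promoter_window",
        "promoter_DMR",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return DMRProfile(counts=counts, config=config, table=table)


def rank_promoter_targets(
    table: pd.DataFrame,
    key: str = "score",
    k: int | None = None,
    descending: bool = True,
) -> pd.DataFrame:
    """Order candidate promoter DMRs by a numeric score, deterministically.

    Ties are broken by ``(chrom, start)`` so the ordering is canonical.
    ``k`` truncates to the top-k rows (the whole list when ``k`` exceeds
    its length).
    """
    if key not in table.columns:
        raise ValueError(
            f"no column {key!r} in the DMR table; supply a numeric score "
            "column (e.g. the BED score carried from the peak caller)"
        )
    scores = pd.to_numeric(table[key], errors="coerce")
    if scores.isna().any():
        raise ValueError(
            f"column {key!r} contains non-numeric or missing values; "
            "supply a fully numeric score column"
        )
    ranked = (
        table.assign(**{key: scores})
        .sort_values(
            [key, "chrom", "start"],
            ascending=[not descending, True, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    if k is not None:
        ranked = ranked.head(k).reset_index(drop=True)
    return ranked
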