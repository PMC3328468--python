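"""Seeded synthetic-data generators for every pipeline stage.

The generators produce inputs with the statistical structure the analysis
stages assume, so the whole pipeline runs and is testable without any
external download:

- paired hypermethylation peak sets with a controllable common fraction
  and CpG-island context enrichment, plus CGI/gene/TSS annotation tracks;
- binary MSP call matrices with per-group, per-target positive rates and a
  shared-latent-factor dependence knob;
- recurrence cohorts with a stated true odds ratio and exponential
  follow-up times;
- a screening-funnel matrix constructed so an exact number of targets
  survives each round.

All output is a pure function of the config (including its seed):
identical configs give byte-identical output.  One master seed can be
fanned out to per-stream sub-seeds with :func:`spawn_seeds` so stages stay
independently reproducible.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .intervals import AnnotationSet, GenomicInterval, PeakSet
from .recurrence import FollowUpCohort
from .screening import MSPCallMatrix, ScreeningRule

__all__ = [
    "PeakSimConfig",
    "MatrixSimConfig",
    "CohortSimConfig",
    "SimulatedPeaks",
    "PlacementError",
    "simulate_peaks",
    "simulate_matrix",
    "simulate_cohort",
    "simulate_funnel_matrix",
    "spawn_seeds",
    "default_group_rates",
]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan one master seed out into ``n`` independent sub-seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


class PlacementError(RuntimeError):
    """Raised when peaks cannot be placed without forbidden overlap."""


class _Occupancy:
    """Per-chromosome sorted, non-overlapping occupied intervals."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def blocked(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        ends = self._ends[chrom]
        i = bisect.bisect_right(starts, start)
        if i < len(starts) and starts[i] < end:
            return True
        return i > 0 and ends[i - 1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_right(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


@dataclass(frozen=True)
class PeakSimConfig:
    """Configuration for paired peak-set simulation.

    Peak-length means default to the two capture libraries' reported mean
    peak lengths (778 bp tumour pool, 659 bp normal pool); lengths are
    truncated-normal with a 50 bp floor.  ``common_fraction`` is the
    fraction of each library's peaks shared with the other library;
    ``p_unique_in_cgi_a`` biases library-A-unique peaks into CpG islands,
    emulating the tumour pool's CGI/promoter hypermethylation enrichment.
    """

    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000),
        ("chr2", 20_000_000),
    )
    n_peaks_a: int = 2000
    n_peaks_b: int = 2000
    peak_length_mean_a: float = 778.0
    peak_length_mean_b: float = 659.0
    peak_length_sd: float = 200.0
    min_peak_length: int = 50
    common_fraction: float = 2 / 3
    p_unique_in_cgi_a: float = 0.6
    p_unique_in_cgi_b: float = 0.05
    n_genes: int = 300
    cgi_gene_fraction: float = 0.7
    intergenic_cgi_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "common_fraction",
            "p_unique_in_cgi_a",
            "p_unique_in_cgi_b",
            "cgi_gene_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.peak_length_mean_a <= 0 or self.peak_length_mean_b <= 0:
            raise ValueError("peak length means must be positive")
        if self.n_peaks_a < 0 or self.n_peaks_b < 0:
            raise ValueError("peak counts must be non-negative")


class SimulatedPeaks(NamedTuple):
    lib_a: PeakSet
    lib_b: PeakSet
    cgi: AnnotationSet
    genes: AnnotationSet
    tss: AnnotationSet


_MAX_ATTEMPTS = 500


def _draw_length(rng: np.random.Generator, mean: float, sd: float, floor: int) -> int:
    return max(floor, int(round(rng.normal(mean, sd))))


def _random_pos(
    rng: np.random.Generator, genome: Sequence[tuple[str, int]], length: int
) -> tuple[str, int]:
    weights = np.array([size for _, size in genome], dtype=float)
    idx = rng.choice(len(genome), p=weights / weights.sum())
    chrom, size = genome[idx]
    if size <= length:
        raise PlacementError(
            f"chromosome {chrom} ({size} bp) shorter than a {length} bp feature"
        )
    return chrom, int(rng.integers(0, size - length))


def _place(
    rng: np.random.Generator,
    genome: Sequence[tuple[str, int]],
    length: int,
    occupancies: Sequence[_Occupancy],
    pad: int = 0,
    proposal: tuple[str, int] | None = None,
) -> tuple[str, int]:
    """Find a placement not blocked in any occupancy; error when the genome
    is too crowded."""
    for attempt in range(_MAX_ATTEMPTS):
        if proposal is not None and attempt == 0:
            chrom, start = proposal
        else:
            chrom, start = _random_pos(rng, genome, length)
        if not any(
            occ.blocked(chrom, start - pad, start + length + pad)
            for occ in occupancies
        ):
            return chrom, start
    raise PlacementError(
        "genome too small to place peaks without forbidden overlap "
        f"(gave up after {_MAX_ATTEMPTS} attempts for a {length} bp peak)"
    )


def simulate_peaks(config: PeakSimConfig) -> SimulatedPeaks:
    """Simulate two peak libraries plus CGI/gene/TSS annotation tracks.

    Common peaks are placed once and copied into both libraries with an
    independent jitter of at most 10 bp (so the copies still overlap);
    library-unique peaks are placed so they never overlap any peak of the
    other library, making the realised common fraction equal the target up
    to rounding.  Peaks within one library never overlap each other.
    """
    rng = np.random.default_rng(config.seed)
    genome = list(config.genome)

    # --- annotations -----------------------------------------------------
    gene_occ = _Occupancy()
    gene_ivs: list[GenomicInterval] = []
    tss_ivs: list[GenomicInterval] = []
    for i in range(config.n_genes):
        length = int(rng.integers(5_000, 30_001))
        chrom, start = _place(rng, genome, length, [gene_occ], pad=1_000)
        gene_occ.add(chrom, start, start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{i:04d}"
        gene_ivs.append(
            GenomicInterval.make(chrom, start, start + length, name=name,
                                 strand=strand)
        )
        tss_pos = start if strand == "+" else start + length - 1
        tss_ivs.append(
            GenomicInterval.make(chrom, tss_pos, tss_pos + 1, name=name,
                                 strand=strand)
        )

    cgi_occ = _Occupancy()
    cgi_ivs: list[GenomicInterval] = []
    for gene, tss in zip(gene_ivs, tss_ivs):
        if rng.random() >= config.cgi_gene_fraction:
            continue
        length = int(rng.integers(500, 2_001))
        start = max(0, tss.start - int(rng.integers(100, length // 2 + 101)))
        if not cgi_occ.blocked(gene.chrom, start, start + length):
            cgi_occ.add(gene.chrom, start, start + length)
            cgi_ivs.append(
                GenomicInterval.make(gene.chrom, start, start + length,
                                     name=f"cgi_{gene.name}")
            )
    n_intergenic = int(round(config.n_genes * config.intergenic_cgi_fraction))
    for i in range(n_intergenic):
        length = int(rng.integers(500, 2_001))
        chrom, start = _place(rng, genome, length, [cgi_occ])
        cgi_occ.add(chrom, start, start + length)
        cgi_ivs.append(
            GenomicInterval.make(chrom, start, start + length, name=f"cgi_x{i:04d}")
        )

    # --- peaks -----------------------------------------------------------
    occ_a, occ_b = _Occupancy(), _Occupancy()
    peaks_a: list[GenomicInterval] = []
    peaks_b: list[GenomicInterval] = []
    n_common = int(round(config.common_fraction * min(config.n_peaks_a,
                                                      config.n_peaks_b)))
    mean_common = (config.peak_length_mean_a + config.peak_length_mean_b) / 2

    def _score(r: np.random.Generator) -> str:
        return f"{r.uniform(10.0, 300.0):.2f}"

    for i in range(n_common):
        length = _draw_length(rng, mean_common, config.peak_length_sd,
                              config.min_peak_length)
        chrom, start = _place(rng, genome, length, [occ_a, occ_b], pad=11)
        for lib, occ, peaks in (("A", occ_a, peaks_a), ("B", occ_b, peaks_b)):
            jitter = int(rng.integers(-10, 11))
            s = max(0, start + jitter)
            occ.add(chrom, s, s + length)
            peaks.append(
                GenomicInterval.make(chrom, s, s + length,
                                     name=f"{lib}_common{i:05d}",
                                     score=_score(rng))
            )

    def _place_unique(
        lib: str,
        n_unique: int,
        mean_len: float,
        p_cgi: float,
        own: _Occupancy,
        other: _Occupancy,
        out: list[GenomicInterval],
    ) -> None:
        for i in range(n_unique):
            length = _draw_length(rng, mean_len, config.peak_length_sd,
                                  config.min_peak_length)
            proposal = None
            if cgi_ivs and rng.random() < p_cgi:
                cgi = cgi_ivs[int(rng.integers(0, len(cgi_ivs)))]
                anchor = int(rng.integers(cgi.start, cgi.end))
                proposal = (cgi.chrom, max(0, anchor - length // 2))
            chrom, start = _place(rng, genome, length, [own, other],
                                  proposal=proposal)
            own.add(chrom, start, start + length)
            out.append(
                GenomicInterval.make(chrom, start, start + length,
                                     name=f"{lib}_unique{i:05d}",
                                     score=_score(rng))
            )

    _place_unique("A", config.n_peaks_a - n_common, config.peak_length_mean_a,
                  config.p_unique_in_cgi_a, occ_a, occ_b, peaks_a)
    _place_unique("B", config.n_peaks_b - n_common, config.peak_length_mean_b,
                  config.p_unique_in_cgi_b, occ_b, occ_a, peaks_b)

    return SimulatedPeaks(
        lib_a=PeakSet(name="lib_a", intervals=peaks_a),
        lib_b=PeakSet(name="lib_b", intervals=peaks_b),
        cgi=AnnotationSet("CGI", cgi_ivs),
        genes=AnnotationSet("gene_body", gene_ivs),
        tss=AnnotationSet("TSS", tss_ivs),
    )


# ---------------------------------------------------------------------------


def default_group_rates() -> dict[str, dict[str, float]]:
    """Per-group, per-marker positive rates matching the bundled reference
    cohort's marginal frequencies."""
    return {
        "BC": datasets.bc_positive_rates().to_dict(),
        "normal_control": datasets.control_positive_rates().to_dict(),
        "nontumor_lesion": datasets.lesion_positive_rates().to_dict(),
    }


@dataclass(frozen=True)
class MatrixSimConfig:
    """Configuration for binary MSP call-matrix simulation.

    Defaults emulate the reference cohort: 212 cancer cases, 149 normal
    controls and 41 benign lesions, with per-marker rates equal to the
    cohort's observed marginals.  ``dependence`` in [0, 1] is the weight
    of a shared per-sample latent uniform in a copula-style mixture: 0
    gives independent targets, larger values give increasing positive
    inter-target correlation while preserving every marginal rate exactly.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "BC": datasets.N_BC,
            "normal_control": datasets.N_CONTROL,
            "nontumor_lesion": datasets.N_LESION,
        }
    )
    rates: dict[str, dict[str, float]] = field(default_factory=default_group_rates)
    dependence: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dependence <= 1.0:
            raise ValueError(f"dependence must be in [0, 1], got {self.dependence}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0, 1]")
        for group, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {group!r} must be > 0")
            for target, p in self.rates[group].items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"rate for {group}/{target} must be in [0, 1], got {p}"
                    )


def simulate_matrix(config: MatrixSimConfig) -> MSPCallMatrix:
    """Draw a binary call matrix with the configured group-wise rates.

    For sample i and target j the call is ``u < p_gj`` where ``u`` is the
    sample's shared latent uniform with probability ``dependence`` and a
    fresh uniform otherwise — marginals are exact, correlation grows with
    the dependence weight.
    """
    rng = np.random.default_rng(config.seed)
    targets = list(next(iter(config.rates.values())).keys())
    frames: list[pd.DataFrame] = []
    group_labels: list[str] = []
    index: list[str] = []
    for group, n in config.group_sizes.items():
        rates = config.rates[group]
        u_shared = rng.random(n)
        cols = {}
        for target in targets:
            p = rates[target]
            fresh = rng.random(n)
            use_shared = rng.random(n) < config.dependence
            u = np.where(use_shared, u_shared, fresh)
            col = (u < p).astype(float)
            if config.missing_rate > 0:
                col[rng.random(n) < config.missing_rate] = np.nan
            cols[target] = col
        ids = [f"{group}_{i:04d}" for i in range(n)]
        frames.append(pd.DataFrame(cols, index=ids))
        group_labels.extend([group] * n)
        index.extend(ids)
    calls = pd.concat(frames)
    groups = pd.Series(group_labels, index=index)
    return MSPCallMatrix(calls, groups)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for recurrence-cohort simulation.

    Defaults emulate the 212-patient recurrence analysis: exposure
    prevalence 90/212 (marker methylated), unexposed event probability
    23/122 and a true odds ratio of 2.37.  Event times are exponential per
    arm (months); non-events get an exponential follow-up (censoring)
    time.  ``censoring_rate`` additionally censors each subject early with
    the given probability — at 1.0 no events are observed.
    """

    n: int = datasets.N_BC
    exposure_prevalence: float = 90 / 212
    true_odds_ratio: float = 2.37
    baseline_event_prob: float = 23 / 122
    event_hazard_exposed: float = 1 / 12.0
    event_hazard_unexposed: float = 1 / 18.0
    followup_hazard: float = 1 / 36.0
    censoring_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exposure_prevalence", "baseline_event_prob",
                     "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.true_odds_ratio <= 0:
            raise ValueError("true_odds_ratio must be > 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")

    @property
    def exposed_event_prob(self) -> float:
        """Event probability in the exposed arm implied by the baseline
        probability and the true odds ratio (logistic relation)."""
        odds = self.true_odds_ratio * self.baseline_event_prob / (
            1 - self.baseline_event_prob
        )
        return odds / (1 + odds)


class SimulatedCohort(NamedTuple):
    cohort: FollowUpCohort
    expected: dict  # expected 2x2 cell counts and arm event probabilities


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Draw a recurrence cohort with a known true odds ratio."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    exposure = (rng.random(n) < config.exposure_prevalence).astype(int)
    p1 = config.exposed_event_prob
    p0 = config.baseline_event_prob
    p_event = np.where(exposure == 1, p1, p0)
    event = (rng.random(n) < p_event).astype(int)

    time = np.empty(n)
    hazard = np.where(exposure == 1, config.event_hazard_exposed,
                      config.event_hazard_unexposed)
    is_event = event == 1
    time[is_event] = rng.exponential(1.0 / hazard[is_event])
    time[~is_event] = rng.exponential(1.0 / config.followup_hazard,
                                      size=(~is_event).sum())
    if config.censoring_rate > 0:
        early = rng.random(n) < config.censoring_rate
        cut = early & is_event
        time[cut] = time[cut] * rng.random(cut.sum())
        event[early] = 0
    time = np.maximum(time, 1e-6)  # keep times strictly positive

    expected = {
        "exposed_events": n * config.exposure_prevalence * p1,
        "exposed_nonevents": n * config.exposure_prevalence * (1 - p1),
        "unexposed_events": n * (1 - config.exposure_prevalence) * p0,
        "unexposed_nonevents": n * (1 - config.exposure_prevalence) * (1 - p0),
        "p_event_exposed": p1,
        "p_event_unexposed": p0,
    }
    return SimulatedCohort(
        cohort=FollowUpCohort(exposure=exposure, time=time, event=event),
        expected=expected,
    )


# ---------------------------------------------------------------------------


def simulate_funnel_matrix(
    seed: int = 0,
    n_targets: int = 104,
    round1_survivors: int = 49,
    final_targets: int = 8,
    n_cell_lines: int = 2,
    n_controls_round1: int = 8,
    n_controls_round2: int = 8,
    n_bc: int = 18,
) -> tuple[MSPCallMatrix, list[ScreeningRule]]:
    """Construct a call matrix realising an exact two-round screening funnel.

    Targets are partitioned (seeded) into round-1 failures, round-2
    failures and final survivors, and per-group positive counts are drawn
    within the ranges that force each fate under the two rules:

    - round 1: methylated in >= 1 cell line and <= 2 of the round-1
      normal controls;
    - round 2: methylated in >= 3 BC samples and <= 1 of the round-2
      normal controls.
    """
    if not final_targets <= round1_survivors <= n_targets:
        raise ValueError("need final_targets <= round1_survivors <= n_targets")
    rng = np.random.default_rng(seed)
    targets = [f"T{i:03d}" for i in range(n_targets)]
    order = rng.permutation(n_targets)
    survivors_r1 = set(targets[i] for i in order[:round1_survivors])
    finals = set(targets[i] for i in order[:final_targets])

    groups_spec = [
        ("cell_line", "", n_cell_lines),
        ("normal_control", "round1", n_controls_round1),
        ("normal_control", "round2", n_controls_round2),
        ("BC", "", n_bc),
    ]
    index, group_labels, batch_labels = [], [], []
    for group, batch, n in groups_spec:
        tag = batch or group
        for i in range(n):
            index.append(f"{tag}_{i:03d}")
            group_labels.append(group)
            batch_labels.append(batch)

    def fill(n: int, k: int, r: np.random.Generator) -> np.ndarray:
        col = np.zeros(n)
        col[r.choice(n, size=k, replace=False)] = 1.0
        return col

    columns: dict[str, np.ndarray] = {}
    for t in targets:
        if t in finals:
            cell_pos = int(rng.integers(1, n_cell_lines + 1))
            c1_pos = int(rng.integers(0, 3))
            bc_pos = int(rng.integers(3, max(4, n_bc // 2 + 1)))
            c2_pos = int(rng.integers(0, 2))
        elif t in survivors_r1:
            cell_pos = int(rng.integers(1, n_cell_lines + 1))
            c1_pos = int(rng.integers(0, 3))
            if rng.random() < 0.5:  # fail round 2 on the BC side
                bc_pos = int(rng.integers(0, 3))
                c2_pos = int(rng.integers(0, 2))
            else:  # fail round 2 on the control side
                bc_pos = int(rng.integers(3, max(4, n_bc // 2 + 1)))
                c2_pos = int(rng.integers(2, n_controls_round2 + 1))
        else:
            if rng.random() < 0.5:  # fail round 1: silent in cell lines
                cell_pos = 0
                c1_pos = int(rng.integers(0, n_controls_round1 + 1))
            else:  # fail round 1: too frequent in controls
                cell_pos = int(rng.integers(1, n_cell_lines + 1))
                c1_pos = int(rng.integers(3, n_controls_round1 + 1))
            bc_pos = int(rng.integers(0, 3))
            c2_pos = int(rng.integers(0, 2))
        columns[t] = np.concatenate(
            [
                fill(n_cell_lines, cell_pos, rng),
                fill(n_controls_round1, c1_pos, rng),
                fill(n_controls_round2, c2_pos, rng),
                fill(n_bc, bc_pos, rng),
            ]
        )

    calls = pd.DataFrame(columns, index=index)
    matrix = MSPCallMatrix(
        calls,
        pd.Series(group_labels, index=index),
        pd.Series(batch_labels, index=index),
    )
    rules = [
        ScreeningRule(
            case_group="cell_line",
            control_group="normal_control",
            min_case_positives=1,
            max_control_positives=2,
            control_batch="round1",
            name="round1",
        ),
        ScreeningRule(
            case_group="BC",
            control_group="normal_control",
            min_case_positives=3,
            max_control_positives=1,
            control_batch="round2",
            name="round2",
        ),
    ]
    return matrix, rules
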