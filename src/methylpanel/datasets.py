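"""Bundled reference counts: urinary MSP methylation in a bladder-cancer
case-control cohort.

These are the printed count data of a urine-based methylation-marker study
(212 bladder-cancer patients, 149 normal controls, 41 benign urinary
lesions; a 48-patient cystoscopy comparison; 21 paired pre/post-surgery
patients; a 104-target two-round screening funnel).  They serve as worked-
example inputs: every diagnostic metric, odds ratio and concordance figure
is *computed* from these counts by the analysis modules, never stored.

``pos`` columns count methylation-positive samples among the group total;
``neg`` columns count negative samples (the study reports specificity-side
counts that way).
"""

from __future__ import annotations

import pandas as pd

from .recurrence import RecurrenceTable

__all__ = [
    "MARKER_COUNTS",
    "PANEL_COUNTS",
    "PANEL_MEMBERS",
    "RECURRENCE_TABLES",
    "CYSTOSCOPY_COMPARISON",
    "PRE_POST_SURGERY",
    "SCREENING_FUNNEL",
    "N_BC",
    "N_CONTROL",
    "N_LESION",
    "bc_positive_rates",
    "control_positive_rates",
    "lesion_positive_rates",
]

N_BC = 212
N_CONTROL = 149
N_LESION = 41

#: Per-marker counts: positives among BC cases, negatives among normal
#: controls, negatives among benign urinary lesions.
MARKER_COUNTS = pd.DataFrame(
    {
        "bc_pos": [90, 84, 57, 56, 52, 52, 33, 20, 111],
        "bc_total": N_BC,
        "control_neg": [142, 140, 145, 144, 147, 147, 146, 147, 144],
        "control_total": N_CONTROL,
        "lesion_neg": [36, 39, 40, 40, 41, 41, 41, 41, 40],
        "lesion_total": N_LESION,
    },
    index=pd.Index(
        ["VAX1", "KCNV1", "ECEL1", "TMEM26", "PROX1", "TAL1", "SLC6A20",
         "LMX1A", "CFTR"],
        name="target",
    ),
)

PANEL_MEMBERS = {
    "panel1": ("VAX1", "KCNV1", "TAL1", "PROX1"),
    "panel2": ("VAX1", "KCNV1", "TAL1", "PROX1", "CFTR"),
}

#: Any-positive panel counts (per-sample joint calls are not published, so
#: panel rows carry their own counts rather than being derivable from the
#: per-marker marginals).
PANEL_COUNTS = pd.DataFrame(
    {
        "bc_pos": [163, 188],
        "bc_total": N_BC,
        "control_neg": [132, 130],
        "control_total": N_CONTROL,
        "lesion_neg": [35, 35],
        "lesion_total": N_LESION,
    },
    index=pd.Index(["panel1", "panel2"], name="panel"),
)

#: Methylation-by-recurrence 2x2 tables among the 212 BC patients
#: (55 recurrent, 157 primary).  Exposure = marker methylated in urine;
#: event = recurrent case.
RECURRENCE_TABLES = {
    "VAX1": RecurrenceTable(
        exposed_events=32, exposed_nonevents=58,
        unexposed_events=23, unexposed_nonevents=99,
    ),
    "LMX1A": RecurrenceTable(
        exposed_events=9, exposed_nonevents=11,
        unexposed_events=46, unexposed_nonevents=146,
    ),
}

#: 48 patients with suspected uroepithelial malignancy: cystoscopy verdict
#: (reference) against the 5-marker any-positive panel.
CYSTOSCOPY_COMPARISON = {
    "ref_positive": 32,
    "ref_positive_panel_positive": 25,
    "ref_negative": 16,
    "ref_negative_panel_negative": 14,
}

#: 21 BC patients sampled before and after surgical resection
#: (transurethral resection + intravesical chemotherapy).
PRE_POST_SURGERY = {"n": 21, "pre_positive": 21, "post_positive": 2}

#: The two-round urine screening funnel over the top 104 promoter targets.
SCREENING_FUNNEL = {
    "n_targets": 104,
    "n_cell_lines": 2,
    "n_controls_round1": 8,
    "n_controls_round2": 8,
    "n_bc_round2": 18,
    "round1_min_case": 1,
    "round1_max_control": 2,
    "round2_min_case": 3,
    "round2_max_control": 1,
    "round1_survivors": 49,
    "final_targets": 8,
}


def bc_positive_rates() -> pd.Series:
    """Per-marker positive-call frequency among BC cases."""
    return MARKER_COUNTS["bc_pos"] / MARKER_COUNTS["bc_total"]


def control_positive_rates() -> pd.Series:
    """Per-marker positive-call frequency among normal controls."""
    return (
        MARKER_COUNTS["control_total"] - MARKER_COUNTS["control_neg"]
    ) / MARKER_COUNTS["control_total"]


def lesion_positive_rates() -> pd.Series:
    """Per-marker positive-call frequency among benign urinary lesions."""
    return (
        MARKER_COUNTS["lesion_total"] - MARKER_COUNTS["lesion_neg"]
    ) / MARKER_COUNTS["lesion_total"]
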