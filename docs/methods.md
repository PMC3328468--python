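# Methods

## Scope and data model

The package analyses the *outputs* of an MBD-capture methylation
experiment and of urine MSP assays: peak BED files, annotation BED
tracks, binary call matrices and 2×2 count tables.  Read alignment and
peak calling are out of scope — the pipeline starts where the peak caller
stops.  All genomic coordinates are 0-based half-open (BED native)
internally; chromosome names are compared by exact string equality.

## DMR calling and context profiling

Two peak libraries are compared with a sorted-sweep overlap engine
(per-chromosome start-sorted index with a running maximum of interval
ends).  A peak is *common* when it overlaps any peak of the other library
by at least `min_bp` bases (default 1 bp — the minimal, assumption-free
criterion; the threshold is configurable and echoed into every profile so
results are self-describing).  Library-unique peaks are the DMRs.

DMRs are tabulated down a narrowing hierarchy: all DMRs; DMRs touching a
gene body; DMRs touching both a gene body and a CpG island; promoter
DMRs.  Promoter windows are strand-aware TSS flanks, by default −2,000 bp
to +500 bp (a conventional promoter definition; configurable).  The final
promoter tier defaults to the fully nested category (gene ∩ CGI ∩
window), which guarantees the hierarchy counts are monotone
(`promoter_DMR ≤ gene_and_CGI_DMR`-side categories never exceed their
parents); `promoter_tier="cgi"` or `"window"` relax the nesting.  A DMR
touching several annotation intervals counts once per category (set
semantics).  Candidate ranking uses the BED score column (descending) by
default — the enrichment statistic peak callers emit there — with
deterministic `(chrom, start)` tie-breaks.

## Screening cascade

Calls are strictly binary (gel MSP yields presence/absence, not
intensity).  Missing calls (failed PCRs) are excluded from both numerator
and denominator of each target's counts and reported per target —
complete-case per target, conservative and auditable.  Each round
partitions the surviving targets by `case_positives ≥ min` AND
`control_positives ≤ max`; rounds compose on the survivor set, so the
audit log reproduces the funnel (e.g. 104 → 49 → 8 in the bundled
reference configuration, where round 1 requires methylation in ≥ 1 of 2
cell-line controls and ≤ 2 of 8 normal controls, and round 2 requires
≥ 3 of 18 cancer urines and ≤ 1 of a second group of 8 normal controls;
the two control cut-offs are deliberately encoded as stated, not
harmonised).  Cell lines act as the *case* group of round 1 because they
carry the tumour methylation the screen is anchored to.  The two
normal-control groups share one group label and are distinguished by a
per-sample `batch` field.

BSP methylation percentage is #M divided by the total number of scored
cytosines, pooled over all sequenced clones of a locus.

## Panel diagnostics

A panel is positive when at least `m` member calls are positive
(default `m = 1`, the any-positive rule).  A sample whose member calls
are all missing gets a missing prediction and is excluded (and counted)
rather than imputed.  Metrics follow the standard confusion-table
identities; zero-denominator metrics are flagged undefined instead of
propagating NaN.  Percentages round half-away-from-zero to two decimals.
Proportion CIs are Wilson score intervals with z = 1.96.

Binary markers have a single operating point, so discriminative ability
is summarised as AUC = (SN + SP)/2 — the area under the one-point ROC
polygon.  This is also the default objective of the exhaustive panel
search (every non-empty subset of ≤ 20 candidates; ties broken toward
fewer genes, then lexicographic member order, making the result
invariant under candidate permutation).

Group comparisons use Pearson's χ² without continuity correction, falling
back to Fisher's exact test (two-sided point-probability rule) when any
expected cell is below 5.  The pre/post-surgery comparison uses the exact
binomial McNemar test on discordant pairs.

## Recurrence statistics

The univariate methylation–recurrence association is the cross-product
odds ratio with the Woolf interval; z is fixed at 1.96 (the conventional
printed value, configurable).  On the bundled VAX1 table (32/90 methylated
vs 23/122 unmethylated recurrences) this reproduces OR 2.37, CI
1.27–4.44 — which is what a univariate logistic regression of recurrence
on a single binary exposure estimates.  A single zero cell triggers the
Haldane–Anscombe +0.5 correction (flagged); a zero margin leaves the OR
undefined (flagged).  Multivariate logistic and Cox models are out of
scope: they require per-patient covariate and follow-up data that the
bundled count tables do not contain.

Kaplan–Meier estimation uses the product-limit form with risk sets
counting all subjects whose follow-up is ≥ t (events precede censorings
at tied times).  The log-rank test uses the observed-minus-expected
statistic over the pooled event-time grid with hypergeometric variance
(standard tie handling), referred to χ²(1).

## Synthetic-data generators

All generators are pure functions of their config, including the seed;
one master seed fans out to per-stream sub-seeds via
`numpy.random.SeedSequence` so stages stay independently reproducible.

**Peaks.**  Genes (5–30 kb, random strand) and CpG islands (0.5–2 kb,
preferentially placed over TSSs with extra intergenic islands) are laid
out first.  Common peaks are placed once and copied into both libraries
with independent ≤ 10 bp jitter; unique peaks are placed so they never
touch the other library, making the realised common fraction equal the
target (default 2/3) up to rounding.  Peak lengths are truncated normal
(means 778/659 bp for the two libraries — the reported library means —
SD 200 bp, floor 50 bp; only the means are reported, so the SD and floor
are the package's choice).  Library-A-unique peaks land inside CpG
islands with probability 0.6 versus 0.05 for library B, reproducing the
tumour-side CGI/promoter enrichment the profiler is meant to detect.
Placement failure on an over-crowded genome raises an error rather than
degrading silently.

**Call matrices.**  Default group sizes are 212 cases / 149 normal
controls / 41 benign lesions with per-marker rates equal to the bundled
cohort's observed marginals.  Dependence between targets uses a shared
per-sample latent uniform: target j's call is `u < p` where `u` is the
shared latent with probability `dependence` and fresh otherwise —
marginals stay exact while pairwise correlation grows with the weight.
The true joint dependence of real markers is unknowable from published
marginals, so panel-level synthetic results are property-tested (SN/SP
monotonicity, search consistency), never asserted to match the cohort's
panel rows.

**Cohorts.**  Exposure ~ Bernoulli(90/212); the exposed event probability
solves the logistic relation implied by the baseline probability (23/122)
and the true OR (default 2.37).  Event times are exponential per arm
(means 12/18 months — chosen so most events fall inside a realistic
surveillance window; the bundled tables contain no per-patient times, so
these are simulation choices); non-events get exponential follow-up
(mean 36 months); an optional `censoring_rate` additionally censors
subjects early (at 1.0 no events are observed and downstream analyses
flag the degenerate margins).

**Funnel matrix.**  For the audit-arithmetic check, a 104-target matrix
is constructed by partitioning targets (seeded) into round-1 failures
(55), round-2 failures (41) and finals (8) and drawing per-group positive
counts inside the ranges that force each fate, then scattering the
positives over samples.  The construction demonstrates the cascade
arithmetic; it makes no claim about the real screening data.

## Calibration experiments and what they show

The acceptance script and test suite recompute, at run time:

- sweep-vs-brute-force identity of the DMR caller on 100 random instances;
- exact funnel counts (49 round-1 survivors, 8 finals) on the constructed
  matrix;
- planted-marker retention: a marker at 90% case / 0% control positivity
  survives the ≥3/≤1 screen across 20 seeds while 1%-background nulls are
  removed;
- log-rank type-I error on 2,000 null cohorts (100 per arm, common
  exponential hazard, independent exponential censoring): within
  [0.04, 0.06];
- Woolf 95% CI coverage over 1,000 cohorts of n = 212 at true OR 2.37:
  within [93%, 97%].

Problem sizes (2,000/1,000 replicates, n ≤ 3,000 peaks) keep the full
battery under a few seconds while leaving Monte-Carlo error well inside
the asserted bands.

Passing these checks shows the *machinery* is correct and calibrated
under the simulated conditions; the generators do not emulate real-data
features such as chromosome-scale peak clustering, batch effects in MSP
calls, non-exponential hazards or informative censoring, so they say
nothing about how the markers themselves would perform in a new cohort.

## Known limitations

- The published table of per-marker diagnostics contains six cells that
  are internally inconsistent with their own printed counts; the bundled
  dataset treats the counts as authoritative (each row's predictive
  values reproduce from them) and the test suite lists the discrepant
  cells explicitly.
- Published per-marker AUCs for binary calls were produced by an
  unstated ROC construction and do not equal (SN+SP)/2; they are not
  reproduced.
- The overlap rule declaring peaks "common" is not published; the
  default is ≥ 1 bp with the threshold exposed, rather than guessing a
  reciprocal-fraction rule.
- The statistic used to rank the 1,627 promoter candidates down to the
  top 104 is unstated; ranking defaults to the BED score column and the
  key is configurable.
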