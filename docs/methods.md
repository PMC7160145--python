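# Methods

## Data model and coordinates

Segments, clinical records, chromosome-arm definitions and gene
annotations are plain dataclasses (`nbsca.core_io`). All coordinates
are 0-based half-open internally. SEG input (`sample, chrom,
loc.start, loc.end, num.mark, seg.mean`) is treated as 1-based
inclusive and converted on read; BED input is passed through; the two
conversions are mutually inverse, and writing then re-reading a SEG
file reproduces the records exactly. Chromosome names are normalised
to the `chr`-prefixed form. Missing clinical values (stage, MYCN
status, survival endpoints) are explicit missing states, never
sentinel numbers, so downstream stages must drop them deliberately;
the survival stage logs how many samples it drops.

Arm extents come from a UCSC `cytoBand.txt`-dialect file: the p arm is
the union of bands whose name starts with `p`, the q arm of `q` bands,
and any gap between them belongs to neither arm. The bundled
`data/cytoband_hg19_arms.txt` is a reduced table (one euchromatic plus
one centromeric band per arm, hg19 arm boundaries) for the
chromosomes analysed by default — it defines arm extents, not a full
ideogram; any full cytoBand file can be substituted.

## SCA calling

A segment's mean log2 ratio is classified as amplification (≥ 2),
gain (≥ 0.2), neutral, loss (≤ −0.3) or homozygous deletion (≤ −2);
boundaries are inclusive toward the aberrant class, a choice that is
measure-zero in practice. Per sample, chromosome and class,
overlapping or abutting segments merge into footprints (a configurable
merge gap, default 0 bp, allows stitching across small gaps). A
footprint is segmental only if it is longer than `min_segment_bp`
(default 3 Mb) and covers less than `whole_chromosome_fraction`
(default 0.95) of its chromosome; the fraction is a package parameter
— the whole-chromosome exclusion needs an operational definition that
tolerates telomeric/centromeric gaps in band coverage. Surviving
footprints yield one call per arm they overlap by at least one base.
Amplification subsumes gain and homozygous deletion subsumes loss at
the arm level, so a sample "has 19p loss" iff it carries a loss-class
call of either strength on 19p. For deposited aberration calls that
are already thresholded, `precalled=True` classifies by the sign of
the log2 ratio only.

## Age-cut-off enrichment scan

Patients aged ≤ 18 months are excluded (their disease is biologically
distinct and would otherwise dominate the younger stratum). For each
yearly cut-off k in {3,…,10}, a 2×2 table of (age > k vs age ≤ k) ×
(SCA present vs absent) is tested two-sided: Pearson chi-square
without continuity correction, switching to the Fisher exact test
when **any** expected cell count is below 5 (the strictest reading of
the usual rule; the switch already guards small counts, so Yates
correction would double-penalise). The Fisher two-sided p is the
probability mass of all tables with the observed margins whose
probability does not exceed the observed table's, with a 1e-7
relative tie tolerance — the test suite verifies this against
exhaustive hypergeometric enumeration for every table with total
≤ 40. A table whose minimum expected count is exactly 5.0 takes the
chi-square branch.

Per-cohort p-values are combined by Stouffer's method on
direction-signed z-scores, zᵢ = dᵢ·Φ⁻¹(1 − pᵢ/2) with dᵢ the sign of
the log odds ratio, Z = Σwᵢzᵢ/√Σwᵢ² (unweighted by default; √n
weights available); combining two-sided p-values without the
direction would reward discordant cohorts. The combined p is
Bonferroni-corrected with m = the number of cut-offs actually tested
by default; m is overridable because the correction factor used in
prior work on this question is ambiguous (a printed corrected/combined
ratio implies m = 10 while 3..10 yields 8 cut-offs), and the worked
arithmetic in the acceptance suite uses m = 10 explicitly. The scan
reports every per-cut-off table, test choice, combined and corrected
p, and the lowest cut-off with corrected p < α (default 0.05).

A structural caveat, demonstrated by the simulation tests: when the
true prevalence steps at age T, the older group at any cut-off k < T
still contains every patient older than T, so sub-threshold cut-offs
carry attenuated but real signal. With cohorts of a few hundred
patients and a 10%→35% step, the scan's lowest significant cut-off
equals the planted T in roughly half of replicates and falls 1–3
years below it otherwise; it essentially never lands above T. The
scan localises an upper bound on the threshold sharply, the threshold
itself only approximately.

## Minimally deleted region

Every maximal contiguous deleted interval of every affected sample
(provenance segments clipped to the arm and unioned) is an MDR
candidate; the MDR is the shortest, with deterministic tie-breaking
(smallest start, then sample id). Recurrence counts samples whose
footprint fully **contains** the MDR — containment, not mere overlap,
is the strictest reading consistent with recurrence fractions below
1, and an overlap-fraction mode can be added for sensitivity analysis.
Gene counting over the MDR uses ≥ 1 bp overlap with half-open
intervals (a gene abutting the MDR end is not counted).

## Co-occurrence

For two SCAs the 2×2 presence table is tested with the same two-sided
Fisher exact test; the odds ratio is ad/bc (∞ when bc = 0 and ad > 0,
0 when ad = 0 and bc > 0, undefined when both vanish). A pair is
mutually exclusive when p < α and OR < 1, co-occurring when p < α and
OR > 1, independent otherwise. No multiple-testing correction is
applied across pairs by default (few pairs are tested and the
assessment is descriptive); a Bonferroni flag exists.

## Survival

Kaplan–Meier curves use the product-limit estimator with tied event
times grouped; the standard error is Greenwood's,
se(t) = S(t)·√Σ dᵢ/(nᵢ(nᵢ−dᵢ)), reported as 0 once the curve reaches
0. "X% ± Y%" summaries are the estimate ± one Greenwood SE in
percent. The two-group log-rank statistic is referred to a 1-df
chi-square. The multivariate Cox model (partial likelihood, Efron tie
handling, Newton iteration — via lifelines) uses the target loss,
MYCN amplification and INSS stage dichotomised 4 vs {1,2,3,4S};
constant covariates are dropped with a warning, and non-convergence
(including complete separation) yields a flagged fit rather than
silent output. The test suite checks the Cox score test against the
log-rank statistic (they coincide for a binary covariate without
ties) and hazard-ratio recovery on simulated data (mean log-HR bias
under 5% at n = 500 over 200 replicates). Times are in years
throughout; the survival evaluation point defaults to 5 years.

## Synthetic cohorts

The generator (`nbsca.synthetic_data`) emulates the structure of the
two-cohort study design. Defaults, chosen once from the published
cohort descriptions: a discovery-style cohort of 556 tumours with
19p-loss prevalence 10% below and 20% above the 6-year threshold and
8.5% of patients above it, and a validation-style cohort of 208 with
19%/35% and 13.5% above; 10–15% of patients are younger than 18
months so the eligibility filter is exercised. Ages are uniform
within the three strata (≤1.5, (1.5, 6], (6, 18]). Every 19p-loss
carrier receives one deletion on 19p whose breakpoints are uniform
subject to containing a fixed 4098-kb core interval; one designated
carrier (preferentially one older than the threshold) gets exactly
the core, planting a known MDR — a consequence is that the planted
recurrence is ~100% of carriers, unlike real cohorts where distal
breakpoints truncate the region. 1q gain is hard-exclusive with 19p
loss (drawn only among non-carriers, 15%/35% by age stratum); 1p loss
(40%/20%) and 2p gain (35%/15%) are independent of it. MYCN
amplification (30%) adds a ~1-Mb focal amplicon, deliberately below
the segmental size filter; stage 4 prevalence is 60%. Survival is
exponential with multiplicative hazards (baseline 0.22/y for OS,
0.30/y for EFS; hazard ratios 1.6 for loss on OS, 1.2 on EFS, 1.6 for
MYCN, 1.8 for stage 4) under uniform censoring on 6–14 years — set so
that five-year OS in the older stratum is ≈14% without and ≈5% with
the loss, with a deliberately weak EFS effect. All draws flow through
one seeded generator in a fixed order, so a seed reproduces a cohort
byte for byte.

What the generator does **not** emulate: genome-wide CNV landscapes,
probe-level noise, platform differences between array generations,
gradual (rather than step) age-prevalence trends, and correlated
stage/age structure. Passing tests therefore certify the statistical
machinery against the generative model, not the biology of any real
cohort.

## Pipeline and numerical choices

`run_all` executes calling → scan → (restricted to the stratum older
than the discovered cut-off, or a fixed one) MDR, co-occurrence and
survival, writing TSV/JSON reports that rerun byte-identically. Any
stage failure aborts with the stage name. Degenerate scan tables
(an empty margin) return p = 1 with direction 0 rather than erroring;
p = 0 inputs to Stouffer are rejected (infinite z); Bonferroni caps
at 1. Simulation-based tests use a few hundred to a few thousand
replicates at cohort sizes of 200–2000 — sizes at which the binomial
and asymptotic approximations they check are informative while the
whole suite stays fast.
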