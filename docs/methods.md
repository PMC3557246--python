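# Methods

`asecall` implements the analytics of a quantitative allele-specific
expression (ASE) assay built on single-nucleotide primer extension (SNuPE)
read out by MALDI-TOF mass spectrometry, together with cohort-level ASE
calling and allele-specific methylation (ASM) analysis. This note records
the models, the defaults that matter, and the design choices made where the
underlying procedure was open.

## Allelic quantification and gDNA correction

A SNuPE reaction at a heterozygous exonic SNP yields two mass peaks whose
heights `h_ref`, `h_alt` are proportional to allele abundance. The basic
statistic is the reference-allele fraction `f = h_ref / (h_ref + h_alt)`.
Technical replicates (typically 4–6) are aggregated by the mean of the
per-replicate fractions, with dispersion reported as the sample SD in
percentage points; replicates below a configurable total-intensity floor
(default 0, i.e. off) are dropped as QC failures. Aggregating fractions
rather than pooling intensities keeps the replicate SD interpretable as a
per-measurement precision figure.

Detection efficiency differs between the two extension products, so a raw
cDNA fraction is biased. In a heterozygote the genomic DNA carries the two
alleles exactly 1:1, so the same sample's gDNA fraction `g` measures the
bias directly. We correct by odds normalization,

    f_corr = (f/g) / (f/g + (1 - f)/(1 - g)),

the unique form that (a) cancels a multiplicative per-allele gain exactly —
if the assay reports `γ·p / (γ·p + (1-p))` for truth `p`, correcting with
the gDNA measurement under the same gain returns `p` — and (b) maps
`f = g` to 0.5 while preserving the monoallelic endpoints 0 and 1. Samples
whose gDNA fraction falls outside the heterozygosity band [0.3, 0.7]
(configurable) are warned about and excluded from cohort calling as
non-informative.

Assay accuracy is validated on mixing standards over the ratio grid
50:1, 25:1, 10:1, 7:1, 5:1, 2:1, 1:1, …, 1:50 (expected fraction
`r/(1+r)`); calibration is a least-squares line of measured vs expected
fraction with the squared Pearson correlation as the accuracy figure.
Regression is done in fraction space rather than log-ratio space because
fractions are bounded and are what the downstream callers consume.
Single-clone sequencing tallies are summarised as a binomial fraction with
a Clopper–Pearson 95% interval.

## Cohort-level ASE calling

Input is one gDNA-corrected cDNA fraction per informative sample, labelled
case or control. Two complementary callers are provided.

**Huber-M α-outlier region.** Robust location μ̂ and scale σ̂ are fitted to
the case fractions by Huber's proposal-2 joint iteration: observations are
winsorized at `k` scale units (default k = 1.345, 95% efficiency at the
normal model), location and scale are updated simultaneously, and the scale
equation carries the normal-consistency constant `E[min(|Z|, k)²]` with an
`n − 1` denominator so that `k → ∞` recovers the sample mean and SD
exactly. Initialisation is the median and normalized MAD; convergence
tolerance 1e-8, at most 100 iterations; a constant sample returns scale 0
with a degeneracy flag. The α-outlier region is the complement of the
central `1 − α` mass of Normal(μ̂, σ̂²): limits `μ̂ ± z_{1−α/2}·σ̂` with the
plain per-observation quantile (no sample-size "somewhere-outlier"
adjustment), α defaulting to 0.05. Estimating on cases (not controls)
makes the region describe the case cohort's own core, which is what the
robust estimators protect against the planted outliers.

**Bidirectional Youden-index outlier cutoffs.** ASE shifts can favour
either allele, so one cutoff is sought below and one above the robust
centre of the case distribution (the case median). For a candidate cutoff
`c` at distance `t = |c − centre|`, the direction's Youden index is

    J(c) = [fraction of cases beyond c in that direction]
         + [fraction of controls within centre ± t] − 1,

maximized over candidates at midpoints of adjacent distinct pooled values
on that side of the centre; ties are broken toward the candidate farthest
from the centre (maximally conservative flagging) and a direction whose
best J is ≤ 0 gets a ±∞ sentinel (no calls). Measuring control specificity
on the *folded* deviation from the case centre — rather than one-sided
against the raw fractions — is deliberate: case and control cohorts can
differ slightly in location (here medians 0.40 vs 0.43) without any sample
being an outlier, and a plain two-sample Youden scan on the raw fractions
would park the cutoff inside that location shift and flag half the cohort.
The folded form keeps the procedure an *outlier* detector centred on the
case distribution, which also means a pure location shift with no outliers
returns sentinels rather than a separating cutoff. Group-level location
and spread differences are instead reported by the screening tests below.

Either caller flags every sample strictly outside `(lower, upper)`; a
sample exactly on a cutoff is negative. No multiple-testing correction is
applied in calling. Screening statistics are the two-sided Mann-Whitney U
test (location) and a two-sided variance-ratio F-test with the larger
variance in the numerator (spread); the F-test is reported as missing for a
constant group.

## Methylation and ASM

Mass-spectrometric per-CpG-unit methylation percentages are normalized
against mixing standards at 0/20/40/60/80/100% methylation by fitting
`measured = a·nominal + b` and inverting per CpG unit, clamped to [0, 100]
with a warning. A single linear gain/offset per amplicon is the simplest
model the six standards can identify.

Bisulfite-clone matrices (clones × CpG calls in {M, U, missing}) are split
by the phasing-SNP allele carried by each clone; clones with an unknown
allele are excluded and counted, and a matrix with no informative allele at
all raises an error (no allelic separation possible). Region methylation
over a closed window (default +58..+263 relative to the TSS, with TSS = +1
and no position 0) pools all non-missing calls across clones:
`100 · #M / (#M + #U)`. Pooling rather than averaging per-clone means keeps
clones with many missing calls from dominating, and makes the full-matrix
value the call-count-weighted mix of the two allele splits. Group
methylation comparisons use the two-sided Mann-Whitney test.

ASM-SNuPE genotypes the phasing SNP separately inside
methylated-specific and unmethylated-specific bisulfite amplicons. A
control CpG guards amplification specificity: the M-amplicon must read
≥ 0.9 methylated and the U-amplicon ≤ 0.1 (purity threshold 0.9,
configurable). Given a clean control, ASM is positive when the
reference-allele fractions of the two amplicons differ by more than the
margin 0.3 (configurable); with a failed control the call is not evaluable.

## Synthetic data: what it emulates and what it does not

The noise model is pure binomial template sampling: each replicate draws
the reference-allele count from Binomial(copies, p), optionally scaled by
deterministic per-allele gains. Binomial sampling alone reproduces the
assay's published sensitivity envelope (mean 4-replicate SD ≈ 0.08
percentage points at 300,000 template copies and ≈ 2.7 at 300 copies,
under the respective bounds of 2 and 6.6), so no additive detector noise is
included by default. The gain term exists to exercise the gDNA correction
end to end.

Two reference cohorts fix the calling conditions. Cohort A (seed 42):
63 controls ~ N(0.43, 0.03²) truncated to [0.33, 0.53], 103 balanced cases
~ N(0.40, 0.04²) truncated to [0.31, 0.52], plus 9 planted low cases
~ U(0.08, 0.22) and 8 planted high cases ~ U(0.60, 0.80). Cohort B
(seed 43): 110 balanced cases ~ N(0.40, 0.04²) truncated to [0.32, 0.50]
plus 5 + 5 planted cases ~ U(0.05, 0.15) ∪ U(0.70, 0.85). Means and
medians mirror the case/control centres the assay observes in practice;
planted ranges are disjoint from the cores. Clone matrices use per-CpG
methylation probabilities 0.83 (repressed allele) and 0.323 (active
allele) with a 5% missing-call rate by default. The demethylation model
makes each allele's expression proportional to `1 − methylation` and
multiplies methylation by `1 − efficiency` under treatment, so full
efficiency restores exactly 0.5 and zero efficiency models withdrawal.

What the generators do *not* emulate: PCR amplification kinetics, raw mass
spectra and peak picking, bisulfite conversion failure beyond the missing
rate, linkage between neighbouring CpGs (calls are independent given the
allele), and biological covariates. Passing tests on these fixtures
demonstrate the estimators' behaviour under the stated sampling models,
not performance on measured spectra.

## Known limitations and numerical notes

* On cohort A the Youden caller recovers exactly the 17 planted cases with
  no control flagged (cutoffs 0.270/0.549). Recovery is exact at the
  cohort's defining seed but is not guaranteed for arbitrary re-draws: the
  balanced-case truncation bounds reach ≈ 3 case-SDs above the case
  centre, so occasionally a balanced case's deviation exceeds every
  control's and is flagged as an 18th positive.
* On cohort B the α-outlier region structurally clips the balanced core:
  the Huber scale of the truncated case distribution is ≈ 0.043, putting
  the upper limit (≈ 0.487) just inside the balanced truncation bound
  0.50. All 10 planted cases are always recovered (sensitivity 1), but on
  average ~1 balanced case lands beyond the limit; at seed 43 two do, so
  the caller reports 12/120 (10.0%). Exact recovery would require a
  case-core spread compatible with a Huber scale above ≈ 0.051, which the
  cohort's stated parameters do not produce. This is a property of the
  fixed study conditions, not of the estimator.
* The α-outlier false-positive rate on pure-null normal cohorts (n = 120)
  matches α = 5% within Monte-Carlo error (checked over 300 cohorts).
* Fractions are kept at full precision internally and in machine-readable
  tables (`%.17g`, round-trip safe); report percentages are rounded to one
  decimal.
* Problem sizes: sensitivity simulations use 1,000 runs of 4 replicates;
  the null false-positive check uses 300 cohorts of 120; the Youden search
  is exhaustive over all candidate midpoints (O(n²) worst case, trivial at
  cohort sizes of a few hundred).
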