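# asecall

Quantitative allele-specific expression (ASE) and allele-specific
methylation (ASM) calling from SNuPE/MALDI-TOF peak intensities.

## The problem

A gene can be transcribed unevenly from its two alleles even in normal
(germline) cells; for tumor-suppressor genes such as *DAPK1* in chronic
lymphocytic leukemia this allelic imbalance is a candidate predisposition
mechanism. ASE is measured at a heterozygous exonic SNP: a single-nucleotide
primer-extension (SNuPE) product is read out by MALDI-TOF mass spectrometry
as two peaks, one per allele, and the reference-allele fraction
`f = h_ref / (h_ref + h_alt)` quantifies the transcript ratio. Because the
two extension products are detected with different efficiencies, the cDNA
fraction is corrected against the same sample's genomic DNA (1:1 in a
heterozygote by construction) via odds normalization

    f_corr = (f/g) / (f/g + (1-f)/(1-g)).

At the cohort level, ASE-positive samples are called as outliers of the
corrected-fraction distribution by two complementary methods:

* **bidirectional Youden-index cutoffs** — per direction around the robust
  case centre, the cutoff maximizing J = sensitivity + specificity − 1
  against the control cohort;
* **α-outlier region** — robust location/scale (μ̂, σ̂) from Huber's
  M-estimator (proposal 2, k = 1.345) on the case fractions, flagging
  samples outside μ̂ ± z₁₋α/₂·σ̂ (α = 5%).

The methylation side quantifies promoter methylation per CpG unit
(normalized against 0–100% mixing standards), splits bisulfite-sequenced
clones by a phasing SNP to score allele-specific methylation over a
positional window, and calls ASM from methylation-specific genotyping
(ASM-SNuPE) gated by a CpG specificity control. Synthetic-data generators
(binomial template sampling, per-allele gain bias, planted-outlier cohorts,
allele-phased clone matrices, demethylation rebalancing) provide every
input the pipeline needs. See `docs/methods.md` for the full model
description.

## Worked example

```bash
asecall simulate cohort --fixture A --out cohort.tsv
asecall call --cohort cohort.tsv --method both --alpha 0.05 --out calls.tsv
```

prints

```
wrote 183 samples (17 planted ASE) to cohort.tsv
youden: cutoffs [0.2701, 0.5489], positive cases 17/120
alpha_outlier: cutoffs [0.3043, 0.4857], positive cases 17/120
screening: Mann-Whitney p = 2.862e-08, F-test p = 3.28e-25
```

Cohort A contains 63 controls, 103 balanced cases and 17 planted
bidirectional ASE cases. The Youden caller places its cutoffs in the gaps
between the balanced core and the planted outliers and flags exactly the
17 planted cases (14.2% of 120) and no control; the screening tests report
the case/control location shift (medians 0.40 vs 0.43) and the
outlier-driven variance inflation. The same computations are available as
library calls (`asecall.call_ase`, `asecall.youden_cutoffs`,
`asecall.huber_m`, ...), and `asecall run --config config.json` executes
the full peaks → fractions → correction → calling pipeline from a TSV of
raw peak intensities.

The numbered drivers under `analysis/` run the complete study on synthetic
data and write their tables to `results/`:

```bash
python analysis/01_validate_assay.py            # calibration + sensitivity
python analysis/02_cohort_calling.py            # cohorts A and B
python analysis/03_cell_line_ase.py             # single-sample examples
python analysis/04_allele_specific_methylation.py
```

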