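"""Synthetic data with the statistical structure the assay assumes.

The generators cover every input of the pipeline so all stages can be
exercised without measured data:

* binomial template-sampling noise at a stated template copy number, with an
  optional deterministic per-allele detection gain (the bias the gDNA
  correction must cancel),
* plasmid-style mixing standard series over a ratio grid,
* case/control cohorts of gDNA-corrected allelic fractions: a control cohort
  tightly distributed around balance, a balanced case core, and planted
  bidirectional ASE cases in separated outlier ranges,
* bisulfite-clone matrices with per-allele methylation probabilities, and
* a deterministic two-allele expression model for demethylating-agent (DAC)
  rebalancing of allelic expression.

Two reference cohorts are exported: ``FIXTURE_A`` (63 controls, 103 balanced
cases, 9 + 8 planted ASE cases, seed 42) sized for the Youden caller and
``FIXTURE_B`` (110 balanced + 10 planted cases, seed 43) for the
alpha-outlier caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ase_calling import CohortRecord, CohortTable, Group
from .methylation import (
    BisulfiteCloneMatrix,
    Clone,
    CloneCall,
    PhasedAllele,
)
from .quantify import (
    Analyte,
    PeakPairMeasurement,
    StandardSeries,
    StandardSeriesEntry,
)

#: Mixing-ratio grid of the plasmid/gDNA standards (copies ref : copies alt).
STANDARD_RATIOS = (50, 25, 10, 7, 5, 2, 1, 1 / 2, 1 / 5, 1 / 7, 1 / 10,
                   1 / 25, 1 / 50)


@dataclass(frozen=True)
class NoiseModel:
    """Binomial template sampling plus deterministic per-allele gain."""

    copies: int
    gain_ref: float = 1.0
    gain_alt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.gain_ref <= 0 or self.gain_alt <= 0:
            raise ValueError("per-allele gains must be positive")


@dataclass(frozen=True)
class PlantedGroup:
    n: int
    fraction_range: tuple[float, float]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated case/control cohort of allelic fractions."""

    n_controls: int
    n_balanced_cases: int
    planted: list[PlantedGroup]
    control_dist: tuple[float, float]       # (mean, sd)
    control_bounds: tuple[float, float]     # truncation interval
    balanced_dist: tuple[float, float]
    balanced_bounds: tuple[float, float]
    seed: int


@dataclass(frozen=True)
class SimulatedCohort:
    table: CohortTable
    planted_ids: list[str]


FIXTURE_A = CohortSpec(
    n_controls=63,
    n_balanced_cases=103,
    planted=[PlantedGroup(9, (0.08, 0.22)), PlantedGroup(8, (0.60, 0.80))],
    control_dist=(0.43, 0.03),
    control_bounds=(0.33, 0.53),
    balanced_dist=(0.40, 0.04),
    balanced_bounds=(0.31, 0.52),
    seed=42,
)

FIXTURE_B = CohortSpec(
    n_controls=0,
    n_balanced_cases=110,
    planted=[PlantedGroup(5, (0.05, 0.15)), PlantedGroup(5, (0.70, 0.85))],
    control_dist=(0.43, 0.03),
    control_bounds=(0.33, 0.53),
    balanced_dist=(0.40, 0.04),
    balanced_bounds=(0.32, 0.50),
    seed=43,
)


def simulate_measurement(
    true_fraction: float, nm: NoiseModel, n_replicates: int,
    sample_id: str = "SIM", snp_id: str = "rs0",
    analyte: Analyte = Analyte.CDNA,
) -> list[PeakPairMeasurement]:
    """Replicate peak pairs from binomial template sampling.

    Each replicate draws the reference-allele template count from
    Binomial(copies, true_fraction); peak intensities are the gain-weighted
    allele counts.  Deterministic for a fixed ``nm.seed``.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    rng = np.random.default_rng(nm.seed)
    counts_ref = rng.binomial(nm.copies, true_fraction, size=n_replicates)
    return [
        PeakPairMeasurement(
            sample_id=sample_id, snp_id=snp_id, analyte=analyte,
            replicate=i + 1, allele_ref="G", allele_alt="A",
            intensity_ref=float(nm.gain_ref * k),
            intensity_alt=float(nm.gain_alt * (nm.copies - k)),
        )
        for i, k in enumerate(counts_ref)
    ]


def simulate_standard_series(
    ratios, nm: NoiseModel, n_replicates: int, snp_id: str = "rs1056719"
) -> StandardSeries:
    """Mixing standard series with measured fractions under the noise model."""
    entries = []
    child_seeds = np.random.SeedSequence(nm.seed).generate_state(
        len(list(ratios)) * n_replicates
    )
    i = 0
    for r in ratios:
        if r <= 0:
            raise ValueError("mixing ratios must be positive")
        expected = r / (1.0 + r)
        for _ in range(n_replicates):
            rep_nm = NoiseModel(copies=nm.copies, gain_ref=nm.gain_ref,
                                gain_alt=nm.gain_alt,
                                seed=int(child_seeds[i]) % (2**31))
            i += 1
            (m,) = simulate_measurement(expected, rep_nm, 1, snp_id=snp_id)
            measured = m.intensity_ref / (m.intensity_ref + m.intensity_alt)
            entries.append(StandardSeriesEntry(
                nominal_ratio=float(r),
                expected_fraction=expected,
                measured_fraction=measured,
                copies_total=nm.copies,
            ))
    return StandardSeries(snp_id=snp_id, entries=entries)


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Case/control cohort with planted bidirectional ASE outliers.

    Controls and the balanced case core are truncated normals; planted
    samples are uniform in their (disjoint) outlier ranges.  Planted sample
    ids are reported alongside the table so recovery can be scored.
    """
    lo_core = min(spec.balanced_bounds[0], spec.control_bounds[0]) \
        if spec.n_controls else spec.balanced_bounds[0]
    hi_core = max(spec.balanced_bounds[1], spec.control_bounds[1]) \
        if spec.n_controls else spec.balanced_bounds[1]
    for pg in spec.planted:
        if pg.fraction_range[0] < hi_core and pg.fraction_range[1] > lo_core:
            raise ValueError(
                f"planted range {pg.fraction_range} overlaps the cohort core "
                f"[{lo_core}, {hi_core}]"
            )
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    ctrl = _truncated_normal(rng, *spec.control_dist, *spec.control_bounds,
                             spec.n_controls)
    for i, f in enumerate(ctrl, start=1):
        records.append(CohortRecord(f"CTRL-{i:03d}", Group.CONTROL, float(f)))
    bal = _truncated_normal(rng, *spec.balanced_dist, *spec.balanced_bounds,
                            spec.n_balanced_cases)
    for i, f in enumerate(bal, start=1):
        records.append(CohortRecord(f"CASE-{i:03d}", Group.CASE, float(f)))
    planted_ids = []
    i = spec.n_balanced_cases
    for pg in spec.planted:
        for f in rng.uniform(*pg.fraction_range, size=pg.n):
            i += 1
            sid = f"CASE-{i:03d}"
            records.append(CohortRecord(sid, Group.CASE, float(f)))
            planted_ids.append(sid)
    return SimulatedCohort(table=CohortTable(records), planted_ids=planted_ids)


def simulate_bisulfite_clones(
    n_clones_per_allele: int,
    p_meth_allele_a: float,
    p_meth_allele_b: float,
    n_cpgs: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    positions: list[int] | None = None,
) -> BisulfiteCloneMatrix:
    """Clone x CpG matrix with allele-specific methylation probabilities.

    Each clone carries a phasing-SNP allele; each CpG is independently
    methylated with the allele's probability and dropped to missing with
    ``missing_rate``.  Default positions span +58..+263, the window over
    which region methylation is scored.
    """
    for p in (p_meth_allele_a, p_meth_allele_b, missing_rate):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if positions is None:
        positions = list(np.linspace(58, 263, n_cpgs).round().astype(int))
    rng = np.random.default_rng(seed)
    clones = []
    for allele, p_meth in ((PhasedAllele.A, p_meth_allele_a),
                           (PhasedAllele.B, p_meth_allele_b)):
        for j in range(n_clones_per_allele):
            calls = {}
            for pos in positions:
                if rng.random() < missing_rate:
                    calls[pos] = CloneCall.MISSING
                elif rng.random() < p_meth:
                    calls[pos] = CloneCall.METH
                else:
                    calls[pos] = CloneCall.UNMETH
            clones.append(Clone(f"{allele.value}-{j + 1:02d}", allele, calls))
    return BisulfiteCloneMatrix(clones)


def simulate_dac_rebalancing(
    methylation_a: float,
    methylation_b: float,
    demethylation_efficiency: float,
    baseline_expression: float = 1.0,
) -> dict[str, float]:
    """Allelic expression fractions before/after demethylating treatment.

    Expression of each allele is proportional to
    ``baseline_expression * (1 - methylation)``; a DNA methyltransferase
    inhibitor (DAC) multiplies each allele's methylation by
    ``1 - demethylation_efficiency``.  Full efficiency therefore restores a
    balanced 0.5/0.5 output; zero efficiency models withdrawal/recovery.
    Returns ``fraction_before`` and ``fraction_after`` for allele A.
    """
    for v in (methylation_a, methylation_b, demethylation_efficiency):
        if not 0.0 <= v <= 1.0:
            raise ValueError("inputs must be in [0, 1]")
    if baseline_expression <= 0:
        raise ValueError("baseline expression must be positive")

    def frac(m_a: float, m_b: float) -> float:
        e_a = baseline_expression * (1.0 - m_a)
        e_b = baseline_expression * (1.0 - m_b)
        if e_a + e_b == 0:
            raise ValueError("no expression: both alleles fully silenced")
        return e_a / (e_a + e_b)

    eff = demethylation_efficiency
    return {
        "fraction_before": frac(methylation_a, methylation_b),
        "fraction_after": frac(methylation_a * (1 - eff),
                               methylation_b * (1 - eff)),
    }
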