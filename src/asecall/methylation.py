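"""Promoter methylation quantification and allele-specific methylation (ASM).

Covers three layers of the methylation analysis:

* standards-based normalization of mass-spectrometric per-CpG-unit
  methylation percentages (a linear gain/offset fitted to mixing standards
  at 0/20/40/60/80/100% methylation and inverted per CpG unit),
* bisulfite-clone matrices (clones x CpG calls in {M, U, missing}) split by
  a heterozygous phasing SNP, with pooled region-level methylation, and
* the ASM-SNuPE assay: quantitative genotyping inside separately amplified
  methylated and unmethylated bisulfite amplicons, gated by a CpG
  specificity control.

CpG and SNP coordinates are integer offsets relative to the transcription
start site (TSS = +1, no position 0); windows are closed intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import AlleleSeparationError, CalibrationError
from .quantify import PeakPairMeasurement, allelic_fraction


@dataclass(frozen=True)
class CpGUnit:
    position: int            # offset relative to TSS (TSS = +1)
    raw_pct: float
    norm_pct: float | None = None


@dataclass(frozen=True)
class MethylationProfile:
    amplicon_id: str
    cpg_units: list[CpGUnit]


@dataclass(frozen=True)
class MethylationStandards:
    """Measured response of mixed methylation standards (nominal % -> measured %)."""

    entries: list[tuple[float, float]]  # (nominal_pct, measured_pct)


class CloneCall(str, Enum):
    METH = "M"
    UNMETH = "U"
    MISSING = "."


class PhasedAllele(str, Enum):
    A = "A"
    B = "B"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Clone:
    clone_id: str
    allele: PhasedAllele
    cpg_calls: dict[int, CloneCall]  # position -> call


@dataclass(frozen=True)
class BisulfiteCloneMatrix:
    clones: list[Clone]

    @property
    def positions(self) -> list[int]:
        return sorted(self.clones[0].cpg_calls) if self.clones else []


@dataclass(frozen=True)
class AsmSnupeResult:
    geno_fraction_meth: float     # ref-allele fraction in the M-specific amplicon
    geno_fraction_unmeth: float   # ref-allele fraction in the U-specific amplicon
    control_ok: bool
    asm_positive: bool | None     # None when the control failed


def normalize_methylation(
    profile: MethylationProfile, standards: MethylationStandards
) -> MethylationProfile:
    """Invert the linear assay distortion estimated from mixing standards.

    Fits measured = a * nominal + b by least squares over the standards and
    applies norm = (raw - b) / a per CpG unit, clamped to [0, 100] with a
    warning on clamping.
    """
    nominal = np.array([e[0] for e in standards.entries], dtype=float)
    measured = np.array([e[1] for e in standards.entries], dtype=float)
    if np.unique(nominal).size < 2:
        raise CalibrationError("methylation standards span fewer than 2 levels")
    a, b = np.polyfit(nominal, measured, 1)
    if abs(a) < 1e-6:
        raise CalibrationError("uninformative standards: near-zero slope")
    units = []
    for u in profile.cpg_units:
        norm = (u.raw_pct - b) / a
        if norm < 0.0 or norm > 100.0:
            warnings.warn(
                f"normalized methylation {norm:.1f}% at {u.position:+d} "
                "clamped to [0, 100]",
                stacklevel=2,
            )
            norm = min(100.0, max(0.0, norm))
        units.append(CpGUnit(position=u.position, raw_pct=u.raw_pct,
                             norm_pct=float(norm)))
    return MethylationProfile(amplicon_id=profile.amplicon_id, cpg_units=units)


def split_clones_by_allele(
    m: BisulfiteCloneMatrix,
) -> tuple[BisulfiteCloneMatrix, BisulfiteCloneMatrix, int]:
    """Partition clones by their phasing-SNP allele.

    Returns the allele-A matrix, the allele-B matrix and the number of
    clones excluded for an unknown allele call.

    Raises
    ------
    AlleleSeparationError
        When no clone carries an informative allele call (no heterozygous
        SNP available for allelic separation).
    """
    a = [c for c in m.clones if c.allele is PhasedAllele.A]
    b = [c for c in m.clones if c.allele is PhasedAllele.B]
    excluded = len(m.clones) - len(a) - len(b)
    if not a and not b:
        raise AlleleSeparationError(
            "no informative SNP for allelic separation: all clone alleles unknown"
        )
    return BisulfiteCloneMatrix(a), BisulfiteCloneMatrix(b), excluded


def region_methylation(
    m: BisulfiteCloneMatrix, start: int, end: int
) -> float:
    """Percent methylated CpG calls pooled over a closed positional window.

    All non-missing calls from all clones at positions in [start, end] are
    pooled; the value is 100 * (#M) / (#M + #U).  Pooling (rather than a
    mean of per-clone means) keeps clones with many missing calls from
    dominating.
    """
    n_meth = 0
    n_called = 0
    for clone in m.clones:
        for pos, call in clone.cpg_calls.items():
            if start <= pos <= end and call is not CloneCall.MISSING:
                n_called += 1
                n_meth += call is CloneCall.METH
    if n_called == 0:
        raise ValueError(
            f"no covered CpG with a call in window [{start:+d}, {end:+d}]"
        )
    return 100.0 * n_meth / n_called


def compare_group_methylation(
    group1: Sequence[float], group2: Sequence[float]
) -> dict[str, float]:
    """Two-sided Mann-Whitney comparison of methylation levels.

    Returns ``p``, ``median1`` and ``median2``.  With constant pooled data
    the test is uninformative and p = 1 is returned with a warning.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.ptp(np.concatenate([g1, g2])) == 0:
        warnings.warn("constant pooled methylation data", stacklevel=2)
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue)
    return {"p": p, "median1": float(np.median(g1)),
            "median2": float(np.median(g2))}


def asm_snupe(
    meth_fraction_pair: PeakPairMeasurement,
    unmeth_fraction_pair: PeakPairMeasurement,
    control_cpg: dict[str, float],
    purity_threshold: float = 0.9,
    asm_margin: float = 0.3,
) -> AsmSnupeResult:
    """Call allele-specific methylation from methylation-specific genotyping.

    The SNP is genotyped separately in the methylated-specific and
    unmethylated-specific bisulfite amplicons.  A control CpG inside each
    amplicon guards against cross-amplification: the M-specific amplicon
    must read >= ``purity_threshold`` methylated at the control site and the
    U-specific amplicon <= 1 - ``purity_threshold``.  Given a clean control,
    ASM is called when the reference-allele fraction differs between the two
    amplicons by more than ``asm_margin``.
    """
    f_meth = allelic_fraction(meth_fraction_pair)
    f_unmeth = allelic_fraction(unmeth_fraction_pair)
    control_ok = (
        control_cpg["meth_amplicon_m_frac"] >= purity_threshold
        and control_cpg["unmeth_amplicon_m_frac"] <= 1.0 - purity_threshold
    )
    positive = (abs(f_meth - f_unmeth) > asm_margin) if control_ok else None
    return AsmSnupeResult(
        geno_fraction_meth=f_meth,
        geno_fraction_unmeth=f_unmeth,
        control_ok=control_ok,
        asm_positive=positive,
    )
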