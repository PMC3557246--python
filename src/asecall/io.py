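"""TSV/JSON readers and writers plus the end-to-end pipeline.

All tables are UTF-8, tab-separated, with a header row and ``.`` for
missing values; machine outputs keep full float precision while report
percentages are rounded to one decimal.  Readers validate the schema and
report malformed rows with their line numbers.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .ase_calling import (
    CallMethod,
    CohortRecord,
    CohortTable,
    Group,
    call_ase,
    screening_tests,
)
from .errors import NonInformativeGenotypeError, SchemaError
from .methylation import (
    BisulfiteCloneMatrix,
    Clone,
    CloneCall,
    MethylationProfile,
    MethylationStandards,
    CpGUnit,
    PhasedAllele,
)
from .quantify import (
    AllelicFraction,
    Analyte,
    PeakPairMeasurement,
    StandardSeries,
    StandardSeriesEntry,
    aggregate_replicates,
    correct_by_gdna,
)

PEAKS_COLUMNS = ["sample_id", "snp_id", "analyte", "replicate",
                 "allele_ref", "allele_alt", "intensity_ref", "intensity_alt"]
STANDARDS_COLUMNS = ["snp_id", "nominal_ratio", "copies_total", "replicate",
                     "intensity_ref", "intensity_alt"]
COHORT_COLUMNS = ["sample_id", "group", "fraction"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_peaks(path: str | Path) -> list[PeakPairMeasurement]:
    """Read ``peaks.tsv`` into typed peak-pair records."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."],
                     keep_default_na=False)
    _require_columns(df, PEAKS_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(PeakPairMeasurement(
                sample_id=row["sample_id"],
                snp_id=row["snp_id"],
                analyte=Analyte(row["analyte"]),
                replicate=int(row["replicate"]),
                allele_ref=row["allele_ref"],
                allele_alt=row["allele_alt"],
                intensity_ref=float(row["intensity_ref"]),
                intensity_alt=float(row["intensity_alt"]),
            ))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {line}: {exc}") from exc
    return records


def write_peaks(ms: list[PeakPairMeasurement], path: str | Path) -> None:
    df = pd.DataFrame([
        {
            "sample_id": m.sample_id, "snp_id": m.snp_id,
            "analyte": m.analyte.value, "replicate": m.replicate,
            "allele_ref": m.allele_ref, "allele_alt": m.allele_alt,
            "intensity_ref": m.intensity_ref, "intensity_alt": m.intensity_alt,
        }
        for m in ms
    ], columns=PEAKS_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_standards(path: str | Path) -> list[StandardSeries]:
    """Read ``standards.tsv`` into one series per SNP assay."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, STANDARDS_COLUMNS, path)
    series = []
    for snp_id, sub in df.groupby("snp_id", sort=True):
        entries = []
        for idx, row in sub.iterrows():
            r = float(row["nominal_ratio"])
            total = float(row["intensity_ref"]) + float(row["intensity_alt"])
            if r <= 0 or total <= 0:
                raise SchemaError(
                    f"{path}: line {idx + 2}: non-positive ratio or intensity"
                )
            entries.append(StandardSeriesEntry(
                nominal_ratio=r,
                expected_fraction=r / (1.0 + r),
                measured_fraction=float(row["intensity_ref"]) / total,
                copies_total=int(row["copies_total"]),
            ))
        series.append(StandardSeries(snp_id=str(snp_id), entries=entries))
    return series


def write_standards(s: StandardSeries, path: str | Path) -> None:
    # intensities are re-expressed from the measured fraction at the stated
    # copy number so the table round-trips through read_standards
    rows = []
    for i, e in enumerate(s.entries, start=1):
        rows.append({
            "snp_id": s.snp_id, "nominal_ratio": e.nominal_ratio,
            "copies_total": e.copies_total, "replicate": i,
            "intensity_ref": e.measured_fraction * e.copies_total,
            "intensity_alt": (1 - e.measured_fraction) * e.copies_total,
        })
    pd.DataFrame(rows, columns=STANDARDS_COLUMNS).to_csv(
        path, sep="\t", index=False)


def write_fractions(fracs: list[AllelicFraction], path: str | Path) -> None:
    df = pd.DataFrame([
        {
            "sample_id": f.sample_id, "snp_id": f.snp_id,
            "analyte": f.analyte.value, "fraction": f.fraction,
            "sd_pct": round(f.sd, 1), "n_replicates": f.n_replicates,
        }
        for f in fracs
    ], columns=["sample_id", "snp_id", "analyte", "fraction", "sd_pct",
                "n_replicates"])
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, COHORT_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(CohortRecord(
                sample_id=str(row["sample_id"]),
                group=Group(row["group"]),
                fraction=float(row["fraction"]),
            ))
        except ValueError as exc:
            raise SchemaError(f"{path}: line {idx + 2}: {exc}") from exc
        if not 0.0 <= records[-1].fraction <= 1.0:
            raise SchemaError(
                f"{path}: line {idx + 2}: fraction outside [0, 1]")
    return CohortTable(records)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    df = pd.DataFrame([
        {"sample_id": r.sample_id, "group": r.group.value,
         "fraction": r.fraction}
        for r in cohort.records
    ], columns=COHORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_clone_matrix(path: str | Path) -> BisulfiteCloneMatrix:
    """Read ``clones.tsv``: clone_id, allele, then one column per CpG offset."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[],
                     keep_default_na=False)
    _require_columns(df, ["clone_id", "allele"], path)
    pos_cols = [c for c in df.columns if c not in ("clone_id", "allele")]
    try:
        positions = {c: int(c) for c in pos_cols}
    except ValueError as exc:
        raise SchemaError(f"{path}: non-integer CpG position column") from exc
    clones = []
    for idx, row in df.iterrows():
        allele = {"A": PhasedAllele.A, "B": PhasedAllele.B}.get(
            row["allele"], PhasedAllele.UNKNOWN)
        calls = {}
        for col, pos in positions.items():
            try:
                calls[pos] = CloneCall(row[col])
            except ValueError as exc:
                raise SchemaError(
                    f"{path}: line {idx + 2}: bad CpG call {row[col]!r}"
                ) from exc
        clones.append(Clone(row["clone_id"], allele, calls))
    return BisulfiteCloneMatrix(clones)


def write_clone_matrix(m: BisulfiteCloneMatrix, path: str | Path) -> None:
    positions = m.positions
    rows = []
    for c in m.clones:
        row = {"clone_id": c.clone_id,
               "allele": c.allele.value if c.allele is not PhasedAllele.UNKNOWN
               else "unknown"}
        for p in positions:
            row[str(p)] = c.cpg_calls[p].value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_methylation_profile(path: str | Path) -> list[MethylationProfile]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["amplicon_id", "position", "raw_pct"], path)
    profiles = []
    for amp, sub in df.groupby("amplicon_id", sort=True):
        units = [CpGUnit(position=int(r["position"]), raw_pct=float(r["raw_pct"]))
                 for _, r in sub.iterrows()]
        profiles.append(MethylationProfile(str(amp), units))
    return profiles


def read_methylation_standards(path: str | Path) -> MethylationStandards:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["nominal_pct", "measured_pct"], path)
    return MethylationStandards(
        [(float(r["nominal_pct"]), float(r["measured_pct"]))
         for _, r in df.iterrows()]
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (serializable to JSON)."""

    peaks_path: str
    groups_path: str
    out_dir: str
    snp_id: str | None = None           # None: use the single SNP present
    alpha: float = 0.05
    huber_k: float = 1.345
    qc_min_total_intensity: float = 0.0
    het_band: tuple[float, float] = (0.3, 0.7)
    purity_threshold: float = 0.9
    asm_margin: float = 0.3
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "het_band" in data:
            data["het_band"] = tuple(data["het_band"])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Quantify -> gDNA-correct -> call -> report, writing all artifacts.

    Writes ``fractions.tsv``, ``corrected.tsv``, ``cohort.tsv``,
    ``calls.tsv``, ``thresholds.json`` and ``report.txt`` under
    ``config.out_dir``.  Deterministic given inputs and config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    peaks = read_peaks(config.peaks_path)
    if config.snp_id is not None:
        peaks = [m for m in peaks if m.snp_id == config.snp_id]
    if not peaks:
        raise SchemaError("quantify: no peak measurements after filtering")

    groups_df = pd.read_csv(config.groups_path, sep="\t")
    _require_columns(groups_df, ["sample_id", "group"], config.groups_path)
    group_of = {str(r["sample_id"]): Group(r["group"])
                for _, r in groups_df.iterrows()}

    by_key: dict[tuple, list[PeakPairMeasurement]] = {}
    for m in peaks:
        by_key.setdefault((m.sample_id, m.snp_id, m.analyte), []).append(m)
    fractions = [
        aggregate_replicates(ms, config.qc_min_total_intensity)
        for ms in by_key.values()
    ]
    write_fractions(fractions, out / "fractions.tsv")

    frac_of = {(f.sample_id, f.snp_id, f.analyte): f for f in fractions}
    corrected_rows = []
    cohort_records = []
    for (sample, snp, analyte), f in sorted(
            frac_of.items(), key=lambda kv: kv[0]):
        if analyte is not Analyte.CDNA:
            continue
        g = frac_of.get((sample, snp, Analyte.GDNA))
        if g is None:
            warnings.warn(f"{sample}/{snp}: no gDNA measurement; skipped")
            continue
        try:
            f_corr = correct_by_gdna(f.fraction, g.fraction, config.het_band)
        except NonInformativeGenotypeError:
            warnings.warn(f"{sample}/{snp}: homozygous gDNA; skipped")
            continue
        if not config.het_band[0] <= g.fraction <= config.het_band[1]:
            continue  # warned inside correct_by_gdna; not informative
        corrected_rows.append({
            "sample_id": sample, "snp_id": snp, "f_cdna": f.fraction,
            "f_gdna": g.fraction, "f_corrected": f_corr,
        })
        if sample in group_of:
            cohort_records.append(
                CohortRecord(sample, group_of[sample], f_corr))
    pd.DataFrame(
        corrected_rows,
        columns=["sample_id", "snp_id", "f_cdna", "f_gdna", "f_corrected"],
    ).to_csv(out / "corrected.tsv", sep="\t", index=False)

    cohort = CohortTable(cohort_records)
    if cohort.n_cases == 0:
        raise SchemaError("ase_calling: no cases")
    write_cohort(cohort, out / "cohort.tsv")

    youden = call_ase(cohort, CallMethod.YOUDEN)
    alpha_res = call_ase(cohort, CallMethod.ALPHA_OUTLIER, alpha=config.alpha,
                         tuning_k=config.huber_k)
    screen = screening_tests(cohort)

    calls_df = pd.DataFrame([
        {
            "sample_id": r.sample_id, "group": r.group.value,
            "fraction": r.fraction,
            "youden_flag": int(youden.flags[r.sample_id]),
            "alpha_flag": int(alpha_res.flags[r.sample_id]),
        }
        for r in cohort.records
    ], columns=["sample_id", "group", "fraction", "youden_flag", "alpha_flag"])
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)

    thresholds = [
        {"method": "youden", "lower": youden.lower_cutoff,
         "upper": youden.upper_cutoff, "location": None, "scale": None,
         "alpha": None},
        {"method": "alpha_outlier", "lower": alpha_res.lower_cutoff,
         "upper": alpha_res.upper_cutoff,
         "location": alpha_res.estimates.location,
         "scale": alpha_res.estimates.scale, "alpha": alpha_res.alpha},
    ]
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2) + "\n")

    n_cases, n_controls = cohort.n_cases, cohort.n_controls
    n_pos_controls = sum(
        youden.flags[r.sample_id] for r in cohort.records
        if r.group is Group.CONTROL
    )
    report = "\n".join([
        f"config {config.digest()}",
        f"cohort: {n_cases} cases, {n_controls} controls",
        (f"youden: lower {youden.lower_cutoff:.4f}, "
         f"upper {youden.upper_cutoff:.4f}, "
         f"ASE-positive cases {youden.n_positive}/{n_cases} "
         f"({100 * youden.n_positive / n_cases:.1f}%), "
         f"positive controls {n_pos_controls}/{n_controls}"),
        (f"alpha_outlier (alpha={config.alpha}): "
         f"location {alpha_res.estimates.location:.4f}, "
         f"scale {alpha_res.estimates.scale:.4f}, "
         f"limits [{alpha_res.lower_cutoff:.4f}, "
         f"{alpha_res.upper_cutoff:.4f}], "
         f"ASE-positive cases {alpha_res.n_positive}/{n_cases} "
         f"({100 * alpha_res.n_positive / n_cases:.1f}%)"),
        (f"screening: Mann-Whitney p = {screen.mw_p:.4g}, "
         f"F-test p = {screen.f_test_p:.4g}, medians case "
         f"{screen.median_case:.2f} / control {screen.median_control:.2f}"),
        "",
    ])
    (out / "report.txt").write_text(report)
    return {
        "youden": youden, "alpha_outlier": alpha_res, "screening": screen,
        "cohort": cohort,
    }
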