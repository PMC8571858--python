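"""Specimen metadata ingestion and DNA-quality statistics.

Herbarium barcoding studies record, for every voucher sampled, the DNA
yield (ng/ul), the two spectrophotometric purity ratios (OD260/280 and
OD260/230), whether the ITS PCR amplified, and whether a complete
ITS1+ITS2 sequence was recovered.  This module loads such tables and
reproduces the standard summaries: per-group purity means, amplification
and sequencing success rates, collection-year stratification by
amplification outcome, and the DNA-concentration-on-age regression used
to ask whether older vouchers yield less DNA.

Two transcribed study tables ship with the package and are exposed via
:func:`packaged_herbarium_records` and :func:`packaged_fresh_records`.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, RowParseError, SchemaError

__all__ = [
    "SpecimenRecord",
    "PuritySummary",
    "RateSummary",
    "RegressionResult",
    "YearStratification",
    "load_specimen_table",
    "packaged_herbarium_records",
    "packaged_fresh_records",
    "summarize_purity",
    "success_rates",
    "year_stratified_summary",
    "regress_concentration_on_age",
    "qc_report",
]

REQUIRED_COLUMNS = (
    "specimen_id",
    "species",
    "collection_date",
    "dna_conc_ng_ul",
    "od_260_280",
    "od_260_230",
    "amplified",
    "full_sequence",
    "genbank_accession",
    "source_class",
)

#: Year the extant material was harvested and all DNA extractions ran;
#: default origin for specimen age.
EXTRACTION_YEAR = 2019

PURITY_METRICS = ("od_260_280", "od_260_230", "dna_conc", "collection_year")


@dataclass(frozen=True)
class SpecimenRecord:
    """One herbarium or fresh specimen with its QC measurements."""

    specimen_id: str
    species: str
    collection_date: _dt.date | None
    collection_year: int | None
    dna_conc: float
    od_260_280: float
    od_260_230: float
    amplified: bool
    full_sequence: bool
    genbank_accession: str | None
    source_class: str
    partial_sequence: bool = False

    def __post_init__(self):
        if self.dna_conc < 0:
            raise ValueError(f"{self.specimen_id}: negative DNA concentration")
        if self.collection_year is not None and not (1800 <= self.collection_year <= 2100):
            raise ValueError(f"{self.specimen_id}: implausible year {self.collection_year}")
        if self.source_class not in ("herbarium", "fresh"):
            raise ValueError(f"{self.specimen_id}: bad source_class {self.source_class!r}")


@dataclass(frozen=True)
class PuritySummary:
    group: str
    metric: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class RateSummary:
    label: str
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent_display(self) -> str:
        return f"{self.percent:.1f}%"


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of DNA concentration (ng/ul) on specimen age (years)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    x_definition: str


@dataclass(frozen=True)
class YearStratification:
    """Collection-year summaries split by amplification outcome."""

    amplified: PuritySummary | None
    not_amplified: PuritySummary | None
    n_undated_excluded: int


def _parse_date(raw: object) -> tuple[_dt.date | None, int | None]:
    """Parse ``YYYY-MM-DD``, ``YYYY-MM``, ``YYYY`` or the literal ``ND``."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None, None
    text = str(raw).strip()
    if text in ("", "ND", "nd"):
        return None, None
    parts = text.split("-")
    try:
        if len(parts) == 3:
            d = _dt.date(int(parts[0]), int(parts[1]), int(parts[2]))
            return d, d.year
        if len(parts) == 2:
            return None, _dt.date(int(parts[0]), int(parts[1]), 1).year
        if len(parts) == 1:
            year = int(parts[0])
            return None, year
    except ValueError:
        pass
    raise ValueError(f"unparseable collection date {text!r}")


def _parse_flag(raw: object, column: str) -> bool:
    text = str(raw).strip().lower()
    if text in ("+", "true", "1", "yes"):
        return True
    if text in ("-", "−", "false", "0", "no", "", "nan"):
        return False
    raise ValueError(f"unrecognised {column} value {raw!r}")


def load_specimen_table(path: str | Path, source_class: str | None = None) -> list[SpecimenRecord]:
    """Read a specimen QC table (CSV) into :class:`SpecimenRecord` objects.

    Parameters
    ----------
    path:
        CSV with the documented header.  Dates are ISO-8601, ``YYYY-MM``,
        ``YYYY`` or the literal ``ND``; the amplification and
        full-sequence columns use ``+``/``-`` or ``true``/``false``.
    source_class:
        If given, overrides the ``source_class`` column for every row
        (``"herbarium"`` or ``"fresh"``).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[SpecimenRecord] = []
    for idx, row in df.iterrows():
        try:
            date, year = _parse_date(row["collection_date"])
            accession = row["genbank_accession"].strip() or None
            partial = False
            if "partial_sequence" in df.columns:
                partial = _parse_flag(row["partial_sequence"], "partial_sequence")
            records.append(
                SpecimenRecord(
                    specimen_id=row["specimen_id"].strip(),
                    species=row["species"].strip(),
                    collection_date=date,
                    collection_year=year,
                    dna_conc=float(row["dna_conc_ng_ul"]),
                    od_260_280=float(row["od_260_280"]),
                    od_260_230=float(row["od_260_230"]),
                    amplified=_parse_flag(row["amplified"], "amplified"),
                    full_sequence=_parse_flag(row["full_sequence"], "full_sequence"),
                    genbank_accession=accession,
                    source_class=source_class or row["source_class"].strip(),
                    partial_sequence=partial,
                )
            )
        except (ValueError, KeyError) as exc:
            raise RowParseError(f"{path} row {idx}: {exc}", row_index=int(idx)) from exc
    return records


def _packaged(name: str) -> list[SpecimenRecord]:
    with resources.as_file(resources.files("herbita.data").joinpath(name)) as p:
        return load_specimen_table(p)


def packaged_herbarium_records() -> list[SpecimenRecord]:
    """The 52 transcribed historic herbarium specimens (1882-2001)."""
    return _packaged("table1_herbarium.csv")


def packaged_fresh_records() -> list[SpecimenRecord]:
    """The 7 transcribed extant (fresh) specimens (USDA GRIN, 2019)."""
    return _packaged("table2_fresh.csv")


def _metric_values(records: Sequence[SpecimenRecord], metric: str) -> np.ndarray:
    if metric not in PURITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {PURITY_METRICS}")
    attr = "dna_conc" if metric == "dna_conc" else metric
    vals = [getattr(r, attr) for r in records]
    return np.asarray([v for v in vals if v is not None], dtype=float)


def summarize_purity(records: Sequence[SpecimenRecord], metric: str) -> PuritySummary:
    """Mean and sample SD (denominator n-1) of a QC metric.

    Records with the metric absent (an undated specimen when
    ``metric="collection_year"``) are excluded; ``n`` counts the values
    actually used.
    """
    values = _metric_values(records, metric)
    if values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 non-missing values for {metric}, got {values.size}"
        )
    groups = {r.source_class for r in records}
    group = groups.pop() if len(groups) == 1 else "mixed"
    return PuritySummary(
        group=group,
        metric=metric,
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        min=float(values.min()),
        max=float(values.max()),
    )


def success_rates(records: Sequence[SpecimenRecord]) -> list[RateSummary]:
    """Amplification and complete-sequence success rates.

    Returns three fractions: amplified/total, full-sequence/total, and
    full-sequence/amplified.  Specimens yielding only a partial ITS read
    count as amplified but not as full sequences.
    """
    if not records:
        raise InsufficientDataError("no records")
    total = len(records)
    n_amp = sum(r.amplified for r in records)
    n_full = sum(r.full_sequence for r in records)
    out = [
        RateSummary("amplified/total", n_amp, total),
        RateSummary("full_sequence/total", n_full, total),
    ]
    if n_amp:
        out.append(RateSummary("full_sequence/amplified", n_full, n_amp))
    return out


def year_stratified_summary(records: Sequence[SpecimenRecord]) -> YearStratification:
    """Collection-year mean +/- SD for failed vs successful amplification.

    Undated records are excluded and counted.  A stratum with fewer than
    two dated records yields ``None`` for that stratum.
    """
    undated = sum(1 for r in records if r.collection_year is None)
    out: dict[bool, PuritySummary | None] = {}
    for outcome in (True, False):
        stratum = [r for r in records if r.amplified is outcome]
        try:
            out[outcome] = summarize_purity(stratum, "collection_year")
        except InsufficientDataError:
            out[outcome] = None
    return YearStratification(
        amplified=out[True], not_amplified=out[False], n_undated_excluded=undated
    )


def regress_concentration_on_age(
    records: Sequence[SpecimenRecord], reference_year: int = EXTRACTION_YEAR
) -> RegressionResult:
    """OLS of DNA concentration on specimen age at extraction.

    Age is ``reference_year - collection_year``: the number of years a
    voucher had been stored when its DNA was extracted (the extraction
    campaign year is the default origin).  Slope magnitude, r-squared and
    the two-sided p-value of the slope are invariant to the choice of
    origin; the intercept then estimates the expected yield of freshly
    collected material.  Undated records are excluded.
    """
    dated = [r for r in records if r.collection_year is not None]
    if len(dated) < 3:
        raise InsufficientDataError(f"need >= 3 dated records, got {len(dated)}")
    x = np.array([reference_year - r.collection_year for r in dated], dtype=float)
    y = np.array([r.dna_conc for r in dated], dtype=float)
    fit = stats.linregress(x, y)
    r_squared = float(fit.rvalue**2)
    p_value = float(fit.pvalue)
    if not math.isfinite(r_squared):  # constant response
        r_squared = 0.0
    if not math.isfinite(p_value):
        p_value = 1.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        p_value=p_value,
        n=len(dated),
        x_definition=f"specimen age in years: {reference_year} - collection_year",
    )


def qc_report(records: Sequence[SpecimenRecord]) -> dict:
    """Full QC summary as a JSON-serialisable dict (CLI backend)."""
    report: dict = {"n_records": len(records)}
    for metric in ("od_260_280", "od_260_230", "dna_conc"):
        try:
            report[metric] = asdict(summarize_purity(records, metric))
        except InsufficientDataError as exc:
            report[metric] = {"error": str(exc)}
    report["rates"] = [
        {"label": r.label, "numerator": r.numerator, "denominator": r.denominator,
         "percent": round(r.percent, 1)}
        for r in success_rates(records)
    ]
    strat = year_stratified_summary(records)
    report["year_stratification"] = {
        "amplified": asdict(strat.amplified) if strat.amplified else None,
        "not_amplified": asdict(strat.not_amplified) if strat.not_amplified else None,
        "n_undated_excluded": strat.n_undated_excluded,
    }
    try:
        report["concentration_on_age"] = asdict(regress_concentration_on_age(records))
    except InsufficientDataError as exc:
        report["concentration_on_age"] = {"error": str(exc)}
    return report


def write_qc_report(records: Sequence[SpecimenRecord], out_dir: str | Path) -> None:
    """Write the QC report as JSON plus a flat TSV of the rate table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = qc_report(records)
    (out / "qc_report.json").write_text(json.dumps(report, indent=2) + "\n")
    rows = ["label\tnumerator\tdenominator\tpercent"]
    for r in report["rates"]:
        rows.append(f"{r['label']}\t{r['numerator']}\t{r['denominator']}\t{r['percent']:.1f}")
    (out / "qc_rates.tsv").write_text("\n".join(rows) + "\n")
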