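"""Reading survey tables, validating records, and writing reports.

Survey exports never share column conventions, so input goes through a
human-editable column-mapping document (YAML or JSON) that names, for
each participant field, the column that holds it, the acuity dialect of
each acuity column, and value maps for coded sex/stratum variables.
Rows that fail validation are collected into a rejects report with row
numbers and reasons; they never abort the run unless more than half of
the file rejects.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .acuity import AcuityDialect, AcuityParseError, AcuityValue, parse_acuity
from .classification import PersonRecord, Sex
from .indicators import CoverageEstimate, NeedSummary, Report

__all__ = [
    "ColumnMapping",
    "SurveyData",
    "SurveyReadError",
    "read_survey",
    "records_to_dataframe",
    "write_cohort",
    "write_report",
]

log = logging.getLogger(__name__)

_TRUE_TOKENS = {"1", "yes", "true"}
_FALSE_TOKENS = {"0", "no", "false"}

ACUITY_FIELDS = (
    "ucva_left", "ucva_right",
    "cva_left", "cva_right",
    "pinhole_left", "pinhole_right",
    "bcva_left", "bcva_right",
)

#: Column names used when this package writes a cohort; doubles as the
#: default mapping for files the package itself produced.
DEFAULT_COLUMNS = {
    "person_id": "person_id",
    "wears_distance_correction": "wears_correction",
    "ucva_left": "ucva_left",
    "ucva_right": "ucva_right",
    "cva_left": "cva_left",
    "cva_right": "cva_right",
    "pinhole_left": "pinhole_left",
    "pinhole_right": "pinhole_right",
    "bcva_left": "bcva_left",
    "bcva_right": "bcva_right",
    "age_years": "age",
    "sex": "sex",
    "weight": "weight",
    "cluster_id": "cluster",
}


class SurveyReadError(RuntimeError):
    pass


class ColumnMapping(BaseModel):
    """Maps survey columns onto participant fields.

    ``wears_distance_correction`` and at least one uncorrected-acuity eye
    are mandatory; everything else is optional.  ``correction_definition``
    records how the survey defined correction (spectacles only, or
    spectacles and contact lenses) and is carried into report metadata.
    """

    wears_distance_correction: str
    ucva_left: Optional[str] = None
    ucva_right: Optional[str] = None
    cva_left: Optional[str] = None
    cva_right: Optional[str] = None
    pinhole_left: Optional[str] = None
    pinhole_right: Optional[str] = None
    bcva_left: Optional[str] = None
    bcva_right: Optional[str] = None
    person_id: Optional[str] = None
    age_years: Optional[str] = None
    sex: Optional[str] = None
    weight: Optional[str] = None
    cluster_id: Optional[str] = None
    strata: dict[str, str] = Field(default_factory=dict)
    acuity_dialect: AcuityDialect = AcuityDialect.METRIC_6
    acuity_dialects: dict[str, AcuityDialect] = Field(default_factory=dict)
    sex_values: dict[str, str] = Field(default_factory=dict)
    strata_values: dict[str, dict[str, str]] = Field(default_factory=dict)
    correction_definition: str = "spectacles or contact lenses"

    @model_validator(mode="after")
    def _check(self):
        if self.ucva_left is None and self.ucva_right is None:
            raise ValueError("at least one uncorrected-acuity column must be mapped")
        for name in self.acuity_dialects:
            if name not in ACUITY_FIELDS:
                raise ValueError(f"acuity_dialects names unknown field {name!r}")
        return self

    def dialect_for(self, field_name: str) -> AcuityDialect:
        return self.acuity_dialects.get(field_name, self.acuity_dialect)

    def mapped_columns(self) -> dict[str, str]:
        cols = {
            name: col
            for name, col in (
                ("wears_distance_correction", self.wears_distance_correction),
                ("person_id", self.person_id),
                ("age_years", self.age_years),
                ("sex", self.sex),
                ("weight", self.weight),
                ("cluster_id", self.cluster_id),
                *((name, getattr(self, name)) for name in ACUITY_FIELDS),
            )
            if col is not None
        }
        for label, col in self.strata.items():
            cols[f"strata.{label}"] = col
        return cols

    @classmethod
    def default(cls) -> "ColumnMapping":
        """Mapping for cohort files written by this package."""
        return cls(strata={"residence": "residence"}, **DEFAULT_COLUMNS)

    @classmethod
    def infer_default(cls, survey_path: str | Path) -> "ColumnMapping":
        """Default mapping for a file in this package's own column layout.

        Columns beyond the standard layout are treated as strata.
        """
        with Path(survey_path).open() as fh:
            header_line = fh.readline().rstrip("\n")
        columns = header_line.split(_sniff_separator(header_line))
        standard = set(DEFAULT_COLUMNS.values())
        kwargs = {
            name: col for name, col in DEFAULT_COLUMNS.items() if col in columns
        }
        strata = {col: col for col in columns if col not in standard}
        return cls(strata=strata, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnMapping":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json", exclude_none=True), sort_keys=True)
        )


@dataclass
class SurveyData:
    """Loaded records plus the rejects report."""

    records: list[PersonRecord]
    rejects: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[PersonRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_bool(token: str, context: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValueError(f"{context}: boolean must be one of 1/0, yes/no, true/false, got {token!r}")


def _sniff_separator(header_line: str) -> str:
    return "\t" if header_line.count("\t") > header_line.count(",") else ","


def _cell(row: pd.Series, column: Optional[str]) -> str:
    if column is None:
        return ""
    return str(row[column]).strip()


def read_survey(path: str | Path, mapping: ColumnMapping) -> SurveyData:
    """Load and validate a delimited survey table.

    The delimiter (comma or tab) is sniffed from the header.  A missing
    mandatory column fails before any row is read; individual bad rows go
    to the rejects report; more than 50% rejected rows is a hard failure.
    """
    path = Path(path)
    if not path.exists():
        raise SurveyReadError(f"survey file not found: {path}")
    with path.open() as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise SurveyReadError(f"{path}: empty file without header")
    sep = _sniff_separator(header_line)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [
        f"{name} -> {col}"
        for name, col in mapping.mapped_columns().items()
        if col not in frame.columns
    ]
    if missing:
        raise SurveyReadError(
            f"{path}: mapped columns missing from header: {', '.join(missing)}"
        )

    records: list[PersonRecord] = []
    rejects: list[tuple[int, str]] = []
    warnings: list[str] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        row_number = i + 2  # 1-based, after the header
        try:
            records.append(_build_record(row, mapping, i, warnings))
        except (ValueError, AcuityParseError) as exc:
            rejects.append((row_number, str(exc)))

    if len(frame) == 0:
        log.warning("%s: no data rows", path)
    if len(frame) > 0 and len(rejects) > len(frame) / 2:
        raise SurveyReadError(
            f"{path}: {len(rejects)} of {len(frame)} rows rejected (>50%); "
            "check the column mapping"
        )
    log.info("%s: loaded %d records, rejected %d rows", path, len(records), len(rejects))
    return SurveyData(records=records, rejects=rejects, warnings=warnings)


def _build_record(
    row: pd.Series, mapping: ColumnMapping, index: int, warnings: list[str]
) -> PersonRecord:
    person_id = _cell(row, mapping.person_id) or f"row{index + 2}"
    context = f"row {index + 2} (person {person_id})"

    wears = _parse_bool(_cell(row, mapping.wears_distance_correction), context)

    acuities: dict[str, Optional[AcuityValue]] = {}
    for name in ACUITY_FIELDS:
        token = _cell(row, getattr(mapping, name))
        acuities[name] = (
            parse_acuity(token, mapping.dialect_for(name), context) if token else None
        )

    age_token = _cell(row, mapping.age_years)
    age = int(float(age_token)) if age_token else None

    sex_token = _cell(row, mapping.sex)
    if sex_token:
        sex_token = mapping.sex_values.get(sex_token, sex_token)
        try:
            sex = Sex(sex_token.lower())
        except ValueError:
            raise ValueError(f"{context}: unknown sex code {sex_token!r}") from None
    else:
        sex = Sex.UNKNOWN

    weight_token = _cell(row, mapping.weight)
    weight = float(weight_token) if weight_token else 1.0

    strata = {}
    for label, col in mapping.strata.items():
        value = _cell(row, col)
        strata[label] = mapping.strata_values.get(label, {}).get(value, value)

    record = PersonRecord(
        person_id=person_id,
        wears_distance_correction=wears,
        age_years=age,
        sex=sex,
        strata=strata,
        weight=weight,
        cluster_id=_cell(row, mapping.cluster_id) or None,
        **acuities,
    )
    warnings.extend(record.validation_warnings())
    return record


def records_to_dataframe(records: Sequence[PersonRecord]) -> pd.DataFrame:
    """Flatten records to the default column layout (lossless round trip)."""
    rows = []
    standard = set(DEFAULT_COLUMNS.values())
    strata_labels = sorted(
        {label for r in records for label in r.strata} - standard
    )
    for r in records:
        row = {
            "person_id": r.person_id,
            "wears_correction": "1" if r.wears_distance_correction else "0",
            "age": "" if r.age_years is None else str(r.age_years),
            "sex": r.sex.value,
            "weight": format(r.weight, "g"),
            "cluster": r.cluster_id or "",
        }
        for name in ACUITY_FIELDS:
            value: Optional[AcuityValue] = getattr(r, name)
            row[DEFAULT_COLUMNS[name]] = value.notation if value is not None else ""
        for label in strata_labels:
            row[label] = r.strata.get(label, "")
        rows.append(row)
    columns = list(DEFAULT_COLUMNS.values()) + strata_labels
    return pd.DataFrame(rows, columns=columns)


def write_cohort(records: Sequence[PersonRecord], path: str | Path) -> None:
    """Write records as a survey CSV readable with the default mapping."""
    records_to_dataframe(records).to_csv(path, index=False, lineterminator="\n")


def default_mapping_for(records: Sequence[PersonRecord]) -> ColumnMapping:
    strata_labels = sorted({label for r in records for label in r.strata})
    return ColumnMapping(
        strata={label: label for label in strata_labels}, **DEFAULT_COLUMNS
    )


# --------------------------------------------------------------------------
# report serialisation

def _round(x: Optional[float], places: int = 4) -> Optional[float]:
    return None if x is None else round(float(x), places)


def _summary_dict(s: NeedSummary) -> dict:
    return {
        "stratum": dict(s.stratum),
        "thresholds": {"need": s.thresholds[0], "outcome": s.thresholds[1]},
        "counts": {
            "met_a": s.met_a,
            "under_met_b": s.under_met_b,
            "unmet_c": s.unmet_c,
            "no_need": s.no_need,
            "other_vi": s.other_vi,
            "indeterminate": s.indeterminate,
        },
        "weighted": {
            "met_a": _round(s.met_a_weight),
            "under_met_b": _round(s.under_met_b_weight),
            "unmet_c": _round(s.unmet_c_weight),
            "no_need": _round(s.no_need_weight),
            "other_vi": _round(s.other_vi_weight),
            "indeterminate": _round(s.indeterminate_weight),
        },
        "n": s.n,
    }


def _estimate_dict(e: CoverageEstimate) -> dict:
    return {
        "indicator": e.indicator.value,
        "value_pct": _round(e.value_pct),
        "value_pct_display": None if e.value_pct is None else f"{e.value_pct:.1f}",
        "numerator": _round(e.numerator),
        "denominator": _round(e.denominator),
        "ci_low_pct": _round(e.ci_low_pct),
        "ci_high_pct": _round(e.ci_high_pct),
        "ci_method": e.ci_method,
        "stratum": dict(e.stratum),
        "thresholds": {"need": e.thresholds[0], "outcome": e.thresholds[1]},
        "standardised": e.standardised,
        "defined": e.defined,
    }


def report_to_dict(report: Report) -> dict:
    return {
        "metadata": {**report.metadata, "tool_version": __version__},
        "entries": [
            {
                "thresholds": {"need": entry.thresholds[0], "outcome": entry.thresholds[1]},
                "summary": _summary_dict(entry.summary),
                "stratum_summaries": [_summary_dict(s) for s in entry.stratum_summaries],
                "estimates": [_estimate_dict(e) for e in entry.estimates],
            }
            for entry in report.entries
        ],
    }


_CSV_FIELDS = [
    "need_threshold", "outcome_threshold", "stratum", "indicator",
    "value_pct", "ci_low_pct", "ci_high_pct", "ci_method",
    "numerator", "denominator", "standardised", "defined",
    "n_met_a", "n_under_met_b", "n_unmet_c", "n_no_need", "n_other_vi",
    "n_indeterminate",
]


def _stratum_key(stratum) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(stratum.items())) or "overall"


def report_to_csv_text(report: Report) -> str:
    buffer = io.StringIO()
    writer = csv.DictWriter(buffer, fieldnames=_CSV_FIELDS, lineterminator="\n")
    writer.writeheader()
    for entry in report.entries:
        summaries = {_stratum_key(s.stratum): s for s in entry.stratum_summaries}
        for e in entry.estimates:
            key = _stratum_key(e.stratum)
            s = summaries.get(key)
            writer.writerow(
                {
                    "need_threshold": e.thresholds[0],
                    "outcome_threshold": e.thresholds[1],
                    "stratum": key,
                    "indicator": e.indicator.value,
                    "value_pct": "" if e.value_pct is None else f"{e.value_pct:.4f}",
                    "ci_low_pct": "" if e.ci_low_pct is None else f"{e.ci_low_pct:.4f}",
                    "ci_high_pct": "" if e.ci_high_pct is None else f"{e.ci_high_pct:.4f}",
                    "ci_method": e.ci_method or "",
                    "numerator": f"{e.numerator:.4f}",
                    "denominator": f"{e.denominator:.4f}",
                    "standardised": int(e.standardised),
                    "defined": int(e.defined),
                    "n_met_a": s.met_a if s else "",
                    "n_under_met_b": s.under_met_b if s else "",
                    "n_unmet_c": s.unmet_c if s else "",
                    "n_no_need": s.no_need if s else "",
                    "n_other_vi": s.other_vi if s else "",
                    "n_indeterminate": s.indeterminate if s else "",
                }
            )
    return buffer.getvalue()


def write_report(report: Report, path: str | Path, format: str = "json") -> None:
    """Serialise a report deterministically (stable key order, fixed decimals)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n")
    elif format == "csv":
        path.write_text(report_to_csv_text(report))
    else:
        raise ValueError(f"unknown report format {format!r}")
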