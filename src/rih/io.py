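"""CSV/JSON/YAML readers, writers and report formatting.

Two long CSV dialects are supported. Scorecards:
``innovation_id, region, criterion_or_attribute, value, source_type`` —
screening rows use yes/no values, attribute rows use A/B/C/D/NA grades and
an optional source_type of 1/2/3/NA (several sources separated by ';').
Ratings: ``item_id, attribute, rater_id, value`` with exactly two distinct
raters and NA for missing cells.

Reports are emitted as JSON with deterministic key order (insertion order
of plain dicts, stable across runs) and as plain-text tables; scores print
to 1 decimal, coefficients to 3 decimals, standard errors to 5, and
percentages as integers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .agreement import AgreementResults, RatingsTable
from .config import (
    ATTRIBUTE_LABELS,
    ATTRIBUTES,
    SCREENING_CRITERIA,
    ToolConfig,
)
from .scorecard import (
    AttributeAssessment,
    Grade,
    RatingSummary,
    SampleSummary,
    Scorecard,
    ScreeningRecord,
    parse_source_type,
)

__all__ = [
    "ScorecardValidationError",
    "read_scorecards",
    "write_scorecards",
    "read_ratings",
    "write_ratings",
    "load_config",
    "rating_report",
    "agreement_report",
    "sample_report",
    "format_rating_table",
    "format_agreement_table",
    "to_json",
]


class ScorecardValidationError(ValueError):
    """Malformed scorecard rows; carries the offending line numbers."""

    def __init__(self, problems: Sequence[str]) -> None:
        self.problems = list(problems)
        super().__init__("invalid scorecard file:\n  " + "\n  ".join(self.problems))


SCORECARD_COLUMNS = ["innovation_id", "region", "criterion_or_attribute", "value", "source_type"]
RATINGS_COLUMNS = ["item_id", "attribute", "rater_id", "value"]


def _is_na(v: object) -> bool:
    return pd.isna(v) or str(v).strip().upper() in ("", "NA", "N/A")


def read_scorecards(path: Union[str, Path], config: Optional[ToolConfig] = None) -> list[Scorecard]:
    """Read and validate a long-form scorecard CSV.

    Every malformed row is reported with its line number (header = line 1)
    in a single :class:`ScorecardValidationError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in SCORECARD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ScorecardValidationError([f"missing columns: {', '.join(missing_cols)}"])

    problems: list[str] = []
    data: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        iid = str(row["innovation_id"]).strip()
        key = str(row["criterion_or_attribute"]).strip()
        value = str(row["value"]).strip()
        if not iid:
            problems.append(f"line {line}: empty innovation_id")
            continue
        entry = data.setdefault(
            iid, {"region": str(row["region"]).strip(), "screening": {}, "attributes": {}}
        )
        if key in SCREENING_CRITERIA:
            if key in entry["screening"]:
                problems.append(f"line {line}: duplicate screening criterion {key!r} for {iid}")
                continue
            if value.lower() not in ("yes", "no", "na", ""):
                problems.append(f"line {line}: screening value {value!r} not yes/no/NA")
                continue
            entry["screening"][key] = None if _is_na(value) else value.lower() == "yes"
        elif key in ATTRIBUTES:
            if key in entry["attributes"]:
                problems.append(f"line {line}: duplicate attribute {key!r} for {iid}")
                continue
            try:
                grade = Grade.parse(value)
            except ValueError as e:
                problems.append(f"line {line}: {e}")
                continue
            raw_src = str(row["source_type"]).strip()
            sources: list[Optional[int]] = []
            if not _is_na(raw_src):
                try:
                    sources = [parse_source_type(tok) for tok in raw_src.split(";") if tok.strip()]
                except ValueError as e:
                    problems.append(f"line {line}: {e}")
                    continue
            entry["attributes"][key] = AttributeAssessment(key, grade, tuple(sources))
        else:
            problems.append(f"line {line}: unknown criterion or attribute {key!r}")
    if problems:
        raise ScorecardValidationError(problems)

    cards = []
    for iid, entry in data.items():
        cards.append(
            Scorecard(
                innovation_id=iid,
                screening=ScreeningRecord(**entry["screening"]),
                assessments=entry["attributes"],
                region=entry["region"],
            )
        )
    return cards


def write_scorecards(scorecards: Sequence[Scorecard], path: Union[str, Path]) -> None:
    rows = []
    for sc in scorecards:
        for crit in SCREENING_CRITERIA:
            v = getattr(sc.screening, crit)
            rows.append(
                (sc.innovation_id, sc.region, crit, "NA" if v is None else ("yes" if v else "no"), "NA")
            )
        for attr in ATTRIBUTES:
            a = sc.assessments[attr]
            srcs = ";".join(str(s) for s in a.sources if s is not None)
            rows.append((sc.innovation_id, sc.region, attr, a.grade.value, srcs or "NA"))
    pd.DataFrame(rows, columns=SCORECARD_COLUMNS).to_csv(path, index=False)


def read_ratings(
    path: Union[str, Path],
    categories: Optional[Sequence[str]] = None,
) -> dict[str, RatingsTable]:
    """Read a long ratings CSV into one RatingsTable per attribute."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"ratings file missing columns: {', '.join(missing_cols)}")
    df["value"] = df["value"].where(~df["value"].apply(_is_na), None)
    tables = {}
    for attr, sub in df.groupby("attribute", sort=True):
        tables[str(attr)] = RatingsTable.from_dataframe(sub, categories=categories)
    return tables


def write_ratings(tables: dict[str, RatingsTable], path: Union[str, Path]) -> None:
    rows = []
    for attr, table in tables.items():
        for item, (r1, r2) in zip(table.item_ids, table.ratings):
            for rater, r in (("R1", r1), ("R2", r2)):
                rows.append((item, attr, rater, table.categories[r - 1] if r else "NA"))
    pd.DataFrame(rows, columns=RATINGS_COLUMNS).to_csv(path, index=False)


def load_config(path: Union[str, Path]) -> ToolConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ToolConfig(**raw)


# --------------------------------------------------------------------------
# Reports


def _fmt_score(v: Optional[float]) -> Optional[float]:
    return None if v is None else round(v, 1)


def rating_report(
    summaries: Sequence[RatingSummary], scorecards: Optional[Sequence[Scorecard]] = None
) -> list[dict]:
    """JSON-ready per-innovation rating report with stable key order."""
    if not summaries:
        raise ValueError("empty report")
    by_id = {sc.innovation_id: sc for sc in scorecards} if scorecards else {}
    out = []
    for s in summaries:
        obj = {
            "innovation_id": s.innovation_id,
            "screening": {
                "proceed": s.screening_proceed,
                "reasons": list(s.screening_reasons),
            },
            "rating": {
                "n_documented": s.n_documented,
                "availability_sufficient": s.availability_sufficient,
                "quality_mean": _fmt_score(s.quality_mean),
                "quality_sufficient": s.quality_sufficient,
                "overall_score": _fmt_score(s.overall_score),
                "interval_label": s.interval_label,
                "meaningful": s.meaningful,
            },
            "canonical": s.canonical,
        }
        sc = by_id.get(s.innovation_id)
        if sc is not None:
            obj["attributes"] = {
                attr: {
                    "grade": sc.assessments[attr].grade.value,
                    "best_source": sc.assessments[attr].best_source,
                }
                for attr in ATTRIBUTES
            }
        out.append(obj)
    return out


def agreement_report(results: dict[str, AgreementResults]) -> list[dict]:
    """JSON-ready agreement report shaped like a per-attribute reliability table."""
    if not results:
        raise ValueError("empty report")
    out = []
    for name, r in results.items():
        out.append(
            {
                "name": name,
                "n": r.n_used,
                "percent_agreement": round(100 * r.pa),
                "statistic": r.statistic,
                "coefficient": round(r.coefficient, 3),
                "se": round(r.se, 5),
                "ci_low": round(r.ci[0], 3),
                "ci_high": round(r.ci[1], 3),
                "p_value": r.p_label,
                "benchmark": r.benchmark,
            }
        )
    return out


def sample_report(summary: SampleSummary) -> dict:
    """JSON-ready whole-sample summary (screening, grades, points, rating)."""
    return {
        "n": summary.n,
        "screening": summary.screening.reset_index().to_dict(orient="records"),
        "grades": summary.grades.reset_index().to_dict(orient="records"),
        "points": [
            {
                k: (None if pd.isna(v) else round(v, 1) if isinstance(v, float) else v)
                for k, v in rec.items()
            }
            for rec in summary.points.reset_index().to_dict(orient="records")
        ],
        "rating": summary.rating.reset_index().to_dict(orient="records"),
    }


def format_rating_table(summaries: Sequence[RatingSummary]) -> str:
    rows = []
    for s in summaries:
        rows.append(
            {
                "Innovation": s.innovation_id,
                "Documented": f"{s.n_documented}/9",
                "Quality mean": "-" if s.quality_mean is None else f"{s.quality_mean:.1f}",
                "Overall score": "-" if s.overall_score is None else f"{s.overall_score:.1f}",
                "Interval": s.interval_label or "-",
                "Meaningful": "yes" if s.meaningful else "no",
            }
        )
    return pd.DataFrame(rows).to_string(index=False)


def format_agreement_table(results: dict[str, AgreementResults]) -> str:
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "Name": ATTRIBUTE_LABELS.get(name, name),
                "N": r.n_used,
                "Percent agreement": f"{round(100 * r.pa)}%",
                "Coefficient": f"{r.coefficient:.3f}",
                "SE": f"{r.se:.5f}",
                "95% CI": f"{r.ci[0]:.3f} to {r.ci[1]:.3f}",
                "P": r.p_label,
                "Benchmark": r.benchmark,
            }
        )
    return pd.DataFrame(rows).to_string(index=False)


def to_json(obj: object, path: Optional[Union[str, Path]] = None) -> str:
    text = json.dumps(obj, indent=2, ensure_ascii=False, allow_nan=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
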