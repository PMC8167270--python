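"""Scorecard engine: screening, assessment and rating of health innovations.

The instrument follows a three-step process. *Screening* applies four
dichotomous gates (two inclusion criteria that must hold, two exclusion
criteria that must not). *Assessment* grades nine attributes, organized in
five value domains, on an ordinal A-D scale mapped to the deliberately
non-equidistant points 5/4/2/1. *Rating* aggregates the assessment into an
overall score (mean points over documented attributes, one decimal) with a
four-interval verbal classification, and qualifies that score with two
meaningfulness gates: enough attributes documented (>= 7 of 9) and good
enough evidence behind them (mean best-source quality >= 2 points, where
each attribute contributes its highest-quality source).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    ATTRIBUTE_DOMAIN,
    ATTRIBUTE_LABELS,
    ATTRIBUTES,
    DEFAULT_CONFIG,
    EXCLUSION_CRITERIA,
    INCLUSION_CRITERIA,
    INTERVAL_LABELS,
    ToolConfig,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Grade",
    "ScreeningRecord",
    "ScreeningOutcome",
    "AttributeAssessment",
    "Scorecard",
    "RatingSummary",
    "SampleSummary",
    "IncompleteScreeningError",
    "UndocumentedAttributeError",
    "QualityNotAssessableError",
    "NoScoreError",
    "grade_to_points",
    "best_source",
    "round_score",
    "count_documented",
    "mean_quality",
    "overall_score",
    "classify_interval",
    "rate",
    "summarize_sample",
]


class IncompleteScreeningError(ValueError):
    """A screening answer is missing, so the outcome cannot be computed."""


class UndocumentedAttributeError(ValueError):
    """Points were requested for an attribute without a grade."""


class QualityNotAssessableError(ValueError):
    """No attribute carries both a grade and a source."""


class NoScoreError(ValueError):
    """No attribute is documented, so there is no overall score."""


class Grade(str, enum.Enum):
    """Four-level ordinal responsibility grade; A is best."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    MISSING = "NA"

    @classmethod
    def parse(cls, value: object) -> "Grade":
        if isinstance(value, Grade):
            return value
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return cls.MISSING
        s = str(value).strip().upper()
        if s in ("", "NA", "N/A", "-", "NAN", "NONE", "MISSING"):
            return cls.MISSING
        try:
            return cls(s)
        except ValueError:
            raise ValueError(f"invalid grade {value!r}: expected A, B, C, D or NA") from None


def parse_source_type(value: object) -> Optional[int]:
    """Parse a source-quality type (1, 2 or 3); ``None`` for missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip().upper()
    if s in ("", "NA", "N/A", "-", "NAN", "NONE", "MISSING"):
        return None
    t = int(float(s))
    if t not in (1, 2, 3):
        raise ValueError(f"invalid source type {value!r}: expected 1, 2, 3 or NA")
    return t


def grade_to_points(grade: Grade, config: ToolConfig = DEFAULT_CONFIG) -> int:
    """Points for a non-missing grade (canonically A=5, B=4, C=2, D=1)."""
    grade = Grade.parse(grade)
    if grade is Grade.MISSING:
        raise UndocumentedAttributeError("undocumented attribute: missing grade has no points")
    return config.grade_points[grade.value]


def best_source(sources: Iterable[Optional[int]]) -> Optional[int]:
    """Highest-quality (maximum type) non-missing source; ``None`` if none.

    When several information sources back an attribute, only the best one
    counts toward the quality component.
    """
    present = [parse_source_type(s) for s in sources]
    present = [s for s in present if s is not None]
    return max(present) if present else None


def _parse_yes_no(value: object) -> Optional[bool]:
    if value is None or isinstance(value, bool):
        return value
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip().lower()
    if s in ("yes", "y", "true", "1"):
        return True
    if s in ("no", "n", "false", "0"):
        return False
    if s in ("", "na", "n/a", "nan", "none"):
        return None
    raise ValueError(f"invalid yes/no answer: {value!r}")


@dataclass(frozen=True)
class ScreeningOutcome:
    proceed: bool
    reasons: tuple[str, ...]


@dataclass
class ScreeningRecord:
    """Answers to the four dichotomous screening criteria.

    ``determinants_of_health`` and ``innovativeness`` are inclusion criteria
    (must be yes); ``unavailability`` and ``corporate_social_irresponsibility``
    are exclusion criteria (must be no).
    """

    determinants_of_health: Optional[bool] = None
    innovativeness: Optional[bool] = None
    unavailability: Optional[bool] = None
    corporate_social_irresponsibility: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in INCLUSION_CRITERIA + EXCLUSION_CRITERIA:
            setattr(self, name, _parse_yes_no(getattr(self, name)))

    def outcome(self) -> ScreeningOutcome:
        """Include/exclude decision with the list of failed criteria."""
        answers = {c: getattr(self, c) for c in INCLUSION_CRITERIA + EXCLUSION_CRITERIA}
        missing = [c for c, v in answers.items() if v is None]
        if missing:
            raise IncompleteScreeningError(
                f"incomplete screening: missing answers for {', '.join(missing)}"
            )
        reasons = [c for c in INCLUSION_CRITERIA if answers[c] is False]
        reasons += [c for c in EXCLUSION_CRITERIA if answers[c] is True]
        return ScreeningOutcome(proceed=not reasons, reasons=tuple(reasons))


def screening_outcome(record: ScreeningRecord) -> ScreeningOutcome:
    """Functional alias for :meth:`ScreeningRecord.outcome`."""
    return record.outcome()


@dataclass
class AttributeAssessment:
    """One attribute's grade and the information sources behind it."""

    attribute_id: str
    grade: Grade = Grade.MISSING
    sources: tuple[Optional[int], ...] = ()

    def __post_init__(self) -> None:
        if self.attribute_id not in ATTRIBUTE_DOMAIN:
            raise ValueError(f"unknown attribute {self.attribute_id!r}")
        self.grade = Grade.parse(self.grade)
        self.sources = tuple(parse_source_type(s) for s in self.sources)

    @property
    def domain(self) -> str:
        return ATTRIBUTE_DOMAIN[self.attribute_id]

    @property
    def documented(self) -> bool:
        return self.grade is not Grade.MISSING

    @property
    def best_source(self) -> Optional[int]:
        return best_source(self.sources)


@dataclass
class Scorecard:
    """One innovation's screening answers plus its nine attribute assessments."""

    innovation_id: str
    screening: ScreeningRecord
    assessments: dict[str, AttributeAssessment] = field(default_factory=dict)
    region: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.assessments, (list, tuple)):
            self.assessments = {a.attribute_id: a for a in self.assessments}
        for attr in ATTRIBUTES:
            self.assessments.setdefault(attr, AttributeAssessment(attr))
        unknown = set(self.assessments) - set(ATTRIBUTES)
        if unknown:
            raise ValueError(f"unknown attributes: {sorted(unknown)}")
        if len(self.assessments) != len(ATTRIBUTES):
            raise ValueError("scorecard must carry exactly one assessment per attribute")

    @classmethod
    def from_points(
        cls,
        innovation_id: str,
        points: Sequence[Optional[int]],
        screening: Optional[ScreeningRecord] = None,
        sources: Optional[Sequence[Optional[int]]] = None,
        config: ToolConfig = DEFAULT_CONFIG,
    ) -> "Scorecard":
        """Build a scorecard from nine point values (5/4/2/1 or None).

        Convenience for reconstructing published scorecards, which print
        points rather than letter grades.
        """
        if len(points) != len(ATTRIBUTES):
            raise ValueError(f"expected {len(ATTRIBUTES)} point values")
        inv = {v: k for k, v in config.grade_points.items()}
        assessments = {}
        for i, (attr, p) in enumerate(zip(ATTRIBUTES, points)):
            if p is None:
                grade = Grade.MISSING
            else:
                if p not in inv:
                    raise ValueError(f"no grade maps to {p} points")
                grade = Grade(inv[p])
            src = () if sources is None else (sources[i],)
            assessments[attr] = AttributeAssessment(attr, grade, src)
        if screening is None:
            screening = ScreeningRecord(True, True, False, False)
        return cls(innovation_id, screening, assessments)

    def documented_attributes(self) -> list[str]:
        return [a for a in ATTRIBUTES if self.assessments[a].documented]


@dataclass(frozen=True)
class RatingSummary:
    """Output of the rating step for one innovation."""

    innovation_id: str
    n_documented: int
    availability_sufficient: bool
    quality_mean: Optional[float]
    quality_sufficient: bool
    overall_score: Optional[float]
    interval_label: Optional[str]
    meaningful: bool
    screening_proceed: Optional[bool]
    screening_reasons: tuple[str, ...]
    canonical: bool = True


def round_score(value: float, config: ToolConfig = DEFAULT_CONFIG) -> float:
    """Round to one decimal using the configured rule (default half-up)."""
    mode = ROUND_HALF_UP if config.rounding == "half_up" else ROUND_HALF_EVEN
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=mode))


def count_documented(
    scorecard: Scorecard, config: ToolConfig = DEFAULT_CONFIG
) -> tuple[int, bool]:
    """Number of attributes with a grade, and whether it reaches the 7/9 bar."""
    n = len(scorecard.documented_attributes())
    return n, n >= config.availability_threshold


def mean_quality(
    scorecard: Scorecard, config: ToolConfig = DEFAULT_CONFIG
) -> tuple[float, bool]:
    """Mean best-source points over attributes with both a grade and a source.

    The sufficiency flag compares the 1-decimal rounded mean against the
    quality threshold (canonically 2 points, boundary inclusive).
    """
    pts = []
    for attr in scorecard.documented_attributes():
        src = scorecard.assessments[attr].best_source
        if src is None:
            logger.info(
                "innovation %s: attribute %s graded but has no source; "
                "excluded from quality mean",
                scorecard.innovation_id,
                attr,
            )
            continue
        pts.append(config.source_points[src])
    if not pts:
        raise QualityNotAssessableError(
            f"innovation {scorecard.innovation_id}: no attribute has a usable source"
        )
    mean = round_score(float(np.mean(pts)), config)
    return mean, mean >= config.quality_threshold


def overall_score(scorecard: Scorecard, config: ToolConfig = DEFAULT_CONFIG) -> float:
    """Mean grade points over documented attributes, rounded to one decimal."""
    documented = scorecard.documented_attributes()
    if not documented:
        raise NoScoreError(
            f"innovation {scorecard.innovation_id}: no documented attribute, no score"
        )
    pts = [grade_to_points(scorecard.assessments[a].grade, config) for a in documented]
    return round_score(float(np.mean(pts)), config)


def classify_interval(score: float, config: ToolConfig = DEFAULT_CONFIG) -> str:
    """Verbal label for a 1-decimal overall score.

    The four printed intervals (1.0-2.0, 2.1-3.0, 3.1-4.0, 4.1-5.0) partition
    the 1-decimal grid exactly, so classification operates on the rounded
    score.
    """
    lo = min(config.interval_edges)
    hi = max(config.grade_points.values())
    if not lo <= score <= hi:
        raise ValueError(f"score {score} outside [{lo}, {hi}]")
    for edge, label in zip(config.interval_edges, INTERVAL_LABELS):
        if score >= edge - 1e-9:
            return label
    return INTERVAL_LABELS[-1]


def rate(scorecard: Scorecard, config: ToolConfig = DEFAULT_CONFIG) -> RatingSummary:
    """Run the full rating step for one scorecard.

    Excluded-at-screening innovations are still rated (the screening outcome
    is reported alongside), and an incomplete screening does not block the
    rating. The overall score is meaningful only when both the availability
    and the quality gates pass.
    """
    n_doc, avail_ok = count_documented(scorecard, config)
    try:
        q_mean, q_ok = mean_quality(scorecard, config)
    except QualityNotAssessableError:
        q_mean, q_ok = None, False
        logger.info("innovation %s: quality not assessable", scorecard.innovation_id)
    try:
        score = overall_score(scorecard, config)
        label = classify_interval(score, config)
    except NoScoreError:
        score, label = None, None
    try:
        outcome = scorecard.screening.outcome()
        proceed, reasons = outcome.proceed, outcome.reasons
    except IncompleteScreeningError:
        proceed, reasons = None, ()
    if not config.canonical:
        logger.warning("non-canonical configuration in use for %s", scorecard.innovation_id)
    return RatingSummary(
        innovation_id=scorecard.innovation_id,
        n_documented=n_doc,
        availability_sufficient=avail_ok,
        quality_mean=q_mean,
        quality_sufficient=q_ok,
        overall_score=score,
        interval_label=label,
        meaningful=avail_ok and q_ok,
        screening_proceed=proceed,
        screening_reasons=reasons,
        canonical=config.canonical,
    )


@dataclass
class SampleSummary:
    """Sample-level descriptive summary of a set of scorecards.

    ``screening`` — include/exclude counts and percentages per criterion plus
    the overall screening outcome; ``grades`` — per-attribute A/B/C/D counts
    with percentages of documented; ``points`` — per-attribute mean/SD/min/max
    of grade points (SD is the sample standard deviation, ddof=1) plus an
    overall-score row; ``rating`` — distributions of the availability,
    quality and interval outcomes.
    """

    n: int
    screening: pd.DataFrame
    grades: pd.DataFrame
    points: pd.DataFrame
    rating: pd.DataFrame


def _pct(count: int, denom: int) -> float:
    return round(100.0 * count / denom) if denom else 0.0


def summarize_sample(
    scorecards: Sequence[Scorecard], config: ToolConfig = DEFAULT_CONFIG
) -> SampleSummary:
    if not scorecards:
        raise ValueError("cannot summarize an empty sample")
    n = len(scorecards)

    # Screening: include/exclude per criterion; exclusion criteria count
    # "yes" as exclude.
    rows = []
    for crit in INCLUSION_CRITERIA + EXCLUSION_CRITERIA:
        answers = [getattr(sc.screening, crit) for sc in scorecards]
        if crit in INCLUSION_CRITERIA:
            inc = sum(a is True for a in answers)
        else:
            inc = sum(a is False for a in answers)
        exc = sum(a is not None for a in answers) - inc
        rows.append((crit, inc, _pct(inc, n), exc, _pct(exc, n)))
    outcomes = []
    for sc in scorecards:
        try:
            outcomes.append(sc.screening.outcome().proceed)
        except IncompleteScreeningError:
            outcomes.append(None)
    inc = sum(o is True for o in outcomes)
    exc = sum(o is False for o in outcomes)
    rows.append(("screening_outcome", inc, _pct(inc, n), exc, _pct(exc, n)))
    screening = pd.DataFrame(
        rows, columns=["criterion", "include", "include_pct", "exclude", "exclude_pct"]
    ).set_index("criterion")

    # Per-attribute grade distribution; percentages are of documented cards.
    grade_rows = []
    point_rows = []
    for attr in ATTRIBUTES:
        grades = [sc.assessments[attr].grade for sc in scorecards]
        doc = [g for g in grades if g is not Grade.MISSING]
        n_doc = len(doc)
        counts = {g: sum(x is Grade[g] for x in doc) for g in "ABCD"}
        grade_rows.append(
            (attr, n_doc)
            + tuple(v for g in "ABCD" for v in (counts[g], _pct(counts[g], n_doc)))
        )
        pts = [config.grade_points[g.value] for g in doc]
        if pts:
            point_rows.append(
                (
                    attr,
                    n_doc,
                    float(np.mean(pts)),
                    float(np.std(pts, ddof=1)) if n_doc > 1 else 0.0,
                    int(np.min(pts)),
                    int(np.max(pts)),
                )
            )
        else:
            point_rows.append((attr, 0, np.nan, np.nan, np.nan, np.nan))
    grades_df = pd.DataFrame(
        grade_rows,
        columns=["attribute", "n_documented"]
        + [f"{g}_{s}" for g in "ABCD" for s in ("count", "pct")],
    ).set_index("attribute")

    summaries = [rate(sc, config) for sc in scorecards]
    scores = [s.overall_score for s in summaries if s.overall_score is not None]
    point_rows.append(
        (
            "overall_score",
            len(scores),
            float(np.mean(scores)) if scores else np.nan,
            float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
            float(np.min(scores)) if scores else np.nan,
            float(np.max(scores)) if scores else np.nan,
        )
    )
    points_df = pd.DataFrame(
        point_rows, columns=["attribute", "n", "mean", "sd", "min", "max"]
    ).set_index("attribute")

    avail = sum(s.availability_sufficient for s in summaries)
    qual = sum(s.quality_sufficient for s in summaries)
    interval_counts = {lab: 0 for lab in INTERVAL_LABELS}
    for s in summaries:
        if s.interval_label is not None:
            interval_counts[s.interval_label] += 1
    rating_rows = [
        ("availability_sufficient", avail, _pct(avail, n)),
        ("availability_insufficient", n - avail, _pct(n - avail, n)),
        ("quality_sufficient", qual, _pct(qual, n)),
        ("quality_insufficient", n - qual, _pct(n - qual, n)),
    ] + [(lab, c, _pct(c, n)) for lab, c in interval_counts.items()]
    rating = pd.DataFrame(rating_rows, columns=["outcome", "count", "pct"]).set_index(
        "outcome"
    )

    return SampleSummary(n=n, screening=screening, grades=grades_df, points=points_df, rating=rating)
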