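"""Configuration for the RIH Tool's scoring constants.

All thresholds of the published instrument live in one validated object so
that every rule applied by the engine is explicit and overridable. The
defaults are the canonical instrument: overriding any of them still works,
but the resulting reports are flagged as non-canonical.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, model_validator

#: Canonical attribute identifiers, in scorecard order.
ATTRIBUTES: tuple[str, ...] = (
    "health_relevance",
    "elsis",
    "health_inequalities",
    "inclusiveness",
    "responsiveness",
    "level_intensity_of_care",
    "frugality",
    "business_model",
    "eco_responsibility",
)

#: Human-readable attribute labels used in reports.
ATTRIBUTE_LABELS: dict[str, str] = {
    "health_relevance": "Health relevance",
    "elsis": "ELSIs",
    "health_inequalities": "Health inequalities",
    "inclusiveness": "Inclusiveness",
    "responsiveness": "Responsiveness",
    "level_intensity_of_care": "Level and intensity of care",
    "frugality": "Frugality",
    "business_model": "Business model",
    "eco_responsibility": "Eco-responsibility",
}

#: The five value domains and their attributes (population health: 3,
#: health system: 3, economic: 1, organizational: 1, environmental: 1).
VALUE_DOMAINS: dict[str, tuple[str, ...]] = {
    "population_health": ("health_relevance", "elsis", "health_inequalities"),
    "health_system": ("inclusiveness", "responsiveness", "level_intensity_of_care"),
    "economic": ("frugality",),
    "organizational": ("business_model",),
    "environmental": ("eco_responsibility",),
}

ATTRIBUTE_DOMAIN: dict[str, str] = {
    attr: dom for dom, attrs in VALUE_DOMAINS.items() for attr in attrs
}

#: Screening criteria: the two inclusion gates must be "yes", the two
#: exclusion gates must be "no" for an innovation to proceed.
INCLUSION_CRITERIA: tuple[str, ...] = ("determinants_of_health", "innovativeness")
EXCLUSION_CRITERIA: tuple[str, ...] = ("unavailability", "corporate_social_irresponsibility")
SCREENING_CRITERIA: tuple[str, ...] = INCLUSION_CRITERIA + EXCLUSION_CRITERIA

#: Interval labels from best to worst.
INTERVAL_LABELS: tuple[str, ...] = (
    "Almost all RIH features are present",
    "Many RIH features are present",
    "Few RIH features are present",
    "Almost no RIH features are present",
)

_CANONICAL_GRADE_POINTS = {"A": 5, "B": 4, "C": 2, "D": 1}
_CANONICAL_SOURCE_POINTS = {1: 1, 2: 2, 3: 3}
# Lower edge of each interval on the 1-decimal score scale, best first.
_CANONICAL_INTERVAL_EDGES = (4.1, 3.1, 2.1, 1.0)


class ToolConfig(BaseModel):
    """Scoring constants of the instrument.

    The defaults reproduce the published tool exactly: the deliberately
    non-equidistant grade points (A=5, B=4, C=2, D=1), source-quality
    points equal to the type number, the availability threshold (>=7 of 9
    attributes documented), the quality threshold (mean source points
    >= 2), and the four score intervals 4.1-5.0 / 3.1-4.0 / 2.1-3.0 /
    1.0-2.0 evaluated on the 1-decimal rounded score.
    """

    grade_points: dict[str, int] = Field(default_factory=lambda: dict(_CANONICAL_GRADE_POINTS))
    source_points: dict[int, int] = Field(default_factory=lambda: dict(_CANONICAL_SOURCE_POINTS))
    availability_threshold: int = 7
    n_attributes: int = 9
    quality_threshold: float = 2.0
    interval_edges: tuple[float, float, float, float] = _CANONICAL_INTERVAL_EDGES
    rounding: Literal["half_up", "half_even"] = "half_up"
    weights_nominal: Literal["identity", "quadratic"] = "identity"
    weights_ordinal: Literal["identity", "quadratic"] = "quadratic"
    confidence_level: float = 0.95

    @model_validator(mode="after")
    def _check(self) -> "ToolConfig":
        if set(self.grade_points) != {"A", "B", "C", "D"}:
            raise ValueError("grade_points must map exactly A, B, C, D")
        if sorted(self.source_points) != [1, 2, 3]:
            raise ValueError("source_points must map types 1, 2, 3")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0, 1)")
        if list(self.interval_edges) != sorted(self.interval_edges, reverse=True):
            raise ValueError("interval_edges must be strictly decreasing")
        return self

    @property
    def canonical(self) -> bool:
        """True when every constant equals the published instrument's value."""
        return (
            self.grade_points == _CANONICAL_GRADE_POINTS
            and self.source_points == _CANONICAL_SOURCE_POINTS
            and self.availability_threshold == 7
            and self.n_attributes == 9
            and self.quality_threshold == 2.0
            and tuple(self.interval_edges) == _CANONICAL_INTERVAL_EDGES
            and self.rounding == "half_up"
        )


DEFAULT_CONFIG = ToolConfig()
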