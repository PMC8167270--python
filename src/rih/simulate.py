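"""Synthetic two-rater ratings and scorecards for offline validation.

The generator emulates a reliability study in which two raters grade the
same items on an ordinal scale: rater 1 draws from a marginal category
distribution; rater 2 copies rater 1 with probability ``agreement_prob``
and otherwise disagrees either by redrawing independently from the marginal
(``independent_redraw``, natural for nominal screening answers) or by
slipping one rank up or down (``adjacent_category``, natural for ordinal
grades, reflected at the scale ends). Cells (or whole items) are then
masked at random to mimic unavailable information.

Because the generating process is fully specified, every agreement
statistic has a closed-form population value here, and the finite-sample
expectation of the AC estimator can be computed analytically to O(1/n) —
see :func:`population_coefficient` and :func:`expected_coefficient`. That
is what makes the estimators testable without any real rater data.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .agreement import RatingsTable, WeightScheme, _resolve_weights
from .config import ATTRIBUTES, DEFAULT_CONFIG, ToolConfig
from .scorecard import AttributeAssessment, Grade, Scorecard, ScreeningRecord

__all__ = [
    "SimulationDesign",
    "simulate_pair",
    "simulate_scorecards",
    "pair_distribution",
    "population_coefficient",
    "expected_coefficient",
    "TABLE_GRADE_MARGINALS",
    "TABLE_MISSING_RATES",
]


class SimulationDesign(BaseModel):
    """Parameters of one synthetic two-rater ratings table.

    Defaults reflect the validation study's setting: 25 items, two raters,
    a 4-level ordinal scale, adjacent-category disagreements.
    """

    n_items: int = 25
    q: int = 4
    marginal: Optional[tuple[float, ...]] = None  # uniform when None
    agreement_prob: float = 0.8
    disagreement_model: str = "adjacent_category"
    missing_rate: float = 0.0
    missing_mode: str = "cell"  # "cell": each cell independently; "item": both cells
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationDesign":
        if self.n_items < 1 or self.q < 2:
            raise ValueError("need n_items >= 1 and q >= 2")
        if not 0 <= self.agreement_prob <= 1:
            raise ValueError("agreement_prob must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.disagreement_model not in ("independent_redraw", "adjacent_category"):
            raise ValueError("unknown disagreement_model")
        if self.missing_mode not in ("cell", "item"):
            raise ValueError("missing_mode must be 'cell' or 'item'")
        if self.marginal is not None:
            m = np.asarray(self.marginal, dtype=float)
            if len(m) != self.q or m.min() < 0 or abs(m.sum() - 1.0) > 1e-9:
                raise ValueError("marginal must be a length-q probability vector")
        return self

    def marginal_vector(self) -> np.ndarray:
        if self.marginal is None:
            return np.full(self.q, 1.0 / self.q)
        return np.asarray(self.marginal, dtype=float)


def simulate_pair(design: SimulationDesign) -> RatingsTable:
    """Draw one seeded two-rater ratings table from the design."""
    rng = np.random.default_rng(design.seed)
    q, n = design.q, design.n_items
    marg = design.marginal_vector()
    r1 = rng.choice(q, size=n, p=marg) + 1
    copy = rng.random(n) < design.agreement_prob
    if design.disagreement_model == "independent_redraw":
        r2_dis = rng.choice(q, size=n, p=marg) + 1
    else:
        step = np.where(
            r1 == 1, 1, np.where(r1 == q, -1, rng.choice([-1, 1], size=n))
        )
        r2_dis = r1 + step
    r2 = np.where(copy, r1, r2_dis)
    ratings = np.stack([r1, r2], axis=1)
    if design.missing_rate > 0:
        if design.missing_mode == "cell":
            mask = rng.random((n, 2)) < design.missing_rate
        else:
            mask = np.repeat(rng.random((n, 1)) < design.missing_rate, 2, axis=1)
        ratings = np.where(mask, 0, ratings)
    rows = [[int(v) if v else None for v in row] for row in ratings]
    categories = [chr(ord("A") + i) for i in range(q)] if q <= 26 else [str(i + 1) for i in range(q)]
    return RatingsTable(rows, categories)


def pair_distribution(design: SimulationDesign) -> np.ndarray:
    """Exact joint distribution P[r1, r2] implied by the design (0-based)."""
    q = design.q
    marg = design.marginal_vector()
    a = design.agreement_prob
    P = np.zeros((q, q))
    for k in range(q):
        P[k, k] += marg[k] * a
        if design.disagreement_model == "independent_redraw":
            P[k, :] += marg[k] * (1 - a) * marg
        else:
            if k == 0:
                P[k, 1] += marg[k] * (1 - a)
            elif k == q - 1:
                P[k, q - 2] += marg[k] * (1 - a)
            else:
                P[k, k - 1] += marg[k] * (1 - a) / 2
                P[k, k + 1] += marg[k] * (1 - a) / 2
    return P


def _population_terms(
    design: SimulationDesign, weights: Union[str, WeightScheme]
) -> tuple[np.ndarray, np.ndarray, float, float, float, np.ndarray]:
    w = _resolve_weights(weights, design.q).matrix
    q = design.q
    P = pair_distribution(design)
    pa = float((P * w).sum())
    pi = (P.sum(axis=1) + P.sum(axis=0)) / 2.0
    c = float(w.sum()) / (q * (q - 1))
    pe = c * float(pi @ (1.0 - pi))
    return P, w, pa, pe, c, pi


def population_coefficient(
    design: SimulationDesign, weights: Union[str, WeightScheme] = "quadratic"
) -> float:
    """Large-sample value of Gwet's AC under the generating process.

    Both pa and pe are evaluated at the generator's true joint distribution;
    this is the limit of the estimator as the number of items grows.
    """
    _, _, pa, pe, _, _ = _population_terms(design, weights)
    return (pa - pe) / (1.0 - pe)


def expected_coefficient(
    design: SimulationDesign, weights: Union[str, WeightScheme] = "quadratic"
) -> float:
    """Finite-sample expectation of the AC estimator, to O(1/n).

    The estimator is a ratio of sample moments, so its mean at n items
    differs from :func:`population_coefficient` by O(1/n) terms. Two
    corrections are applied, both computed exactly from the generator's
    joint distribution: (i) the chance-agreement estimator
    c * sum_k pi_hat_k (1 - pi_hat_k) is biased down by c * Var(s_k)/n per
    category, and (ii) the second-order delta expansion of the ratio
    contributes covariance terms between the observed- and chance-agreement
    estimators (chance agreement linearized in the category propensities).
    Missingness is accounted for by replacing n with the expected number of
    items rated by both raters.
    """
    P, w, pa, pe, c, pi = _population_terms(design, weights)
    q = design.q
    if design.missing_mode == "cell":
        keep = (1.0 - design.missing_rate) ** 2
    else:
        keep = 1.0 - design.missing_rate
    n_eff = design.n_items * keep
    if n_eff < 2:
        raise ValueError("expected complete-pair count below 2")

    # Single-item moments of a = w[r1, r2] and s_k = (1[r1=k] + 1[r2=k])/2.
    idx = np.arange(q)
    Ea = pa
    Ea2 = float((P * w * w).sum())
    # E[s_k s_l] and E[a s_k] by enumeration over the q^2 outcomes.
    s_of = ((idx[:, None, None] == idx[None, :, None]).astype(float)
            + (idx[:, None, None] == idx[None, None, :])) / 2.0  # s_of[k, r1, r2]
    Ess = np.einsum("krs,lrs,rs->kl", s_of, s_of, P)
    Eas = np.einsum("krs,rs,rs->k", s_of, w, P)
    var_s = np.diag(Ess) - pi**2

    lam = c * (1.0 - 2.0 * pi)  # gradient of pe in pi
    var_pe = float(lam @ (Ess - np.outer(pi, pi)) @ lam) / n_eff
    cov_a_pe = float(lam @ (Eas - Ea * pi)) / n_eff

    e_pe = pe - c * float(var_s.sum()) / n_eff  # exact mean of the pe estimator
    mu_a = pa - e_pe
    mu_b = 1.0 - e_pe
    cov_ab = -cov_a_pe + var_pe  # Cov(pa_hat - pe_hat, 1 - pe_hat)
    return mu_a / mu_b - cov_ab / mu_b**2 + mu_a * var_pe / mu_b**3


# --------------------------------------------------------------------------
# Synthetic scorecards

# Default per-attribute grade marginals: the observed A/B/C/D distribution
# of the validation sample (counts normalized per attribute).
TABLE_GRADE_MARGINALS: dict[str, tuple[float, ...]] = {
    "health_relevance": (21 / 25, 1 / 25, 1 / 25, 2 / 25),
    "elsis": (1 / 22, 4 / 22, 16 / 22, 1 / 22),
    "health_inequalities": (10 / 20, 6 / 20, 2 / 20, 2 / 20),
    "inclusiveness": (2 / 21, 4 / 21, 13 / 21, 2 / 21),
    "responsiveness": (18 / 22, 2 / 22, 1 / 22, 1 / 22),
    "level_intensity_of_care": (15 / 23, 2 / 23, 5 / 23, 1 / 23),
    "frugality": (11 / 22, 8 / 22, 3 / 22, 0.0),
    "business_model": (7 / 21, 5 / 21, 5 / 21, 4 / 21),
    "eco_responsibility": (3 / 11, 1 / 11, 7 / 11, 0.0),
}

# Default per-attribute missingness: 1 - documented/25 in the validation
# sample (information simply unavailable for some innovations).
TABLE_MISSING_RATES: dict[str, float] = {
    "health_relevance": 0.0,
    "elsis": 1 - 22 / 25,
    "health_inequalities": 1 - 20 / 25,
    "inclusiveness": 1 - 21 / 25,
    "responsiveness": 1 - 22 / 25,
    "level_intensity_of_care": 1 - 23 / 25,
    "frugality": 1 - 22 / 25,
    "business_model": 1 - 21 / 25,
    "eco_responsibility": 1 - 11 / 25,
}

# Source-type marginal (types 1/2/3). Chosen so roughly a third of
# simulated innovations reach a mean source quality of 2 points, matching
# the validation sample's rating-step distribution.
DEFAULT_SOURCE_MARGINAL: tuple[float, float, float] = (0.4, 0.3, 0.3)

# Screening: inclusion criteria nearly always met in a purposive sample of
# candidate responsible innovations; each exclusion gate trips for ~12%.
DEFAULT_SCREENING_YES_PROBS: dict[str, float] = {
    "determinants_of_health": 1.0,
    "innovativeness": 1.0,
    "unavailability": 0.12,
    "corporate_social_irresponsibility": 0.12,
}

_GRADES = ("A", "B", "C", "D")


def simulate_scorecards(
    n: int = 25,
    grade_marginals: Optional[dict[str, Sequence[float]]] = None,
    source_marginals: Optional[dict[str, Sequence[float]]] = None,
    missing_rates: Optional[dict[str, float]] = None,
    screening_yes_probs: Optional[dict[str, float]] = None,
    seed: int = 0,
    config: ToolConfig = DEFAULT_CONFIG,
) -> list[Scorecard]:
    """Draw a seeded sample of complete scorecards.

    Defaults emulate the validation sample: 25 innovations, per-attribute
    grade marginals and missingness as observed there, and a source-quality
    mix under which about a third of innovations clear the quality gate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grade_marginals = {**TABLE_GRADE_MARGINALS, **(grade_marginals or {})}
    missing_rates = {**TABLE_MISSING_RATES, **(missing_rates or {})}
    source_marginals = {
        **{a: DEFAULT_SOURCE_MARGINAL for a in ATTRIBUTES},
        **(source_marginals or {}),
    }
    screening_yes_probs = {**DEFAULT_SCREENING_YES_PROBS, **(screening_yes_probs or {})}
    for attr in ATTRIBUTES:
        gm = np.asarray(grade_marginals[attr], dtype=float)
        sm = np.asarray(source_marginals[attr], dtype=float)
        if len(gm) != 4 or gm.min() < 0 or abs(gm.sum() - 1) > 1e-9:
            raise ValueError(f"invalid grade marginal for {attr}")
        if len(sm) != 3 or sm.min() < 0 or abs(sm.sum() - 1) > 1e-9:
            raise ValueError(f"invalid source marginal for {attr}")
        if not 0 <= missing_rates[attr] <= 1:
            raise ValueError(f"invalid missing rate for {attr}")

    rng = np.random.default_rng(seed)
    cards = []
    for i in range(n):
        screening = ScreeningRecord(
            **{
                crit: bool(rng.random() < p)
                for crit, p in screening_yes_probs.items()
            }
        )
        assessments = {}
        for attr in ATTRIBUTES:
            if rng.random() < missing_rates[attr]:
                assessments[attr] = AttributeAssessment(attr, Grade.MISSING, ())
            else:
                g = _GRADES[rng.choice(4, p=np.asarray(grade_marginals[attr], dtype=float))]
                src = int(rng.choice(3, p=np.asarray(source_marginals[attr], dtype=float))) + 1
                assessments[attr] = AttributeAssessment(attr, Grade(g), (src,))
        cards.append(
            Scorecard(
                innovation_id=f"SIM-{i + 1:03d}",
                screening=screening,
                assessments=assessments,
                region="synthetic",
            )
        )
    return cards
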