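"""Two-rater agreement statistics: weighted percent agreement and Gwet's AC.

Gwet's AC1 (nominal scales) and AC2 (its weighted extension for ordinal
scales) are chance-corrected agreement coefficients of the form

    gamma = (pa - pe) / (1 - pe)

where ``pa`` is the (possibly weighted) observed agreement and ``pe`` a
chance-agreement probability built from the propensity of raters to use
each category:

    pe = (T_w / (q (q - 1))) * sum_k pi_k (1 - pi_k)

with ``T_w`` the sum of all agreement weights, ``q`` the number of
categories and ``pi_k`` the mean across subjects of the proportion of
raters who placed the subject in category k. With identity weights
(T_w = q) this is AC1; with quadratic weights

    w_kl = 1 - ((k - l) / (q - 1))^2

it is AC2, which grants near-miss disagreements most of the credit —
appropriate for ordinal grades. Unlike kappa-type statistics, pe is not
driven toward pa when the marginal distribution is extreme, which makes the
AC family resistant to the well-known kappa paradoxes.

Standard errors use the subject-level linearization for two raters (no
finite-population correction: the rated subjects are treated as a sample
from an unbounded universe); a delete-one jackknife is provided as an
independent cross-check. Confidence intervals use Student's t with
``n_used - 1`` degrees of freedom and are clipped to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeightScheme",
    "identity_weights",
    "quadratic_weights",
    "RatingsTable",
    "InterRaterAgreement",
    "AgreementResults",
    "CorrelationEstimate",
    "DegenerateTableError",
    "percent_agreement",
    "gwet_ac",
    "landis_koch",
    "hinkle_interpretation",
    "pearson_correlation",
    "sample_size",
]


class DegenerateTableError(ValueError):
    """Chance agreement saturates (pe = 1): the coefficient is undefined."""


# --------------------------------------------------------------------------
# Weight schemes


@dataclass(frozen=True)
class WeightScheme:
    """Symmetric agreement-weight matrix over q ordered categories.

    ``matrix[k, l]`` is the credit (in [0, 1], 1 on the diagonal) granted
    when one rater uses category k+1 and the other l+1.
    """

    kind: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 2:
            raise ValueError("weight matrix must be square with q >= 2")
        if not np.allclose(m, m.T):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("weight matrix diagonal must be 1")
        if m.min() < 0 or m.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)

    @property
    def q(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> float:
        """T_w, the sum of all weights."""
        return float(self.matrix.sum())


def identity_weights(q: int) -> WeightScheme:
    """Exact-match weights: full credit on the diagonal, none elsewhere."""
    if q < 2:
        raise ValueError("q must be >= 2")
    return WeightScheme("identity", np.eye(q))


def quadratic_weights(q: int) -> WeightScheme:
    """Quadratic partial-credit weights w_kl = 1 - ((k - l)/(q - 1))^2."""
    if q < 2:
        raise ValueError("q must be >= 2")
    k = np.arange(q, dtype=float)
    return WeightScheme("quadratic", 1.0 - ((k[:, None] - k[None, :]) / (q - 1)) ** 2)


def _resolve_weights(weights: Union[str, WeightScheme], q: int) -> WeightScheme:
    if isinstance(weights, WeightScheme):
        if weights.q != q:
            raise ValueError(f"weight scheme is {weights.q}x{weights.q}, table has q={q}")
        return weights
    if weights == "identity":
        return identity_weights(q)
    if weights == "quadratic":
        return quadratic_weights(q)
    raise ValueError(f"unknown weight scheme {weights!r}")


# --------------------------------------------------------------------------
# Ratings container


class RatingsTable:
    """n subjects x 2 raters of ordered categorical ratings, missing allowed.

    Ratings are stored as 1-based ranks into ``categories``; 0 encodes a
    missing cell. Agreement statistics use pairwise deletion: only subjects
    rated by both raters enter the computation, which is what produces the
    varying-N column of a per-attribute reliability report.
    """

    def __init__(
        self,
        ratings: Sequence[Sequence[Optional[int]]],
        categories: Sequence[str],
        item_ids: Optional[Sequence[str]] = None,
    ) -> None:
        if len(categories) < 2:
            raise ValueError("need at least 2 categories")
        arr = np.zeros((len(ratings), 2), dtype=int)
        for i, row in enumerate(ratings):
            if len(row) != 2:
                raise ValueError("exactly 2 raters per subject")
            for j, v in enumerate(row):
                if v is None:
                    continue
                v = int(v)
                if not 1 <= v <= len(categories):
                    raise ValueError(f"rating {v} outside 1..{len(categories)}")
                arr[i, j] = v
        self.ratings = arr
        self.categories = tuple(str(c) for c in categories)
        self.item_ids = (
            tuple(str(i) for i in item_ids)
            if item_ids is not None
            else tuple(str(i) for i in range(1, len(ratings) + 1))
        )
        if len(self.item_ids) != len(ratings):
            raise ValueError("item_ids length mismatch")

    @property
    def q(self) -> int:
        return len(self.categories)

    @property
    def n(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_used(self) -> int:
        return int(np.sum(np.all(self.ratings > 0, axis=1)))

    def complete_pairs(self) -> np.ndarray:
        """The (n_used, 2) array of subjects rated by both raters."""
        return self.ratings[np.all(self.ratings > 0, axis=1)]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        categories: Optional[Sequence[str]] = None,
        item_col: str = "item_id",
        rater_col: str = "rater_id",
        value_col: str = "value",
    ) -> "RatingsTable":
        """Build from a long table with one row per (item, rater) rating.

        ``categories`` fixes the ordinal order; if omitted, the sorted
        distinct values are used (correct for A<B<C<D-style labels).
        """
        raters = sorted(df[rater_col].dropna().unique())
        if len(raters) != 2:
            raise ValueError(f"exactly 2 raters required, found {len(raters)}")
        item_order = df[item_col].drop_duplicates().tolist()
        wide = (
            df.pivot_table(index=item_col, columns=rater_col, values=value_col, aggfunc="first")
            .reindex(columns=raters)
            .reindex(index=item_order)
        )
        values = df[value_col].dropna().astype(str)
        values = values[~values.str.upper().isin(["NA", "N/A", ""])]
        if categories is None:
            categories = sorted(values.unique())
        rank = {str(c): i + 1 for i, c in enumerate(categories)}
        unknown = set(values.unique()) - set(rank)
        if unknown:
            raise ValueError(f"values outside the category set: {sorted(unknown)}")

        def to_rank(v: object) -> Optional[int]:
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            s = str(v)
            if s.upper() in ("NA", "N/A", ""):
                return None
            return rank[s]

        rows = [[to_rank(wide.iloc[i, 0]), to_rank(wide.iloc[i, 1])] for i in range(len(wide))]
        return cls(rows, categories, item_ids=[str(i) for i in wide.index])


# --------------------------------------------------------------------------
# Core estimators


def percent_agreement(table: RatingsTable, weights: Union[str, WeightScheme] = "identity") -> float:
    """(Weighted) percent agreement over subjects rated by both raters.

    With identity weights this is the raw proportion of exact agreements;
    with quadratic weights near misses earn partial credit.
    """
    pairs = table.complete_pairs()
    if len(pairs) == 0:
        raise ValueError("no subject rated by both raters")
    w = _resolve_weights(weights, table.q).matrix
    return float(w[pairs[:, 0] - 1, pairs[:, 1] - 1].mean())


@dataclass(frozen=True)
class AgreementResults:
    """Fitted agreement estimate for one ratings table.

    ``coefficient`` is Gwet's AC1 (identity weights) or AC2 (weighted);
    ``se`` is the linearized standard error, ``ci`` the t-based confidence
    interval clipped to [-1, 1], ``p_value`` the two-sided test of
    coefficient = 0 (NaN when the SE is exactly 0, reported "n/a"), and
    ``benchmark`` the Landis-Koch verbal band.
    """

    statistic: str
    pa: float
    pe: float
    coefficient: float
    se: float
    ci: tuple[float, float]
    p_value: float
    n_used: int
    q: int
    conf_level: float
    benchmark: str
    weights_kind: str

    @property
    def p_label(self) -> str:
        if math.isnan(self.p_value):
            return "n/a"
        if self.p_value < 0.001:
            return "<.001"
        return f"{self.p_value:.3f}".lstrip("0")

    def summary(self) -> str:
        lines = [
            f"Gwet's {self.statistic} agreement ({self.weights_kind} weights, "
            f"q={self.q}, N={self.n_used})",
            "-" * 64,
            f"Percent agreement      {self.pa:8.4f}",
            f"Chance agreement       {self.pe:8.4f}",
            f"Coefficient            {self.coefficient:8.4f}   ({self.benchmark})",
            f"Std. error             {self.se:8.5f}",
            f"{round(self.conf_level * 100)}% CI                 "
            f"{self.ci[0]:.3f} to {self.ci[1]:.3f}",
            f"P value (coef = 0)     {self.p_label:>8}",
        ]
        return "\n".join(lines)


class InterRaterAgreement:
    """Model: chance-corrected agreement between two raters.

    Parameters
    ----------
    table : RatingsTable
        Subjects x 2 raters of ordinal/nominal ratings (missing allowed;
        pairwise deletion applies).
    weights : {"identity", "quadratic"} or WeightScheme
        Identity weights give AC1 (nominal scales); quadratic weights give
        AC2 (ordinal scales).
    conf_level : float
        Confidence level for the interval (default 0.95).
    """

    def __init__(
        self,
        table: RatingsTable,
        weights: Union[str, WeightScheme] = "identity",
        conf_level: float = 0.95,
    ) -> None:
        self.table = table
        self.weights = _resolve_weights(weights, table.q)
        if not 0 < conf_level < 1:
            raise ValueError("conf_level must be in (0, 1)")
        self.conf_level = conf_level

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        weights: Union[str, WeightScheme] = "identity",
        categories: Optional[Sequence[str]] = None,
        conf_level: float = 0.95,
        **cols: str,
    ) -> "InterRaterAgreement":
        return cls(
            RatingsTable.from_dataframe(df, categories=categories, **cols),
            weights=weights,
            conf_level=conf_level,
        )

    # -- internals ---------------------------------------------------------

    def _components(self) -> tuple[np.ndarray, np.ndarray, float, float, np.ndarray]:
        """Per-subject agreement a_i, per-subject chance pe_i, pa, pe, pi."""
        pairs = self.table.complete_pairs()
        n, q = len(pairs), self.table.q
        if n < 2:
            raise ValueError("need at least 2 subjects rated by both raters")
        w = self.weights.matrix
        a = w[pairs[:, 0] - 1, pairs[:, 1] - 1]
        # s[i, k]: proportion of the 2 raters placing subject i in category k
        s = ((pairs[:, 0, None] == np.arange(1, q + 1)).astype(float)
             + (pairs[:, 1, None] == np.arange(1, q + 1))) / 2.0
        pi = s.mean(axis=0)
        c = self.weights.total / (q * (q - 1))
        pe_i = c * (s @ (1.0 - pi))
        return a, pe_i, float(a.mean()), float(pe_i.mean()), pi

    def fit(self) -> AgreementResults:
        """Estimate the coefficient, its linearized SE, CI and p-value."""
        a, pe_i, pa, pe, _ = self._components()
        n = len(a)
        if pe >= 1.0 - 1e-12:
            if pa >= 1.0 - 1e-12:
                # saturated but perfectly agreeing: coefficient pinned at 1
                coef = 1.0
            else:
                raise DegenerateTableError("chance agreement saturates (pe = 1)")
        else:
            coef = (pa - pe) / (1.0 - pe)
        # Subject-level linearization: influence of subject i on the
        # coefficient, correcting for its contribution to pe.
        if pe < 1.0 - 1e-12:
            gamma_i = (a - pe) / (1.0 - pe)
            gamma_star = gamma_i - 2.0 * (1.0 - coef) * (pe_i - pe) / (1.0 - pe)
            var = float(np.sum((gamma_star - coef) ** 2)) / (n * (n - 1))
            var = max(var, 0.0)
        else:
            var = 0.0
        se = math.sqrt(var)
        tcrit = float(stats.t.ppf(0.5 + self.conf_level / 2.0, n - 1))
        ci = (max(coef - tcrit * se, -1.0), min(coef + tcrit * se, 1.0))
        if se == 0.0:
            p = float("nan")
        else:
            tval = coef / se
            p = float(2.0 * stats.t.sf(abs(tval), n - 1))
        return AgreementResults(
            statistic="AC1" if self.weights.kind == "identity" else "AC2",
            pa=pa,
            pe=pe,
            coefficient=coef,
            se=se,
            ci=ci,
            p_value=p,
            n_used=n,
            q=self.table.q,
            conf_level=self.conf_level,
            benchmark=landis_koch(coef),
            weights_kind=self.weights.kind,
        )

    def jackknife_se(self) -> float:
        """Delete-one jackknife SE of the coefficient (cross-check oracle)."""
        pairs = self.table.complete_pairs()
        n, q = len(pairs), self.table.q
        if n < 3:
            raise ValueError("jackknife needs at least 3 complete subjects")
        w = self.weights.matrix
        a = w[pairs[:, 0] - 1, pairs[:, 1] - 1]
        s = ((pairs[:, 0, None] == np.arange(1, q + 1)).astype(float)
             + (pairs[:, 1, None] == np.arange(1, q + 1))) / 2.0
        c = self.weights.total / (q * (q - 1))
        sum_a, sum_s = a.sum(), s.sum(axis=0)
        coefs = np.empty(n)
        for i in range(n):
            pa_i = (sum_a - a[i]) / (n - 1)
            pi_i = (sum_s - s[i]) / (n - 1)
            pe_i = c * float(pi_i @ (1.0 - pi_i))
            coefs[i] = (pa_i - pe_i) / (1.0 - pe_i)
        return float(math.sqrt((n - 1) / n * np.sum((coefs - coefs.mean()) ** 2)))


def gwet_ac(
    table: RatingsTable,
    weights: Union[str, WeightScheme] = "identity",
    conf_level: float = 0.95,
) -> AgreementResults:
    """Convenience wrapper: fit Gwet's AC on a ratings table."""
    return InterRaterAgreement(table, weights=weights, conf_level=conf_level).fit()


# --------------------------------------------------------------------------
# Interpretation scales


_LANDIS_KOCH = (
    (0.81, "Almost perfect"),
    (0.61, "Substantial"),
    (0.41, "Moderate"),
    (0.21, "Fair"),
    (0.0, "Slight"),
)


def landis_koch(coefficient: float) -> str:
    """Landis-Koch verbal band for an agreement coefficient.

    Band edges are resolved on the 2-decimal rounded coefficient so the
    printed bands (<0.0, 0.0-0.20, 0.21-0.40, ..., 0.81-1.00) partition.
    """
    if coefficient > 1.0 + 1e-9:
        raise ValueError("agreement coefficient cannot exceed 1")
    c = round(coefficient, 2)
    if c < 0.0:
        return "Poor"
    for edge, label in _LANDIS_KOCH:
        if c >= edge:
            return label
    return "Poor"


_HINKLE = (
    (0.90, "very high"),
    (0.70, "high"),
    (0.50, "moderate"),
    (0.30, "low"),
    (0.0, "negligible"),
)


def hinkle_interpretation(r: float) -> str:
    """Rule-of-thumb verbal band for the size of a Pearson correlation.

    Uses |r| (2-decimal rounded) for the magnitude band; the direction is
    appended for non-negligible correlations.
    """
    if abs(r) > 1.0 + 1e-9:
        raise ValueError("|r| cannot exceed 1")
    m = round(abs(r), 2)
    for edge, label in _HINKLE:
        if m >= edge:
            if label == "negligible":
                return "negligible correlation"
            direction = "positive" if r >= 0 else "negative"
            return f"{label} {direction} correlation"
    return "negligible correlation"


@dataclass(frozen=True)
class CorrelationEstimate:
    r: float
    p_value: float
    n: int
    interpretation: str


def pearson_correlation(x: Iterable[float], y: Iterable[float]) -> CorrelationEstimate:
    """Pearson's r between two score vectors with a two-sided p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationEstimate(
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
        interpretation=hinkle_interpretation(float(res.statistic)),
    )


# --------------------------------------------------------------------------
# Planning


def sample_size(error_margin: float, confidence: float = 0.95) -> int:
    """Subjects needed so the worst-case CI half-width of a two-rater
    percent agreement stays within ``error_margin``.

    Uses the normal approximation at the least favourable proportion 0.5:
    the smallest n with z * sqrt(0.25 / n) <= error_margin. An error margin
    of +/-0.20 at 95% confidence plans for 25 subjects.
    """
    if not 0 < error_margin < 1:
        raise ValueError("error_margin must be in (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    n = max(1, math.ceil((z * 0.5 / error_margin) ** 2 - 1e-9))
    while z * math.sqrt(0.25 / n) > error_margin:  # guard the ceil against fp slop
        n += 1
    return n
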