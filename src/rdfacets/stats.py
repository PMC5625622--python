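"""Ranking, banding, grading and significance-filtering of facet values.

For one facet with *N* distinct values, let c_1..c_N be the whole-database
counts and c'_1..c'_N the counts within the current query result. The
exploratory operations are:

frequency ranking
    descending/ascending order of the chosen counts, ties by label.
average band
    values whose frequency lies inside the closed interval [μ−Mσ, μ+Mσ],
    where μ and σ are the mean and population standard deviation of the
    counts; decreasing M zooms in on the average.
extreme bands
    values strictly above μ+M̄σ (upper) or strictly below μ−M̄σ (lower);
    increasing M̄ zooms in on the extremes.
color grading
    a hue/brightness pair from the standardized deviation z=(f−μ)/σ:
    above-average values render yellow, below-average green, brightness
    proportional to |z| (capped at z=3).
binomial significance
    a facet value is expected in a query with probability p_i = c_i / Σc_j.
    With n' = Σ c'_j result entries, the exact binomial probabilities
    α_i = P(X = c'_i), β_i = P(X > c'_i), γ_i = P(X < c'_i) under
    Bin(n', p_i) measure how surprising the observed count is: a small α_i
    flags the value as unusually represented, β_i / γ_i quantify over- and
    under-representation. Values can be ranked by ascending α and filtered
    to those with α ≤ λ·P_M, where P_M is the smallest (top-ranked) α.

No multiple-testing correction is applied across facet values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .errors import InconsistentCountsError

#: Deviations beyond this many σ render at full brightness.
Z_CAP = 3.0


@dataclass
class FacetDistribution:
    """Counts of the N distinct values of one facet (baseline and in-query)."""

    labels: list[str]
    baseline: list[int]
    query: list[int] | None = None

    def __post_init__(self):
        n = len(self.labels)
        if n < 1:
            raise ValueError("a facet distribution needs at least one value")
        if self.query is None:
            self.query = list(self.baseline)
        if len(self.baseline) != n or len(self.query) != n:
            raise ValueError("labels, baseline and query must have equal length")
        if any(c < 0 for c in self.baseline) or any(c < 0 for c in self.query):
            raise ValueError("counts must be non-negative integers")
        if sum(self.baseline) <= 0:
            raise ValueError("baseline counts must not all be zero")
        for lab, c, q in zip(self.labels, self.baseline, self.query):
            if q > c:
                raise InconsistentCountsError(
                    f"value {lab!r}: in-result count {q} exceeds baseline {c}")

    @classmethod
    def from_facet_counts(cls, counts, facet: str) -> "FacetDistribution":
        """Build from engine ``FacetValueCount`` rows for one facet."""
        rows = sorted((c for c in counts if c.facet == facet),
                      key=lambda c: c.value)
        return cls(labels=[c.value for c in rows],
                   baseline=[c.baseline_count for c in rows],
                   query=[c.query_count for c in rows])

    def present(self) -> "FacetDistribution":
        """The sub-distribution of values present in the current result.

        Facet display lists only values with a non-zero in-result count;
        bands and color grades are computed over this view. The full
        distribution (absent values included) is what the binomial baseline
        proportions must come from.
        """
        keep = [i for i, q in enumerate(self.query) if q > 0]
        if not keep:
            raise ValueError("no facet value is present in the result")
        return FacetDistribution(
            labels=[self.labels[i] for i in keep],
            baseline=[self.baseline[i] for i in keep],
            query=[self.query[i] for i in keep])

    def counts(self, count_field: str = "query") -> np.ndarray:
        if count_field not in ("baseline", "query"):
            raise ValueError("count_field must be 'baseline' or 'query'")
        return np.asarray(self.baseline if count_field == "baseline"
                          else self.query, dtype=float)

    def mean_std(self, count_field: str = "query") -> tuple[float, float]:
        """Mean and population standard deviation of the chosen counts."""
        c = self.counts(count_field)
        return float(c.mean()), float(c.std(ddof=0))


@dataclass(frozen=True)
class BandParams:
    """Tunable band/filter parameters: M (average band half-width in σ),
    M̄ (extreme-band threshold in σ), λ (significance zoom, ≥ 1)."""

    M: float = 1.0
    M_bar: float = 1.0
    lam: float = 2.0

    def __post_init__(self):
        if self.M <= 0 or self.M_bar <= 0:
            raise ValueError("M and M_bar must be strictly positive")
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")


def frequency_rank(dist: FacetDistribution, order: str = "descending",
                   count_field: str = "query") -> list[str]:
    """Labels ordered by frequency; ties broken lexicographically."""
    if order not in ("descending", "ascending"):
        raise ValueError("order must be 'descending' or 'ascending'")
    sign = -1.0 if order == "descending" else 1.0
    c = dist.counts(count_field)
    return [lab for _, lab in
            sorted(zip(sign * c, dist.labels), key=lambda t: (t[0], t[1]))]


def average_band(dist: FacetDistribution, M: float,
                 count_field: str = "query") -> list[str]:
    """Values with frequency inside the closed interval [μ−Mσ, μ+Mσ].

    The interval is closed, so the σ=0 degenerate case (all counts equal)
    retains every value for any M. Decreasing M never grows the set.
    """
    if M <= 0:
        raise ValueError("M must be strictly positive")
    mu, sigma = dist.mean_std(count_field)
    c = dist.counts(count_field)
    keep = (c >= mu - M * sigma) & (c <= mu + M * sigma)
    return [lab for lab, k in zip(dist.labels, keep) if k]


def extreme_band(dist: FacetDistribution, M_bar: float, tail: str = "upper",
                 count_field: str = "query") -> list[str]:
    """Values strictly beyond μ+M̄σ (upper) or μ−M̄σ (lower).

    Strict inequalities make the σ=0 case empty for either tail; increasing
    M̄ never grows the set.
    """
    if M_bar <= 0:
        raise ValueError("M_bar must be strictly positive")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    mu, sigma = dist.mean_std(count_field)
    c = dist.counts(count_field)
    keep = c > mu + M_bar * sigma if tail == "upper" else c < mu - M_bar * sigma
    return [lab for lab, k in zip(dist.labels, keep) if k]


def grade(f: float, mu: float, sigma: float, z_cap: float = Z_CAP
          ) -> tuple[str, float]:
    """Color grade of a frequency: (hue, brightness).

    Hue is ``above_mean`` (rendered yellow) for (f−μ)/σ > 0, otherwise
    ``below_mean`` (green). Brightness is |f−μ|/(σ·z_cap) clipped to [0, 1];
    a zero σ grades everything at brightness 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return "below_mean", 0.0
    z = (f - mu) / sigma
    hue = "above_mean" if z > 0 else "below_mean"
    return hue, float(min(1.0, abs(z) / z_cap))


def binom_significance(dist: FacetDistribution
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact binomial (α, β, γ) for every facet value.

    α_i = P(X = c'_i), β_i = P(X > c'_i), γ_i = P(X < c'_i) under
    Bin(n', p_i) with n' = Σc'_j and p_i = c_i/Σc_j. Probabilities are
    evaluated through log-space gamma functions, so they stay accurate for
    large n'. α+β+γ = 1 for every value.
    """
    c = np.asarray(dist.baseline, dtype=float)
    q = np.asarray(dist.query, dtype=float)
    n_prime = q.sum()
    if np.any(q > n_prime):
        raise InconsistentCountsError(
            "an in-result count exceeds the number of result entries")
    p = c / c.sum()
    alpha = binom.pmf(q, n_prime, p)
    beta = binom.sf(q, n_prime, p)
    gamma = binom.cdf(q - 1, n_prime, p)
    return alpha, beta, gamma


def significance_rank(labels: list[str], probs: np.ndarray) -> list[str]:
    """Labels in ascending order of probability, ties lexicographic.

    Applicable to α (overall surprise), β (over-representation) or γ
    (under-representation).
    """
    return [lab for _, lab in sorted(zip(np.asarray(probs, dtype=float),
                                         labels), key=lambda t: (t[0], t[1]))]


def significance_filter(labels: list[str], probs: np.ndarray,
                        lam: float) -> list[str]:
    """Values whose probability is within λ of the best one.

    With P_M the smallest probability, keeps values with p ≤ λ·P_M. The
    comparison is inclusive so λ=1 retains exactly the top value and its
    exact ties; increasing λ grows the set monotonically.
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    probs = np.asarray(probs, dtype=float)
    p_m = probs.min()
    return [lab for lab, p in zip(labels, probs) if p <= lam * p_m]


@dataclass(frozen=True)
class FacetValueStats:
    """Full per-value statistics row for one facet value."""

    label: str
    baseline_count: int
    query_count: int
    z: float
    hue: str
    brightness: float
    alpha: float
    beta: float
    gamma: float
    rank: int  # ascending-α rank, 1..N


def compute_facet_stats(dist: FacetDistribution, count_field: str = "query",
                        z_cap: float = Z_CAP) -> list[FacetValueStats]:
    """All per-value statistics, in the distribution's label order."""
    mu, sigma = dist.mean_std(count_field)
    alpha, beta, gamma = binom_significance(dist)
    order = significance_rank(dist.labels, alpha)
    rank = {lab: i + 1 for i, lab in enumerate(order)}
    c = dist.counts(count_field)
    rows = []
    for i, lab in enumerate(dist.labels):
        hue, brightness = grade(c[i], mu, sigma, z_cap)
        z = 0.0 if sigma == 0 else (c[i] - mu) / sigma
        rows.append(FacetValueStats(
            label=lab, baseline_count=dist.baseline[i],
            query_count=dist.query[i], z=float(z), hue=hue,
            brightness=brightness, alpha=float(alpha[i]),
            beta=float(beta[i]), gamma=float(gamma[i]), rank=rank[lab]))
    return rows


def facet_stats_view(counts, facet: str, z_cap: float = Z_CAP
                     ) -> list[FacetValueStats]:
    """Per-value statistics for the facet values present in a result.

    *counts* are engine ``FacetValueCount`` rows gathered with
    ``include_absent=True``: the binomial probabilities are computed against
    the full whole-database baseline, while frequencies, z-scores, color
    grades and ranks are given over the present-in-result view (the values a
    facet actually lists).
    """
    full = FacetDistribution.from_facet_counts(counts, facet)
    alpha, beta, gamma = binom_significance(full)
    probs = {lab: (float(alpha[i]), float(beta[i]), float(gamma[i]))
             for i, lab in enumerate(full.labels)}
    present = full.present()
    mu, sigma = present.mean_std("query")
    order = significance_rank(present.labels,
                              [probs[lab][0] for lab in present.labels])
    rank = {lab: i + 1 for i, lab in enumerate(order)}
    rows = []
    for i, lab in enumerate(present.labels):
        f = present.query[i]
        hue, brightness = grade(f, mu, sigma, z_cap)
        z = 0.0 if sigma == 0 else (f - mu) / sigma
        a, b, g = probs[lab]
        rows.append(FacetValueStats(
            label=lab, baseline_count=present.baseline[i], query_count=f,
            z=float(z), hue=hue, brightness=brightness,
            alpha=a, beta=b, gamma=g, rank=rank[lab]))
    return rows
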