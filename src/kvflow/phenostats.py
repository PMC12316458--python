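"""Statistics for left-right phenotype count data.

Experiments scoring heart looping, visceral organ placement or marker
expression yield one categorical outcome per embryo, so a condition is
summarised by a vector of multinomial category counts.  This module
implements the statistics used on such tables:

* a dissimilarity statistic ``delta`` — the sum over categories of absolute
  differences between the two empirical frequency vectors (twice the total
  variation distance);
* a pooled-resplit permutation test of the null hypothesis that two
  conditions share one multinomial outcome distribution;
* a Beta posterior for a binary malformation probability under a uniform
  prior, whose posterior standard deviation provides the error bar;
* the two-sided Fisher exact test for 2x2 tables;
* reconstruction of integer counts from percentages printed to a fixed
  number of decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateTableError,
    DimensionMismatchError,
    DomainError,
    ParameterError,
    ReconstructionError,
)

__all__ = [
    "OutcomeTable",
    "PermutationResult",
    "BinomialPosterior",
    "FisherResult",
    "ReconstructionResult",
    "delta_dissimilarity",
    "permutation_test",
    "binomial_posterior",
    "fisher_exact_two_sided",
    "reconstruct_counts",
    "nearest_counts",
]


@dataclass(frozen=True)
class OutcomeTable:
    """Multinomial category counts observed under one experimental condition.

    Parameters
    ----------
    condition :
        Label of the condition (e.g. ``"WT"`` or ``"triplMut"``).
    categories :
        Ordered category labels, length ``m >= 2``.  The ordering must be
        shared by both tables entering a two-sample comparison.
    counts :
        Non-negative integer count per category.
    """

    condition: str
    categories: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.categories) != len(self.counts):
            raise DimensionMismatchError(
                f"{len(self.categories)} categories but {len(self.counts)} counts"
            )
        if len(self.categories) < 2:
            raise DomainError("an outcome table needs at least two categories")
        if any(c < 0 for c in self.counts):
            raise DomainError(f"negative count in {self.counts}")
        if self.total_n < 1:
            raise DomainError("an outcome table needs at least one observation")

    @property
    def total_n(self) -> int:
        return sum(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.total_n


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the pooled-resplit permutation test."""

    delta_observed: float
    n_resamples: int
    exceedances: int
    p_value: float
    is_lower_bound: bool
    seed: int

    def __post_init__(self):
        assert 0 <= self.exceedances <= self.n_resamples
        assert self.is_lower_bound == (self.exceedances == 0)

    @property
    def reported_p(self) -> float:
        """p to report: exceedances/K, or the resolution bound 1/K when zero.

        With zero exceedances the test only establishes p < 1/K, so the
        bound itself is the honest number to print (``is_lower_bound`` marks
        this case).
        """
        if self.is_lower_bound:
            return 1.0 / self.n_resamples
        return self.p_value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_lower_bound:
            return f"p < {1.0 / self.n_resamples:g} (0/{self.n_resamples} exceedances)"
        return f"p = {self.p_value:g} ({self.exceedances}/{self.n_resamples} exceedances)"


@dataclass(frozen=True)
class BinomialPosterior:
    """Beta posterior over a malformation probability, uniform prior.

    ``k`` malformed outcomes out of ``n`` give posterior Beta(k+1, n-k+1);
    the maximum-likelihood estimate is the empirical frequency k/n and the
    posterior standard deviation serves as the error bar.
    """

    k: int
    n: int
    mle: float = field(init=False)
    alpha_post: int = field(init=False)
    beta_post: int = field(init=False)

    def __post_init__(self):
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not 0 <= self.k <= self.n:
            raise DomainError(f"k={self.k} outside [0, n={self.n}]")
        object.__setattr__(self, "mle", self.k / self.n)
        object.__setattr__(self, "alpha_post", self.k + 1)
        object.__setattr__(self, "beta_post", self.n - self.k + 1)

    @property
    def posterior_mean(self) -> float:
        a, b = self.alpha_post, self.beta_post
        return a / (a + b)

    @property
    def posterior_sd(self) -> float:
        a, b = self.alpha_post, self.beta_post
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    @property
    def interval(self) -> tuple[float, float]:
        """posterior mean +/- one posterior SD, clipped to [0, 1]."""
        m, s = self.posterior_mean, self.posterior_sd
        return (max(0.0, m - s), min(1.0, m + s))

    def distribution(self):
        """The posterior as a frozen ``scipy.stats.beta`` distribution."""
        return stats.beta(self.alpha_post, self.beta_post)


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher exact test result for a 2x2 table."""

    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float


@dataclass(frozen=True)
class ReconstructionResult:
    """Integer counts recovered from printed percentages."""

    total: int
    counts: tuple[int, ...]
    max_deviation: float  # largest |100*k/N - printed| over categories, in points
    exact: bool  # True when every deviation is below half a printed unit


def _as_counts(x) -> np.ndarray:
    if isinstance(x, OutcomeTable):
        x = x.counts
    arr = np.asarray(x, dtype=np.int64)
    if arr.ndim != 1:
        raise DimensionMismatchError("counts must be a 1-D vector")
    if (arr < 0).any():
        raise DomainError(f"negative count in {arr.tolist()}")
    return arr


def _int_delta_statistic(counts_a: np.ndarray, counts_b: np.ndarray, n_a: int, n_b: int):
    """delta * n_a * n_b as an exact integer, immune to float ties."""
    return np.abs(counts_a * n_b - counts_b * n_a).sum(axis=-1)


def delta_dissimilarity(counts_a, counts_b) -> float:
    """Sum over categories of |f_a - f_b| between two frequency vectors.

    The statistic is symmetric, lies in [0, 2] and equals twice the total
    variation distance between the two empirical distributions.
    """
    a = _as_counts(counts_a)
    b = _as_counts(counts_b)
    if a.shape != b.shape:
        raise DimensionMismatchError(
            f"category count mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    n_a, n_b = int(a.sum()), int(b.sum())
    if n_a < 1 or n_b < 1:
        raise DomainError("each condition needs at least one observation")
    return float(_int_delta_statistic(a, b, n_a, n_b)) / (n_a * n_b)


def permutation_test(
    table_a,
    table_b,
    n_resamples: int = 100_000,
    seed: int = 0,
) -> PermutationResult:
    """Pooled-resplit permutation test for two multinomial outcome vectors.

    All ``N_a + N_b`` labelled observations are pooled and repeatedly
    re-separated at random (without replacement) into groups of the original
    sizes; the dissimilarity ``delta'`` of each resplit is compared with the
    observed ``delta``.  The p-value is the frequency of resamples with
    ``delta' >= delta`` (ties count).  Drawing which pooled observations land
    in group *a* is a multivariate hypergeometric draw of the pooled category
    counts, which is how the resampling is executed; the comparison is done
    on the integer statistic ``sum_c |k_a,c*N_b - k_b,c*N_a|`` so ties are
    exact.

    Reproducible for a fixed ``seed``.  With zero exceedances the result
    carries ``is_lower_bound`` and ``reported_p`` returns the bound ``1/K``.
    """
    if n_resamples <= 0:
        raise ParameterError(f"n_resamples must be positive, got {n_resamples}")
    a = _as_counts(table_a)
    b = _as_counts(table_b)
    if a.shape != b.shape:
        raise DimensionMismatchError(
            f"category count mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    n_a, n_b = int(a.sum()), int(b.sum())
    if n_a < 1 or n_b < 1:
        raise DomainError("each condition needs at least one observation")

    t_obs = int(_int_delta_statistic(a, b, n_a, n_b))
    pooled = a + b

    rng = np.random.default_rng(seed)
    # Resplit in chunks to bound memory at large K.
    exceed = 0
    chunk = 200_000
    remaining = n_resamples
    while remaining > 0:
        size = min(chunk, remaining)
        ka = rng.multivariate_hypergeometric(pooled, n_a, size=size)
        kb = pooled[None, :] - ka
        t_perm = np.abs(ka * n_b - kb * n_a).sum(axis=1)
        exceed += int((t_perm >= t_obs).sum())
        remaining -= size

    return PermutationResult(
        delta_observed=t_obs / (n_a * n_b),
        n_resamples=n_resamples,
        exceedances=exceed,
        p_value=exceed / n_resamples,
        is_lower_bound=(exceed == 0),
        seed=seed,
    )


def binomial_posterior(k: int, n: int) -> BinomialPosterior:
    """Posterior over a malformation probability from k malformed out of n.

    Uniform prior on [0, 1]; posterior Beta(k+1, n-k+1).
    """
    return BinomialPosterior(k=int(k), n=int(n))


def fisher_exact_two_sided(table) -> FisherResult:
    """Exact two-sided Fisher test on a 2x2 count table.

    Two-sided by the point-probability convention: the p-value sums the
    hypergeometric probabilities of every table with the same margins whose
    point probability does not exceed that of the observed table.  The
    computation is delegated to :func:`scipy.stats.fisher_exact`, which
    implements exactly this convention.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise DimensionMismatchError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise DomainError("table entries must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero margin in table {arr.tolist()}")
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    return FisherResult(
        table=tuple(tuple(int(v) for v in row) for row in arr),
        p_two_sided=min(p, 1.0),
    )


def _percent_candidate(percentages: np.ndarray, total: int) -> np.ndarray:
    return np.rint(percentages * total / 100.0).astype(np.int64)


def reconstruct_counts(
    percentages: Sequence[float],
    max_total: int = 1000,
    known_total: int | None = None,
    decimals: int = 2,
) -> ReconstructionResult:
    """Recover integer counts from percentages printed to ``decimals`` places.

    Finds the smallest total ``N <= max_total`` (or validates
    ``known_total``) for which non-negative integers summing to ``N``
    reproduce every printed percentage to within half a unit in the last
    printed decimal.  Deterministic; raises :class:`ReconstructionError`
    (listing the nearest misses) when no consistent total exists.
    """
    pct = np.asarray(percentages, dtype=float)
    if pct.ndim != 1 or pct.size < 2:
        raise DimensionMismatchError("need a 1-D vector of >= 2 percentages")
    if (pct < 0).any():
        raise DomainError("percentages must be non-negative")
    if abs(pct.sum() - 100.0) > 0.02:
        raise DomainError(
            f"percentages sum to {pct.sum():.4f}, expected 100 +/- 0.02"
        )
    if max_total < pct.size:
        raise ParameterError("max_total smaller than the number of categories")
    tol = 0.5 * 10.0 ** (-decimals)

    totals = [known_total] if known_total is not None else range(1, max_total + 1)
    near: list[tuple[int, tuple[int, ...], float]] = []
    for total in totals:
        if total < 1:
            raise DomainError(f"invalid total {total}")
        k = _percent_candidate(pct, total)
        if k.sum() != total:
            continue
        dev = float(np.max(np.abs(100.0 * k / total - pct)))
        if dev < tol:
            return ReconstructionResult(
                total=int(total),
                counts=tuple(int(v) for v in k),
                max_deviation=dev,
                exact=True,
            )
        near.append((int(total), tuple(int(v) for v in k), dev))

    near.sort(key=lambda t: t[2])
    raise ReconstructionError(
        f"no integer counts reproduce {pct.tolist()} to +/-{tol:g} "
        f"for any total <= {max_total}"
        + (f" (known_total={known_total})" if known_total is not None else "")
        + (f"; nearest misses: {near[:3]}" if near else ""),
        near_misses=near[:10],
    )


def nearest_counts(percentages: Sequence[float], total: int) -> ReconstructionResult:
    """Nearest-integer counts at a fixed total (largest-remainder rounding).

    For table rows whose printed percentages are internally inconsistent
    with the stated sample size (rounding or transcription slips), this
    returns the integer composition of ``total`` closest to the printed
    row, with the residual mismatch reported in ``max_deviation``.
    """
    pct = np.asarray(percentages, dtype=float)
    if (pct < 0).any():
        raise DomainError("percentages must be non-negative")
    if total < 1:
        raise DomainError("total must be >= 1")
    ideal = pct * total / 100.0
    k = np.floor(ideal).astype(np.int64)
    remainder = ideal - k
    short = int(total - k.sum())
    if short < 0:  # can happen when percentages sum above 100
        order = np.argsort(remainder)
        for i in order[: -short]:
            k[i] -= 1
    else:
        order = np.argsort(-remainder)
        for i in order[:short]:
            k[i] += 1
    dev = float(np.max(np.abs(100.0 * k / total - pct)))
    return ReconstructionResult(
        total=int(total),
        counts=tuple(int(v) for v in k),
        max_deviation=dev,
        exact=bool(dev < 0.005),
    )
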