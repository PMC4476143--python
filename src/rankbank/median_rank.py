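"""Interpolated median rank: a dominance statistic for uneven communities.

The statistic is the (possibly fractional) rank at which the cumulative
descending-abundance curve reaches one half.  The cumulative curve is
taken piecewise linear through ``(0, 0)`` and ``(k, sum of the top-k
fractions)``; anchoring at the origin is what allows values below 1 when
a single OTU holds more than half of a sample.  Roughly, the value is
the number of abundant OTUs in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RankAbundance",
    "MedianRankResult",
    "interpolated_median_rank",
    "classify_median_ranks",
    "dwell_fraction",
]

_KNOT_TOL = 1e-12


@dataclass
class RankAbundance:
    """Descending, normalized abundance vector for one sample.

    ``fractions`` is sorted non-increasing, strictly positive, and sums
    to 1 within 1e-9.  Construct from arbitrary counts or fractions with
    :meth:`from_values` (zeros dropped, ordering canonicalized).
    """

    fractions: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("fractions must be a non-empty 1-D vector")
        if np.any(f <= 0):
            raise ValueError("fractions must be strictly positive (drop zeros first)")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("fractions must be sorted non-increasing")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {f.sum():.12g})")
        self.fractions = f

    @classmethod
    def from_values(
        cls, values: Sequence[float], sample_id: str | None = None
    ) -> "RankAbundance":
        """Build from raw counts or unnormalized abundances.

        Zeros are dropped, values sorted descending and normalized.
        """
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D vector")
        if np.any(v < 0):
            raise ValueError("values must be non-negative")
        v = v[v > 0]
        if v.size == 0:
            raise ValueError("all values are zero")
        v = np.sort(v)[::-1]
        return cls(fractions=v / v.sum(), sample_id=sample_id)

    @property
    def n_otus(self) -> int:
        return int(self.fractions.size)


@dataclass(frozen=True)
class MedianRankResult:
    sample_id: str | None
    median_rank: float
    n_otus: int


def interpolated_median_rank(ra: RankAbundance | Sequence[float]) -> MedianRankResult:
    """Rank at which the cumulative abundance curve crosses 0.5.

    The curve passes through ``(0, 0)`` and ``(k, C_k)`` with
    ``C_k = f_1 + ... + f_k``; the crossing is linearly interpolated
    within the containing unit segment.  A crossing landing exactly on a
    knot returns that integer rank.

    Examples
    --------
    >>> interpolated_median_rank([0.4, 0.3, 0.2, 0.1]).median_rank
    1.3333333333333333
    >>> interpolated_median_rank([0.25, 0.25, 0.25, 0.25]).median_rank
    2.0
    """
    if not isinstance(ra, RankAbundance):
        ra = RankAbundance.from_values(ra)
    cum = np.cumsum(ra.fractions)
    k = int(np.searchsorted(cum, 0.5 - _KNOT_TOL))  # first index with C >= 0.5
    if abs(cum[k] - 0.5) <= _KNOT_TOL:
        rank = float(k + 1)
    else:
        prev = cum[k - 1] if k > 0 else 0.0
        rank = k + (0.5 - prev) / ra.fractions[k]
    return MedianRankResult(
        sample_id=ra.sample_id, median_rank=float(rank), n_otus=ra.n_otus
    )


@dataclass
class MedianRankClassification:
    """Per-sample dominance class plus per-class tallies."""

    classes: dict
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tally = {k: 0 for k in ("low_outlier", "stable", "intermediate", "high_outlier")}
        for c in self.classes.values():
            tally[c] += 1
        self.counts = tally

    def n_outliers(self, include_intermediate: bool = True) -> int:
        n = self.counts["low_outlier"] + self.counts["high_outlier"]
        if include_intermediate:
            n += self.counts["intermediate"]
        return n


def classify_median_ranks(
    results: Iterable[MedianRankResult],
    stable_range: tuple[float, float] = (1.0, 4.0),
    high_range: tuple[float, float] = (6.0, 7.0),
) -> MedianRankClassification:
    """Classify samples by median rank.

    ``low_outlier``: below the stable range; ``stable``: inside it
    (inclusive); ``high_outlier``: at or above ``high_range`` minimum;
    ``intermediate``: between stable and high.
    """
    lo, hi = stable_range
    h_lo, h_hi = high_range
    if not (lo < hi <= h_lo < h_hi):
        raise ValueError(
            f"malformed ranges: stable={stable_range}, high={high_range}"
        )
    results = list(results)
    if not results:
        raise ValueError("no results to classify")
    classes: dict = {}
    for i, res in enumerate(results):
        key = res.sample_id if res.sample_id is not None else i
        r = res.median_rank
        if r < lo:
            classes[key] = "low_outlier"
        elif r <= hi:
            classes[key] = "stable"
        elif r >= h_lo:
            classes[key] = "high_outlier"
        else:
            classes[key] = "intermediate"
    return MedianRankClassification(classes=classes)


@dataclass(frozen=True)
class DwellFractionResult:
    fraction: float
    n_outliers: int
    n_total: int
    ci_low: float
    ci_high: float
    confidence: float


def dwell_fraction(
    results: Iterable[MedianRankResult],
    stable_range: tuple[float, float] = (1.0, 4.0),
    high_range: tuple[float, float] = (6.0, 7.0),
    confidence: float = 0.95,
) -> DwellFractionResult:
    """Fraction of samples outside the stable dominance band.

    Under the assumption that samples are uniform snapshots of a
    recurring boom-and-crash cycle, this estimates the share of cycle
    time spent in the transient (outlier) stages.  Every non-stable
    sample counts as an outlier.  The interval is exact Clopper-Pearson.
    """
    results = list(results)
    cls = classify_median_ranks(results, stable_range, high_range)
    k = cls.n_outliers(include_intermediate=True)
    n = len(results)
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return DwellFractionResult(
        fraction=k / n, n_outliers=k, n_total=n,
        ci_low=lo, ci_high=hi, confidence=confidence,
    )
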