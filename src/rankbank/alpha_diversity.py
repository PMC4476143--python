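"""Per-sample richness and diversity: analytic rarefaction, Chao1,
inverse Simpson."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .otu_io import OtuTable

__all__ = [
    "RarefactionCurve",
    "DiversityEstimate",
    "rarefaction_curve",
    "rarefaction_resampled",
    "chao1",
    "inverse_simpson",
    "alpha_table",
]


def _clean_counts(counts: Sequence[float]) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if np.any(c < 0) or np.any(c != np.round(c)):
        raise ValueError("counts must be non-negative integers")
    c = c[c > 0].astype(np.int64)
    if c.size == 0:
        raise ValueError("all counts are zero")
    return c


@dataclass(frozen=True)
class RarefactionCurve:
    """Expected richness at increasing subsample sizes for one sample."""

    sample_id: str | None
    n: np.ndarray          # subsample sizes, ascending, last = total reads
    expected_s: np.ndarray  # E[S_n]

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "n": self.n, "expected_s": self.expected_s}
        )


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def rarefaction_curve(
    counts: Sequence[float], step: int = 1, sample_id: str | None = None
) -> RarefactionCurve:
    """Analytic (hypergeometric) rarefaction.

    ``E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)]`` evaluated at
    ``n = step, 2*step, ..., N`` (N always included), computed with
    log-gamma to avoid overflow.
    """
    c = _clean_counts(counts)
    if step < 1:
        raise ValueError("step must be >= 1")
    total = int(c.sum())
    sizes = np.arange(step, total + 1, step, dtype=np.int64)
    if sizes.size == 0 or sizes[-1] != total:
        sizes = np.append(sizes, total)
    # log C(N - N_i, n) - log C(N, n), with C(m, n) = 0 when n > m
    expected = np.empty(sizes.size)
    log_cn = _log_comb(total, sizes)
    for idx, n in enumerate(sizes):
        m = total - c  # per-OTU remaining pool
        ok = m >= n
        absent = np.zeros(c.size)
        absent[ok] = np.exp(_log_comb(m[ok], n) - log_cn[idx])
        expected[idx] = np.sum(1.0 - absent)
    return RarefactionCurve(sample_id=sample_id, n=sizes, expected_s=expected)


def rarefaction_resampled(
    counts: Sequence[float],
    step: int = 1,
    n_iter: int = 100,
    seed: int | None = None,
    sample_id: str | None = None,
) -> RarefactionCurve:
    """Monte-Carlo rarefaction (subsampling without replacement).

    Cross-check for :func:`rarefaction_curve`; not used by the pipeline.
    """
    c = _clean_counts(counts)
    rng = np.random.default_rng(seed)
    total = int(c.sum())
    pool = np.repeat(np.arange(c.size), c)
    sizes = np.arange(step, total + 1, step, dtype=np.int64)
    if sizes.size == 0 or sizes[-1] != total:
        sizes = np.append(sizes, total)
    acc = np.zeros(sizes.size)
    for _ in range(n_iter):
        perm = rng.permutation(pool)
        for idx, n in enumerate(sizes):
            acc[idx] += np.unique(perm[:n]).size
    return RarefactionCurve(sample_id=sample_id, n=sizes, expected_s=acc / n_iter)


def chao1(counts: Sequence[float], variant: str = "bias_corrected") -> float:
    """Chao1 minimum-richness estimate from singleton/doubleton counts.

    ``classic``: ``S_obs + F1^2 / (2 F2)``; ``bias_corrected`` (default):
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``.  The classic form with no
    doubletons falls back to the bias-corrected form with a warning.
    """
    c = _clean_counts(counts)
    s_obs = c.size
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if variant == "classic":
        if f2 == 0:
            warnings.warn(
                "classic Chao1 undefined with no doubletons; "
                "using bias-corrected form",
                UserWarning,
            )
            return chao1(counts, variant="bias_corrected")
        return s_obs + f1 * f1 / (2.0 * f2)
    if variant == "bias_corrected":
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    raise ValueError(f"unknown Chao1 variant {variant!r}")


def inverse_simpson(counts: Sequence[float], estimator: str = "unbiased") -> float:
    """Inverse Simpson diversity.

    ``plugin``: ``1 / sum(p_i^2)`` — ranges from 1 (one OTU) to S
    (perfectly even).  ``unbiased`` (default, mothur-compatible):
    ``N (N - 1) / sum(n_i (n_i - 1))``; all-singleton input makes the
    unbiased form infinite, reported as ``inf`` with a warning.
    """
    c = _clean_counts(counts)
    total = int(c.sum())
    if estimator == "plugin":
        p = c / total
        return float(1.0 / np.sum(p * p))
    if estimator == "unbiased":
        if total < 2:
            raise ValueError("unbiased inverse Simpson requires N >= 2")
        denom = float(np.sum(c * (c - 1.0)))
        if denom == 0.0:
            warnings.warn(
                "all OTUs are singletons; unbiased inverse Simpson is infinite",
                UserWarning,
            )
            return float("inf")
        return total * (total - 1.0) / denom
    raise ValueError(f"unknown inverse Simpson estimator {estimator!r}")


def alpha_table(table: OtuTable, rarefaction_step: int | None = None) -> pd.DataFrame:
    """Tidy per-sample diversity summary (one row per sample/metric/variant)."""
    rows = []
    for sid, row in zip(table.sample_ids, table.counts):
        c = row[row > 0]
        rows.append((sid, "s_obs", "observed", float(c.size)))
        rows.append((sid, "chao1", "bias_corrected", chao1(c)))
        rows.append((sid, "chao1", "classic", chao1(c, variant="classic")))
        rows.append((sid, "inv_simpson", "unbiased", inverse_simpson(c)))
        rows.append((sid, "inv_simpson", "plugin", inverse_simpson(c, "plugin")))
    return pd.DataFrame(rows, columns=["sample_id", "metric", "variant", "value"])


def rarefaction_table(table: OtuTable, step: int = 1) -> pd.DataFrame:
    """Rarefaction curves for every sample, long format."""
    frames = [
        rarefaction_curve(row, step=step, sample_id=sid).as_dataframe()
        for sid, row in zip(table.sample_ids, table.counts)
    ]
    return pd.concat(frames, ignore_index=True)
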