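"""Least-squares fits of rank-abundance curves.

Three shapes are fitted to each sample's descending normalized
abundances ``y_r`` at ranks ``r = 1..S``:

power        ``f(r) = a * r**(-b)``
exponential  ``f(r) = a * exp(-k * r)``
lognormal    ``f(r) = exp(mu + sigma * Phi^{-1}(1 - (r - 0.5) / S))``

Fits minimise the SSE on the *untransformed* fractions (matching
spreadsheet-solver practice on rank-abundance plots); log-space
regressions serve only as starting points.  An alternative lognormal
parameterization, a Gaussian in log-rank
``f(r) = a * exp(-(ln r - mu)^2 / (2 sigma^2))``, is available via
``lognormal_form="gaussian_logrank"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .median_rank import RankAbundance
from .otu_io import OtuTable

__all__ = [
    "RadFitResult",
    "fit_rad",
    "fit_all_models",
    "best_model",
    "parameter_correlation",
    "rad_fit_table",
    "MODELS",
]

MODELS = ("power", "exponential", "lognormal")
_TIE_ORDER = {m: i for i, m in enumerate(MODELS)}
_SSE_TOL = 1e-10


@dataclass(frozen=True)
class RadFitResult:
    """One model family fitted to one sample's rank-abundance curve."""

    sample_id: str | None
    model: str
    params: dict
    sse: float
    converged: bool
    n_points: int

    @property
    def shape_param(self) -> float:
        """The decay-rate parameter: b, k, or sigma."""
        for key in ("b", "k", "sigma"):
            if key in self.params:
                return self.params[key]
        raise KeyError("no shape parameter in params")


def _lognormal_quantiles(s: int) -> np.ndarray:
    # midpoint plotting positions (r - 0.5)/S mapped through the normal quantile
    r = np.arange(1, s + 1)
    return stats.norm.ppf(1.0 - (r - 0.5) / s)


def _model_predict(model: str, theta: np.ndarray, r: np.ndarray, q: np.ndarray):
    if model == "power":
        a, b = theta
        return a * r ** (-b)
    if model == "exponential":
        a, k = theta
        return a * np.exp(-k * r)
    if model == "lognormal":
        mu, sigma = theta
        return np.exp(mu + sigma * q)
    if model == "gaussian_logrank":
        a, mu, sigma = theta
        return a * np.exp(-((np.log(r) - mu) ** 2) / (2.0 * sigma**2))
    raise ValueError(f"unknown model {model!r}")


def _seeds(model: str, y: np.ndarray, r: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """Log-linear regression seeds plus fixed perturbations (multi-start)."""
    ly = np.log(y)
    if model == "power":
        slope, intercept = np.polyfit(np.log(r), ly, 1)
        base = np.array([np.exp(intercept), max(-slope, 1e-3)])
        scales = [1.0, 0.5, 2.0]
        return [base * np.array([1.0, s]) for s in scales]
    if model == "exponential":
        slope, intercept = np.polyfit(r, ly, 1)
        base = np.array([np.exp(intercept), max(-slope, 1e-4)])
        return [base * np.array([1.0, s]) for s in (1.0, 0.5, 2.0)]
    if model == "lognormal":
        sigma, mu = np.polyfit(q, ly, 1)
        sigma = max(sigma, 1e-3)
        return [
            np.array([mu, sigma]),
            np.array([mu, sigma * 2.0]),
            np.array([mu - 1.0, sigma * 0.5]),
        ]
    if model == "gaussian_logrank":
        a0 = float(y[0])
        return [
            np.array([a0, 0.0, 1.0]),
            np.array([a0, 1.0, 2.0]),
            np.array([2 * a0, -1.0, 0.5]),
        ]
    raise ValueError(f"unknown model {model!r}")


def _bounds(model: str) -> tuple[np.ndarray, np.ndarray]:
    if model in ("power", "exponential"):
        return np.array([1e-12, 1e-9]), np.array([np.inf, np.inf])
    if model == "lognormal":
        return np.array([-np.inf, 1e-9]), np.array([np.inf, np.inf])
    if model == "gaussian_logrank":
        return np.array([1e-12, -np.inf, 1e-9]), np.array([np.inf, np.inf, np.inf])
    raise ValueError(f"unknown model {model!r}")


def fit_rad(
    ra: RankAbundance | Sequence[float],
    model: str,
    lognormal_form: str = "quantile",
) -> RadFitResult:
    """Fit one model family by multi-start nonlinear least squares.

    Raises if there are fewer points than parameters + 1.  A fit that
    fails to converge is returned flagged ``converged=False``, never
    silently.
    """
    if not isinstance(ra, RankAbundance):
        ra = RankAbundance.from_values(ra)
    fit_model = model
    if model == "lognormal" and lognormal_form == "gaussian_logrank":
        fit_model = "gaussian_logrank"
    elif model == "lognormal" and lognormal_form != "quantile":
        raise ValueError(f"unknown lognormal_form {lognormal_form!r}")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")

    y = ra.fractions
    s = y.size
    n_params = 3 if fit_model == "gaussian_logrank" else 2
    if s < n_params + 1:
        raise ValueError(
            f"{model} fit needs at least {n_params + 1} nonzero ranks, got {s}"
        )
    r = np.arange(1, s + 1, dtype=float)
    q = _lognormal_quantiles(s)
    lo, hi = _bounds(fit_model)

    best_theta, best_sse, ok = None, np.inf, False
    for seed in _seeds(fit_model, y, r, q):
        theta0 = np.clip(seed, lo + 1e-12, None)
        try:
            res = optimize.least_squares(
                lambda th: _model_predict(fit_model, th, r, q) - y,
                theta0,
                bounds=(lo, hi),
                xtol=1e-14,
                ftol=_SSE_TOL,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:  # numerical failure on one start is not fatal
            continue
        sse = float(2.0 * res.cost)
        if sse < best_sse - 1e-18 or best_theta is None:
            best_theta, best_sse = res.x, sse
            ok = bool(res.success)
    if best_theta is None:
        return RadFitResult(ra.sample_id, model, {}, np.inf, False, s)

    names = {
        "power": ("a", "b"),
        "exponential": ("a", "k"),
        "lognormal": ("mu", "sigma"),
        "gaussian_logrank": ("a", "mu", "sigma"),
    }[fit_model]
    params = dict(zip(names, map(float, best_theta)))
    return RadFitResult(ra.sample_id, model, params, best_sse, ok, s)


def fit_all_models(
    ra: RankAbundance | Sequence[float], lognormal_form: str = "quantile"
) -> dict[str, RadFitResult]:
    return {m: fit_rad(ra, m, lognormal_form=lognormal_form) for m in MODELS}


def best_model(results: Iterable[RadFitResult]) -> str | None:
    """Model with minimal SSE; ties broken power < exponential < lognormal.

    Returns None (with a warning) if any fit did not converge.
    """
    results = list(results)
    if {r.model for r in results} != set(MODELS):
        raise ValueError("need exactly one fit per model family")
    if not all(r.converged for r in results):
        bad = [r.model for r in results if not r.converged]
        warnings.warn(f"unconverged fits ({bad}); best model withheld", UserWarning)
        return None
    return min(results, key=lambda r: (round(r.sse / 1e-12) * 1e-12, _TIE_ORDER[r.model])).model


@dataclass(frozen=True)
class ParameterCorrelation:
    r: float
    n: int
    sample_ids: tuple
    degenerate: bool = False


def parameter_correlation(results: Iterable[RadFitResult]) -> ParameterCorrelation:
    """Pearson correlation between fitted power-law ``b`` and exponential ``k``
    across samples (pairing by sample id)."""
    by_sample: dict = {}
    for res in results:
        if res.model in ("power", "exponential") and res.converged:
            by_sample.setdefault(res.sample_id, {})[res.model] = res
    pairs = {
        sid: (d["power"].params["b"], d["exponential"].params["k"])
        for sid, d in by_sample.items()
        if "power" in d and "exponential" in d
    }
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 samples with both fits, got {len(pairs)}")
    sids = tuple(pairs)
    b = np.array([pairs[s][0] for s in sids])
    k = np.array([pairs[s][1] for s in sids])
    if np.ptp(b) == 0 or np.ptp(k) == 0:
        return ParameterCorrelation(r=float("nan"), n=len(sids), sample_ids=sids,
                                    degenerate=True)
    r = float(np.corrcoef(b, k)[0, 1])
    return ParameterCorrelation(r=r, n=len(sids), sample_ids=sids)


def rad_fit_table(table: OtuTable, lognormal_form: str = "quantile") -> pd.DataFrame:
    """Fit all three models to every sample; tidy output with best-model flags."""
    rows = []
    for sid, row in zip(table.sample_ids, table.counts):
        ra = RankAbundance.from_values(row, sample_id=sid)
        fits = fit_all_models(ra, lognormal_form=lognormal_form)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            winner = best_model(fits.values())
        for m, res in fits.items():
            keys = list(res.params)
            rows.append(
                {
                    "sample_id": sid,
                    "model": m,
                    "param1_name": keys[0] if keys else "",
                    "param1": res.params.get(keys[0]) if keys else np.nan,
                    "param2_name": keys[1] if len(keys) > 1 else "",
                    "param2": res.params.get(keys[1]) if len(keys) > 1 else np.nan,
                    "sse": res.sse,
                    "converged": res.converged,
                    "best": m == winner,
                }
            )
    return pd.DataFrame(rows)
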