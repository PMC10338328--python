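"""Derived resistance summaries.

Everything here is computed draw-by-draw from the posterior: lethal
concentrations LC_q, the LC10-LC90 heterogeneity span, the lethal-dose
density (inverse transform sampling), assay variability (per-draw mean
absolute error on the percent-mortality scale), background mortality, and
classical fit statistics (R^2, RMSE).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import CurveParams, TemporalParams, mortality_from_arrays
from .data import BioassayDataset
from .sampling import PosteriorSamples

__all__ = [
    "LCEstimate",
    "VariabilityEstimate",
    "LCComparison",
    "lc_quantile",
    "lc_posterior",
    "lethal_dose_samples",
    "variability",
    "fit_statistics",
    "compare_lc",
    "background_mortality_summary",
    "heterogeneity",
    "fitted_mortality",
    "metrics_report",
]


def _lc_model_scale(B, C, E, q):
    """Model-scale dose x* solving the background-corrected mortality = q.

    Rearranging the 5PL with background correction (p - A) / (1 - A) = q
    gives  x* = exp(C + ln((1-q)^(-1/E) - 1) / B); the background level A
    cancels, so LC_q is independent of A.
    """
    return np.exp(C + np.log(np.power(1.0 - q, -1.0 / np.asarray(E)) - 1.0) / B)


def lc_quantile(params, q: float, year: int | None = None) -> float:
    """Lethal concentration (% a.i., raw scale) at mortality quantile ``q``.

    The closed form is solved on the sqrt-dose model scale and squared to
    undo the concentration transform.  Temporal parameter sets require
    ``year``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if isinstance(params, TemporalParams):
        if year is None:
            raise ValueError("temporal parameters require a year")
        params = params.curve_for_year(int(year))
    if not isinstance(params, CurveParams):
        raise TypeError(f"expected CurveParams, got {type(params).__name__}")
    x = _lc_model_scale(params.B, params.C, params.E, q)
    return float(x * x)


@dataclasses.dataclass
class LCEstimate:
    """Posterior lethal-concentration estimate at quantile ``q``.

    ``point`` is the posterior median; ``mean`` is also carried because
    strain-level tables are often reported as the mean across draws.
    """

    q: float
    draws: np.ndarray
    summary_type: str = "median"

    @property
    def point(self) -> float:
        return float(np.median(self.draws))

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def interval(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.draws, [2.5, 97.5])
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        lo, hi = self.interval
        return {
            "q": self.q,
            "point": self.point,
            "mean": self.mean,
            "lower": lo,
            "upper": hi,
            "summary_type": self.summary_type,
        }

    def __repr__(self) -> str:
        lo, hi = self.interval
        return f"LC{self.q * 100:g} = {self.point:.4g} (95% CI {lo:.4g}-{hi:.4g})"


@dataclasses.dataclass
class VariabilityEstimate:
    """Per-draw mean absolute deviation of observed from fitted mortality (%)."""

    values: np.ndarray  # one value per posterior draw, percent scale

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def interval(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.values, [2.5, 97.5])
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        lo, hi = self.interval
        return {"median": self.median, "lower": lo, "upper": hi}


@dataclasses.dataclass
class LCComparison:
    """Posterior overlap probability P[LC_a > LC_b] from paired resampling."""

    probability: float
    count: int
    n_pairs: int

    def __float__(self) -> float:
        return self.probability

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def lc_posterior(
    samples: PosteriorSamples, q: float, year: int | None = None
) -> LCEstimate:
    """Apply the LC_q closed form to every retained posterior draw."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    arr = samples.curve_arrays(year=year)
    x = _lc_model_scale(arr["B"], arr["C"], arr["E"], q)
    return LCEstimate(q=q, draws=x * x)


def heterogeneity(samples: PosteriorSamples, year: int | None = None) -> dict:
    """LC10/LC90 means across draws and their difference (% a.i.).

    A wide LC10-LC90 span indicates a heterogeneous population: some
    mosquitoes die at low doses while others survive much higher ones.
    """
    lc10 = lc_posterior(samples, 0.1, year=year)
    lc90 = lc_posterior(samples, 0.9, year=year)
    return {
        "lc10": lc10.mean,
        "lc90": lc90.mean,
        "difference": lc90.mean - lc10.mean,
    }


def lethal_dose_samples(
    samples: PosteriorSamples,
    n_samples: int,
    seed: int = 0,
    year: int | None = None,
) -> np.ndarray:
    """Draws from the lethal-dose distribution by inverse transform sampling.

    Each sample pairs a uniformly chosen posterior draw with u ~ U(0, 1)
    and returns LC_u; the empirical distribution is the (background-
    corrected) density of the concentration at which an individual
    mosquito dies.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    rng = np.random.default_rng(seed)
    arr = samples.curve_arrays(year=year)
    idx = rng.integers(0, arr["A"].size, size=n_samples)
    u = rng.uniform(size=n_samples)
    x = _lc_model_scale(arr["B"][idx], arr["C"][idx], arr["E"][idx], u)
    return x * x


def fitted_mortality(samples: PosteriorSamples, dataset: BioassayDataset) -> np.ndarray:
    """(n_draws, n_records) fitted mean mortality for every retained draw."""
    with np.errstate(divide="ignore"):
        lnx = 0.5 * np.log(dataset.concentrations)
    if samples.variant == "base":
        arr = samples.curve_arrays()
        return mortality_from_arrays(
            arr["A"][:, None], arr["B"][:, None], arr["C"][:, None],
            arr["E"][:, None], lnx[None, :],
        )
    years = dataset.years
    if years is None:
        raise ValueError("temporal samples require years on the dataset")
    uyears = sorted(set(int(y) for y in years))
    year_idx = np.searchsorted(uyears, years)
    per = {k: [] for k in ("A", "B", "C", "E")}
    for y in uyears:
        arr = samples.curve_arrays(year=y)
        for k in per:
            per[k].append(arr[k])
    mats = {k: np.stack(v, axis=1) for k, v in per.items()}  # (n_draws, n_years)
    return mortality_from_arrays(
        mats["A"][:, year_idx], mats["B"][:, year_idx],
        mats["C"][:, year_idx], mats["E"][:, year_idx], lnx[None, :],
    )


def variability(
    dataset: BioassayDataset,
    samples: PosteriorSamples,
    mode: str = "curve",
    seed: int = 0,
) -> VariabilityEstimate:
    """Assay variability: per-draw mean absolute error, percent scale.

    For each retained draw j,  v_j = sum_i |y_i - y'_ij| / n  where y_i is
    the observed percent mortality and y'_ij the fitted-curve percent
    mortality at record i (``mode="curve"``, the default reading) or a
    binomial posterior-predictive replicate (``mode="predictive"``).
    Summarised by the median and 2.5-97.5% quantiles across draws and
    interpreted as percent variability in mortality from the best-fit line.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    p = fitted_mortality(samples, dataset)
    obs = dataset.mortality * 100.0
    if mode == "curve":
        fit = p * 100.0
    elif mode == "predictive":
        rng = np.random.default_rng(seed)
        y_rep = rng.binomial(dataset.n_tested[None, :], p)
        fit = y_rep / dataset.n_tested[None, :] * 100.0
    else:
        raise ValueError("mode must be 'curve' or 'predictive'")
    values = np.abs(obs[None, :] - fit).mean(axis=1)
    return VariabilityEstimate(values=values)


def mean_absolute_deviation(observed_pct, fitted_pct) -> float:
    """Single-draw variability: mean |observed - fitted| in percent."""
    o = np.asarray(observed_pct, dtype=float)
    f = np.asarray(fitted_pct, dtype=float)
    if o.size == 0:
        raise ValueError("empty input")
    return float(np.abs(o - f).mean())


def fit_statistics(dataset: BioassayDataset, samples: PosteriorSamples) -> dict:
    """R^2 and RMSE of observed percent mortality vs the posterior-median curve."""
    p = fitted_mortality(samples, dataset)
    fitted = np.median(p, axis=0) * 100.0
    obs = dataset.mortality * 100.0
    resid = obs - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        import warnings

        warnings.warn("zero variance in observations; R^2 undefined", RuntimeWarning)
        r2 = math.nan
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean(resid**2)))
    resid_by_conc = (
        pd.DataFrame({"concentration": dataset.concentrations, "residual": resid})
        .groupby("concentration")["residual"]
        .agg(["mean", "std", "count"])
    )
    return {"r2": r2, "rmse": rmse, "residuals": resid, "residuals_by_concentration": resid_by_conc}


def compare_lc(
    lc_a: LCEstimate,
    lc_b: LCEstimate,
    n_pairs: int = 10000,
    seed: int = 0,
) -> LCComparison:
    """P[LC_a > LC_b] by resampling independent pairs of posterior draws."""
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    rng = np.random.default_rng(seed)
    a = rng.choice(lc_a.draws, size=n_pairs, replace=True)
    b = rng.choice(lc_b.draws, size=n_pairs, replace=True)
    count = int(np.sum(a > b))
    return LCComparison(probability=count / n_pairs, count=count, n_pairs=n_pairs)


def background_mortality_summary(samples: PosteriorSamples) -> dict:
    """Posterior background mortality A on the percent scale.

    For ``base_time`` fits the per-year A draws are averaged within each
    draw before summarising.
    """
    if samples.variant == "base_time":
        a = np.mean(
            [samples.stacked(f"A[{y}]") for y in samples.years], axis=0
        )
    else:
        a = samples.stacked("A")
    a = a * 100.0
    lo, hi = np.percentile(a, [2.5, 97.5])
    return {
        "mean": float(a.mean()),
        "median": float(np.median(a)),
        "lower": float(lo),
        "upper": float(hi),
    }


def metrics_report(
    dataset: BioassayDataset,
    samples: PosteriorSamples,
    qs: Sequence[float] = (0.1, 0.5, 0.9),
    year: int | None = None,
    seed: int = 0,
) -> dict:
    """JSON-ready bundle of the standard resistance summaries."""
    report = {
        "lc": {f"lc{q * 100:g}": lc_posterior(samples, q, year=year).to_dict() for q in qs},
        "heterogeneity": heterogeneity(samples, year=year),
        "background_mortality": background_mortality_summary(samples),
        "variability": variability(dataset, samples, seed=seed).to_dict(),
    }
    stats = fit_statistics(dataset, samples)
    report["r2"] = None if math.isnan(stats["r2"]) else stats["r2"]
    report["rmse"] = stats["rmse"]
    return report
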