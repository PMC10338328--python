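"""Model and Results objects tying data, curves and sampling together.

Usage mirrors the fit/results split familiar from statistical modelling
libraries::

    model = DoseResponseModel(dataset, variant="base")
    res = model.fit(seed=1)
    print(res.summary())
    res.lc(0.5)            # posterior LC50
    res.variability()
    res.loo()
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .curves import (
    PriorSpec,
    binomial_logpmf,
    default_priors,
    mortality_from_arrays,
)
from .data import BioassayDataset
from .sampling import PosteriorSamples, SamplerConfig, adaptive_metropolis

__all__ = [
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_model",
    "posterior_predictive_check",
    "VARIANTS",
]

VARIANTS = ("base", "linear_time", "individual_time", "base_time")

# unconstrained-scale transform per parameter letter
_TRANSFORMS = {"A": "logit", "B": "log", "C": "id", "E": "log", "F": "id", "G": "id"}


def _log_dose(concentrations: np.ndarray) -> np.ndarray:
    """ln of the sqrt-scale dose; -inf flags control records."""
    with np.errstate(divide="ignore"):
        return 0.5 * np.log(np.asarray(concentrations, dtype=float))


class DoseResponseModel:
    """Binomial 5PL dose-response model for one bioassay dataset.

    Parameters
    ----------
    dataset
        Validated :class:`~bioassayfit.data.BioassayDataset` with at least
        two distinct nonzero concentrations.
    variant
        One of ``base``, ``linear_time``, ``individual_time``,
        ``base_time``.  Temporal variants require a year on every record.
    priors
        Optional :class:`~bioassayfit.curves.PriorSpec`; defaults to the
        framework's weakly-informative set.
    """

    def __init__(
        self,
        dataset: BioassayDataset,
        variant: str = "base",
        priors: PriorSpec | None = None,
    ) -> None:
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
        dataset.require_fittable()
        self.dataset = dataset
        self.variant = variant
        self.priors = priors if priors is not None else default_priors()

        self._conc = dataset.concentrations
        self._n = dataset.n_tested.astype(float)
        self._y = dataset.n_dead.astype(float)
        self._lnx = _log_dose(self._conc)
        from scipy.special import gammaln

        self._coef = gammaln(self._n + 1) - gammaln(self._y + 1) - gammaln(self._n - self._y + 1)

        if variant != "base":
            years = dataset.years
            if years is None:
                raise ValueError(
                    f"variant {variant!r} requires a year on every record"
                )
            self.years: tuple[int, ...] = tuple(sorted(set(int(y) for y in years)))
            if len(self.years) < 2:
                warnings.warn(
                    "temporal variant fitted to a single year; it degenerates "
                    "to the base model",
                    UserWarning,
                )
            self._year_idx = np.searchsorted(self.years, years)
        else:
            self.years = tuple(sorted(set(int(y) for y in dataset.years))) if dataset.years is not None else ()
            self._year_idx = None

        self.param_names = self._build_param_names()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        variant: str = "base",
        priors: PriorSpec | None = None,
        schema: Mapping[str, str] | None = None,
    ) -> "DoseResponseModel":
        """Build from a DataFrame with the standard bioassay columns."""
        import io

        from .data import read_bioassay_csv

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_bioassay_csv(buf, schema=schema), variant, priors)

    # -- parameterisation ---------------------------------------------------

    def _build_param_names(self) -> list[str]:
        if self.variant == "base":
            return ["A", "B", "C", "E"]
        if self.variant == "linear_time":
            return ["A", "B", "E", "F", "G"]
        if self.variant == "individual_time":
            return ["A", "B", "E"] + [f"C[{y}]" for y in self.years]
        return [  # base_time (fitted per year; names for assembled output)
            f"{p}[{y}]" for y in self.years for p in ("A", "B", "C", "E")
        ]

    def _constrain(self, theta: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Map unconstrained chain positions to parameter dict + log-Jacobian."""
        values: dict[str, np.ndarray] = {}
        logjac = np.zeros(theta.shape[0])
        for j, name in enumerate(self.param_names):
            t = _TRANSFORMS[name.split("[", 1)[0]]
            col = theta[:, j]
            if t == "logit":
                v = 1.0 / (1.0 + np.exp(-col))
                logjac += np.log(v) + np.log1p(-v)
            elif t == "log":
                v = np.exp(col)
                logjac += col
            else:
                v = col
            values[name] = v
        return values, logjac

    def _record_prob(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """(n_batch, n_records) mean mortality for a batch of parameter dicts."""
        lnx = self._lnx[None, :]
        if self.variant == "base":
            return mortality_from_arrays(
                values["A"][:, None], values["B"][:, None],
                values["C"][:, None], values["E"][:, None], lnx,
            )
        if self.variant == "linear_time":
            t = (np.asarray(self.dataset.years) - self.years[0]).astype(float)
            c_rec = values["F"][:, None] + values["G"][:, None] * t[None, :]
            return mortality_from_arrays(
                values["A"][:, None], values["B"][:, None], c_rec,
                values["E"][:, None], lnx,
            )
        if self.variant == "individual_time":
            c_mat = np.stack([values[f"C[{y}]"] for y in self.years], axis=1)
            c_rec = c_mat[:, self._year_idx]
            return mortality_from_arrays(
                values["A"][:, None], values["B"][:, None], c_rec,
                values["E"][:, None], lnx,
            )
        # base_time: assembled from per-year fits; evaluated via indexing
        per = {}
        for p in ("A", "B", "C", "E"):
            mat = np.stack([values[f"{p}[{y}]"] for y in self.years], axis=1)
            per[p] = mat[:, self._year_idx]
        return mortality_from_arrays(per["A"], per["B"], per["C"], per["E"], lnx)

    def _log_likelihood_batch(self, p: np.ndarray) -> np.ndarray:
        from .curves import LIKELIHOOD_EPS

        pc = np.clip(p, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
        return (
            self._coef[None, :]
            + self._y[None, :] * np.log(pc)
            + (self._n - self._y)[None, :] * np.log1p(-pc)
        ).sum(axis=1)

    def _log_prior_batch(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        lp = np.zeros(next(iter(values.values())).shape[0])
        for name, v in values.items():
            lp = lp + np.asarray(self.priors.entry(name).logpdf(v))
        return lp

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalised log posterior on the unconstrained scale (batched)."""
        values, logjac = self._constrain(theta)
        return (
            self._log_likelihood_batch(self._record_prob(values))
            + self._log_prior_batch(values)
            + logjac
        )

    def _initial_positions(self, rng: np.random.Generator, n_chains: int) -> np.ndarray:
        nz = self._conc[self._conc > 0]
        c_guess = float(np.mean(0.5 * np.log(nz)))
        theta = np.empty((n_chains, len(self.param_names)))
        for j, name in enumerate(self.param_names):
            letter = name.split("[", 1)[0]
            if letter == "A":
                a = rng.uniform(0.02, 0.15, n_chains)
                theta[:, j] = np.log(a / (1 - a))
            elif letter == "B":
                theta[:, j] = np.log(rng.uniform(2.0, 8.0, n_chains))
            elif letter == "E":
                theta[:, j] = np.log(rng.uniform(2.0, 10.0, n_chains))
            elif letter == "G":
                theta[:, j] = rng.normal(0.0, 0.05, n_chains)
            else:  # C or F: near the centre of the tested dose range
                theta[:, j] = c_guess + rng.normal(0.0, 0.5, n_chains)
        return theta

    # -- fitting ------------------------------------------------------------

    def fit(self, config: SamplerConfig | None = None, **kwargs) -> "DoseResponseResults":
        """Sample the posterior; keyword arguments override config fields."""
        if config is None:
            config = SamplerConfig(**kwargs)
        elif kwargs:
            config = dataclasses.replace(config, **kwargs)

        if self.variant == "base_time":
            return self._fit_base_time(config)

        notes: list[str] = []
        if np.ptp(self.dataset.mortality) == 0.0:
            notes.append(
                "all records share one observed mortality: no dose-response "
                "signal; estimates are prior-driven"
            )

        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xB10A55)))
        theta0 = self._initial_positions(rng, config.n_chains)
        for _ in range(20):
            lp0 = self.log_posterior(theta0)
            bad = ~np.isfinite(lp0)
            if not bad.any():
                break
            theta0[bad] = self._initial_positions(rng, int(bad.sum()))

        draws3, accept = adaptive_metropolis(self.log_posterior, theta0, config)
        n_chains, n_kept, dim = draws3.shape
        flat = draws3.reshape(-1, dim)
        values, _ = self._constrain(flat)
        draw_map = {
            name: values[name].reshape(n_chains, n_kept) for name in self.param_names
        }
        p = self._record_prob(values)
        from .curves import LIKELIHOOD_EPS

        pc = np.clip(p, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
        ll = (
            self._coef[None, :]
            + self._y[None, :] * np.log(pc)
            + (self._n - self._y)[None, :] * np.log1p(-pc)
        ).reshape(n_chains, n_kept, len(self.dataset))

        samples = PosteriorSamples(
            draw_map,
            ll,
            config,
            self.variant,
            years=self.years or None,
            accept_rate=accept,
            warnings_list=notes,
        )
        return DoseResponseResults(self, samples)

    def _fit_base_time(self, config: SamplerConfig) -> "DoseResponseResults":
        """Independent base-model fit per year, reassembled in record order."""
        seeds = np.random.SeedSequence(config.seed).generate_state(len(self.years))
        draw_map: dict[str, np.ndarray] = {}
        ll = np.zeros((config.n_chains, config.n_kept, len(self.dataset)))
        notes: list[str] = []
        rhat_ok = True
        for i, year in enumerate(self.years):
            mask = np.asarray(self.dataset.years) == year
            sub = self.dataset.subset(mask)
            sub_cfg = dataclasses.replace(config, seed=int(seeds[i] & 0x7FFFFFFF))
            sub_model = DoseResponseModel(sub, "base", self.priors)
            sub_res = sub_model.fit(sub_cfg)
            for p in ("A", "B", "C", "E"):
                draw_map[f"{p}[{year}]"] = sub_res.posterior.draws[p]
            ll[:, :, mask] = sub_res.posterior.log_lik_chains
            notes.extend(f"{year}: {w}" for w in sub_res.posterior.warnings)
            rhat_ok &= sub_res.converged
        samples = PosteriorSamples(
            draw_map, ll, config, "base_time", years=self.years, warnings_list=notes
        )
        return DoseResponseResults(self, samples)


def fit_model(
    dataset: BioassayDataset,
    variant: str = "base",
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorSamples:
    """Functional entry point returning the raw posterior samples."""
    return DoseResponseModel(dataset, variant, priors).fit(config or SamplerConfig()).posterior


def posterior_predictive_check(
    samples: PosteriorSamples,
    dataset: BioassayDataset,
    seed: int = 0,
    max_draws: int = 2000,
) -> dict:
    """Replicate counts from the posterior predictive and score the fit.

    For a thinned subset of retained draws j and each record i, simulates
    ``y_rep ~ Binomial(n_i, p_ij)``.  Returns the replicate matrix,
    per-concentration residuals (observed proportion minus posterior-median
    fitted proportion) and each observation's mid-tail probability under
    its predictive distribution (uniform when the model is well
    calibrated).
    """
    if not samples.converged:
        warnings.warn(
            "posterior predictive check on unconverged samples", UserWarning
        )
    rng = np.random.default_rng(seed)
    p = _metrics.fitted_mortality(samples, dataset)
    if p.shape[0] > max_draws:
        idx = rng.choice(p.shape[0], size=max_draws, replace=False)
        p = p[idx]
    n = dataset.n_tested
    y = dataset.n_dead
    y_rep = rng.binomial(n[None, :], p)
    p_med = np.median(p, axis=0)
    resid = dataset.mortality - p_med
    # randomised PIT: P(Y_rep < y) + U * P(Y_rep = y), uniform under the model
    less = (y_rep < y[None, :]).mean(axis=0)
    equal = (y_rep == y[None, :]).mean(axis=0)
    tail = less + rng.uniform(size=y.size) * equal
    resid_by_conc = (
        pd.DataFrame({"concentration": dataset.concentrations, "residual": resid})
        .groupby("concentration")["residual"]
        .agg(["mean", "std", "count"])
    )
    return {
        "y_rep": y_rep,
        "residuals": resid,
        "residuals_by_concentration": resid_by_conc,
        "tail_prob": tail,
    }


class DoseResponseResults:
    """Fit results: posterior draws, diagnostics, and derived metrics."""

    def __init__(self, model: DoseResponseModel, posterior: PosteriorSamples) -> None:
        self.model = model
        self.posterior = posterior

    # diagnostics ------------------------------------------------------------
    @property
    def rhat(self) -> dict[str, float]:
        return self.posterior.rhat

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, median, 95% CI, R-hat."""
        rows = []
        for name in self.posterior.param_names:
            d = self.posterior.stacked(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "median": np.median(d),
                    "2.5%": np.percentile(d, 2.5),
                    "97.5%": np.percentile(d, 97.5),
                    "rhat": self.posterior.rhat[name],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def __repr__(self) -> str:
        head = (
            f"DoseResponseResults(variant={self.model.variant!r}, "
            f"n_records={len(self.model.dataset)}, draws={self.posterior.n_draws}, "
            f"converged={self.converged})"
        )
        return head + "\n" + self.summary().to_string()

    # derived metrics ----------------------------------------------------------
    def lc(self, q: float = 0.5, year: int | None = None):
        """Posterior lethal concentration at mortality quantile ``q``."""
        return _metrics.lc_posterior(self.posterior, q, year=year)

    def heterogeneity(self, year: int | None = None) -> dict:
        return _metrics.heterogeneity(self.posterior, year=year)

    def lethal_dose_samples(self, n_samples: int = 10000, seed: int = 0, year: int | None = None):
        return _metrics.lethal_dose_samples(
            self.posterior, n_samples, seed=seed, year=year
        )

    def variability(self, mode: str = "curve", seed: int = 0):
        return _metrics.variability(
            self.model.dataset, self.posterior, mode=mode, seed=seed
        )

    def fit_statistics(self) -> dict:
        return _metrics.fit_statistics(self.model.dataset, self.posterior)

    def background_mortality(self) -> dict:
        return _metrics.background_mortality_summary(self.posterior)

    def posterior_predictive(self, seed: int = 0) -> dict:
        return posterior_predictive_check(self.posterior, self.model.dataset, seed=seed)

    def loo(self):
        from .comparison import loo_elpd

        return loo_elpd(self.posterior.log_lik_chains)

    def metrics_report(self, qs=(0.1, 0.5, 0.9), year: int | None = None, seed: int = 0) -> dict:
        return _metrics.metrics_report(
            self.model.dataset, self.posterior, qs=qs, year=year, seed=seed
        )

    # plotting / persistence ---------------------------------------------------
    def plot_fit(self, ax=None, year: int | None = None, n_curve_draws: int = 200):
        """Observed mortality and the posterior median curve (optional CI band)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ds = self.model.dataset
        conc = ds.concentrations
        nz = conc[conc > 0]
        grid = np.geomspace(nz.min() / 4, nz.max() * 4, 200)
        arrays = self.posterior.curve_arrays(year=year)
        lnx = 0.5 * np.log(grid)
        sel = np.linspace(0, arrays["A"].size - 1, min(n_curve_draws, arrays["A"].size)).astype(int)
        curves = mortality_from_arrays(
            arrays["A"][sel, None], arrays["B"][sel, None],
            arrays["C"][sel, None], arrays["E"][sel, None], lnx[None, :],
        )
        med = np.median(curves, axis=0)
        lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
        ax.fill_between(grid, lo, hi, alpha=0.25)
        ax.plot(grid, med, lw=2)
        ax.scatter(np.where(conc > 0, conc, nz.min() / 8), ds.mortality, s=18, c="k")
        ax.set_xscale("log")
        ax.set_xlabel("concentration (% a.i.)")
        ax.set_ylabel("mortality")
        return ax

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write draws (CSV) + diagnostics (JSON); returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "posterior": outdir / "posterior.csv",
            "diagnostics": outdir / "diagnostics.json",
        }
        self.posterior.to_frame().to_csv(paths["posterior"], index=False)
        paths["diagnostics"].write_text(
            json.dumps(self.posterior.diagnostics(), indent=2)
        )
        return paths
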