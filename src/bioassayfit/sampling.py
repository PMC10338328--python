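"""Posterior sampling machinery.

An adaptive random-walk Metropolis sampler runs several independent chains
(vectorised across chains).  During warmup each chain adapts a full
proposal covariance (Haario-style running estimate) and a global step-size
scale targeting a ~30% acceptance rate; both are frozen afterwards, so the
retained draws come from a fixed Markov kernel.  Convergence is assessed
with rank-normalised split-R-hat.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = ["SamplerConfig", "PosteriorSamples", "split_rhat", "adaptive_metropolis"]


@dataclasses.dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    Defaults mirror common practice for this model family: 4 chains of
    5000 iterations with the first half discarded as warmup; escalate
    ``n_iterations`` to 10000 if chains are slow to converge.
    """

    n_chains: int = 4
    n_iterations: int = 5000
    warmup_fraction: float = 0.5
    seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (required for R-hat)")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.n_iterations < 4:
            raise ValueError("n_iterations must be >= 4")

    @property
    def n_warmup(self) -> int:
        return int(math.floor(self.warmup_fraction * self.n_iterations))

    @property
    def n_kept(self) -> int:
        return self.n_iterations - self.n_warmup


def split_rhat(draws: np.ndarray) -> float:
    """Rank-normalised split-R-hat for one parameter.

    ``draws`` has shape (n_chains, n_draws).  Each chain is split in half,
    pooled draws are rank-transformed to normal scores, and the classic
    between/within variance ratio is computed on the scores.  Values near 1
    indicate mixing.  Degenerate (zero-variance) input returns NaN with a
    warning.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("need >= 2 chains and >= 4 draws per chain")
    if np.ptp(draws) == 0.0:
        warnings.warn("all draws identical; R-hat undefined", RuntimeWarning)
        return math.nan
    half = draws.shape[1] // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = split.shape
    r = rankdata(split, method="average", axis=None).reshape(m, n)
    z = ndtri((r - 0.375) / (m * n + 0.25))
    chain_means = z.mean(axis=1)
    w = z.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined", RuntimeWarning)
        return math.nan
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def adaptive_metropolis(
    log_post: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    config: SamplerConfig,
    target_accept: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Run vectorised adaptive random-walk Metropolis chains.

    Parameters
    ----------
    log_post
        Maps an (n_chains, dim) array of unconstrained positions to an
        (n_chains,) array of log posterior densities (may be -inf).
    init
        (n_chains, dim) starting positions with finite log posterior.
    config
        Chain count, iteration budget, warmup fraction, seed.

    Returns
    -------
    draws : (n_chains, n_kept, dim) post-warmup positions.
    accept_rate : (n_chains,) post-warmup acceptance rates.
    """
    init = np.asarray(init, dtype=float)
    n_chains, dim = init.shape
    if n_chains != config.n_chains:
        raise ValueError("init rows must equal config.n_chains")
    rng = np.random.default_rng(config.seed)

    theta = init.copy()
    lp = log_post(theta)
    if not np.all(np.isfinite(lp)):
        raise ValueError("initial positions must have finite log posterior")

    n_warm, n_kept = config.n_warmup, config.n_kept
    draws = np.empty((n_chains, n_kept, dim))
    accepted = np.zeros(n_chains)

    # per-chain running moments for the Haario covariance estimate
    mean = theta.copy()
    m2 = np.zeros((n_chains, dim, dim))
    count = 1
    log_scale = np.full(n_chains, math.log(2.38 / math.sqrt(dim)))
    chol = np.tile(np.eye(dim) * 0.1, (n_chains, 1, 1))
    jitter = 1e-10 * np.eye(dim)

    for it in range(config.n_iterations):
        z = rng.standard_normal((n_chains, dim))
        step = np.einsum("cij,cj->ci", chol, z) * np.exp(log_scale)[:, None]
        prop = theta + step
        lp_prop = log_post(prop)
        log_u = np.log(rng.uniform(size=n_chains))
        with np.errstate(invalid="ignore"):
            log_alpha = lp_prop - lp
        accept = log_u < log_alpha
        theta[accept] = prop[accept]
        lp[accept] = lp_prop[accept]

        if it < n_warm:
            # running mean / scatter update
            count += 1
            delta = theta - mean
            mean += delta / count
            m2 += np.einsum("ci,cj->cij", delta, theta - mean)
            alpha = np.exp(np.minimum(0.0, np.where(np.isfinite(log_alpha), log_alpha, -np.inf)))
            log_scale += (alpha - target_accept) / (1 + it) ** 0.6
            if it >= max(50, 2 * dim) and (it + 1) % 50 == 0:
                cov = m2 / (count - 1) + jitter
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        else:
            draws[:, it - n_warm, :] = theta
            accepted += accept

    return draws, accepted / max(n_kept, 1)


class PosteriorSamples:
    """Container for per-chain posterior draws with diagnostics.

    Attributes
    ----------
    draws
        Mapping parameter name -> (n_chains, n_kept) array on the
        constrained scale.
    rhat
        Mapping parameter name -> rank-normalised split-R-hat.
    log_lik
        Pointwise log-likelihood, (total retained draws, n_records);
        the per-chain view is :attr:`log_lik_chains`.
    converged
        True iff every parameter's R-hat is below the configured threshold.
    """

    def __init__(
        self,
        draws: Mapping[str, np.ndarray],
        log_lik_chains: np.ndarray,
        config: SamplerConfig,
        variant: str,
        years: Sequence[int] | None = None,
        accept_rate: np.ndarray | None = None,
        warnings_list: Sequence[str] = (),
    ) -> None:
        self.draws = {k: np.asarray(v) for k, v in draws.items()}
        self.log_lik_chains = np.asarray(log_lik_chains)
        self.config = config
        self.variant = variant
        self.years = None if years is None else tuple(int(y) for y in years)
        self.accept_rate = accept_rate
        self.warnings = list(warnings_list)
        self.rhat: dict[str, float] = {}
        for name, arr in self.draws.items():
            if np.ptp(arr) == 0.0:
                self.rhat[name] = math.nan
            else:
                self.rhat[name] = split_rhat(arr)
        finite = [v for v in self.rhat.values() if not math.isnan(v)]
        self.converged = bool(finite) and all(
            v < config.rhat_threshold for v in finite
        )

    @property
    def param_names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_kept

    @property
    def log_lik(self) -> np.ndarray:
        """(n_draws, n_records) pointwise log-likelihood, chains pooled."""
        c, k, n = self.log_lik_chains.shape
        return self.log_lik_chains.reshape(c * k, n)

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter pooled across chains, shape (n_draws,)."""
        return self.draws[name].reshape(-1)

    def curve_arrays(self, year: int | None = None) -> dict[str, np.ndarray]:
        """Pooled draw arrays for A, B, C, E (C made effective per year).

        Temporal variants require ``year``; the base variant ignores it.
        """
        if self.variant == "base":
            return {k: self.stacked(k) for k in ("A", "B", "C", "E")}
        if year is None:
            raise ValueError(
                f"{self.variant!r} samples require an explicit year for curve metrics"
            )
        year = int(year)
        if self.variant == "linear_time":
            t0 = min(self.years) if self.years else 0
            c_eff = self.stacked("F") + self.stacked("G") * (year - t0)
            return {
                "A": self.stacked("A"),
                "B": self.stacked("B"),
                "C": c_eff,
                "E": self.stacked("E"),
            }
        if self.variant == "individual_time":
            return {
                "A": self.stacked("A"),
                "B": self.stacked("B"),
                "C": self.stacked(f"C[{year}]"),
                "E": self.stacked("E"),
            }
        if self.variant == "base_time":
            return {k: self.stacked(f"{k}[{year}]") for k in ("A", "B", "C", "E")}
        raise ValueError(f"unknown variant {self.variant!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws table: chain, draw index, one column per parameter."""
        c, k = self.n_chains, self.n_kept
        cols = {
            "chain": np.repeat(np.arange(c), k),
            "draw": np.tile(np.arange(k), c),
        }
        for name, arr in self.draws.items():
            cols[name] = arr.reshape(-1)
        return pd.DataFrame(cols)

    def diagnostics(self) -> dict:
        return {
            "rhat": {k: (None if math.isnan(v) else v) for k, v in self.rhat.items()},
            "converged": self.converged,
            "n_chains": self.n_chains,
            "n_kept_per_chain": self.n_kept,
            "variant": self.variant,
            "years": self.years,
            "seed": self.config.seed,
            "n_iterations": self.config.n_iterations,
            "warmup_fraction": self.config.warmup_fraction,
            "rhat_threshold": self.config.rhat_threshold,
            "accept_rate": (
                None if self.accept_rate is None else list(map(float, self.accept_rate))
            ),
            "warnings": self.warnings,
        }
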