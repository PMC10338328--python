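"""Five-parameter logistic (5PL) dose-response curves with background mortality.

The mean mortality at concentration ``x`` (% active ingredient) is

    p(x) = D + (A - D) / [1 + exp(B * (ln x' - C))]**E,   x' = sqrt(x)

where ``A`` is background (control) mortality, ``B`` the slope/shape, ``C``
the location on the log-sqrt-concentration axis, ``D`` the upper asymptote
(fixed at 1: enough insecticide kills everything), and ``E`` the asymmetry.
Concentrations enter on the square-root scale to compress the doubling
series typical of intensity bioassays; all lethal-concentration outputs are
reported back on the raw scale.

Temporal variants let the curve drift across survey years:

* ``linear_time``  — C becomes F + G * t (t = year - first year),
* ``individual_time`` — a free C_t per year, shared A, B, E,
* ``base_time``    — a full independent parameter set per year.

Dead mosquito counts are binomial: y_i ~ Binomial(n_i, p(x_i)).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, log_ndtr, ndtr

__all__ = [
    "CurveParams",
    "TemporalParams",
    "LinearTimeParams",
    "IndividualTimeParams",
    "BaseTimeParams",
    "PriorEntry",
    "PriorSpec",
    "default_priors",
    "transform_concentration",
    "mean_mortality",
    "mean_mortality_temporal",
    "log_likelihood",
    "log_prior",
    "prior_predictive_sample",
    "LIKELIHOOD_EPS",
]

#: Mean-mortality clamp applied inside the binomial log-likelihood so that
#: observed survivors at p -> 1 (or deaths at p -> 0) stay finite.
LIKELIHOOD_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class CurveParams:
    """Base-model parameter set (D fixed at 1 unless explicitly unfixed)."""

    A: float
    B: float
    C: float
    E: float
    D: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.A < 1.0:
            raise ValueError(f"A (background mortality) must be in (0, 1), got {self.A}")
        if self.B <= 0:
            raise ValueError(f"B (slope) must be > 0, got {self.B}")
        if self.E <= 0:
            raise ValueError(f"E (asymmetry) must be > 0, got {self.E}")
        if self.D <= 0:
            raise ValueError(f"D (upper asymptote) must be > 0, got {self.D}")


class TemporalParams:
    """Marker base class for the year-varying parameterisations."""

    variant: str


@dataclasses.dataclass(frozen=True)
class LinearTimeParams(TemporalParams):
    """Shared A, B, E; location drifts linearly: C_eff(t) = F + G * t.

    ``t`` is the year coded relative to ``t0`` (the earliest year in the
    fitted dataset), so F is the location in the first survey year.
    """

    A: float
    B: float
    E: float
    F: float
    G: float
    t0: int = 0
    variant: str = dataclasses.field(default="linear_time", init=False, repr=False)

    def curve_for_year(self, year: int) -> CurveParams:
        return CurveParams(self.A, self.B, self.F + self.G * (year - self.t0), self.E)


@dataclasses.dataclass(frozen=True)
class IndividualTimeParams(TemporalParams):
    """Shared A, B, E with a free location C_t per survey year."""

    A: float
    B: float
    E: float
    C_by_year: Mapping[int, float]
    variant: str = dataclasses.field(default="individual_time", init=False, repr=False)

    def curve_for_year(self, year: int) -> CurveParams:
        if year not in self.C_by_year:
            raise KeyError(f"year {year} not covered; have {sorted(self.C_by_year)}")
        return CurveParams(self.A, self.B, self.C_by_year[year], self.E)


@dataclasses.dataclass(frozen=True)
class BaseTimeParams(TemporalParams):
    """A full independent 5PL parameter set per survey year."""

    params_by_year: Mapping[int, CurveParams]
    variant: str = dataclasses.field(default="base_time", init=False, repr=False)

    def curve_for_year(self, year: int) -> CurveParams:
        if year not in self.params_by_year:
            raise KeyError(f"year {year} not covered; have {sorted(self.params_by_year)}")
        return self.params_by_year[year]


def transform_concentration(concentration):
    """Map raw % a.i. to the model dose scale (square root).

    The model evaluates the logistic in ``ln sqrt(x)``; lethal
    concentrations solved on the model scale are squared to report on the
    raw scale.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = np.sqrt(c)
    return float(out) if out.ndim == 0 else out


def _softplus(z):
    """log(1 + e^z), overflow-safe."""
    z = np.asarray(z, dtype=float)
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def mortality_from_arrays(A, B, C, E, log_dose, D=1.0):
    """Vectorised 5PL mean mortality.

    ``log_dose`` is ln of the model-scale (sqrt-transformed) dose, with
    ``-inf`` denoting control records; the control limit is A exactly.
    Broadcasts parameter arrays against ``log_dose``.
    """
    A, B, C, E = (np.asarray(v, dtype=float) for v in (A, B, C, E))
    log_dose = np.asarray(log_dose, dtype=float)
    with np.errstate(invalid="ignore"):
        z = B * (log_dose - C)
    # (1 + e^z)^-E = exp(-E * softplus(z))
    control = np.isneginf(log_dose)
    z = np.where(control, 0.0, z)
    damp = np.exp(-E * _softplus(z))
    p = D + (A - D) * damp
    # the zero-dose limit is the background mortality A, returned exactly
    return np.where(control, A + 0.0 * p, p)


def mean_mortality(params: CurveParams, concentration):
    """Mean mortality proportion at a raw concentration (scalar or array)."""
    x = transform_concentration(concentration)
    with np.errstate(divide="ignore"):
        log_dose = np.log(np.asarray(x, dtype=float))
    out = mortality_from_arrays(params.A, params.B, params.C, params.E, log_dose, params.D)
    return float(out) if np.ndim(out) == 0 else out


def mean_mortality_temporal(params: TemporalParams, concentration, year: int):
    """Mean mortality under a temporal variant for a given survey year."""
    return mean_mortality(params.curve_for_year(int(year)), concentration)


def _record_probabilities(params, dataset) -> np.ndarray:
    if isinstance(params, CurveParams):
        return np.asarray(mean_mortality(params, dataset.concentrations))
    years = dataset.years
    if years is None:
        raise ValueError("temporal parameters require a year on every record")
    p = np.empty(len(dataset))
    for i, (c, y) in enumerate(zip(dataset.concentrations, years)):
        p[i] = mean_mortality_temporal(params, c, int(y))
    return p


def binomial_logpmf(y, n, p):
    """log Binomial(y | n, p) with p clamped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    pc = np.clip(np.asarray(p, dtype=float), LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
    coef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return coef + y * np.log(pc) + (n - y) * np.log1p(-pc)


def log_likelihood(params, dataset):
    """Binomial log-likelihood of a dataset under a parameter set.

    Returns ``(total, pointwise)`` where ``pointwise`` is the per-record
    vector needed by leave-one-out cross-validation.
    """
    p = _record_probabilities(params, dataset)
    pointwise = binomial_logpmf(dataset.n_dead, dataset.n_tested, p)
    return float(pointwise.sum()), pointwise


# ---------------------------------------------------------------------------
# Priors


@dataclasses.dataclass(frozen=True)
class PriorEntry:
    """One parameter's prior: normal, positive-truncated normal, or fixed.

    ``half_normal`` means a normal(location, scale) truncated to
    [lower, upper] with lower defaulting to 0 (the convention used for the
    A, B and E defaults); the truncation constant is included in the
    density.  ``scale`` is a standard deviation.
    """

    family: str  # "normal" | "half_normal" | "fixed"
    location: float
    scale: float = 0.0
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.family not in ("normal", "half_normal", "fixed"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family != "fixed" and self.scale <= 0:
            raise ValueError("scale must be > 0 for stochastic priors")

    def logpdf(self, value: float) -> float:
        if self.family == "fixed":
            return 0.0
        v = (np.asarray(value, dtype=float) - self.location) / self.scale
        base = -0.5 * v**2 - 0.5 * math.log(2 * math.pi) - math.log(self.scale)
        if self.family == "normal":
            return base
        lo = (self.lower - self.location) / self.scale
        hi = (self.upper - self.location) / self.scale
        log_z = np.log(ndtr(hi) - ndtr(lo)) if math.isfinite(hi) else log_ndtr(-lo)
        out = np.where(
            (np.asarray(value) < self.lower) | (np.asarray(value) > self.upper),
            -np.inf,
            base - log_z,
        )
        return float(out) if np.ndim(out) == 0 else out

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "fixed":
            return np.full(size, self.location) if size else self.location
        if self.family == "normal":
            return rng.normal(self.location, self.scale, size=size)
        lo = (self.lower - self.location) / self.scale
        hi = (self.upper - self.location) / self.scale
        dist = stats.truncnorm(lo, hi, loc=self.location, scale=self.scale)
        return dist.rvs(size=size, random_state=rng)


class PriorSpec(dict):
    """Mapping parameter name -> :class:`PriorEntry` with default fallback.

    Parameter names for temporal variants use per-year suffixes such as
    ``C[2016]`` or ``A[2016]``; lookups fall back to the bare letter so one
    entry per letter covers all years.
    """

    def entry(self, name: str) -> PriorEntry:
        if name in self:
            return self[name]
        bare = name.split("[", 1)[0]
        if bare in self:
            return self[bare]
        raise KeyError(f"no prior for parameter {name!r}; have {sorted(self)}")

    @classmethod
    def from_dict(cls, spec: Mapping[str, Mapping[str, object]]) -> "PriorSpec":
        """Build from a JSON-style dict: {name: {family, location, scale, ...}}."""
        out = cls()
        for name, entry in spec.items():
            out[name] = PriorEntry(**entry)
        return out


def default_priors() -> PriorSpec:
    """The framework's weakly-informative defaults.

    A ~ N+(0, 0.1) truncated above at 1; B ~ N+(5, 10); C ~ N(0, 5);
    D fixed at 1; E ~ N+(7, 10); F, G ~ N(0, 5).  Scales are standard
    deviations.
    """
    return PriorSpec(
        A=PriorEntry("half_normal", 0.0, 0.1, lower=0.0, upper=1.0),
        B=PriorEntry("half_normal", 5.0, 10.0),
        C=PriorEntry("normal", 0.0, 5.0),
        D=PriorEntry("fixed", 1.0),
        E=PriorEntry("half_normal", 7.0, 10.0),
        F=PriorEntry("normal", 0.0, 5.0),
        G=PriorEntry("normal", 0.0, 5.0),
    )


def _free_param_values(params) -> dict[str, float]:
    if isinstance(params, CurveParams):
        return {"A": params.A, "B": params.B, "C": params.C, "E": params.E}
    if isinstance(params, LinearTimeParams):
        return {"A": params.A, "B": params.B, "E": params.E, "F": params.F, "G": params.G}
    if isinstance(params, IndividualTimeParams):
        out = {"A": params.A, "B": params.B, "E": params.E}
        out.update({f"C[{y}]": c for y, c in sorted(params.C_by_year.items())})
        return out
    if isinstance(params, BaseTimeParams):
        out = {}
        for y, cp in sorted(params.params_by_year.items()):
            out.update({f"A[{y}]": cp.A, f"B[{y}]": cp.B, f"C[{y}]": cp.C, f"E[{y}]": cp.E})
        return out
    raise TypeError(f"unsupported parameter object {type(params).__name__}")


def log_prior(params, priors: PriorSpec) -> float:
    """Sum of per-parameter log prior densities; -inf outside support."""
    total = 0.0
    for name, value in _free_param_values(params).items():
        lp = priors.entry(name).logpdf(value)
        if not np.isfinite(lp):
            return -math.inf
        total += float(lp)
    return total


def prior_predictive_sample(
    priors: PriorSpec,
    concentrations: Sequence[float],
    n_curves: int,
    seed: int | np.random.Generator = 0,
):
    """Draw dose-response curves from the prior.

    Returns ``(curves, params)``: an ``(n_curves, n_conc)`` array of mean
    mortalities and the list of drawn :class:`CurveParams`.
    """
    if n_curves <= 0:
        raise ValueError("n_curves must be > 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    conc = np.asarray(list(concentrations), dtype=float)
    draws: list[CurveParams] = []
    curves = np.empty((n_curves, conc.size))
    for j in range(n_curves):
        cp = CurveParams(
            A=float(np.clip(priors.entry("A").sample(rng), 1e-12, 1 - 1e-12)),
            B=float(max(priors.entry("B").sample(rng), 1e-12)),
            C=float(priors.entry("C").sample(rng)),
            E=float(max(priors.entry("E").sample(rng), 1e-12)),
        )
        draws.append(cp)
        curves[j] = mean_mortality(cp, conc)
    return curves, draws
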