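"""Model comparison: PSIS-LOO elpd, paired Z-tests, hypothesis workflows.

Out-of-sample predictive performance is scored by approximate
leave-one-out cross-validation (Pareto-smoothed importance sampling).
Convention used throughout: **higher elpd means better predictive
density**; reports also carry ``-elpd`` (deviance scale) to avoid
ambiguity.  Two workflows are provided:

* :func:`strain_difference_test` — pooled curve vs one curve per strain;
* :func:`temporal_change_test` — fixed curve vs three nested temporal
  variants, selected in order of complexity with a significance gate.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .curves import PriorSpec
from .data import BioassayDataset, BioassayValidationError
from .model import DoseResponseModel
from .sampling import SamplerConfig

__all__ = [
    "LooResult",
    "ElpdComparison",
    "SelectionReport",
    "loo_elpd",
    "compare_elpd",
    "strain_difference_test",
    "temporal_change_test",
]

#: Pareto tail-shape above which a pointwise contribution is flagged unreliable.
PARETO_K_THRESHOLD = 0.7


@dataclasses.dataclass
class LooResult:
    """Approximate leave-one-out expected log predictive density."""

    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    @property
    def n_bad_points(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_THRESHOLD))

    def to_dict(self) -> dict:
        return {
            "elpd": self.elpd,
            "se": self.se,
            "n_bad_points": self.n_bad_points,
            "neg_elpd": -self.elpd,
        }


def loo_elpd(log_lik: np.ndarray, n_chains: int | None = None) -> LooResult:
    """PSIS-LOO from a pointwise log-likelihood array.

    ``log_lik`` is (n_chains, n_draws, n_records) or (total_draws,
    n_records) with ``n_chains`` given so the chain structure can be
    restored.  Needs a healthy number of draws (>= 100) for the importance
    weights to be usable.
    """
    import arviz as az

    ll = np.asarray(log_lik, dtype=float)
    if ll.ndim == 2:
        if n_chains is None:
            n_chains = 1
        if ll.shape[0] % n_chains:
            raise ValueError("total draws not divisible by n_chains")
        ll = ll.reshape(n_chains, ll.shape[0] // n_chains, ll.shape[1])
    if ll.ndim != 3:
        raise ValueError("log_lik must be 2- or 3-dimensional")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood matrix contains non-finite values")
    if ll.shape[0] * ll.shape[1] < 100:
        raise ValueError("need at least 100 draws for PSIS-LOO")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(
            posterior={"_lp": ll.sum(axis=2)},
            log_likelihood={"y": ll},
        )
        res = az.loo(idata, pointwise=True)
    return LooResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i.values, dtype=float),
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
    )


@dataclasses.dataclass
class ElpdComparison:
    """Paired difference of two LOO results on the same records."""

    elpd_diff: float
    diff_se: float
    z: float
    p_value: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_elpd(loo_a: LooResult, loo_b: LooResult) -> ElpdComparison:
    """elpd_a - elpd_b with a paired SE and two-sided normal P-value.

    Both results must be computed on the same records in the same order.
    """
    a, b = loo_a.pointwise, loo_b.pointwise
    if a.shape != b.shape:
        raise ValueError(
            f"mismatched record counts: {a.shape[0]} vs {b.shape[0]}"
        )
    d = a - b
    diff = float(d.sum())
    se = float(math.sqrt(d.size) * d.std(ddof=1)) if d.size > 1 else 0.0
    if se == 0.0:
        if diff == 0.0:
            return ElpdComparison(0.0, 0.0, 0.0, 1.0)
        warnings.warn("zero SE with nonzero elpd difference", RuntimeWarning)
        return ElpdComparison(diff, 0.0, math.copysign(math.inf, diff), 0.0)
    z = diff / se
    p = float(2.0 * norm.sf(abs(z)))
    return ElpdComparison(diff, se, z, p)


@dataclasses.dataclass
class SelectionReport:
    """Outcome of a model-selection workflow."""

    models: dict
    comparisons: list
    selected: str | None
    threshold: float
    convention: str = "higher elpd is better (neg_elpd given for the deviance-scale reading)"
    warnings: list = dataclasses.field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        payload = dataclasses.asdict(self)
        payload["models"] = {
            k: (v.to_dict() if isinstance(v, LooResult) else v)
            for k, v in self.models.items()
        }
        payload["comparisons"] = [
            {**c, "result": c["result"].to_dict()}
            if isinstance(c.get("result"), ElpdComparison)
            else c
            for c in self.comparisons
        ]
        return json.dumps(payload, indent=2, **kwargs)


def _derived_config(config: SamplerConfig, tag: int) -> SamplerConfig:
    seed = int(np.random.SeedSequence((config.seed, tag)).generate_state(1)[0] & 0x7FFFFFFF)
    return dataclasses.replace(config, seed=seed)


def strain_difference_test(
    dataset: BioassayDataset,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    threshold: float = 0.05,
) -> SelectionReport:
    """Pooled curve vs one curve per group (strain), compared by LOO.

    The per-group model's pointwise log-likelihoods are reassembled in the
    pooled record order so the comparison is paired.  Groups with fewer
    than two distinct nonzero concentrations are excluded with a warning.
    """
    config = config or SamplerConfig()
    groups = dataset.split_by_group()
    if len(groups) < 2:
        raise ValueError(
            f"strain-difference test needs >= 2 groups, found {len(groups)}"
        )
    notes: list[str] = []
    usable: dict[str, BioassayDataset] = {}
    keep_mask = np.zeros(len(dataset), dtype=bool)
    group_labels = np.array(
        ["<none>" if g is None else str(g) for g in dataset.groups]
    )
    for name, sub in groups.items():
        try:
            sub.require_fittable()
        except BioassayValidationError as exc:
            notes.append(f"group {name!r} excluded: {exc}")
            continue
        usable[name] = sub
        keep_mask |= group_labels == name
    if len(usable) < 2:
        raise ValueError("fewer than 2 fittable groups after exclusions")
    pooled_data = dataset if keep_mask.all() else dataset.subset(keep_mask)
    labels = group_labels[keep_mask]

    pooled_res = DoseResponseModel(pooled_data, "base", priors).fit(
        _derived_config(config, 0)
    )
    pooled_loo = loo_elpd(pooled_res.posterior.log_lik_chains)

    split_ll = np.zeros(
        (config.n_chains, config.n_kept, len(pooled_data))
    )
    for i, (name, sub) in enumerate(usable.items()):
        res = DoseResponseModel(sub, "base", priors).fit(_derived_config(config, i + 1))
        split_ll[:, :, labels == name] = res.posterior.log_lik_chains
    split_loo = loo_elpd(split_ll)

    comp = compare_elpd(split_loo, pooled_loo)
    selected = (
        "strain_difference"
        if comp.elpd_diff > 0 and comp.p_value < threshold
        else "no_strain_difference"
    )
    return SelectionReport(
        models={"no_strain_difference": pooled_loo, "strain_difference": split_loo},
        comparisons=[
            {"pair": "strain_difference vs no_strain_difference", "result": comp}
        ],
        selected=selected,
        threshold=threshold,
        warnings=notes,
    )


#: complexity order of the temporal workflow (free-parameter count ascending)
TEMPORAL_ORDER = ("fixed", "linear_time", "individual_time", "base_time")


def temporal_change_test(
    dataset: BioassayDataset,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    threshold: float = 0.05,
) -> SelectionReport:
    """Has resistance changed over time?  Nested-model selection by LOO.

    Fits the fixed (year-blind base) model and the three temporal
    variants, then walks up the complexity order; a more complex model
    replaces the current champion only when its elpd improvement is
    significant at ``threshold`` (the comparison table is always emitted
    so stricter cutoffs can be applied post hoc).
    """
    config = config or SamplerConfig()
    years = dataset.years
    if years is None or len(set(map(int, years))) < 2:
        raise ValueError("temporal-change test needs records from >= 2 distinct years")

    notes: list[str] = []
    loos: dict[str, LooResult] = {}
    for i, name in enumerate(TEMPORAL_ORDER):
        variant = "base" if name == "fixed" else name
        try:
            res = DoseResponseModel(dataset, variant, priors).fit(
                _derived_config(config, 10 + i)
            )
            if not res.converged:
                notes.append(f"{name}: R-hat criterion not met")
            loos[name] = loo_elpd(res.posterior.log_lik_chains)
        except (BioassayValidationError, ValueError) as exc:
            notes.append(f"{name}: fit failed ({exc})")

    comparisons: list[dict] = []
    champion: str | None = "fixed" if "fixed" in loos else None
    for name in TEMPORAL_ORDER[1:]:
        if name not in loos:
            continue
        if champion is None:
            champion = name
            continue
        comp = compare_elpd(loos[name], loos[champion])
        comparisons.append({"pair": f"{name} vs {champion}", "result": comp})
        if comp.elpd_diff > 0 and comp.p_value < threshold:
            champion = name
    selected = champion if loos else None
    return SelectionReport(
        models=dict(loos),
        comparisons=comparisons,
        selected=selected,
        threshold=threshold,
        warnings=notes,
    )
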