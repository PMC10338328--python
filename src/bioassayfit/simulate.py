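"""Seeded synthetic bioassay generator.

Generates datasets with exactly the statistical structure the model
assumes — binomial deaths around a 5PL mean-mortality curve — so that
fitting, metrics and hypothesis tests can be exercised end-to-end and
checked against known truth.  Presets emulate the two study designs the
framework targets: laboratory strain assays (susceptible vs resistant
colonies on a doubling concentration series) and multi-year field tube
assays with stable or drifting resistance.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .curves import (
    BaseTimeParams,
    CurveParams,
    IndividualTimeParams,
    LinearTimeParams,
    TemporalParams,
    mean_mortality,
    mean_mortality_temporal,
)
from .data import BioassayDataset, BioassayRecord

__all__ = [
    "ScenarioSpec",
    "simulate_bioassay",
    "preset_scenarios",
    "curve_with_lc50",
    "location_for_lc50",
]


def location_for_lc50(lc50: float, B: float, E: float) -> float:
    """Location parameter C giving a target LC50 on the raw % a.i. scale.

    Inverts the LC closed form at q = 1/2:
    C = ln(sqrt(lc50)) - ln(2**(1/E) - 1) / B.
    """
    if lc50 <= 0:
        raise ValueError("lc50 must be > 0")
    return 0.5 * math.log(lc50) - math.log(2.0 ** (1.0 / E) - 1.0) / B


def curve_with_lc50(lc50: float, A: float = 0.03, B: float = 5.0, E: float = 7.0) -> CurveParams:
    """A base-model parameter set with the requested true LC50."""
    return CurveParams(A=A, B=B, C=location_for_lc50(lc50, B, E), E=E)


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one synthetic study.

    ``concentrations`` must include 0 (controls).  ``years`` triggers a
    multi-year design; ``truth`` may then be temporal.  Defaults of 25
    mosquitoes per tube and 4 replicate tubes per concentration reflect
    typical WHO tube practice.
    """

    truth: CurveParams | TemporalParams
    concentrations: tuple[float, ...]
    n_per_tube: int = 25
    replicates: int = 4
    years: tuple[int, ...] | None = None
    seed: int = 0
    name: str = "scenario"
    group: str | None = None
    insecticide: str | None = None

    def __post_init__(self) -> None:
        if len(self.concentrations) == 0:
            raise ValueError("concentration grid must be non-empty")
        if self.n_per_tube <= 0 or self.replicates <= 0:
            raise ValueError("n_per_tube and replicates must be > 0")
        if isinstance(self.truth, TemporalParams) and not self.years:
            raise ValueError("temporal truth requires years")

    def _truth_curves(self) -> list[CurveParams]:
        if isinstance(self.truth, CurveParams):
            return [self.truth]
        return [self.truth.curve_for_year(y) for y in self.years]

    def check_span(self) -> None:
        """Warn when the dose grid does not span background to near-total kill."""
        nz = [c for c in self.concentrations if c > 0]
        if not nz:
            warnings.warn("grid has no nonzero concentrations", UserWarning)
            return
        for cp in self._truth_curves():
            top = mean_mortality(cp, max(nz))
            bottom = mean_mortality(cp, min(nz))
            if top < 0.9 or bottom > cp.A + 0.5:
                warnings.warn(
                    f"dose grid does not span background-to-near-1 mortality "
                    f"under the truth (p(min)={bottom:.2f}, p(max)={top:.2f})",
                    UserWarning,
                )
                return

    def true_lc50(self, year: int | None = None) -> float:
        from .metrics import lc_quantile

        return lc_quantile(self.truth, 0.5, year=year)

    def to_dict(self) -> dict:
        truth = self.truth
        if isinstance(truth, CurveParams):
            truth_d = {"variant": "base", **dataclasses.asdict(truth)}
        elif isinstance(truth, LinearTimeParams):
            truth_d = dataclasses.asdict(truth) | {"variant": "linear_time"}
        elif isinstance(truth, IndividualTimeParams):
            truth_d = {
                "variant": "individual_time",
                "A": truth.A, "B": truth.B, "E": truth.E,
                "C_by_year": {str(k): v for k, v in truth.C_by_year.items()},
            }
        else:
            truth_d = {
                "variant": "base_time",
                "params_by_year": {
                    str(y): dataclasses.asdict(cp)
                    for y, cp in truth.params_by_year.items()
                },
            }
        return {
            "name": self.name,
            "truth": truth_d,
            "concentrations": list(self.concentrations),
            "n_per_tube": self.n_per_tube,
            "replicates": self.replicates,
            "years": None if self.years is None else list(self.years),
            "seed": self.seed,
        }


def simulate_bioassay(spec: ScenarioSpec, seed: int | None = None) -> BioassayDataset:
    """Generate a dataset: y ~ Binomial(n_per_tube, p_truth(c[, t])).

    Reproducible: the same spec (and seed) yields an identical dataset.
    ``seed`` overrides ``spec.seed`` when given.
    """
    spec.check_span()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    years: Sequence[int | None] = spec.years if spec.years else (None,)
    records: list[BioassayRecord] = []
    for year in years:
        for conc in spec.concentrations:
            if year is None or isinstance(spec.truth, CurveParams):
                p = mean_mortality(
                    spec.truth
                    if isinstance(spec.truth, CurveParams)
                    else spec.truth.curve_for_year(year),
                    conc,
                )
            else:
                p = mean_mortality_temporal(spec.truth, conc, year)
            deaths = rng.binomial(spec.n_per_tube, p, size=spec.replicates)
            for d in deaths:
                records.append(
                    BioassayRecord(
                        concentration=float(conc),
                        n_tested=spec.n_per_tube,
                        n_dead=int(d),
                        group=spec.group or spec.name,
                        year=year,
                        insecticide=spec.insecticide,
                    )
                )
    return BioassayDataset(
        records,
        metadata={"scenario": spec.to_dict(), "source": "synthetic"},
    )


def _doubling_grid(center: float, n_below: int, n_above: int) -> tuple[float, ...]:
    """0 plus a doubling series centred on ``center``."""
    return (0.0,) + tuple(center * 2.0**k for k in range(-n_below, n_above + 1))


#: Linear-time drift giving a 2.8-fold LC50 increase over 5 year steps
#: (LC50 scales as exp(2 * G * t) on the raw concentration scale).
_DRIFT_G = math.log(2.8) / (2 * 5)

_FIELD_YEARS = tuple(range(2016, 2022))


def preset_scenarios() -> dict[str, ScenarioSpec]:
    """Named study designs with realistic truths.

    * ``lab_susceptible`` — steep curve, true LC50 4.9e-5 % (susceptible
      colony scale).
    * ``lab_resistant`` — same shape, LC50 4.8e-3 %, higher background
      mortality (strongly resistant colony scale).
    * ``lab_resistant_heterogeneous`` — flatter slope (wider LC10-LC90
      span), LC50 3.9e-3 %.
    * ``field_stable`` — 6-year tube series, LC50 constant at 0.25 %.
    * ``field_drift`` — 6-year series whose LC50 grows 2.8-fold from the
      first to the last year.
    """
    lab_b, lab_e = 5.0, 7.0
    field_b, field_e = 3.0, 7.0
    f_stable = location_for_lc50(0.25, field_b, field_e)
    f_drift0 = location_for_lc50(0.25 / 2.8, field_b, field_e)
    field_grid = (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6)
    return {
        "lab_susceptible": ScenarioSpec(
            truth=curve_with_lc50(4.9e-5, A=0.03, B=lab_b, E=lab_e),
            concentrations=_doubling_grid(4.9e-5, 4, 4),
            name="lab_susceptible",
            insecticide="permethrin",
        ),
        "lab_resistant": ScenarioSpec(
            truth=curve_with_lc50(4.8e-3, A=0.09, B=lab_b, E=lab_e),
            concentrations=_doubling_grid(4.8e-3, 4, 4),
            name="lab_resistant",
            insecticide="permethrin",
        ),
        "lab_resistant_heterogeneous": ScenarioSpec(
            truth=curve_with_lc50(3.9e-3, A=0.04, B=2.0, E=lab_e),
            concentrations=_doubling_grid(3.9e-3, 5, 5),
            name="lab_resistant_heterogeneous",
            insecticide="permethrin",
        ),
        "field_stable": ScenarioSpec(
            truth=LinearTimeParams(
                A=0.01, B=field_b, E=field_e, F=f_stable, G=0.0, t0=_FIELD_YEARS[0]
            ),
            concentrations=field_grid,
            n_per_tube=30,
            replicates=2,
            years=_FIELD_YEARS,
            name="field_stable",
            insecticide="deltamethrin",
        ),
        "field_drift": ScenarioSpec(
            truth=LinearTimeParams(
                A=0.01, B=field_b, E=field_e, F=f_drift0, G=_DRIFT_G, t0=_FIELD_YEARS[0]
            ),
            concentrations=field_grid,
            n_per_tube=30,
            replicates=2,
            years=_FIELD_YEARS,
            name="field_drift",
            insecticide="deltamethrin",
        ),
    }


def write_scenario(dataset: BioassayDataset, spec: ScenarioSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the standard CSV plus a truth JSON sidecar."""
    from .data import write_bioassay_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": outdir / f"{spec.name}.csv",
        "truth": outdir / f"{spec.name}_truth.json",
    }
    write_bioassay_csv(dataset, paths["csv"])
    paths["truth"].write_text(json.dumps(spec.to_dict(), indent=2))
    return paths
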