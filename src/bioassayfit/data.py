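"""Bioassay records: validation, CSV I/O, Abbott correction, DC conversion.

An intensity bioassay exposes batches ("tubes") of mosquitoes to a series of
insecticide concentrations, including a no-insecticide control, and records
how many died.  One :class:`BioassayRecord` is one tube; a
:class:`BioassayDataset` is the collection fitted as a unit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BioassayRecord",
    "BioassayDataset",
    "SchemaError",
    "BioassayValidationError",
    "read_bioassay_csv",
    "write_bioassay_csv",
    "abbott_correct",
    "concentration_to_dc_multiple",
    "dc_multiple_to_concentration",
    "DEFAULT_DC_TABLE",
]

#: WHO tube discriminating concentrations (% active ingredient) used when no
#: table is supplied.  Override via the ``dc_table`` argument.
DEFAULT_DC_TABLE: dict[str, float] = {
    "deltamethrin": 0.05,
    "permethrin": 0.75,
}

#: Logical field -> default CSV column name. ``concentration_pct`` is accepted
#: as an alias for ``concentration``.
DEFAULT_SCHEMA: dict[str, str] = {
    "concentration": "concentration",
    "n_tested": "n_tested",
    "n_dead": "n_dead",
    "group": "group",
    "year": "year",
    "insecticide": "insecticide",
}

_REQUIRED_FIELDS = ("concentration", "n_tested", "n_dead")
_OPTIONAL_FIELDS = ("group", "year", "insecticide")


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class BioassayValidationError(ValueError):
    """One or more rows violate the bioassay-record invariants."""


@dataclasses.dataclass(frozen=True)
class BioassayRecord:
    """A single assay replicate.

    Parameters
    ----------
    concentration
        Insecticide concentration in % active ingredient; 0 denotes an
        unexposed control tube.
    n_tested
        Number of mosquitoes exposed (> 0).
    n_dead
        Number dead at scoring time (0 <= n_dead <= n_tested).
    group, year, insecticide
        Optional covariates: strain/village label, calendar year, compound.
    """

    concentration: float
    n_tested: int
    n_dead: int
    group: str | None = None
    year: int | None = None
    insecticide: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise BioassayValidationError(
                f"concentration must be finite and >= 0, got {self.concentration!r}"
            )
        if int(self.n_tested) != self.n_tested or self.n_tested <= 0:
            raise BioassayValidationError(
                f"n_tested must be a positive integer, got {self.n_tested!r}"
            )
        if int(self.n_dead) != self.n_dead or not 0 <= self.n_dead <= self.n_tested:
            raise BioassayValidationError(
                f"n_dead must be an integer in [0, n_tested], got "
                f"n_dead={self.n_dead!r}, n_tested={self.n_tested!r}"
            )

    @property
    def mortality(self) -> float:
        """Observed mortality proportion ``n_dead / n_tested``."""
        return self.n_dead / self.n_tested


class BioassayDataset:
    """An ordered collection of validated :class:`BioassayRecord`.

    The dataset carries optional metadata (source label, insecticide,
    units).  Curve fitting requires at least two distinct nonzero
    concentrations.
    """

    def __init__(
        self,
        records: Iterable[BioassayRecord],
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        self.records: tuple[BioassayRecord, ...] = tuple(records)
        if not self.records:
            raise BioassayValidationError("dataset must contain at least one record")
        self.metadata: dict[str, object] = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BioassayDataset) and self.records == other.records
        )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([r.concentration for r in self.records], dtype=float)

    @property
    def n_tested(self) -> np.ndarray:
        return np.array([r.n_tested for r in self.records], dtype=int)

    @property
    def n_dead(self) -> np.ndarray:
        return np.array([r.n_dead for r in self.records], dtype=int)

    @property
    def mortality(self) -> np.ndarray:
        """Observed per-record mortality proportions."""
        return self.n_dead / self.n_tested

    @property
    def years(self) -> np.ndarray | None:
        ys = [r.year for r in self.records]
        if any(y is None for y in ys):
            return None
        return np.array(ys, dtype=int)

    @property
    def groups(self) -> list[str | None]:
        return [r.group for r in self.records]

    def distinct_nonzero_concentrations(self) -> np.ndarray:
        c = self.concentrations
        return np.unique(c[c > 0])

    def require_fittable(self) -> None:
        """Raise unless the dataset supports curve fitting."""
        if len(self.distinct_nonzero_concentrations()) < 2:
            raise BioassayValidationError(
                "curve fitting requires at least 2 distinct nonzero concentrations"
            )

    def subset(self, mask: Sequence[bool]) -> "BioassayDataset":
        recs = [r for r, m in zip(self.records, mask) if m]
        return BioassayDataset(recs, self.metadata)

    def split_by_group(self) -> dict[str, "BioassayDataset"]:
        out: dict[str, BioassayDataset] = {}
        for g in dict.fromkeys(self.groups):  # preserves order
            key = "<none>" if g is None else str(g)
            out[key] = self.subset([r.group == g for r in self.records])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


def _resolve_schema(
    columns: Sequence[str], schema: Mapping[str, str] | None
) -> dict[str, str]:
    schema = dict(schema or {})
    resolved: dict[str, str] = {}
    for field in _REQUIRED_FIELDS + _OPTIONAL_FIELDS:
        candidates = [schema.get(field, DEFAULT_SCHEMA[field])]
        if field == "concentration" and "concentration" not in schema:
            candidates.append("concentration_pct")
        col = next((c for c in candidates if c in columns), None)
        if col is None and field in _REQUIRED_FIELDS:
            raise SchemaError(
                f"required column {candidates[0]!r} (field {field!r}) not found; "
                f"available columns: {list(columns)}"
            )
        if col is not None:
            resolved[field] = col
    return resolved


def read_bioassay_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    metadata: Mapping[str, object] | None = None,
) -> BioassayDataset:
    """Read a comma-separated, UTF-8, headered bioassay table.

    ``schema`` maps logical field names (``concentration``, ``n_tested``,
    ``n_dead``, optionally ``group``/``year``/``insecticide``) to the column
    names used in the file.  Counts are required: mortality given only as a
    percentage cannot feed the binomial likelihood and is rejected.

    Raises
    ------
    SchemaError
        A required column cannot be resolved.
    BioassayValidationError
        A row violates the record invariants; the message carries the
        1-based data row number.
    """
    df = pd.read_csv(path, encoding="utf-8")
    cols = _resolve_schema(list(df.columns), schema)
    records: list[BioassayRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        try:
            for count_field in ("n_tested", "n_dead"):
                v = row[cols[count_field]]
                if float(v) != int(float(v)):
                    raise BioassayValidationError(
                        f"{count_field} must be an integer count, got {v!r}"
                    )
            rec = BioassayRecord(
                concentration=float(row[cols["concentration"]]),
                n_tested=int(row[cols["n_tested"]]),
                n_dead=int(row[cols["n_dead"]]),
                group=(
                    None
                    if "group" not in cols or pd.isna(row[cols["group"]])
                    else str(row[cols["group"]])
                ),
                year=(
                    None
                    if "year" not in cols or pd.isna(row[cols["year"]])
                    else int(row[cols["year"]])
                ),
                insecticide=(
                    None
                    if "insecticide" not in cols or pd.isna(row[cols["insecticide"]])
                    else str(row[cols["insecticide"]])
                ),
            )
        except (BioassayValidationError, ValueError) as exc:
            problems.append(f"row {rownum}: {exc}")
            continue
        records.append(rec)
    if problems:
        raise BioassayValidationError("; ".join(problems))
    return BioassayDataset(records, metadata)


def write_bioassay_csv(dataset: BioassayDataset, path: str | Path) -> None:
    """Write a dataset back to the standard CSV schema (round-trip safe)."""
    dataset.to_frame().to_csv(path, index=False, encoding="utf-8")


def write_metadata_sidecar(
    dataset: BioassayDataset, path: str | Path, **extra: object
) -> None:
    """JSON sidecar carrying units, DC table and any extra metadata."""
    payload = {
        "concentration_units": "% active ingredient",
        "dc_table": DEFAULT_DC_TABLE,
        **dataset.metadata,
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def abbott_correct(observed_mortality, control_mortality):
    """Classical Abbott correction ``(p - c) / (1 - c)``, floored at 0.

    Provided for comparison with conventional analyses only: the
    dose-response model estimates background mortality as the zero-dose
    asymptote ``A`` and never requires pre-corrected data.

    Accepts scalars or arrays; ``control_mortality`` must be < 1.
    """
    p = np.asarray(observed_mortality, dtype=float)
    c = np.asarray(control_mortality, dtype=float)
    if np.any(c >= 1.0) or np.any(c < 0.0):
        raise ValueError("control_mortality must lie in [0, 1)")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("observed_mortality must lie in [0, 1]")
    out = np.maximum((p - c) / (1.0 - c), 0.0)
    return float(out) if out.ndim == 0 else out


def _lookup_dc(insecticide: str, dc_table: Mapping[str, float] | None) -> float:
    table = DEFAULT_DC_TABLE if dc_table is None else dict(dc_table)
    key = insecticide.strip().lower()
    norm = {k.strip().lower(): v for k, v in table.items()}
    if key not in norm:
        raise KeyError(
            f"unknown insecticide {insecticide!r}; known: {sorted(norm)}"
        )
    dc = float(norm[key])
    if dc <= 0:
        raise ValueError(f"discriminating concentration must be > 0, got {dc}")
    return dc


def concentration_to_dc_multiple(
    concentration: float,
    insecticide: str,
    dc_table: Mapping[str, float] | None = None,
) -> float:
    """Convert % a.i. to a multiple of the discriminating concentration.

    E.g. 0.25% deltamethrin with DC 0.05% is 5x the discriminating dose.
    """
    return float(concentration) / _lookup_dc(insecticide, dc_table)


def dc_multiple_to_concentration(
    multiple: float,
    insecticide: str,
    dc_table: Mapping[str, float] | None = None,
) -> float:
    """Inverse of :func:`concentration_to_dc_multiple`."""
    return float(multiple) * _lookup_dc(insecticide, dc_table)
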