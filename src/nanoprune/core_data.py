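"""Domain types, CSV I/O, cleaning, aggregation and OECD validity checks.

The central container is :class:`DescriptorMatrix`: one row per
(material, concentration) exposure condition, one column per
nanodescriptor or experimental parameter, with per-column metadata
(descriptor kind, concentration-dependence flag, units).  Bioassay
observations are plain :class:`BioassayRecord` rows that get aggregated
into per-(material, day, endpoint) :class:`ResponseSeries`.

Missing descriptor values are recorded, never imputed: imputation of
instrument dropouts (e.g. an XRD crystallite size that could not be
resolved for some compositions) would bias downstream model selection,
so the cleaning step removes the whole column instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "DescriptorKind",
    "DescriptorColumn",
    "DescriptorMatrix",
    "BioassayRecord",
    "ResponseSeries",
    "ValidityReport",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_bioassay_table",
    "write_bioassay_table",
    "clean_missing",
    "aggregate_series",
    "check_validity",
]

#: Experimental parameters that co-vary with the exposure concentration
#: and therefore must not enter the concentration-independent stages
#: (clustering, pruning); they re-enter only before the final fit.
CONCENTRATION_DEPENDENT_DEFAULTS = (
    "concentration",
    "hydrodynamic_size",
    "zeta_potential",
)


class DescriptorKind(str, enum.Enum):
    """Family of a descriptor column."""

    CONSTITUTIONAL = "constitutional"
    POTENTIAL_ENERGY = "potential_energy"
    LATTICE_ENERGY = "lattice_energy"
    TOPOLOGY = "topology"
    SIZE = "size"
    FORCE_VECTOR = "force_vector"
    EXPERIMENTAL = "experimental"


@dataclass(frozen=True)
class Material:
    """A library member: pure/doped metal-oxide NM or a reference salt.

    Parameters
    ----------
    name
        Unique material identifier (e.g. ``"10%Fe-CuO"``).
    fe_fraction
        Percent Fe doping in [0, 100].  Reference salts and non-CuO
        controls carry their nominal value with ``is_reference_salt``
        or a name marker.
    is_reference_salt
        True for ionic controls such as CuCl2.
    """

    name: str
    fe_fraction: float = 0.0
    is_reference_salt: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fe_fraction <= 100.0:
            raise ValueError(
                f"fe_fraction must be in [0, 100], got {self.fe_fraction!r}"
            )


@dataclass(frozen=True)
class DescriptorColumn:
    name: str
    kind: DescriptorKind = DescriptorKind.EXPERIMENTAL
    concentration_dependent: bool = False
    units: str = ""


@dataclass
class DescriptorMatrix:
    """(material, concentration) rows x named descriptor columns.

    ``data`` is indexed by a (material, concentration) MultiIndex; NaN
    entries mark recorded missing values.  ``schema`` carries one
    :class:`DescriptorColumn` per data column, in column order.
    """

    data: pd.DataFrame
    schema: list[DescriptorColumn] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.schema:
            self.schema = [DescriptorColumn(name=c) for c in self.data.columns]
        names = [c.name for c in self.schema]
        if names != list(self.data.columns):
            raise ValueError("schema column names must match data columns in order")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate (material, concentration) row keys: {dups}")

    @property
    def column_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def column_meta(self, name: str) -> DescriptorColumn:
        for col in self.schema:
            if col.name == name:
                return col
        raise KeyError(name)

    def concentration_independent_columns(self) -> list[str]:
        return [c.name for c in self.schema if not c.concentration_dependent]

    def concentration_dependent_columns(self) -> list[str]:
        return [c.name for c in self.schema if c.concentration_dependent]

    def subset(self, columns: list[str]) -> "DescriptorMatrix":
        meta = {c.name: c for c in self.schema}
        return DescriptorMatrix(
            data=self.data[columns].copy(),
            schema=[meta[c] for c in columns],
        )


@dataclass(frozen=True)
class BioassayRecord:
    """One organism count for one test container."""

    material: str
    concentration: float  # mg/kg soil dry weight
    replicate: int
    day: int  # 21 or 49
    endpoint: str  # "survival" or "reproduction"
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.day not in (21, 49):
            raise ValueError(f"day must be 21 or 49, got {self.day}")
        if self.endpoint not in ("survival", "reproduction"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")


@dataclass
class ResponseSeries:
    """Aggregated concentration-response curve for one (material, day, endpoint)."""

    material: str
    day: int
    endpoint: str
    concentrations: np.ndarray  # strictly increasing
    mean: np.ndarray
    sd: np.ndarray  # NaN where n == 1
    n: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.n < 1):
            raise ValueError("replicate counts must be >= 1")

    def nonzero(self) -> "ResponseSeries":
        """The series restricted to non-zero concentrations (controls dropped)."""
        keep = self.concentrations > 0
        return ResponseSeries(
            self.material,
            self.day,
            self.endpoint,
            self.concentrations[keep],
            self.mean[keep],
            self.sd[keep],
            self.n[keep],
        )


@dataclass(frozen=True)
class ValidityReport:
    """OECD enchytraeid-reproduction-test control validity criteria.

    Valid iff control adult mortality < 20%, every control replicate
    has > 50 juveniles, and the control coefficient of variation < 50%.
    All three comparisons are strict, following the guideline wording.
    """

    control_mortality: float
    control_juveniles_mean: float
    control_juveniles_min: float
    control_cv: float
    valid: bool


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_descriptor_table(path, schema: list[DescriptorColumn] | None = None) -> DescriptorMatrix:
    """Read a descriptor CSV whose first two columns are material, concentration.

    Missing cells are recorded as NaN, not imputed.  Duplicate
    (material, concentration) keys and non-numeric cells raise
    ``ValueError`` naming the offender.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    if raw.shape[1] < 3:
        raise ValueError("descriptor table needs material, concentration and >=1 descriptor column")
    mat_col, conc_col = raw.columns[:2]
    index = pd.MultiIndex.from_arrays(
        [raw[mat_col], pd.to_numeric(raw[conc_col])],
        names=["material", "concentration"],
    )
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate (material, concentration) row keys: {dups}")
    values = {}
    for col in raw.columns[2:]:
        parsed = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            if pd.isna(cell):
                parsed[i] = np.nan
                continue
            try:
                # float() is correctly rounded; pandas' fast parser is not
                parsed[i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} in column {col!r} at row {index[i]}"
                ) from None
        values[col] = parsed
    data = pd.DataFrame(values, index=index)

    def default_meta(name: str) -> DescriptorColumn:
        # without a sidecar schema, the standard concentration-dependent
        # experimental parameters are recognised by name so they never
        # leak into the concentration-independent stages
        dependent = name in CONCENTRATION_DEPENDENT_DEFAULTS
        return DescriptorColumn(
            name=name,
            kind=DescriptorKind.EXPERIMENTAL,
            concentration_dependent=dependent,
        )

    if schema is not None:
        meta = {c.name: c for c in schema}
        cols = [meta.get(c, default_meta(c)) for c in data.columns]
    else:
        cols = [default_meta(c) for c in data.columns]
    return DescriptorMatrix(data=data, schema=cols)


def write_descriptor_table(m: DescriptorMatrix, path) -> None:
    # key columns get reserved names so a "concentration" descriptor
    # column (the exposure dose as an experimental variable) can coexist
    # with the row key
    key = pd.DataFrame(
        {
            "material": m.data.index.get_level_values(0),
            "row_concentration": m.data.index.get_level_values(1),
        }
    )
    out = pd.concat([key, m.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")


def read_bioassay_table(path) -> list[BioassayRecord]:
    """Read bioassay CSV with columns material, concentration, replicate, day, endpoint, count."""
    df = pd.read_csv(path)
    required = {"material", "concentration", "replicate", "day", "endpoint", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bioassay table missing columns: {sorted(missing)}")
    return [
        BioassayRecord(
            material=str(r.material),
            concentration=float(r.concentration),
            replicate=int(r.replicate),
            day=int(r.day),
            endpoint=str(r.endpoint),
            count=int(r.count),
        )
        for r in df.itertuples()
    ]


def write_bioassay_table(records: list[BioassayRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning / aggregation / validity
# ---------------------------------------------------------------------------


def clean_missing(m: DescriptorMatrix) -> tuple[DescriptorMatrix, list[str]]:
    """Drop every column with at least one missing value.

    Returns the cleaned matrix (row set unchanged) and the ordered list
    of removed column names.  Raises if nothing survives.
    """
    removed = [c for c in m.data.columns if m.data[c].isna().any()]
    kept = [c for c in m.data.columns if c not in removed]
    if not kept:
        raise ValueError("no descriptors survive cleaning")
    return m.subset(kept), removed


def aggregate_series(records: list[BioassayRecord]) -> list[ResponseSeries]:
    """Aggregate replicate counts into one ResponseSeries per (material, day, endpoint).

    Means are plain averages over replicates; sd uses the n-1
    denominator and is NaN for single replicates.
    """
    if not records:
        return []
    df = pd.DataFrame([r.__dict__ for r in records])
    out: list[ResponseSeries] = []
    for (mat, day, ep), grp in df.groupby(["material", "day", "endpoint"], sort=True):
        agg = (
            grp.groupby("concentration")["count"]
            .agg(["mean", "std", "count"])
            .sort_index()
        )
        out.append(
            ResponseSeries(
                material=mat,
                day=int(day),
                endpoint=ep,
                concentrations=agg.index.to_numpy(dtype=float),
                mean=agg["mean"].to_numpy(),
                sd=agg["std"].to_numpy(),
                n=agg["count"].to_numpy(),
            )
        )
    return out


def check_validity(
    controls: list[BioassayRecord], n_adults_introduced: int = 10
) -> ValidityReport:
    """Evaluate OECD control validity on concentration-0 records.

    Survival records give adult mortality (relative to
    ``n_adults_introduced`` adults per replicate, 10 in the standard
    test); reproduction records give juvenile counts.  All criteria are
    strict inequalities.
    """
    ctrl = [r for r in controls if r.concentration == 0]
    if not ctrl:
        raise ValueError("no control (concentration 0) records supplied")
    adults = [r.count for r in ctrl if r.endpoint == "survival"]
    juveniles = [r.count for r in ctrl if r.endpoint == "reproduction"]
    if not adults or not juveniles:
        raise ValueError("controls must include both survival and reproduction records")

    mortality = (n_adults_introduced - float(np.mean(adults))) / n_adults_introduced
    juv_mean = float(np.mean(juveniles))
    juv_min = float(np.min(juveniles))
    cv = float(np.std(juveniles, ddof=1) / juv_mean) if len(juveniles) > 1 else 0.0
    valid = (mortality < 0.20) and (juv_min > 50) and (cv < 0.50)
    return ValidityReport(
        control_mortality=mortality,
        control_juveniles_mean=juv_mean,
        control_juveniles_min=juv_min,
        control_cv=cv,
        valid=valid,
    )
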