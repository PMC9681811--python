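"""Species-level derived estimators and cross-species power-law regressions.

From a packaged table of visual-system measurements (eye axial diameter,
retinal ganglion cell counts, visual acuity in cycles/degree, V-1 surface
area and neuron totals, inter-bundle spacing and bundle density) the module
derives: the estimated total number of minicolumn bundles in the left V-1
(density x area), the number of neurons per minicolumn under a cylinder
model (each bundle drains a cylinder whose diameter is the median
inter-bundle distance, applied to the areal neuron density), minicolumns
per orientation pinwheel, and log10-log10 OLS power-law fits between any
pair of positive variables — notably the tight acuity ~ total-bundles
relationship.

Derived columns are never pre-filled from the table: they are recomputed by
these operations and cross-checked against the printed values in tests.
Ape/human rows carry (low, high) total-bundle ranges because their
tangential and orthogonal density estimates differ; regressions resolve a
range by a selectable policy (midpoint by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

MISSING = float("nan")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species row; missing measurements are ``None``."""

    species: str
    order: str
    eye_axial_mm: Optional[float]
    retinal_gc_millions: Optional[float]
    acuity_cpd: Optional[float]
    body_mass_kg: Optional[float]
    v1_area_mm2: Optional[float]
    v1_neurons_millions: Optional[float]
    interbundle_um: Optional[float]
    density_orthogonal_mm2: Optional[float]
    density_tangential_mm2: Optional[float]
    printed_total_low: Optional[float]
    printed_total_high: Optional[float]
    printed_neurons_per_column: Optional[float]


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(y) on log10(x): y = 10^intercept * x^exponent."""

    exponent: float
    intercept: float
    r_squared: float
    n_points: int
    excluded: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("power-law fit needs at least 3 species")


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def load_species_table() -> list[SpeciesRecord]:
    """The packaged 10-species table, with explicit missing markers."""
    with resources.files("bundlemap.data").joinpath("species_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    records = []
    for _, row in df.iterrows():
        kwargs = {"species": row["species"], "order": row["order"]}
        for col in df.columns:
            if col in ("species", "order"):
                continue
            v = row[col]
            kwargs[col] = None if pd.isna(v) else float(v)
        records.append(SpeciesRecord(**kwargs))
    return records


def total_bundles(bundle_density_mm2: float, v1_area_mm2: float) -> int:
    """Estimated total bundles in the left V-1: density x area, rounded."""
    if bundle_density_mm2 is None or v1_area_mm2 is None:
        return None
    if bundle_density_mm2 <= 0 or v1_area_mm2 <= 0:
        raise ValueError("density and area must be positive")
    return _round_half_even(bundle_density_mm2 * v1_area_mm2)


def total_bundles_range(record: SpeciesRecord):
    """Total-bundle estimate(s) for a species record.

    Returns a single int when only one density is tabulated, a (low, high)
    tuple when both tangential and orthogonal densities exist, or None when
    density or area is missing.
    """
    area = record.v1_area_mm2
    densities = [
        d
        for d in (record.density_tangential_mm2, record.density_orthogonal_mm2)
        if d is not None
    ]
    if area is None or not densities:
        return None
    totals = sorted(total_bundles(d, area) for d in densities)
    if len(totals) == 1:
        return totals[0]
    return (totals[0], totals[-1])


def neurons_per_column(
    v1_neurons_millions: float, v1_area_mm2: float, interbundle_um: float
) -> int:
    """Cylinder-model neurons per minicolumn.

    Areal neuron density (per mm^2) times the cross-section of a cylinder
    with diameter equal to the median inter-bundle distance.
    """
    if None in (v1_neurons_millions, v1_area_mm2, interbundle_um):
        return None
    if min(v1_neurons_millions, v1_area_mm2, interbundle_um) <= 0:
        raise ValueError("all inputs must be positive")
    areal_density = v1_neurons_millions * 1e6 / v1_area_mm2  # neurons/mm^2
    cylinder_mm2 = np.pi * (interbundle_um / 2.0 / 1000.0) ** 2
    return _round_half_even(areal_density * cylinder_mm2)


def per_pinwheel(
    total_bundles_count: float,
    n_pinwheels: float,
    orientation_columns: float | None = None,
) -> int:
    """Minicolumns per orientation pinwheel (optionally per orientation column)."""
    if total_bundles_count <= 0:
        raise ValueError("total bundle count must be positive")
    if n_pinwheels <= 0:
        raise ValueError("pinwheel count must be positive")
    per = total_bundles_count / n_pinwheels
    if orientation_columns is not None:
        if orientation_columns <= 0:
            raise ValueError("orientation column count must be positive")
        per = per / orientation_columns
    return _round_half_even(per)


def powerlaw_fit(x, y, labels=None, excluded=()) -> PowerLawFit:
    """OLS of log10(y) on log10(x) over strictly positive pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive values")
    res = stats.linregress(np.log10(x), np.log10(y))
    return PowerLawFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
        excluded=tuple(excluded),
    )


def resolve_total(record: SpeciesRecord, range_policy: str = "midpoint"):
    """Total-bundle value entering a regression, with range policy applied.

    Species whose table row prints a single total (one effective estimate)
    use the orthogonal-density product — the tabulated convention.  Species
    with a printed (low, high) range resolve it per ``range_policy``:
    ``midpoint`` (default), ``low`` or ``high``, on the recomputed endpoints.
    """
    if range_policy not in ("midpoint", "low", "high"):
        raise ValueError("range_policy must be midpoint/low/high")
    tb = total_bundles_range(record)
    if tb is None:
        return None
    if isinstance(tb, tuple) and record.printed_total_high is None:
        # both densities tabulated but a single printed total: use the
        # orthogonal-density endpoint, matching the table's convention
        return total_bundles(record.density_orthogonal_mm2, record.v1_area_mm2)
    if isinstance(tb, tuple):
        low, high = tb
        return {"low": low, "high": high, "midpoint": (low + high) / 2.0}[range_policy]
    return tb


_FIELDS = {
    "acuity": "acuity_cpd",
    "body_mass": "body_mass_kg",
    "retinal_gc": "retinal_gc_millions",
    "v1_neurons": "v1_neurons_millions",
    "interbundle_distance": "interbundle_um",
    "eye_axial": "eye_axial_mm",
}


def _variable(record: SpeciesRecord, name: str, range_policy: str):
    if name == "total_bundles":
        return resolve_total(record, range_policy)
    if name == "neurons_per_column":
        return neurons_per_column(
            record.v1_neurons_millions, record.v1_area_mm2, record.interbundle_um
        )
    field = _FIELDS.get(name, name)
    return getattr(record, field)


def fit_table(
    records: list[SpeciesRecord],
    x: str,
    y: str,
    range_policy: str = "midpoint",
) -> PowerLawFit:
    """Power-law fit between two named variables across the species table.

    Variable names: acuity, body_mass, retinal_gc, v1_neurons,
    interbundle_distance, eye_axial, total_bundles, neurons_per_column, or
    any raw record field name.  Species missing either variable are excluded
    from the fit but listed in ``PowerLawFit.excluded``.
    """
    xs, ys, excluded = [], [], []
    for rec in records:
        xv = _variable(rec, x, range_policy)
        yv = _variable(rec, y, range_policy)
        if xv is None or yv is None:
            excluded.append(rec.species)
            continue
        xs.append(xv)
        ys.append(yv)
    return powerlaw_fit(xs, ys, excluded=tuple(excluded))


def derived_table(records: list[SpeciesRecord]) -> pd.DataFrame:
    """Recomputed derived columns next to the printed ones, for inspection."""
    rows = []
    for rec in records:
        tb = total_bundles_range(rec)
        if isinstance(tb, tuple):
            low, high = tb
        else:
            low = high = tb
        rows.append(
            {
                "species": rec.species,
                "total_bundles_low": low,
                "total_bundles_high": high,
                "printed_total_low": rec.printed_total_low,
                "printed_total_high": rec.printed_total_high,
                "neurons_per_column": neurons_per_column(
                    rec.v1_neurons_millions, rec.v1_area_mm2, rec.interbundle_um
                ),
                "printed_neurons_per_column": rec.printed_neurons_per_column,
            }
        )
    return pd.DataFrame(rows)
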