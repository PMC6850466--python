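"""Reference tables: wood density, density-reduction factors, collapse
ratios, and carbon concentrations, with species -> genus -> group fallback.

Carbon is computed per piece as volume x BD x DR x CC where

* ``BD`` is the initial (undecayed) bulk density of the species (g/cm3,
  equivalently Mg/m3), treated as fixed per species;
* ``DR`` is the density-reduction factor (decayed:undecayed density) for the
  species x decay class, with a mean and standard error; draws come from a
  normal truncated below at zero;
* ``CC`` is the carbon fraction of dry mass by hardwood/softwood/unknown
  group, likewise (mean, SE) with truncated-normal draws.

Cross-sections flatten as wood decays; the collapse ratio ``CR``
(height:width) is sampled uniformly from an empirical pool of observed
values per decay class.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .pieces import SENTINEL_SPECIES, UNKNOWN, UNKNOWN_HARDWOOD, UNKNOWN_SOFTWOOD

HARDWOOD = "hardwood"
SOFTWOOD = "softwood"
GROUPS = (HARDWOOD, SOFTWOOD, "unknown")

_SENTINEL_GROUP = {
    UNKNOWN_HARDWOOD: HARDWOOD,
    UNKNOWN_SOFTWOOD: SOFTWOOD,
    UNKNOWN: "unknown",
}


class ResolutionError(KeyError):
    """A species code cannot be resolved to any density entry."""


class ConfigurationError(ValueError):
    """A reference table is structurally unusable (e.g. empty sample list)."""


@dataclass(frozen=True)
class DensityEntry:
    """Initial density plus per-decay-class reduction factors for one taxon.

    ``resolution_level`` records how the entry was obtained: 'species' for a
    direct table hit, 'genus' for a mean over congeners, 'other' for the
    hardwood/softwood/unknown group default.
    """

    species_code: str
    genus: str
    group: str
    initial_density_g_cm3: float
    reduction_mean: Tuple[float, float, float, float, float]
    reduction_se: Tuple[float, float, float, float, float]
    resolution_level: str = "species"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}, got {self.group}")
        if not self.initial_density_g_cm3 > 0:
            raise ConfigurationError("initial density must be > 0")
        for m in self.reduction_mean:
            if not 0 < m <= 1.25:
                raise ConfigurationError(
                    f"reduction_mean must lie in (0, 1.25], got {m}"
                )
        for s in self.reduction_se:
            if s < 0:
                raise ConfigurationError("reduction_se must be >= 0")


@dataclass(frozen=True)
class CollapseTable:
    """Pools of observed collapse-ratio values, one list per decay class."""

    samples: Tuple[Tuple[float, ...], ...]  # index 0 -> decay class 1

    def __post_init__(self) -> None:
        if len(self.samples) != 5:
            raise ConfigurationError("collapse table needs exactly 5 class lists")
        for c, vals in enumerate(self.samples, start=1):
            if not vals:
                raise ConfigurationError(f"collapse class {c} sample list is empty")
            for v in vals:
                if not 0 < v <= 1.5:
                    raise ConfigurationError(
                        f"collapse ratio {v} (class {c}) outside (0, 1.5]"
                    )

    def values(self, decay_class: int) -> Tuple[float, ...]:
        return self.samples[decay_class - 1]


@dataclass(frozen=True)
class CarbonTable:
    """Carbon mass fraction (mean, SE) per hardwood/softwood/unknown group."""

    params: Mapping[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.params:
                raise ConfigurationError(f"carbon table missing group '{g}'")
            mean, se = self.params[g]
            if not 0 < mean < 1:
                raise ConfigurationError(f"carbon fraction must be in (0,1), got {mean}")
            if se < 0:
                raise ConfigurationError("carbon SE must be >= 0")


@dataclass
class ReferenceTables:
    """All literature-derived inputs bundled together.

    ``species_meta`` maps species codes that have no density row of their own
    to a (genus, group) pair so the fallback hierarchy can still resolve them.
    """

    density: Dict[str, DensityEntry]
    collapse: CollapseTable
    carbon: CarbonTable
    species_meta: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def genus_group_of(self, species_code: str) -> Optional[Tuple[str, str]]:
        if species_code in self.density:
            e = self.density[species_code]
            return e.genus, e.group
        if species_code in self.species_meta:
            return self.species_meta[species_code]
        if species_code in _SENTINEL_GROUP:
            return ("", _SENTINEL_GROUP[species_code])
        return None


# ---------------------------------------------------------------------------
# resolution


def _group_default_entry(group: str, density: Mapping[str, DensityEntry]) -> DensityEntry:
    """Mean entry over every species of the group ('other' tier).

    For the 'unknown' group the average runs over all species in the table.
    """
    members = [
        e for e in density.values()
        if group == "unknown" or e.group == group
    ]
    if not members:
        raise ResolutionError(f"no density entries available for group '{group}'")
    return _mean_entry(members, species_code=f"__{group}__", genus="", group=group,
                       level="other")


def _mean_entry(entries: Sequence[DensityEntry], species_code: str, genus: str,
                group: str, level: str) -> DensityEntry:
    bd = float(np.mean([e.initial_density_g_cm3 for e in entries]))
    rm = tuple(
        float(np.mean([e.reduction_mean[k] for e in entries])) for k in range(5)
    )
    rs = tuple(
        float(np.mean([e.reduction_se[k] for e in entries])) for k in range(5)
    )
    return DensityEntry(species_code, genus, group, bd, rm, rs, resolution_level=level)


def resolve_entry(species_code: str, tables: ReferenceTables) -> DensityEntry:
    """Resolve a species code to a density entry via species -> genus -> group.

    The genus tier averages the entries of congeneric species present in the
    table (unweighted). Sentinel codes resolve directly to the group tier.
    """
    density = tables.density
    if species_code in density:
        return density[species_code]
    gg = tables.genus_group_of(species_code)
    if gg is None:
        raise ResolutionError(
            f"species '{species_code}' has no density entry, genus or group metadata"
        )
    genus, group = gg
    if genus:
        congeners = [e for e in density.values() if e.genus == genus]
        if congeners:
            return _mean_entry(congeners, species_code, genus, group, level="genus")
    return _group_default_entry(group, density)


def resolve_density(
    species_code: str, decay_class: int, tables: ReferenceTables
) -> Tuple[float, float, float, str]:
    """Return (BD, DR mean, DR SE, resolution level) for a species x class."""
    entry = resolve_entry(species_code, tables)
    k = decay_class - 1
    return (
        entry.initial_density_g_cm3,
        entry.reduction_mean[k],
        entry.reduction_se[k],
        entry.resolution_level,
    )


# ---------------------------------------------------------------------------
# sampling


def truncnorm_positive(
    mean, se, rng: np.random.Generator, size=None
) -> np.ndarray | float:
    """Draw from N(mean, se^2) truncated below at 0 (inverse-CDF method).

    Degenerate SEs (0) return the mean unchanged.
    """
    mean = np.asarray(mean, dtype=float)
    se = np.asarray(se, dtype=float)
    if size is None:
        size = np.broadcast_shapes(mean.shape, se.shape)
    u = rng.random(size)
    lo = ndtr(-mean / np.where(se > 0, se, 1.0))  # CDF at the zero bound
    draws = mean + se * ndtri(lo + u * (1.0 - lo))
    out = np.where(se > 0, draws, mean)
    # Guard the open bound: u ~ 0 can land exactly on the truncation point.
    out = np.maximum(out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def sample_collapse_ratio(
    decay_class: int, table: CollapseTable, rng: np.random.Generator
) -> float:
    """Uniform draw from the observed collapse-ratio pool of a decay class."""
    vals = table.values(decay_class)
    return float(vals[rng.integers(len(vals))])


def nominal_collapse_ratio(decay_class: int, table: CollapseTable) -> float:
    """Arithmetic mean of the class pool; used for no-uncertainty baselines."""
    return float(np.mean(table.values(decay_class)))


def carbon_concentration(group: str, table: CarbonTable) -> Tuple[float, float]:
    """(mean fraction, SE fraction) of carbon concentration for a group."""
    if group not in table.params:
        raise ConfigurationError(f"unknown species group '{group}'")
    mean, se = table.params[group]
    return float(mean), float(se)


def sample_reduction(
    entry: DensityEntry, decay_class: int, rng: np.random.Generator
) -> float:
    """One truncated-normal draw of the density-reduction factor."""
    k = decay_class - 1
    return float(
        truncnorm_positive(entry.reduction_mean[k], entry.reduction_se[k], rng, size=())
    )


# ---------------------------------------------------------------------------
# default tables (synthetic fixtures)

#: Synthetic collapse-ratio pools shaped like published decay-class patterns
#: (medians declining from ~1.0 at class 1 to ~0.5 at class 5). These are
#: package fixtures, not field data.
_DEFAULT_COLLAPSE = (
    (0.92, 0.95, 0.97, 0.98, 1.00, 1.00, 1.00, 1.02, 1.03, 1.05, 1.08, 1.10),
    (0.78, 0.82, 0.86, 0.90, 0.93, 0.95, 0.97, 1.00, 1.00, 1.02, 1.05, 1.12),
    (0.58, 0.65, 0.72, 0.78, 0.82, 0.85, 0.88, 0.92, 0.95, 1.00, 1.03, 1.10),
    (0.40, 0.48, 0.55, 0.62, 0.68, 0.72, 0.75, 0.80, 0.85, 0.92, 0.98, 1.05),
    (0.25, 0.32, 0.38, 0.45, 0.50, 0.52, 0.58, 0.65, 0.72, 0.80, 0.88, 0.95),
)

#: Synthetic density entries (BD in g/cm3; DR mean/SE per class 1..5) for a
#: small northeastern-US species pool; values are fixtures shaped like the
#: literature (density and DR decline with decay class), not measured data.
_DEFAULT_DENSITY_ROWS = [
    # code, genus, group, BD, DR means 1..5, DR SEs 1..5
    ("acer_rubrum", "Acer", HARDWOOD, 0.49,
     (1.00, 0.85, 0.64, 0.45, 0.30), (0.04, 0.07, 0.11, 0.13, 0.14)),
    ("acer_saccharum", "Acer", HARDWOOD, 0.56,
     (1.00, 0.87, 0.66, 0.44, 0.28), (0.04, 0.07, 0.11, 0.13, 0.14)),
    ("betula_papyrifera", "Betula", HARDWOOD, 0.48,
     (0.99, 0.82, 0.60, 0.42, 0.27), (0.05, 0.08, 0.12, 0.14, 0.15)),
    ("betula_alleghaniensis", "Betula", HARDWOOD, 0.55,
     (1.00, 0.84, 0.63, 0.43, 0.28), (0.05, 0.08, 0.12, 0.14, 0.15)),
    ("fagus_grandifolia", "Fagus", HARDWOOD, 0.56,
     (1.00, 0.86, 0.65, 0.46, 0.31), (0.04, 0.08, 0.12, 0.14, 0.15)),
    ("quercus_rubra", "Quercus", HARDWOOD, 0.56,
     (1.01, 0.88, 0.68, 0.48, 0.33), (0.04, 0.07, 0.11, 0.13, 0.15)),
    ("prunus_serotina", "Prunus", HARDWOOD, 0.47,
     (0.99, 0.83, 0.62, 0.43, 0.29), (0.05, 0.08, 0.12, 0.14, 0.15)),
    ("populus_tremuloides", "Populus", HARDWOOD, 0.35,
     (0.98, 0.80, 0.58, 0.40, 0.26), (0.05, 0.09, 0.12, 0.14, 0.15)),
    ("picea_rubens", "Picea", SOFTWOOD, 0.37,
     (1.00, 0.86, 0.66, 0.47, 0.32), (0.04, 0.07, 0.11, 0.13, 0.14)),
    ("picea_glauca", "Picea", SOFTWOOD, 0.37,
     (1.00, 0.85, 0.65, 0.46, 0.31), (0.04, 0.07, 0.11, 0.13, 0.14)),
    ("pinus_strobus", "Pinus", SOFTWOOD, 0.34,
     (0.99, 0.84, 0.63, 0.44, 0.30), (0.05, 0.08, 0.11, 0.13, 0.14)),
    ("pinus_resinosa", "Pinus", SOFTWOOD, 0.41,
     (1.00, 0.85, 0.64, 0.45, 0.30), (0.05, 0.08, 0.11, 0.13, 0.14)),
    ("tsuga_canadensis", "Tsuga", SOFTWOOD, 0.38,
     (1.00, 0.86, 0.66, 0.48, 0.33), (0.04, 0.08, 0.12, 0.14, 0.15)),
    ("abies_balsamea", "Abies", SOFTWOOD, 0.33,
     (0.98, 0.82, 0.61, 0.43, 0.29), (0.05, 0.08, 0.12, 0.14, 0.15)),
]

#: Carbon concentration constants used by national inventory practice:
#: 49% (hardwood), 52% (softwood), 51% (unknown), with small SEs.
DEFAULT_CARBON = CarbonTable(
    {
        HARDWOOD: (0.49, 0.0043),
        SOFTWOOD: (0.52, 0.0042),
        "unknown": (0.51, 0.0042),
    }
)


def default_tables() -> ReferenceTables:
    """Packaged synthetic reference tables (fixtures, not field data)."""
    density = {
        code: DensityEntry(code, genus, group, bd, rm, rs)
        for code, genus, group, bd, rm, rs in _DEFAULT_DENSITY_ROWS
    }
    return ReferenceTables(
        density=density,
        collapse=CollapseTable(_DEFAULT_COLLAPSE),
        carbon=DEFAULT_CARBON,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def read_density_csv(path: str | Path) -> Dict[str, DensityEntry]:
    """Read density entries from CSV.

    Columns: species_code, genus, group, initial_density_g_cm3,
    dr_mean_1..dr_mean_5, dr_se_1..dr_se_5.
    """
    df = pd.read_csv(path)
    required = ["species_code", "genus", "group", "initial_density_g_cm3"]
    required += [f"dr_mean_{k}" for k in range(1, 6)]
    required += [f"dr_se_{k}" for k in range(1, 6)]
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(f"density CSV missing column '{col}'")
    out: Dict[str, DensityEntry] = {}
    for _, row in df.iterrows():
        code = str(row["species_code"])
        out[code] = DensityEntry(
            code,
            str(row["genus"]),
            str(row["group"]),
            float(row["initial_density_g_cm3"]),
            tuple(float(row[f"dr_mean_{k}"]) for k in range(1, 6)),
            tuple(float(row[f"dr_se_{k}"]) for k in range(1, 6)),
        )
    return out


def read_collapse_csv(path: str | Path) -> CollapseTable:
    """Read collapse-ratio pools from long-format CSV (decay_class, value)."""
    df = pd.read_csv(path)
    for col in ("decay_class", "value"):
        if col not in df.columns:
            raise ConfigurationError(f"collapse CSV missing column '{col}'")
    lists: List[Tuple[float, ...]] = []
    for c in range(1, 6):
        vals = tuple(float(v) for v in df.loc[df["decay_class"] == c, "value"])
        if not vals:
            raise ConfigurationError(f"collapse CSV has no values for class {c}")
        lists.append(vals)
    return CollapseTable(tuple(lists))


def read_carbon_csv(path: str | Path) -> CarbonTable:
    """Read carbon parameters from CSV (group, mean_fraction, se_fraction)."""
    df = pd.read_csv(path)
    for col in ("group", "mean_fraction", "se_fraction"):
        if col not in df.columns:
            raise ConfigurationError(f"carbon CSV missing column '{col}'")
    params = {
        str(row["group"]): (float(row["mean_fraction"]), float(row["se_fraction"]))
        for _, row in df.iterrows()
    }
    return CarbonTable(params)


def write_density_csv(density: Mapping[str, DensityEntry], path: str | Path) -> None:
    rows = []
    for e in density.values():
        row = {
            "species_code": e.species_code,
            "genus": e.genus,
            "group": e.group,
            "initial_density_g_cm3": e.initial_density_g_cm3,
        }
        row.update({f"dr_mean_{k+1}": e.reduction_mean[k] for k in range(5)})
        row.update({f"dr_se_{k+1}": e.reduction_se[k] for k in range(5)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_collapse_csv(table: CollapseTable, path: str | Path) -> None:
    rows = [
        {"decay_class": c, "value": v}
        for c in range(1, 6)
        for v in table.values(c)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_carbon_csv(table: CarbonTable, path: str | Path) -> None:
    rows = [
        {"group": g, "mean_fraction": m, "se_fraction": s}
        for g, (m, s) in table.params.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
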