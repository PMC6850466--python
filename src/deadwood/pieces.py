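"""Domain types for downed coarse woody debris (DCWD) inventories.

A plot is sampled with the line-intersect method: pieces of dead wood whose
central axis crosses one of the plot's transects are tallied, recording the
intersect diameter ``DI``, the cavity diameter ``DH`` if the piece is hollow,
the species (or an unknown-hardwood / unknown-softwood / unknown sentinel),
a 1-5 decay class, and the position along the transect.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

#: Sentinel species codes used when a piece cannot be identified.
UNKNOWN_HARDWOOD = "unknown_hardwood"
UNKNOWN_SOFTWOOD = "unknown_softwood"
UNKNOWN = "unknown"
SENTINEL_SPECIES = frozenset({UNKNOWN_HARDWOOD, UNKNOWN_SOFTWOOD, UNKNOWN})

#: Minimum tally diameter (cm); pieces must be strictly larger. 3 inches.
MIN_TALLY_DIAMETER_CM = 7.6
#: Minimum tally length (cm) for decay classes 1-4. 6 inches.
MIN_TALLY_LENGTH_CM = 15.0
#: Class-5 pieces must be longer than this (cm). 5 feet.
MIN_CLASS5_LENGTH_CM = 152.0
#: Class-5 pieces must stick out at least this far (cm) above the floor.
MIN_CLASS5_HEIGHT_CM = 13.0


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class PlotDesign:
    """Transect geometry of one plot.

    The default mirrors the post-2012 national inventory design: four
    circular subplots, each carrying one 14.6 m transect, for a total
    transect length L = 58.4 m.
    """

    plot_id: str
    n_transects: int = 4
    transect_length_m: float = 14.6

    def __post_init__(self) -> None:
        if self.n_transects < 1:
            raise ValidationError(f"n_transects must be >= 1, got {self.n_transects}")
        if self.transect_length_m <= 0:
            raise ValidationError(
                f"transect_length_m must be > 0, got {self.transect_length_m}"
            )

    @property
    def total_length_m(self) -> float:
        """Total transect length L (m) entering the per-hectare expansion."""
        return self.n_transects * self.transect_length_m


@dataclass(frozen=True)
class DCWDPiece:
    """One tallied piece of downed coarse woody debris."""

    plot_id: str
    subplot_id: int
    position_m: float
    diameter_cm: float
    hollow_diameter_cm: float = 0.0
    species_code: str = UNKNOWN
    decay_class: int = 3
    length_cm: Optional[float] = None
    exposed_height_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.diameter_cm > 0:
            raise ValidationError(f"diameter_cm must be > 0, got {self.diameter_cm}")
        if not 0 <= self.hollow_diameter_cm <= self.diameter_cm:
            raise ValidationError(
                "hollow_diameter_cm must lie in [0, diameter_cm]; got "
                f"DH={self.hollow_diameter_cm} with DI={self.diameter_cm}"
            )
        if self.decay_class not in (1, 2, 3, 4, 5):
            raise ValidationError(f"decay_class must be in 1..5, got {self.decay_class}")
        if self.position_m < 0:
            raise ValidationError(f"position_m must be >= 0, got {self.position_m}")
        if self.length_cm is not None and self.length_cm <= 0:
            raise ValidationError(f"length_cm must be > 0, got {self.length_cm}")

    @property
    def is_hollow(self) -> bool:
        return self.hollow_diameter_cm > 0


@dataclass(frozen=True)
class PairedObservation:
    """The same physical piece as recorded by the production and QA crews.

    Hollow diameters may be absent (``None``) on either side when a crew did
    not record the piece as hollow; difference models for cavity diameter are
    built only from pairs where both crews measured one.
    """

    plot_id: str
    pair_id: str
    production_diameter_cm: float
    qa_diameter_cm: float
    production_decay_class: int
    qa_decay_class: int
    production_species: str
    qa_species: str
    production_hollow_cm: Optional[float] = None
    qa_hollow_cm: Optional[float] = None

    def __post_init__(self) -> None:
        for side, d in (("production", self.production_diameter_cm),
                        ("qa", self.qa_diameter_cm)):
            if not d > 0:
                raise ValidationError(f"{side} diameter must be > 0, got {d}")
        for side, c in (("production", self.production_decay_class),
                        ("qa", self.qa_decay_class)):
            if c not in (1, 2, 3, 4, 5):
                raise ValidationError(f"{side} decay class must be in 1..5, got {c}")


@dataclass(frozen=True)
class PlotEstimate:
    """Deterministic per-plot estimate: volume (m3/ha) and carbon (Mg C/ha)."""

    plot_id: str
    volume_m3_ha: float
    carbon_MgC_ha: float

    def __post_init__(self) -> None:
        if self.volume_m3_ha < 0 or self.carbon_MgC_ha < 0:
            raise ValidationError("plot estimates must be non-negative")
        if not (math.isfinite(self.volume_m3_ha) and math.isfinite(self.carbon_MgC_ha)):
            raise ValidationError("plot estimates must be finite")
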