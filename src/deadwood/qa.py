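"""Empirical measurement-error models built from paired production/QA data.

Blind remeasurement audits provide two independent records of the same
pieces. For continuous variables (intersect diameter, cavity diameter) the
model is simply the pool of observed QA - production differences; a
perturbation adds one uniformly resampled difference to a measurement. For
class variables (decay class, species) the model is a row-conditional
confusion table: the production value indexes the row, and a perturbation
replaces it with a uniform draw over the QA values observed in that row
(multiplicity preserved), which reproduces the empirical conditional
distribution exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np

from .pieces import DCWDPiece, PairedObservation
from .reference import ReferenceTables

CONTINUOUS_VARIABLES = ("diameter", "hollow_diameter")
CATEGORICAL_VARIABLES = ("decay_class", "species")


class ModelBuildError(ValueError):
    """No usable paired data for the requested variable."""


@dataclass(frozen=True)
class ContinuousErrorModel:
    """Pool of QA - production differences (cm) for one continuous variable."""

    variable: str
    difference_samples: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.difference_samples:
            raise ModelBuildError(f"no difference samples for '{self.variable}'")
        if not np.all(np.isfinite(self.difference_samples)):
            raise ModelBuildError(f"non-finite difference for '{self.variable}'")

    @property
    def is_degenerate(self) -> bool:
        return all(d == 0.0 for d in self.difference_samples)


@dataclass(frozen=True)
class ConfusionModel:
    """Row-conditional confusion table for one class variable.

    Each production value maps to the list of QA values seen with it,
    with multiplicity; row sampling is uniform over list entries.
    """

    variable: str
    rows: Dict[Hashable, Tuple[Hashable, ...]]

    def __post_init__(self) -> None:
        for key, vals in self.rows.items():
            if not vals:
                raise ModelBuildError(f"empty confusion row for {key!r}")

    @property
    def is_degenerate(self) -> bool:
        return all(all(v == k for v in vals) for k, vals in self.rows.items())

    def row_probabilities(self, production_value: Hashable) -> Dict[Hashable, float]:
        vals = self.rows[production_value]
        n = len(vals)
        out: Dict[Hashable, float] = {}
        for v in vals:
            out[v] = out.get(v, 0.0) + 1.0 / n
        return out


# ---------------------------------------------------------------------------
# piece matching

_MatchResult = Tuple[
    List[Tuple[DCWDPiece, DCWDPiece]], List[DCWDPiece], List[DCWDPiece]
]


def match_pieces(
    production: Sequence[DCWDPiece],
    qa: Sequence[DCWDPiece],
    position_tol_m: float = 1.0,
    diameter_tol_cm: float = 7.62,
) -> _MatchResult:
    """Greedy nearest-position pairing of two crews' tallies of one transect.

    Candidate pairs within both tolerances are accepted in order of smaller
    position gap, then smaller diameter gap, then production tally order;
    each piece matches at most once. Returns (pairs, unmatched production,
    unmatched QA). This is a pragmatic stand-in for the inventory program's
    full matching algorithm.
    """
    candidates = []
    for i, p in enumerate(production):
        for j, q in enumerate(qa):
            dpos = abs(p.position_m - q.position_m)
            ddia = abs(p.diameter_cm - q.diameter_cm)
            if dpos <= position_tol_m and ddia <= diameter_tol_cm:
                candidates.append((dpos, ddia, i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_q: set[int] = set()
    pairs: List[Tuple[DCWDPiece, DCWDPiece]] = []
    for _, _, i, j in candidates:
        if i in used_p or j in used_q:
            continue
        used_p.add(i)
        used_q.add(j)
        pairs.append((production[i], qa[j]))
    unmatched_p = [p for i, p in enumerate(production) if i not in used_p]
    unmatched_q = [q for j, q in enumerate(qa) if j not in used_q]
    return pairs, unmatched_p, unmatched_q


# ---------------------------------------------------------------------------
# model building


def filter_outlier_pairs(
    pairs: Sequence[PairedObservation], max_abs_diameter_diff_cm: float = 50.0
) -> List[PairedObservation]:
    """Drop pairs whose diameter disagreement exceeds a sanity threshold.

    Gross disagreements are recording errors, not the measurement error the
    propagation is meant to capture; the default 50 cm only removes
    transcription-scale mistakes.
    """
    return [
        p
        for p in pairs
        if abs(p.qa_diameter_cm - p.production_diameter_cm) <= max_abs_diameter_diff_cm
    ]


def build_continuous_error(
    pairs: Sequence[PairedObservation], variable: str
) -> ContinuousErrorModel:
    """Compile QA - production differences for 'diameter' or 'hollow_diameter'.

    The cavity model uses only pairs where both crews recorded a cavity; no
    parametric distribution is fitted.
    """
    if variable == "diameter":
        diffs = [p.qa_diameter_cm - p.production_diameter_cm for p in pairs]
    elif variable == "hollow_diameter":
        diffs = [
            p.qa_hollow_cm - p.production_hollow_cm
            for p in pairs
            if p.production_hollow_cm is not None and p.qa_hollow_cm is not None
        ]
    else:
        raise ModelBuildError(f"unknown continuous variable '{variable}'")
    if not diffs:
        raise ModelBuildError(f"no qualifying pairs for variable '{variable}'")
    return ContinuousErrorModel(variable, tuple(float(d) for d in diffs))


def build_confusion(
    pairs: Sequence[PairedObservation], variable: str
) -> ConfusionModel:
    """Build the row-conditional confusion table for 'decay_class' or 'species'."""
    if variable == "decay_class":
        obs = [(p.production_decay_class, p.qa_decay_class) for p in pairs]
    elif variable == "species":
        obs = [(p.production_species, p.qa_species) for p in pairs]
    else:
        raise ModelBuildError(f"unknown categorical variable '{variable}'")
    if not obs:
        raise ModelBuildError(f"no pairs for variable '{variable}'")
    rows: Dict[Hashable, List[Hashable]] = {}
    for prod, qa in obs:
        rows.setdefault(prod, []).append(qa)
    return ConfusionModel(variable, {k: tuple(v) for k, v in rows.items()})


def group_confusion_rows(
    model: ConfusionModel, tables: ReferenceTables
) -> Dict[str, Tuple[Hashable, ...]]:
    """Aggregate species confusion rows by hardwood/softwood/unknown group.

    Used as the fallback row for species never seen in the paired data.
    """
    agg: Dict[str, List[Hashable]] = {}
    for prod, qa_vals in model.rows.items():
        gg = tables.genus_group_of(str(prod))
        if gg is None:
            continue
        agg.setdefault(gg[1], []).extend(qa_vals)
    return {g: tuple(v) for g, v in agg.items()}


def sample_perturbation(
    model: ContinuousErrorModel | ConfusionModel,
    production_value,
    rng: np.random.Generator,
):
    """Perturb one production measurement through an error model.

    Continuous: value + a uniformly resampled difference. Categorical:
    uniform draw from the confusion row; values with no row are returned
    unchanged (identity fallback keeps sampling total).
    """
    if isinstance(model, ContinuousErrorModel):
        d = model.difference_samples[rng.integers(len(model.difference_samples))]
        return production_value + d
    row = model.rows.get(production_value)
    if row is None:
        return production_value
    return row[rng.integers(len(row))]


# ---------------------------------------------------------------------------
# model set + JSON round trip


@dataclass
class ErrorModelSet:
    """All error models used by the propagation engine."""

    diameter: ContinuousErrorModel
    hollow_diameter: Optional[ContinuousErrorModel]
    decay_class: ConfusionModel
    species: ConfusionModel

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[PairedObservation],
        outlier_threshold_cm: Optional[float] = 50.0,
    ) -> "ErrorModelSet":
        if outlier_threshold_cm is not None:
            pairs = filter_outlier_pairs(pairs, outlier_threshold_cm)
        try:
            hollow = build_continuous_error(pairs, "hollow_diameter")
        except ModelBuildError:
            hollow = None
        return cls(
            diameter=build_continuous_error(pairs, "diameter"),
            hollow_diameter=hollow,
            decay_class=build_confusion(pairs, "decay_class"),
            species=build_confusion(pairs, "species"),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "diameter": list(self.diameter.difference_samples),
            "hollow_diameter": (
                list(self.hollow_diameter.difference_samples)
                if self.hollow_diameter
                else None
            ),
            "decay_class": {
                str(k): list(v) for k, v in self.decay_class.rows.items()
            },
            "species": {str(k): list(v) for k, v in self.species.rows.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ErrorModelSet":
        payload = json.loads(Path(path).read_text())
        hollow = payload.get("hollow_diameter")
        return cls(
            diameter=ContinuousErrorModel("diameter", tuple(payload["diameter"])),
            hollow_diameter=(
                ContinuousErrorModel("hollow_diameter", tuple(hollow))
                if hollow
                else None
            ),
            decay_class=ConfusionModel(
                "decay_class",
                {int(k): tuple(int(x) for x in v)
                 for k, v in payload["decay_class"].items()},
            ),
            species=ConfusionModel(
                "species",
                {k: tuple(v) for k, v in payload["species"].items()},
            ),
        )
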