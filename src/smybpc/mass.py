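"""Delta-mass molecular-weight model and the six MW groups of sMyBP-C.

Variant masses on an SDS-PAGE gel differ only through the short in-frame
segments that alternative splicing adds or removes, so a variant's molecular
weight is predicted relative to an anchor variant:

    MW(v) = MW(anchor) + delta_aa(v, anchor) * mean_residue_mass

with ``delta_aa`` the signed residue difference summed over the cassette
exons (11, 13, 12, 11, 18 and 19 residues for exons 2, 3, 4, 5, 10 and 23)
plus the difference in post-C10 tail length (26, 35, 3 or 33 residues).  The
default anchor is h-v9 (126 kDa), which lacks every NH2-terminal cassette,
and the default mean residue mass is 0.110 kDa.  Predictions are rounded
half-away-from-zero to 0.5 kDa, the precision of the printed masses.

For band interpretation the variants fall into six MW groups (heaviest
first): 1 = v1/v5/v202 (131-131.5), 2 = v2/v6/v013 (129-129.5), 3 =
v3/v7/v10 (128), 4 = v8/v002 (127-127.5), 5 = v4/v9 (126-126.5) and 6 =
v012 (115.5 kDa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .catalog import (
    CASSETTE_EXONS,
    ExonSpec,
    InclusionPattern,
    VariantRecord,
    get_variant,
    load_architecture,
    load_catalog,
    resolve_tail,
)

__all__ = [
    "MassModel",
    "MwGroup",
    "GroupAssignment",
    "CalibrationResult",
    "CalibrationError",
    "UnsupportedComparisonError",
    "GROUP_MEMBERS",
    "GROUP_COLORS",
    "delta_aa",
    "predict_mw",
    "calibrate",
    "mw_groups",
    "assign_group",
    "default_mass_model",
]


class UnsupportedComparisonError(ValueError):
    """Raised when delta_aa involves an internal-start pattern, whose missing
    residue count is not known."""


class CalibrationError(ValueError):
    """Raised when the catalog cannot identify the residue mass (no spread)."""


def _aa_lengths(architecture: Optional[Sequence[ExonSpec]]) -> dict[int, int]:
    if architecture is None:
        architecture = load_architecture()
    return {
        s.index: s.aa_length
        for s in architecture
        if s.index in CASSETTE_EXONS and s.aa_length is not None
    }


def delta_aa(
    pattern_a: InclusionPattern,
    pattern_b: InclusionPattern,
    architecture: Optional[Sequence[ExonSpec]] = None,
) -> int:
    """Signed residue-count difference between two frame-valid patterns.

    Antisymmetric: ``delta_aa(a, b) == -delta_aa(b, a)``.
    """
    if pattern_a.truncated or pattern_b.truncated:
        raise UnsupportedComparisonError(
            "internal-start patterns have no printed residue count for the "
            "truncated segment; delta_aa is undefined for them"
        )
    aa = _aa_lengths(architecture)
    delta = sum(
        aa[exon] * (int(pattern_a.flag(exon)) - int(pattern_b.flag(exon)))
        for exon in CASSETTE_EXONS
    )
    delta += resolve_tail(pattern_a).aa_after_C10 - resolve_tail(pattern_b).aa_after_C10
    return delta


@dataclass(frozen=True)
class MassModel:
    """Anchored delta-mass predictor."""

    anchor_id: str
    anchor_mass: float  # kDa
    anchor_pattern: InclusionPattern
    mean_residue_mass: float = 0.110  # kDa per residue
    rounding_step: float = 0.5  # kDa

    def __post_init__(self) -> None:
        if not 0.100 <= self.mean_residue_mass <= 0.120:
            raise ValueError(
                f"mean_residue_mass {self.mean_residue_mass} outside [0.100, 0.120]"
            )
        if self.rounding_step <= 0:
            raise ValueError("rounding_step must be positive")


def default_mass_model(catalog: Optional[Iterable[VariantRecord]] = None) -> MassModel:
    """The default model: anchored on h-v9 at its printed 126 kDa."""
    records = list(catalog) if catalog is not None else load_catalog()
    anchor = get_variant(records, "h-v9")
    return MassModel(
        anchor_id=anchor.id,
        anchor_mass=anchor.printed_mw,
        anchor_pattern=anchor.pattern,
    )


def _round_half_away(value: float, step: float) -> float:
    q = value / step
    return math.copysign(math.floor(abs(q) + 0.5), q) * step


def predict_mw(
    pattern: InclusionPattern,
    model: Optional[MassModel] = None,
    architecture: Optional[Sequence[ExonSpec]] = None,
) -> float:
    """Predict a variant's molecular weight in kDa from its exon composition."""
    if model is None:
        model = default_mass_model()
    delta = delta_aa(pattern, model.anchor_pattern, architecture)
    raw = model.anchor_mass + delta * model.mean_residue_mass
    return _round_half_away(raw, model.rounding_step)


@dataclass(frozen=True)
class CalibrationResult:
    model: MassModel
    fitted_mean_residue_mass: float
    residuals: dict[str, float]  # id -> predicted - printed, kDa (unrounded)


def calibrate(
    catalog: Iterable[VariantRecord],
    anchor_id: str = "h-v9",
    architecture: Optional[Sequence[ExonSpec]] = None,
) -> CalibrationResult:
    """Least-squares fit of the mean residue mass against printed masses.

    Minimizes sum((anchor_mass + d_i * m - printed_i)^2) over the
    non-truncated human full-length variants; closed form
    m = sum(d_i * y_i) / sum(d_i^2) with y_i the printed offset from the
    anchor mass.
    """
    records = [r for r in catalog if not r.partial]
    anchor = get_variant(records, anchor_id)
    usable = [
        r for r in records
        if r.species == "human" and not r.pattern.truncated
    ]
    if len(usable) < 2:
        raise CalibrationError("need at least two variants with printed masses")
    deltas = [delta_aa(r.pattern, anchor.pattern, architecture) for r in usable]
    denom = sum(d * d for d in deltas)
    if denom == 0:
        raise CalibrationError("degenerate design: all residue differences are zero")
    num = sum(d * (r.printed_mw - anchor.printed_mw) for d, r in zip(deltas, usable))
    fitted = num / denom
    model = MassModel(
        anchor_id=anchor.id,
        anchor_mass=anchor.printed_mw,
        anchor_pattern=anchor.pattern,
        mean_residue_mass=fitted,
    )
    residuals = {
        r.id: (anchor.printed_mw + d * fitted) - r.printed_mw
        for d, r in zip(deltas, usable)
    }
    return CalibrationResult(model=model, fitted_mean_residue_mass=fitted, residuals=residuals)


#: Printed six-group partition of the 14 human variants, heaviest first.
GROUP_MEMBERS = {
    1: ("h-v1", "h-v5", "h-v202"),
    2: ("h-v2", "h-v6", "h-v013"),
    3: ("h-v3", "h-v7", "h-v10"),
    4: ("h-v8", "h-v002"),
    5: ("h-v4", "h-v9"),
    6: ("h-v012",),
}

GROUP_COLORS = {1: "red", 2: "orange", 3: "yellow", 4: "green", 5: "blue", 6: "purple"}


@dataclass(frozen=True)
class MwGroup:
    index: int
    members: tuple[str, ...]
    mass_range: tuple[float, float]  # kDa, (low, high)
    center: float  # kDa, mean of members' printed MWs
    color_label: str


def mw_groups(catalog: Optional[Iterable[VariantRecord]] = None) -> list[MwGroup]:
    """The six MW groups with centers computed from the printed masses."""
    records = list(catalog) if catalog is not None else load_catalog()
    groups = []
    for index, members in GROUP_MEMBERS.items():
        masses = [get_variant(records, m).printed_mw for m in members]
        groups.append(
            MwGroup(
                index=index,
                members=members,
                mass_range=(min(masses), max(masses)),
                center=sum(masses) / len(masses),
                color_label=GROUP_COLORS[index],
            )
        )
    return groups


@dataclass(frozen=True)
class GroupAssignment:
    """Nearest-group call for one estimated band mass."""

    group: Optional[MwGroup]
    distance: float  # kDa to nearest center (inf when no groups)
    ambiguous: bool
    runner_up: Optional[MwGroup] = None

    @property
    def group_index(self) -> Optional[int]:
        return None if self.group is None else self.group.index

    @property
    def candidate_variants(self) -> tuple[str, ...]:
        return () if self.group is None else self.group.members


def assign_group(
    mass: float,
    groups: Sequence[MwGroup],
    tolerance: float = 1.5,
    margin: float = 0.5,
) -> GroupAssignment:
    """Assign a sized band to the MW group with the nearest center.

    Returns no group when the nearest center is farther than ``tolerance``;
    flags the call ambiguous (with the runner-up attached) when the two best
    distances differ by less than ``margin``.  Ties go to the heavier group.
    """
    if not groups:
        raise ValueError("groups must be nonempty")
    ranked = sorted(groups, key=lambda g: (abs(mass - g.center), g.index))
    best = ranked[0]
    best_d = abs(mass - best.center)
    if best_d > tolerance:
        return GroupAssignment(group=None, distance=best_d, ambiguous=False)
    if len(ranked) > 1:
        second = ranked[1]
        second_d = abs(mass - second.center)
        if second_d - best_d < margin:
            return GroupAssignment(
                group=best, distance=best_d, ambiguous=True, runner_up=second
            )
    return GroupAssignment(group=best, distance=best_d, ambiguous=False)
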