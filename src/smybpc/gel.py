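"""SDS-PAGE band sizing from ladder calibration, and band-to-group assignment.

Protein migration on a denaturing gel is approximately log-linear in
molecular weight over a narrow mass window, so band masses are estimated by
ordinary least squares of log10(mass) on relative migration (Rf; 0 at the
well, 1 at the dye front) over the marker lane, then reading each band's Rf
through the fitted standard curve.  Sized bands are assigned to the six
sMyBP-C MW groups by nearest group center (see :mod:`smybpc.mass`).

The 115-132 kDa analysis window sits comfortably inside the default
250-50 kDa ladder, where the semilog model is an excellent approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mass import GroupAssignment, MwGroup, assign_group

__all__ = [
    "LadderLane",
    "StandardCurve",
    "BandObservation",
    "AssignmentResult",
    "InsufficientCalibrationError",
    "LadderDataError",
    "ExtrapolationWarning",
    "DEFAULT_LADDER_MASSES",
    "default_ladder",
    "fit_standard_curve",
    "estimate_mass",
    "rf_for_mass",
    "assign_bands",
    "read_ladder",
    "write_ladder",
    "read_band_table",
    "write_band_table",
    "groups_per_lane",
]


class InsufficientCalibrationError(ValueError):
    """Fewer than three ladder markers."""


class LadderDataError(ValueError):
    """Ladder migrations are not monotone in mass."""


class ExtrapolationWarning(UserWarning):
    """A band's Rf lies outside the calibrated marker range."""


@dataclass(frozen=True)
class LadderLane:
    """Marker lane: (mass kDa, Rf) pairs."""

    markers: tuple[tuple[float, float], ...]

    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.markers], dtype=float)

    def rfs(self) -> np.ndarray:
        return np.array([r for _, r in self.markers], dtype=float)


#: Default simulated ladder: brackets the 115-132 kDa analysis window.
DEFAULT_LADDER_MASSES = (250.0, 150.0, 125.0, 100.0, 75.0, 50.0)


def default_ladder() -> LadderLane:
    """Log-linear ladder spanning Rf 0 (250 kDa) to 1 (50 kDa)."""
    top, bottom = DEFAULT_LADDER_MASSES[0], DEFAULT_LADDER_MASSES[-1]
    span = math.log10(top) - math.log10(bottom)
    markers = tuple(
        (m, (math.log10(top) - math.log10(m)) / span) for m in DEFAULT_LADDER_MASSES
    )
    return LadderLane(markers=markers)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted semilog sizing model: log10(mass) = intercept + slope * Rf."""

    slope: float
    intercept: float
    fit_r2: float
    rf_min: float
    rf_max: float
    residuals: tuple[float, ...] = ()  # per-marker, log10 kDa units

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise LadderDataError("standard curve slope must be negative")


def fit_standard_curve(ladder: LadderLane) -> StandardCurve:
    """OLS of log10(marker mass) on Rf.

    Requires at least three markers with Rf strictly increasing as mass
    decreases.
    """
    if len(ladder.markers) < 3:
        raise InsufficientCalibrationError(
            f"need >=3 ladder markers, got {len(ladder.markers)}"
        )
    order = np.argsort(-ladder.masses())  # heaviest first
    masses = ladder.masses()[order]
    rfs = ladder.rfs()[order]
    if not np.all(np.diff(rfs) > 0):
        raise LadderDataError("ladder Rf must strictly increase as mass decreases")
    log_mass = np.log10(masses)
    fit = stats.linregress(rfs, log_mass)
    predicted = fit.intercept + fit.slope * rfs
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fit_r2=float(fit.rvalue**2),
        rf_min=float(rfs.min()),
        rf_max=float(rfs.max()),
        residuals=tuple(float(r) for r in (log_mass - predicted)),
    )


def estimate_mass(
    curve: StandardCurve, rf: float, extrapolation_margin: float = 0.05
) -> float:
    """Mass in kDa at a given Rf; strictly decreasing in Rf.

    Emits :class:`ExtrapolationWarning` when the Rf lies beyond the
    calibrated marker range by more than ``extrapolation_margin``.
    """
    if rf < curve.rf_min - extrapolation_margin or rf > curve.rf_max + extrapolation_margin:
        warnings.warn(
            f"Rf {rf:.3f} outside calibrated range "
            f"[{curve.rf_min:.3f}, {curve.rf_max:.3f}] +/- {extrapolation_margin}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(10.0 ** (curve.intercept + curve.slope * rf))


def rf_for_mass(curve: StandardCurve, mass: float) -> float:
    """Inverse of :func:`estimate_mass` (used to place synthetic bands)."""
    return (math.log10(mass) - curve.intercept) / curve.slope


@dataclass(frozen=True)
class BandObservation:
    """One immunoreactive band in a fiber lane."""

    lane_id: str
    rf: float
    estimated_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rf <= 1.0:
            raise ValueError(f"rf {self.rf} outside [0, 1]")


@dataclass(frozen=True)
class AssignmentResult:
    """A sized band with its MW-group call."""

    band: BandObservation
    group_index: Optional[int]
    candidate_variants: tuple[str, ...]
    ambiguous: bool
    runner_up_index: Optional[int] = None


def _merge_sized(
    sized: list[BandObservation], merge_window: float
) -> list[BandObservation]:
    """Collapse bands closer than the gel resolution floor (mass-sorted input)."""
    merged: list[list[BandObservation]] = []
    for band in sized:
        if merged and abs(merged[-1][-1].estimated_mass - band.estimated_mass) < merge_window:
            merged[-1].append(band)
        else:
            merged.append([band])
    out = []
    for cluster in merged:
        if len(cluster) == 1:
            out.append(cluster[0])
        else:
            out.append(
                BandObservation(
                    lane_id=cluster[0].lane_id,
                    rf=float(np.mean([b.rf for b in cluster])),
                    estimated_mass=float(np.mean([b.estimated_mass for b in cluster])),
                )
            )
    return out


def assign_bands(
    bands: Iterable[BandObservation],
    curve: StandardCurve,
    groups: Sequence[MwGroup],
    tolerance: float = 1.5,
    margin: float = 0.5,
    merge_window: float = 0.25,
) -> list[AssignmentResult]:
    """Size each band through the standard curve and assign it to a MW group.

    Lanes are processed independently: bands are sorted by estimated mass
    (descending), bands within ``merge_window`` kDa are merged (gel
    resolution floor), and duplicate hits on the same group within a lane are
    collapsed to the closest band.
    """
    by_lane: dict[str, list[BandObservation]] = {}
    lane_order: list[str] = []
    for band in bands:
        if band.lane_id not in by_lane:
            by_lane[band.lane_id] = []
            lane_order.append(band.lane_id)
        by_lane[band.lane_id].append(band)

    results: list[AssignmentResult] = []
    for lane in lane_order:
        sized = [
            replace(b, estimated_mass=estimate_mass(curve, b.rf))
            for b in by_lane[lane]
        ]
        sized.sort(key=lambda b: -b.estimated_mass)
        sized = _merge_sized(sized, merge_window)
        best_per_group: dict[Optional[int], tuple[float, AssignmentResult]] = {}
        lane_results: list[AssignmentResult] = []
        for band in sized:
            call: GroupAssignment = assign_group(
                band.estimated_mass, groups, tolerance=tolerance, margin=margin
            )
            result = AssignmentResult(
                band=band,
                group_index=call.group_index,
                candidate_variants=call.candidate_variants,
                ambiguous=call.ambiguous,
                runner_up_index=None if call.runner_up is None else call.runner_up.index,
            )
            key = call.group_index
            if key is not None and key in best_per_group:
                if call.distance < best_per_group[key][0]:
                    lane_results.remove(best_per_group[key][1])
                    best_per_group[key] = (call.distance, result)
                    lane_results.append(result)
                continue
            if key is not None:
                best_per_group[key] = (call.distance, result)
            lane_results.append(result)
        lane_results.sort(
            key=lambda r: -(r.band.estimated_mass if r.band.estimated_mass else 0.0)
        )
        results.extend(lane_results)
    return results


def groups_per_lane(results: Iterable[AssignmentResult]) -> dict[str, frozenset[int]]:
    """Recovered group set per lane (unassigned bands dropped)."""
    lanes: dict[str, set[int]] = {}
    for r in results:
        lanes.setdefault(r.band.lane_id, set())
        if r.group_index is not None:
            lanes[r.band.lane_id].add(r.group_index)
    return {lane: frozenset(groups) for lane, groups in lanes.items()}


# --- plain-text interchange -------------------------------------------------

def read_ladder(path: Path | str) -> LadderLane:
    """Read a ladder TSV with columns mass_kda, rf."""
    df = pd.read_csv(path, sep="\t")
    return LadderLane(
        markers=tuple((float(m), float(r)) for m, r in zip(df["mass_kda"], df["rf"]))
    )


def write_ladder(ladder: LadderLane, path: Path | str) -> None:
    pd.DataFrame(
        {"mass_kda": ladder.masses(), "rf": ladder.rfs()}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_band_table(path: Path | str) -> list[BandObservation]:
    """Read a band TSV with columns lane_id, band_index, rf."""
    df = pd.read_csv(path, sep="\t", dtype={"lane_id": str})
    df = df.sort_values(["lane_id", "band_index"], kind="stable")
    return [
        BandObservation(lane_id=row.lane_id, rf=float(row.rf))
        for row in df.itertuples()
    ]


def write_band_table(bands: pd.DataFrame, path: Path | str) -> None:
    bands.to_csv(path, sep="\t", index=False, float_format="%.6f")
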