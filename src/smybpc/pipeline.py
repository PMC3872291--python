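"""End-to-end band-table -> fiber-profile pipeline.

Glue that mirrors the study workflow: calibrate the standard curve from the
ladder lane, size and group-assign every band, and rebuild per-fiber
:class:`~smybpc.fibers.FiberRecord` objects ready for pattern tallying.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .fibers import FiberRecord
from .gel import (
    AssignmentResult,
    BandObservation,
    LadderLane,
    assign_bands,
    fit_standard_curve,
    groups_per_lane,
)
from .mass import MwGroup, mw_groups

__all__ = ["recover_fibers", "bands_from_frame"]


def bands_from_frame(bands: pd.DataFrame) -> list[BandObservation]:
    """Band observations from a (lane_id, band_index, rf) table."""
    ordered = bands.sort_values(["lane_id", "band_index"], kind="stable")
    return [
        BandObservation(lane_id=str(row.lane_id), rf=float(row.rf))
        for row in ordered.itertuples()
    ]


def recover_fibers(
    bands: pd.DataFrame | Iterable[BandObservation],
    ladder: LadderLane,
    muscle: str,
    groups: Optional[Sequence[MwGroup]] = None,
    myosin_of_lane: Optional[dict[str, frozenset[str]]] = None,
    tolerance: float = 1.5,
    margin: float = 0.5,
) -> tuple[list[FiberRecord], list[AssignmentResult]]:
    """Size, assign and regroup bands into per-fiber records.

    Returns the fibers (one per lane, in lane order) together with the raw
    per-band assignment results.
    """
    if isinstance(bands, pd.DataFrame):
        bands = bands_from_frame(bands)
    else:
        bands = list(bands)
    curve = fit_standard_curve(ladder)
    results = assign_bands(
        bands, curve, groups if groups is not None else mw_groups(),
        tolerance=tolerance, margin=margin,
    )
    lane_groups = groups_per_lane(results)
    fibers = [
        FiberRecord(
            fiber_id=lane,
            muscle=muscle,
            groups=found,
            myosin=(myosin_of_lane or {}).get(lane, frozenset()),
        )
        for lane, found in lane_groups.items()
    ]
    return fibers, results
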