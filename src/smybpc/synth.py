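"""Synthetic single-fiber western datasets with known ground truth.

Two generators:

* :func:`generate_fixture` deterministically reconstructs the study datasets
  from the printed pattern frequencies: 48 soleus fibers over 13 group
  patterns and 41 FDB fibers over 5 single-group patterns.  Printed "~"
  percentages are rounded targets, so fibers-per-pattern come from an exact
  integer apportionment (:func:`solve_integer_counts`) that minimizes the
  worst percent deviation.  Bands are placed noiselessly at the group-center
  masses by inverting the default standard curve, so a noiseless round trip
  through the gel pipeline recovers the pattern table exactly.

* :func:`simulate_gel` draws fibers from the count-normalized pattern
  frequencies and jitters each band's migration with Gaussian Rf noise
  (default sd 0.002), emitting the ground truth alongside for recovery
  testing.  All randomness flows from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fibers import TABLE_FDB_MYOSIN, FiberRecord, PatternKey, write_fiber_table
from .gel import LadderLane, default_ladder, fit_standard_curve, rf_for_mass, write_band_table, write_ladder
from .mass import MwGroup, mw_groups

__all__ = [
    "FrequencyPreset",
    "SimulationConfig",
    "TruthRecord",
    "Fixture",
    "PresetError",
    "soleus_preset",
    "fdb_preset",
    "solve_integer_counts",
    "generate_fixture",
    "simulate_gel",
    "write_fixture",
]


class PresetError(ValueError):
    """Raised when no integer count vector can realize a preset."""


@dataclass(frozen=True)
class FrequencyPreset:
    """Printed pattern frequencies and myosin complements for one muscle."""

    muscle: str
    n_fibers: int
    pattern_percents: dict[PatternKey, float]
    myosin_map: dict[PatternKey, frozenset[str]]


def soleus_preset() -> FrequencyPreset:
    """The 48-fiber soleus dataset: 13 patterns.

    Percents follow the printed listing (singles 4/10/4/2; group-5 pairs
    2/2/6; group-6 pairs 40/12/6/4; triples 2/4; the {5,6} pair appears once
    at 6).  Myosin complements follow the lane description, under which the
    I+IIa share is the printed per-pattern sum (the tabulated reference in
    :mod:`smybpc.fibers` disagrees for the single-group {2} and {3} rows, a
    discrepancy the association check surfaces).
    """
    percents: dict[PatternKey, float] = {
        (1,): 4, (2,): 10, (3,): 4, (4,): 2,
        (1, 5): 2, (4, 5): 2, (5, 6): 6,
        (1, 6): 40, (2, 6): 12, (3, 6): 6, (4, 6): 4,
        (1, 2, 6): 2, (1, 3, 6): 4,
    }
    myosin: dict[PatternKey, frozenset[str]] = {
        key: frozenset({"I"}) for key in percents
    }
    for key in ((2,), (3,), (1, 6), (2, 6), (3, 6), (4, 6), (5, 6)):
        myosin[key] = frozenset({"I", "IIa"})
    return FrequencyPreset(
        muscle="soleus", n_fibers=48, pattern_percents=percents, myosin_map=myosin
    )


def fdb_preset() -> FrequencyPreset:
    """The 41-fiber FDB dataset: 5 single-group patterns at 39/32/17/7/5%."""
    percents: dict[PatternKey, float] = {
        (1,): 39, (2,): 32, (3,): 17, (4,): 7, (5,): 5,
    }
    return FrequencyPreset(
        muscle="FDB",
        n_fibers=41,
        pattern_percents=percents,
        myosin_map=dict(TABLE_FDB_MYOSIN),
    )


def solve_integer_counts(preset: FrequencyPreset) -> dict[PatternKey, int]:
    """Exact integer apportionment of printed percentages.

    Returns counts summing to ``n_fibers`` minimizing the maximum absolute
    deviation between 100*count/n and the printed percent (L-infinity), with
    ties broken by minimum total (L1) deviation and then by adjusting the
    lexicographically earliest pattern.  Solved by parametric search over
    the finite set of achievable deviations with a feasibility test on the
    induced count boxes; the L1 step is an optimal greedy marginal
    allocation over the separable convex costs.
    """
    n = preset.n_fibers
    keys = sorted(preset.pattern_percents, key=lambda k: (len(k), k))
    if not keys:
        if n == 0:
            return {}
        raise PresetError(f"no patterns but n_fibers={n}")
    percents = np.array([preset.pattern_percents[k] for k in keys], dtype=float)
    targets = percents * n / 100.0

    def boxes(t: float) -> tuple[np.ndarray, np.ndarray]:
        lo = np.ceil((percents - t) * n / 100.0 - 1e-9).astype(int)
        hi = np.floor((percents + t) * n / 100.0 + 1e-9).astype(int)
        return np.maximum(lo, 0), np.maximum(hi, 0)

    def feasible(t: float) -> bool:
        lo, hi = boxes(t)
        return int(lo.sum()) <= n <= int(hi.sum())

    # Candidate L-inf values: deviations of every achievable count.
    candidates = sorted(
        {
            abs(100.0 * c / n - p)
            for p in percents
            for c in range(0, n + 1)
        }
    )
    t_star = next(t for t in candidates if feasible(t))
    lo, hi = boxes(t_star)

    # L1-optimal counts inside the boxes: start at the clamped rounded
    # targets, then move unit-by-unit toward the required sum, always taking
    # the cheapest marginal move (ties -> earliest pattern).
    counts = np.clip(np.rint(targets).astype(int), lo, hi)
    while counts.sum() != n:
        direction = 1 if counts.sum() < n else -1
        best_i, best_cost = None, None
        for i in range(len(keys)):
            c_new = counts[i] + direction
            if c_new < lo[i] or c_new > hi[i]:
                continue
            cost = abs(c_new - targets[i]) - abs(counts[i] - targets[i])
            if best_cost is None or cost < best_cost - 1e-12:
                best_i, best_cost = i, cost
        if best_i is None:
            raise PresetError(
                f"infeasible preset: cannot reach n={n} within deviation {t_star}"
            )
        counts[best_i] += direction
    return {k: int(c) for k, c in zip(keys, counts)}


@dataclass(frozen=True)
class TruthRecord:
    """Per-fiber ground truth emitted with every synthetic dataset."""

    groups: dict[str, tuple[int, ...]]
    masses: dict[str, tuple[float, ...]]
    myosin: dict[str, tuple[str, ...]]


@dataclass(frozen=True)
class Fixture:
    """A synthetic dataset: fibers, band table, ladder and truth."""

    fibers: list[FiberRecord]
    bands: pd.DataFrame  # lane_id, band_index, rf
    ladder: LadderLane
    truth: TruthRecord


def _group_centers(groups: Optional[list[MwGroup]] = None) -> dict[int, float]:
    if groups is None:
        groups = mw_groups()
    return {g.index: g.center for g in groups}


def _build_fixture(
    pattern_of_fiber: list[PatternKey],
    preset: FrequencyPreset,
    ladder: LadderLane,
    group_masses: dict[int, float],
    rf_noise_sd: float,
    rng: Optional[np.random.Generator],
) -> Fixture:
    curve = fit_standard_curve(ladder)
    fibers: list[FiberRecord] = []
    band_rows: list[dict] = []
    truth_groups: dict[str, tuple[int, ...]] = {}
    truth_masses: dict[str, tuple[float, ...]] = {}
    truth_myosin: dict[str, tuple[str, ...]] = {}
    for i, key in enumerate(pattern_of_fiber, start=1):
        fiber_id = f"{preset.muscle}_{i:03d}"
        myosin = preset.myosin_map.get(key, frozenset())
        fibers.append(
            FiberRecord(
                fiber_id=fiber_id,
                muscle=preset.muscle,
                groups=frozenset(key),
                myosin=myosin,
            )
        )
        masses = sorted((group_masses[g] for g in key), reverse=True)
        for j, mass in enumerate(masses, start=1):
            rf = rf_for_mass(curve, mass)
            if rng is not None and rf_noise_sd > 0:
                rf += rng.normal(0.0, rf_noise_sd)
            band_rows.append(
                {"lane_id": fiber_id, "band_index": j, "rf": float(np.clip(rf, 0.0, 1.0))}
            )
        truth_groups[fiber_id] = key
        truth_masses[fiber_id] = tuple(masses)
        truth_myosin[fiber_id] = tuple(sorted(myosin))
    bands = pd.DataFrame(band_rows, columns=["lane_id", "band_index", "rf"])
    return Fixture(
        fibers=fibers,
        bands=bands,
        ladder=ladder,
        truth=TruthRecord(groups=truth_groups, masses=truth_masses, myosin=truth_myosin),
    )


def generate_fixture(
    preset: FrequencyPreset,
    ladder: Optional[LadderLane] = None,
    group_masses: Optional[dict[int, float]] = None,
) -> Fixture:
    """Deterministic reconstruction of a printed dataset (no randomness)."""
    counts = solve_integer_counts(preset)
    pattern_of_fiber = [
        key for key in sorted(counts, key=lambda k: (len(k), k))
        for _ in range(counts[key])
    ]
    return _build_fixture(
        pattern_of_fiber,
        preset,
        ladder or default_ladder(),
        group_masses or _group_centers(),
        rf_noise_sd=0.0,
        rng=None,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Stochastic gel simulation settings (a fixed seed fixes the output)."""

    seed: int
    n_fibers: int
    rf_noise_sd: float = 0.002
    ladder: Optional[LadderLane] = None
    group_masses: Optional[dict[int, float]] = None

    def __post_init__(self) -> None:
        if self.rf_noise_sd < 0:
            raise ValueError("rf_noise_sd must be >= 0")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")


def simulate_gel(config: SimulationConfig, preset: FrequencyPreset) -> Fixture:
    """Sample fibers from the preset's count-normalized frequencies and add
    Gaussian Rf migration noise to every band."""
    counts = solve_integer_counts(preset)
    keys = sorted(counts, key=lambda k: (len(k), k))
    probs = np.array([counts[k] for k in keys], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(config.seed)
    drawn = rng.choice(len(keys), size=config.n_fibers, p=probs)
    pattern_of_fiber = [keys[i] for i in drawn]
    return _build_fixture(
        pattern_of_fiber,
        preset,
        config.ladder or default_ladder(),
        config.group_masses or _group_centers(),
        rf_noise_sd=config.rf_noise_sd,
        rng=rng,
    )


def write_fixture(fixture: Fixture, outdir: Path | str) -> dict[str, Path]:
    """Write fibers.tsv, bands.tsv, ladder.tsv and truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fibers": outdir / "fibers.tsv",
        "bands": outdir / "bands.tsv",
        "ladder": outdir / "ladder.tsv",
        "truth": outdir / "truth.json",
    }
    write_fiber_table(fixture.fibers, paths["fibers"])
    write_band_table(fixture.bands, paths["bands"])
    write_ladder(fixture.ladder, paths["ladder"])
    truth = {
        "groups": {k: list(v) for k, v in fixture.truth.groups.items()},
        "masses": {k: list(v) for k, v in fixture.truth.masses.items()},
        "myosin": {k: list(v) for k, v in fixture.truth.myosin.items()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return paths
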