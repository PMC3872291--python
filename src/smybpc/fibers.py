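"""Single-fiber expression profiling of sMyBP-C MW groups.

Each analyzed fiber carries a set of MW groups (from its immunoreactive band
profile) and, optionally, the myosin heavy-chain isoforms (I, IIa, IIx) seen
in the same lane.  This module tallies the distinct group-combination
patterns across fibers of one muscle, computes how many fibers express one,
two or three groups, computes the per-group occurrence rates, and
cross-tabulates patterns against myosin complements.

Reported percentages are integers rounded half-away-from-zero; where a
distribution must total 100 (the multiplicity distribution) the integers are
reconciled by the largest-remainder method, mirroring the approximate
integer percentages of the source data.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "FiberRecord",
    "PatternTally",
    "MyosinAssociation",
    "AssociationRowCheck",
    "TABLE_SOLEUS_MYOSIN",
    "TABLE_FDB_MYOSIN",
    "tally_patterns",
    "multiplicity_distribution",
    "group_occurrence",
    "myosin_association",
    "check_association",
    "largest_remainder_percents",
    "read_fiber_table",
    "write_fiber_table",
]

PatternKey = tuple[int, ...]


@dataclass(frozen=True)
class FiberRecord:
    """One analyzed single fiber."""

    fiber_id: str
    muscle: str  # soleus | FDB
    groups: frozenset[int]
    myosin: frozenset[str] = frozenset()

    @property
    def pattern_key(self) -> PatternKey:
        return tuple(sorted(self.groups))


@dataclass(frozen=True)
class PatternTally:
    pattern_key: PatternKey
    count: int
    percent: int  # of the muscle's analyzed fibers, rounded to integer


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _analyzed(fibers: Iterable[FiberRecord], muscle: Optional[str]) -> list[FiberRecord]:
    # Fibers with no detected bands carry no signal and leave the denominator.
    return [
        f for f in fibers
        if f.groups and (muscle is None or f.muscle == muscle)
    ]


def tally_patterns(
    fibers: Iterable[FiberRecord], muscle: Optional[str] = None
) -> list[PatternTally]:
    """One tally per distinct group-combination pattern, sorted by
    (pattern size, pattern)."""
    records = _analyzed(fibers, muscle)
    total = len(records)
    counts = Counter(f.pattern_key for f in records)
    return [
        PatternTally(
            pattern_key=key,
            count=count,
            percent=_round_half_away(100.0 * count / total),
        )
        for key, count in sorted(counts.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]


def largest_remainder_percents(shares: Sequence[float], total: int = 100) -> list[int]:
    """Integer percentages summing to ``total`` via the largest-remainder
    method (ties to the earlier entry)."""
    floors = [math.floor(s) for s in shares]
    leftover = total - sum(floors)
    remainders = sorted(
        range(len(shares)), key=lambda i: (-(shares[i] - floors[i]), i)
    )
    out = list(floors)
    for i in remainders[:leftover]:
        out[i] += 1
    return out


def multiplicity_distribution(
    fibers: Iterable[FiberRecord], muscle: Optional[str] = None
) -> dict[int, int]:
    """Percent of fibers expressing 1, 2 or 3 MW groups (sums to 100)."""
    records = _analyzed(fibers, muscle)
    if not records:
        return {1: 0, 2: 0, 3: 0}
    total = len(records)
    counts = Counter(min(len(f.groups), 3) for f in records)
    shares = [100.0 * counts.get(k, 0) / total for k in (1, 2, 3)]
    ints = largest_remainder_percents(shares)
    return {k: v for k, v in zip((1, 2, 3), ints)}


def group_occurrence(
    fibers: Iterable[FiberRecord], muscle: Optional[str] = None
) -> dict[int, float]:
    """Percent of fibers containing each group 1-6 (may sum beyond 100 under
    co-expression).  Exact percentages; round for display."""
    records = _analyzed(fibers, muscle)
    total = len(records)
    return {
        g: (100.0 * sum(g in f.groups for f in records) / total) if total else 0.0
        for g in range(1, 7)
    }


# --- myosin isoform association --------------------------------------------

#: Printed soleus pattern -> myosin complement reference table.
TABLE_SOLEUS_MYOSIN: dict[PatternKey, frozenset[str]] = {
    (1,): frozenset({"I"}),
    (2,): frozenset({"I"}),
    (3,): frozenset({"I"}),
    (4,): frozenset({"I"}),
    (1, 5): frozenset({"I"}),
    (4, 5): frozenset({"I"}),
    (1, 6): frozenset({"I", "IIa"}),
    (2, 6): frozenset({"I", "IIa"}),
    (3, 6): frozenset({"I", "IIa"}),
    (4, 6): frozenset({"I", "IIa"}),
    (5, 6): frozenset({"I", "IIa"}),
    (1, 2, 6): frozenset({"I"}),
    (1, 3, 6): frozenset({"I"}),
}

#: Printed FDB pattern -> myosin complement reference table.
TABLE_FDB_MYOSIN: dict[PatternKey, frozenset[str]] = {
    (1,): frozenset({"I", "IIx"}),
    (2,): frozenset({"I", "IIa"}),
    (3,): frozenset({"I", "IIx"}),
    (4,): frozenset({"I", "IIa", "IIx"}),
    (5,): frozenset({"IIa"}),
}


@dataclass(frozen=True)
class MyosinAssociation:
    """Observed myosin complements per expression pattern."""

    mapping: dict[PatternKey, dict[frozenset[str], int]]
    excluded_unlabeled: int  # fibers without myosin labels, dropped


@dataclass(frozen=True)
class AssociationRowCheck:
    pattern_key: PatternKey
    expected: Optional[frozenset[str]]  # None when the pattern has no row
    observed: tuple[frozenset[str], ...]
    match: bool


def myosin_association(
    fibers: Iterable[FiberRecord], muscle: Optional[str] = None
) -> MyosinAssociation:
    """Cross-tabulate expression patterns against myosin complements.

    Fibers lacking myosin labels (unstained lanes) are excluded and counted.
    """
    records = _analyzed(fibers, muscle)
    labeled = [f for f in records if f.myosin]
    mapping: dict[PatternKey, dict[frozenset[str], int]] = {}
    for f in labeled:
        per_pattern = mapping.setdefault(f.pattern_key, {})
        per_pattern[f.myosin] = per_pattern.get(f.myosin, 0) + 1
    return MyosinAssociation(
        mapping=mapping, excluded_unlabeled=len(records) - len(labeled)
    )


def check_association(
    assoc: MyosinAssociation,
    reference: dict[PatternKey, frozenset[str]],
) -> list[AssociationRowCheck]:
    """Compare observed pattern/myosin pairs against a printed reference map.

    A row matches when every observed complement for the pattern equals the
    reference complement; patterns absent from the reference never match.
    """
    checks = []
    for key in sorted(assoc.mapping, key=lambda k: (len(k), k)):
        observed = tuple(sorted(assoc.mapping[key], key=sorted))
        expected = reference.get(key)
        match = expected is not None and all(o == expected for o in observed)
        checks.append(
            AssociationRowCheck(
                pattern_key=key, expected=expected, observed=observed, match=match
            )
        )
    return checks


# --- plain-text interchange -------------------------------------------------

def read_fiber_table(path: Path | str) -> list[FiberRecord]:
    """Read a fiber TSV: fiber_id, muscle, groups (comma-joined), myosin
    (comma-joined, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples():
        groups = frozenset(
            int(g) for g in str(row.groups).split(",") if g.strip()
        ) if not pd.isna(row.groups) else frozenset()
        myosin = (
            frozenset(m.strip() for m in str(row.myosin).split(",") if m.strip())
            if not pd.isna(row.myosin)
            else frozenset()
        )
        records.append(
            FiberRecord(
                fiber_id=str(row.fiber_id),
                muscle=str(row.muscle),
                groups=groups,
                myosin=myosin,
            )
        )
    return records


def write_fiber_table(fibers: Iterable[FiberRecord], path: Path | str) -> None:
    rows = [
        {
            "fiber_id": f.fiber_id,
            "muscle": f.muscle,
            "groups": ",".join(str(g) for g in sorted(f.groups)),
            "myosin": ",".join(sorted(f.myosin)),
        }
        for f in fibers
    ]
    pd.DataFrame(rows, columns=["fiber_id", "muscle", "groups", "myosin"]).to_csv(
        path, sep="\t", index=False
    )
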