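"""Partition of the non-genetic variable space into cells.

The variable space is a grid over up to three axes: backward temporal
windows of length ``T`` days counted from the event date, geographic
areas, and political groups.  Each cell j of the resulting partition
carries two integers: ``N_j``, the number of still-unidentified
candidates whose variable values fall in the cell, and ``I_j``, the
number of already-solved cases falling there, with sum(N_j) = N and
sum(I_j) = n_s exactly.

Temporal bins are half-open intervals, day-granular, going backward:
the day immediately before the event date lies in bin 1, which covers
offsets 1..T days before the event; bin b covers offsets
(b-1)*T + 1 .. b*T.  Half-open binning prevents double counting at the
boundaries.

Cell numbering is deterministic and row-major with the geographic axis
varying fastest, the political axis next and the temporal axis slowest,
so a 3-areas x 3-windows grid is listed left to right, top to bottom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import PartitionError
from .io import UNKNOWN, EventSpec, Roster, VictimRecord

#: Canonical axis order: slowest-varying first.
VARIABLES = ("temporal", "political", "geographic")


@dataclass(frozen=True)
class PartitionSpec:
    """Which variables define the cells, and their category structure.

    Parameters
    ----------
    variables
        Non-empty subset of ``{"temporal", "geographic", "political"}``.
    window_days
        Temporal window length T in days; required iff ``temporal`` is
        an active variable.
    geo_categories, political_categories
        Declared category labels, in display order.  When declared, the
        grid keeps empty cells for those labels (stable shape across
        cross-validation realizations); when left empty the observed
        labels are used in sorted order and empty cells are dropped.
    n_temporal_bins
        Declared number of temporal bins.  When ``None``, enough bins
        are built to cover the earliest record in the roster.
    """

    variables: tuple[str, ...]
    window_days: Optional[int] = None
    geo_categories: tuple[str, ...] = ()
    political_categories: tuple[str, ...] = ()
    n_temporal_bins: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "geo_categories", tuple(self.geo_categories))
        object.__setattr__(
            self, "political_categories", tuple(self.political_categories)
        )
        if not self.variables:
            raise ValueError("variables must be a non-empty subset")
        unknown = set(self.variables) - set(VARIABLES)
        if unknown:
            raise ValueError(f"unknown variables: {sorted(unknown)}")
        if "temporal" in self.variables:
            if self.window_days is None or self.window_days < 1:
                raise ValueError(
                    "window_days >= 1 is required for a temporal partition"
                )

    @property
    def active(self) -> tuple[str, ...]:
        """Active variables in canonical (slowest-first) axis order."""
        return tuple(v for v in VARIABLES if v in self.variables)


def temporal_bin(
    kidnap_date, event_date, window_days: int
) -> int:
    """1-based backward temporal bin of a kidnap date.

    Bin b covers kidnap dates (b-1)*T + 1 .. b*T whole days before the
    event date (half-open calendar intervals
    ``[T_e - b*T, T_e - (b-1)*T)``).
    """
    offset = (event_date - kidnap_date).days
    if offset < 1:
        raise PartitionError(
            f"kidnap date {kidnap_date} is not before the event date "
            f"{event_date}; the record is outside the candidate set"
        )
    return (offset - 1) // window_days + 1


def assign_cell(
    record: VictimRecord, spec: PartitionSpec, event: EventSpec
) -> tuple:
    """Map one record to its cell label.

    The label is a tuple with one entry per active variable in canonical
    axis order: the temporal bin index (int), the political group and/or
    the geographic area (str).  Pure function of its inputs.
    """
    parts = []
    for var in spec.active:
        if var == "temporal":
            parts.append(
                temporal_bin(record.kidnap_date, event.event_date, spec.window_days)
            )
        elif var == "political":
            parts.append(record.political_group or UNKNOWN)
        else:
            parts.append(record.geo_area or UNKNOWN)
    return tuple(parts)


@dataclass(frozen=True)
class CellTable:
    """The m cells of a partition with per-cell candidate and solved counts.

    Attributes
    ----------
    spec, event
        The partition and event the table was built under.
    labels
        Cell labels, one per cell, in deterministic grid order; cell_id
        j is the 1-based position in this list.
    N_j, I_j
        Integer arrays of candidate and solved counts per cell.
    member_ids
        Candidate victim ids per cell (the sets N_j counts).
    solved_ids
        Identified-case ids per cell (what I_j counts).
    """

    spec: PartitionSpec
    event: EventSpec
    labels: tuple[tuple, ...]
    N_j: np.ndarray
    I_j: np.ndarray
    member_ids: tuple[tuple[str, ...], ...]
    solved_ids: tuple[tuple[str, ...], ...]

    @property
    def m(self) -> int:
        return len(self.labels)

    @property
    def n_candidates(self) -> int:
        return int(self.N_j.sum())

    @property
    def n_solved(self) -> int:
        return int(self.I_j.sum())

    def label_strings(self) -> list[dict]:
        """One dict per cell with cell_id and per-variable label columns."""
        rows = []
        for j, label in enumerate(self.labels, start=1):
            row = {"cell_id": j}
            for var, value in zip(self.spec.active, label):
                if var == "temporal":
                    row["temporal_bin"] = f"temp{value}"
                elif var == "political":
                    row["political_group"] = value
                else:
                    row["geo_area"] = value
            rows.append(row)
        return rows

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.label_strings())
        frame["N_j"] = self.N_j
        frame["I_j"] = self.I_j
        return frame

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        for col in ("temporal_bin", "geo_area", "political_group"):
            if col not in frame.columns:
                frame[col] = ""
        cols = ["cell_id", "temporal_bin", "geo_area", "political_group", "N_j", "I_j"]
        frame[cols].to_csv(path, index=False)


def _axis_domains(roster: Roster, spec: PartitionSpec) -> dict[str, list]:
    """Per-variable value domain (declared order, or observed sorted)."""
    records = roster.candidates + roster.identified
    domains: dict[str, list] = {}
    for var in spec.active:
        if var == "temporal":
            if spec.n_temporal_bins is not None:
                domains[var] = list(range(1, spec.n_temporal_bins + 1))
            else:
                latest = max(
                    (roster.event.event_date - r.kidnap_date).days
                    for r in records
                ) if records else 1
                n_bins = (latest - 1) // spec.window_days + 1
                domains[var] = list(range(1, n_bins + 1))
        elif var == "political":
            if spec.political_categories:
                domains[var] = list(spec.political_categories)
            else:
                domains[var] = sorted(
                    {r.political_group or UNKNOWN for r in records}
                )
        else:
            if spec.geo_categories:
                domains[var] = list(spec.geo_categories)
            else:
                domains[var] = sorted({r.geo_area or UNKNOWN for r in records})
    return domains


def _declared(spec: PartitionSpec) -> bool:
    """True when every active axis has an explicitly declared domain."""
    for var in spec.active:
        if var == "temporal" and spec.n_temporal_bins is None:
            return False
        if var == "political" and not spec.political_categories:
            return False
        if var == "geographic" and not spec.geo_categories:
            return False
    return True


def build_cell_table(roster: Roster, spec: PartitionSpec) -> CellTable:
    """Tabulate N_j and I_j over the cell grid.

    The grid is the cross-product of the active-variable domains.  Cells
    with ``N_j = I_j = 0`` are retained only when every axis domain was
    declared in the spec, so a declared grid keeps a stable shape across
    cross-validation realizations.  Invariants: sum(N_j) = N and
    sum(I_j) = n_s, and every candidate and identified record maps to
    exactly one cell.
    """
    domains = _axis_domains(roster, spec)
    grid = list(product(*(domains[var] for var in spec.active)))
    index = {label: j for j, label in enumerate(grid)}

    n_j = np.zeros(len(grid), dtype=int)
    i_j = np.zeros(len(grid), dtype=int)
    members: list[list[str]] = [[] for _ in grid]
    solved: list[list[str]] = [[] for _ in grid]

    for rec in roster.candidates:
        label = assign_cell(rec, spec, roster.event)
        if label not in index:
            raise PartitionError(
                f"{rec.victim_id}: cell {label} is outside the declared grid"
            )
        j = index[label]
        n_j[j] += 1
        members[j].append(rec.victim_id)
    for rec in roster.identified:
        label = assign_cell(rec, spec, roster.event)
        if label not in index:
            raise PartitionError(
                f"{rec.victim_id}: cell {label} is outside the declared grid"
            )
        j = index[label]
        i_j[j] += 1
        solved[j].append(rec.victim_id)

    if not _declared(spec):
        keep = [j for j in range(len(grid)) if n_j[j] > 0 or i_j[j] > 0]
    else:
        keep = list(range(len(grid)))

    return CellTable(
        spec=spec,
        event=roster.event,
        labels=tuple(grid[j] for j in keep),
        N_j=n_j[keep],
        I_j=i_j[keep],
        member_ids=tuple(tuple(sorted(members[j])) for j in keep),
        solved_ids=tuple(tuple(sorted(solved[j])) for j in keep),
    )
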