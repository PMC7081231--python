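"""Built-in worked example: a 3-areas x 3-windows grid of 217 candidates.

This is the small cohort used throughout the documentation and tests: a
partition into m = 9 GeoTemporal cells built with a 15-day temporal
window and three geographic areas, holding N = 217 candidates and
n_s = 22 already-identified cases with occupancy

    =====  =======  =======  ======
    cell   geo1     geo2     geo3
    =====  =======  =======  ======
    temp1  35, 0    12, 2     3, 0
    temp2  54, 9    23, 3     1, 0
    temp3  56, 4    27, 4     6, 0
    =====  =======  =======  ======

(each entry N_j, I_j; cells numbered left to right, top to bottom).
The roster is generated programmatically; member kidnap dates are
spread across the days of their temporal window.
"""

from __future__ import annotations

import datetime as _dt

from .io import EventSpec, Roster, VictimRecord
from .partition import PartitionSpec

#: Candidate counts per cell, row-major (geo fastest, temporal slowest).
NINE_CELL_N = (35, 12, 3, 54, 23, 1, 56, 27, 6)
#: Solved-case counts per cell, same order.
NINE_CELL_I = (0, 2, 0, 9, 3, 0, 4, 4, 0)

_GEO = ("geo1", "geo2", "geo3")
_WINDOW = 15
_EVENT_DATE = _dt.date(1976, 8, 20)


def nine_cell_spec() -> PartitionSpec:
    """The declared 3x3 GeoTemporal partition of the worked example."""
    return PartitionSpec(
        variables=("temporal", "geographic"),
        window_days=_WINDOW,
        geo_categories=_GEO,
        n_temporal_bins=3,
    )


def nine_cell_event() -> EventSpec:
    return EventSpec(
        event_id="worked-example",
        event_date=_EVENT_DATE,
        n_e=250,
        description="illustrative 9-cell GeoTemporal cohort",
    )


def nine_cell_roster() -> Roster:
    """Roster realizing the worked-example occupancy exactly.

    Candidates of cell (temporal bin b, area g) get kidnap dates cycling
    through the days of window b, so the occupancy is invariant to the
    window convention details inside a bin.
    """
    event = nine_cell_event()
    records = []
    counter = 0
    for j, (n_j, i_j) in enumerate(zip(NINE_CELL_N, NINE_CELL_I)):
        bin_index = j // len(_GEO)  # 0-based temporal bin
        geo = _GEO[j % len(_GEO)]
        for kind, count in (("candidate", n_j), ("identified", i_j)):
            for k in range(count):
                counter += 1
                day_offset = bin_index * _WINDOW + (k % _WINDOW) + 1
                records.append(
                    VictimRecord(
                        victim_id=f"v{counter:03d}",
                        kidnap_date=event.event_date
                        - _dt.timedelta(days=day_offset),
                        geo_area=geo,
                        status=kind,
                    )
                )
    return Roster.from_records(event, records)
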