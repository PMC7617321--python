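"""Oriented topological events: cell divisions and T1 neighbor exchanges.

Divisions are read off the tracking table (a lineage replaced by two
children in one frame); the division axis is the new daughter-daughter
junction angle plus 90 degrees, modulo 180. T1 transitions are neighbor
exchanges in a four-cell quartet: a junction shorter than a bond cutoff
is treated as a contracted four-way vertex, and an event is emitted at
the first frame where a previously adjacent pair has lost contact while
the opposite diagonal pair has gained a junction at least as long as the
cutoff. Candidate T1s involving a cell that divides within one frame of
the exchange are excluded (division neighborhoods are a known source of
spurious exchanges) and logged rather than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .angles import classify_orientation
from .polarity import AngularDistribution, weighted_angle_histogram
from .tissue import JunctionGraph, TrackingTable

logger = logging.getLogger(__name__)

__all__ = [
    "DivisionEvent",
    "T1Event",
    "OrientationSummary",
    "division_angle",
    "detect_divisions",
    "detect_t1",
    "summarize_orientations",
]


@dataclass
class DivisionEvent:
    frame: int
    mother_lineage: int
    daughter_cells: tuple[int, int]
    new_junction_angle: float | None  # degrees [0, 180); None if daughters not adjacent
    division_angle: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class T1Event:
    frame: int
    losing_pair: tuple[int, int]  # lineage ids that lost contact
    gaining_pair: tuple[int, int]  # lineage ids that gained the new junction
    new_junction_angle: float


@dataclass
class OrientationSummary:
    n_AP: int
    n_PD: int
    ap_pd_ratio: float | None
    histogram: AngularDistribution
    n_undefined: int = 0


def division_angle(new_junction_angle: float) -> float:
    """Division axis: 90 degrees is added to the new-junction angle."""
    a = float(new_junction_angle)
    if not (0.0 <= a < 180.0):
        raise ValueError(f"angle {a!r} outside [0, 180)")
    return (a + 90.0) % 180.0


def detect_divisions(
    tracking: TrackingTable,
    graphs: dict[int, JunctionGraph],
) -> list[DivisionEvent]:
    """One event per lineage gaining two children in a single frame.

    The new-junction angle is the orientation of the daughter-daughter
    junction in the first shared frame; daughters without a shared
    junction are flagged ``no_shared_junction`` with an undefined angle.
    """
    events: list[DivisionEvent] = []
    for _, row in tracking.divisions().iterrows():
        if len(row["children"]) != 2:
            continue  # a single re-parented lineage is not a division
        frame = int(row["frame"])
        cell_of = tracking.cell_of(frame)
        d1, d2 = (cell_of.get(ch) for ch in row["children"])
        flags: list[str] = []
        angle = div = None
        if d1 is None or d2 is None:
            flags.append("daughter_missing_in_frame")
        else:
            g = graphs.get(frame)
            j = g.junction_between(d1, d2) if g is not None else None
            if j is None:
                flags.append("no_shared_junction")
            else:
                angle = j.orientation
                div = division_angle(angle)
        events.append(
            DivisionEvent(
                frame=frame,
                mother_lineage=int(row["parent_lineage_id"]),
                daughter_cells=(d1 if d1 is not None else -1, d2 if d2 is not None else -1),
                new_junction_angle=angle,
                division_angle=div,
                flags=flags,
            )
        )
    return sorted(events, key=lambda e: (e.frame, e.mother_lineage))


def _lineage_adjacency(graph: JunctionGraph, lineage: dict[int, int], cutoff_px: float):
    """(effective adjacency >= cutoff, any adjacency, neighbor map) in lineage ids."""
    eff: set[frozenset] = set()
    neigh: dict[int, set[int]] = {}
    for j in graph.junctions:
        la, lb = lineage.get(j.cell_a), lineage.get(j.cell_b)
        if la is None or lb is None or la == lb:
            continue
        pair = frozenset((la, lb))
        neigh.setdefault(la, set()).add(lb)
        neigh.setdefault(lb, set()).add(la)
        if j.length_px >= cutoff_px:
            eff.add(pair)
    return eff, neigh


def detect_t1(
    tracking: TrackingTable,
    graphs: dict[int, JunctionGraph],
    bond_cutoff: float = 4.0,
) -> list[T1Event]:
    """Detect T1 transitions between consecutive frames.

    ``bond_cutoff`` is the four-way-vertex threshold in pixels of
    junction chord length: shorter junctions count as contracted
    vertices, i.e. as no contact.
    """
    frames = sorted(f for f in graphs if f in set(tracking.frames()))
    div_by_frame: dict[int, set[int]] = {}
    for _, row in tracking.divisions().iterrows():
        players = {int(row["parent_lineage_id"])} | {int(c) for c in row["children"]}
        div_by_frame.setdefault(int(row["frame"]), set()).update(players)

    adj = {
        f: _lineage_adjacency(graphs[f], tracking.lineage_of(f), bond_cutoff) for f in frames
    }
    events: list[T1Event] = []
    for prev, cur in zip(frames[:-1], frames[1:]):
        eff_prev, neigh_prev = adj[prev]
        eff_cur, _ = adj[cur]
        lineage_cur = tracking.lineage_of(cur)
        cell_cur = {v: k for k, v in lineage_cur.items()}
        dividing = div_by_frame.get(prev, set()) | div_by_frame.get(cur, set())
        dividing |= div_by_frame.get(cur + 1, set())
        for pair in eff_prev - eff_cur:
            a, b = sorted(pair)
            common = (neigh_prev.get(a, set()) & neigh_prev.get(b, set())) - {a, b}
            for c in sorted(common):
                for d in sorted(common):
                    if d <= c:
                        continue
                    gained = frozenset((c, d))
                    if gained in eff_prev or gained not in eff_cur:
                        continue
                    quartet = {a, b, c, d}
                    if quartet & dividing:
                        logger.info(
                            "T1 candidate at frame %d quartet %s excluded: "
                            "division within one frame",
                            cur,
                            sorted(quartet),
                        )
                        continue
                    cc, cd = cell_cur.get(c), cell_cur.get(d)
                    if cc is None or cd is None:
                        continue
                    j = graphs[cur].junction_between(cc, cd)
                    if j is None:
                        continue
                    events.append(
                        T1Event(
                            frame=cur,
                            losing_pair=(a, b),
                            gaining_pair=(c, d),
                            new_junction_angle=j.orientation,
                        )
                    )
    return sorted(events, key=lambda e: (e.frame, e.losing_pair))


def summarize_orientations(angles: list[float | None]) -> OrientationSummary:
    """AP/PD counts, AP:PD ratio and 10-degree count histogram.

    Angles in [45, 135) are AP. ``None`` entries (undefined angles) are
    counted separately and excluded from the ratio and histogram. With no
    PD events the ratio is undefined (None), never infinity.
    """
    defined = [a for a in angles if a is not None]
    n_undef = len(angles) - len(defined)
    n_ap = sum(1 for a in defined if classify_orientation(a) == "AP")
    n_pd = len(defined) - n_ap
    ratio = (n_ap / n_pd) if n_pd > 0 else None
    hist = weighted_angle_histogram([(a, 1.0) for a in defined], weighting_mode="count")
    return OrientationSummary(
        n_AP=n_ap, n_PD=n_pd, ap_pd_ratio=ratio, histogram=hist, n_undefined=n_undef
    )
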