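"""Directed vascular-graph model of a parafoveal capillary network.

Segments (vessels) are nodes of a directed graph; three-way junctions define
the edges. A BIFURCATION sends flow from one major (parent) vessel into two
minor daughters; a CONFLUENCE drains two minor vessels into one major
collector. Crossings — vessels that overlap without connecting — are stored
but never create adjacency.

Derived quantities follow the field's conventions:

* feeders are vessels wider than 8 um lumen diameter with no upstream parent
  in the field;
* branch order is 1 for the feeding arteriole and increases by one at every
  bifurcation along the upstream path;
* feeder distance is the path length from the upstream end of the feeding
  arteriole to the *center* of the queried vessel (full lengths of all
  upstream segments plus half the segment's own length).

When several upstream paths exist (anastomoses, multiple feeders) the path
minimizing summed length is used, ties broken by the lexicographically
smallest id sequence.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .errors import AnalysisError, InputError, StructureError

#: Lumen diameter (um) above which a parentless vessel counts as a feeding arteriole.
FEEDER_DIAMETER_UM = 8.0


class JunctionKind(str, Enum):
    BIFURCATION = "BIFURCATION"
    CONFLUENCE = "CONFLUENCE"


class CapillaryType(str, Enum):
    """Capillary taxonomy by the junction kinds at the two ends of a vessel.

    AC (arteriolar): fed by a bifurcation, feeds a bifurcation.
    VC (venular): fed by a confluence, drains into a confluence.
    TC (terminal): fed by a bifurcation, drains into a confluence.
    WC ("unorthodox"): the collecting junction precedes the supplying one
    along the flow direction.
    """

    AC = "AC"
    VC = "VC"
    TC = "TC"
    WC = "WC"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class VesselSegment:
    id: str
    length: Optional[float] = None          # um
    diameter: Optional[float] = None        # um, lumen
    diameter_ci: Optional[tuple] = None     # (lower um, upper um)
    depth: Optional[float] = None           # um from PR1
    is_feeder: bool = False
    capillary_type: CapillaryType = CapillaryType.UNCLASSIFIED
    branch_order: Optional[int] = None
    feeder_distance: Optional[float] = None  # um

    def __post_init__(self):
        if self.length is not None and self.length <= 0:
            raise InputError(f"segment {self.id}: length must be > 0 um")
        if self.diameter is not None and self.diameter <= 0:
            raise InputError(f"segment {self.id}: diameter must be > 0 um")
        if self.diameter_ci is not None and self.diameter is not None:
            lo, hi = self.diameter_ci
            if not (lo <= self.diameter <= hi):
                raise InputError(
                    f"segment {self.id}: diameter {self.diameter} outside CI ({lo}, {hi})"
                )

    @property
    def radius(self) -> Optional[float]:
        return None if self.diameter is None else self.diameter / 2.0


@dataclass
class Junction:
    id: str
    kind: JunctionKind
    major_id: str                 # parent at a bifurcation; collector at a confluence
    minor_ids: tuple              # exactly two segment ids

    def __post_init__(self):
        ids = (self.major_id,) + tuple(self.minor_ids)
        if len(self.minor_ids) != 2 or len(set(ids)) != 3:
            raise StructureError(
                f"junction {self.id}: requires exactly 3 distinct incident segments, got {ids}"
            )

    def incident(self) -> tuple:
        return (self.major_id,) + tuple(self.minor_ids)


@dataclass
class VascularNetwork:
    segments: dict = field(default_factory=dict)    # id -> VesselSegment
    junctions: dict = field(default_factory=dict)   # id -> Junction
    crossings: list = field(default_factory=list)   # [(seg_a, seg_b), ...]
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- junction lookup at the two ends of a segment ---------------------
    def upstream_junction(self, seg_id: str) -> Optional[Junction]:
        """Junction feeding this segment (bifurcation daughter / confluence collector)."""
        self._check_id(seg_id)
        for j in self._sorted_junctions():
            if (j.kind is JunctionKind.BIFURCATION and seg_id in j.minor_ids) or (
                j.kind is JunctionKind.CONFLUENCE and seg_id == j.major_id
            ):
                return j
        return None

    def downstream_junction(self, seg_id: str) -> Optional[Junction]:
        """Junction drained by this segment (bifurcation parent / confluence tributary)."""
        self._check_id(seg_id)
        for j in self._sorted_junctions():
            if (j.kind is JunctionKind.BIFURCATION and seg_id == j.major_id) or (
                j.kind is JunctionKind.CONFLUENCE and seg_id in j.minor_ids
            ):
                return j
        return None

    def feeder_ids(self) -> list:
        return sorted(s.id for s in self.segments.values() if s.is_feeder)

    def _sorted_junctions(self) -> Iterable[Junction]:
        return (self.junctions[k] for k in sorted(self.junctions))

    def _check_id(self, seg_id: str) -> None:
        if seg_id not in self.segments:
            raise InputError(f"unknown segment id {seg_id!r}")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

_SEG_REQUIRED = ("id",)
_EDGE_REQUIRED = ("junction_id", "kind", "parent_id", "daughter1_id", "daughter2_id")


def build_network(segments_table: pd.DataFrame, edges_table: pd.DataFrame) -> VascularNetwork:
    """Assemble a :class:`VascularNetwork` from a per-segment table and a
    connectivity (junction) table.

    ``segments_table`` must carry an ``id`` column; ``length_um``,
    ``diameter_um`` and ``depth_um`` are used when present. ``edges_table``
    rows are junctions (``kind`` BIFURCATION/CONFLUENCE) or non-connecting
    CROSSING rows (pairing ``parent_id`` with ``daughter1_id``).
    """
    net = VascularNetwork()

    ids = [str(i) for i in segments_table["id"]]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise InputError(f"duplicate segment id(s): {sorted(dupes)}")

    def _num(row, col):
        if col not in segments_table.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    for _, row in segments_table.iterrows():
        sid = str(row["id"])
        ci = None
        lo, hi = _num(row, "diameter_ci_lower_um"), _num(row, "diameter_ci_upper_um")
        if lo is not None and hi is not None:
            ci = (lo, hi)
        net.segments[sid] = VesselSegment(
            id=sid,
            length=_num(row, "length_um"),
            diameter=_num(row, "diameter_um"),
            diameter_ci=ci,
            depth=_num(row, "depth_um"),
        )
        net.graph.add_node(sid)

    for _, row in edges_table.iterrows():
        kind_raw = str(row["kind"]).strip().upper()
        jid = str(row["junction_id"])
        ref = [str(row["parent_id"]), str(row["daughter1_id"])]
        if kind_raw == "CROSSING":
            for sid in ref:
                if sid not in net.segments:
                    raise InputError(f"crossing {jid} references unknown segment id {sid!r}")
            net.crossings.append(tuple(ref))
            continue
        try:
            kind = JunctionKind(kind_raw)
        except ValueError:
            raise StructureError(f"junction {jid}: unknown kind {kind_raw!r}") from None
        major = str(row["parent_id"])
        minors = (str(row["daughter1_id"]), str(row["daughter2_id"]))
        for sid in (major,) + minors:
            if sid not in net.segments:
                raise InputError(f"junction {jid} references unknown segment id {sid!r}")
        if jid in net.junctions:
            raise InputError(f"duplicate junction id {jid!r}")
        j = Junction(id=jid, kind=kind, major_id=major, minor_ids=minors)
        net.junctions[jid] = j
        if kind is JunctionKind.BIFURCATION:
            for m in minors:
                net.graph.add_edge(major, m, junction_id=jid, kind=kind)
        else:
            for m in minors:
                net.graph.add_edge(m, major, junction_id=jid, kind=kind)
    return net


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _role_slots(j: Junction, kind: JunctionKind):
    """(segment, end) slots occupied by junction *j* if it had the given kind."""
    if kind is JunctionKind.BIFURCATION:
        slots = [(j.major_id, "down")] + [(m, "up") for m in j.minor_ids]
    else:
        slots = [(j.major_id, "up")] + [(m, "down") for m in j.minor_ids]
    return slots


def validate_network(net: VascularNetwork) -> list:
    """Report structural violations without raising.

    Checks: (a) junctions whose labelled kind conflicts with the flow roles
    implied by the rest of the network — resolved greedily: the junction
    whose kind flip removes the most role conflicts is reported as a kind
    mismatch and its claims retracted, until no flip helps; (b) segments
    fed or drained by more than one junction; (c) feeders with inflow.
    """

    def _flip(kind):
        return (
            JunctionKind.CONFLUENCE
            if kind is JunctionKind.BIFURCATION
            else JunctionKind.BIFURCATION
        )

    def _inflow_penalty(j, kind):
        # a role set that sends flow into a feeder cannot be right
        penalty = 0
        for sid, end in _role_slots(j, kind):
            if end == "up" and net.segments[sid].is_feeder:
                penalty += 1
        return penalty

    violations = []
    excused: set = set()
    while True:
        claims: dict = {}
        live = [j for j in net._sorted_junctions() if j.id not in excused]
        for j in live:
            for slot in _role_slots(j, j.kind):
                claims.setdefault(slot, []).append(j.id)
        best = None
        for j in live:
            n_lab = sum(
                1 for s in _role_slots(j, j.kind) if len(claims.get(s, [])) > 1
            ) + _inflow_penalty(j, j.kind)
            n_flip = sum(
                1
                for s in _role_slots(j, _flip(j.kind))
                if any(o != j.id for o in claims.get(s, []))
            ) + _inflow_penalty(j, _flip(j.kind))
            benefit = n_lab - n_flip
            if n_lab > 0 and benefit > 0 and (best is None or benefit > best[0]):
                best = (benefit, j)
        if best is None:
            break
        _, j = best
        violations.append(
            {
                "type": "kind-mismatch",
                "junction_id": j.id,
                "detail": f"labelled {j.kind.value} but flow roles fit {_flip(j.kind).value}",
            }
        )
        excused.add(j.id)

    claims = {}
    for j in net._sorted_junctions():
        if j.id in excused:
            continue
        for slot in _role_slots(j, j.kind):
            claims.setdefault(slot, []).append(j.id)

    for (sid, end), owners in sorted(claims.items()):
        if len(owners) > 1:
            violations.append(
                {
                    "type": "duplicate-role",
                    "segment_id": sid,
                    "detail": f"{end}stream end claimed by junctions {owners}",
                }
            )

    for sid in sorted(net.segments):
        seg = net.segments[sid]
        if seg.is_feeder and net.graph.in_degree(sid) > 0:
            violations.append(
                {"type": "feeder-inflow", "segment_id": sid, "detail": "feeder has inflow"}
            )
    return violations


# ---------------------------------------------------------------------------
# feeders, branch order, feeder distance
# ---------------------------------------------------------------------------

def identify_feeders(net: VascularNetwork, min_diameter: float = FEEDER_DIAMETER_UM) -> set:
    """Flag segments wider than *min_diameter* um with no upstream parent.

    Raises :class:`AnalysisError` when no segment qualifies anywhere in the
    network — feeder distance and branch order are then undefined.
    """
    feeders = set()
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        if seg.diameter is not None and seg.diameter > min_diameter and net.graph.in_degree(sid) == 0:
            seg.is_feeder = True
            feeders.add(sid)
        else:
            seg.is_feeder = False
    if not feeders:
        raise AnalysisError(
            f"no candidate feeding arteriole (> {min_diameter} um with no parent)"
        )
    return feeders


def _shortest_upstream(net: VascularNetwork) -> dict:
    """Min-summed-length path from any feeder to every reachable segment.

    Returns ``{seg_id: (upstream_length_sum, path_ids)}`` where the length
    sum covers the *strictly upstream* segments (feeder included, the target
    excluded). Ties in length break on the smallest lexicographic id path.
    """
    feeders = net.feeder_ids()
    if not feeders:
        raise AnalysisError("no feeders flagged; run identify_feeders first")
    best: dict = {}
    heap: list = [(0.0, (f,)) for f in sorted(feeders)]
    heapq.heapify(heap)
    while heap:
        cost, path = heapq.heappop(heap)
        u = path[-1]
        if u in best:
            continue
        best[u] = (cost, path)
        out = sorted(net.graph.successors(u))
        if out:
            lu = net.segments[u].length
            if lu is None:
                raise InputError(f"segment {u} on an upstream path has no length")
            for v in out:
                if v not in best:
                    heapq.heappush(heap, (cost + lu, path + (v,)))
    return best


def compute_topology(net: VascularNetwork) -> pd.DataFrame:
    """Branch order and feeder distance for every feeder-reachable segment.

    Results are stored on the segments and returned as a table. Unreachable
    segments keep ``None`` metrics.
    """
    best = _shortest_upstream(net)
    rows = []
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        if sid not in best:
            seg.branch_order = None
            seg.feeder_distance = None
            continue
        cost, path = best[sid]
        order = 1
        for a, b in zip(path[:-1], path[1:]):
            if net.graph.edges[a, b]["kind"] is JunctionKind.BIFURCATION:
                order += 1
        if seg.length is None:
            raise InputError(f"segment {sid} has no length; feeder distance undefined")
        seg.branch_order = order
        seg.feeder_distance = cost + seg.length / 2.0
        rows.append(
            {"id": sid, "branch_order": order, "feeder_distance_um": seg.feeder_distance}
        )
    return pd.DataFrame(rows, columns=["id", "branch_order", "feeder_distance_um"])


def branch_order(net: VascularNetwork, seg_id: str) -> int:
    """1 + number of bifurcations on the shortest upstream path from a feeder."""
    net._check_id(seg_id)
    best = _shortest_upstream(net)
    if seg_id not in best:
        raise AnalysisError(f"segment {seg_id} is not reachable from any feeder")
    _, path = best[seg_id]
    order = 1
    for a, b in zip(path[:-1], path[1:]):
        if net.graph.edges[a, b]["kind"] is JunctionKind.BIFURCATION:
            order += 1
    return order


def feeder_distance(net: VascularNetwork, seg_id: str) -> float:
    """Summed upstream vessel lengths plus half this segment's length (um)."""
    net._check_id(seg_id)
    best = _shortest_upstream(net)
    if seg_id not in best:
        raise AnalysisError(f"segment {seg_id} is not reachable from any feeder")
    cost, _ = best[seg_id]
    length = net.segments[seg_id].length
    if length is None:
        raise InputError(f"segment {seg_id} has no length")
    return cost + length / 2.0


# ---------------------------------------------------------------------------
# capillary classification
# ---------------------------------------------------------------------------

def classify_segment(net: VascularNetwork, seg_id: str) -> CapillaryType:
    """Capillary type from the junction kinds at the vessel's two ends."""
    up = net.upstream_junction(seg_id)
    down = net.downstream_junction(seg_id)
    if up is None or down is None:
        t = CapillaryType.UNCLASSIFIED
    elif up.kind is JunctionKind.BIFURCATION and down.kind is JunctionKind.BIFURCATION:
        t = CapillaryType.AC
    elif up.kind is JunctionKind.CONFLUENCE and down.kind is JunctionKind.CONFLUENCE:
        t = CapillaryType.VC
    elif up.kind is JunctionKind.BIFURCATION and down.kind is JunctionKind.CONFLUENCE:
        t = CapillaryType.TC
    else:
        t = CapillaryType.WC
    net.segments[seg_id].capillary_type = t
    return t


def classify_network(net: VascularNetwork) -> dict:
    """Classify every segment; returns ``{segment_id: CapillaryType}``."""
    return {sid: classify_segment(net, sid) for sid in sorted(net.segments)}
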