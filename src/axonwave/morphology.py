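"""Varicose-axon morphologies: SWC I/O, compartmentalization, geometry.

A :class:`Morphology` is a tree of 3-D points with per-point radius, the
standard neuronal-reconstruction representation (SWC interchange format).
For simulation it is cut into iso-potential compartments of bounded length
(:func:`discretize`); mossy-fiber work samples the axon at every micrometer,
so the default compartment length is 1 um.

Units: um for geometry, Ohm*cm for axial resistivity, uF/cm^2 for specific
capacitance, MOhm / pF at the circuit level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Morphology",
    "Node",
    "CompartmentGrid",
    "read_swc",
    "write_swc",
    "discretize",
    "local_capacitance",
    "detect_boutons",
]

# SWC structure-type codes used for our labels
_LABEL_TO_SWC = {"soma": 1, "axon": 2, "bouton": 5, "filopodium": 6}
_SWC_TO_LABEL = {v: k for k, v in _LABEL_TO_SWC.items()}

VALID_LABELS = frozenset(_LABEL_TO_SWC)


class MorphologyError(ValueError):
    """Structural or validation failure in a morphology."""


@dataclass(frozen=True)
class Node:
    id: int
    parent_id: int | None
    x: float
    y: float
    z: float
    radius: float
    label: str = "axon"


@dataclass
class Morphology:
    """Tree of reconstruction points, parent-before-child ordered."""

    nodes: list[Node]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.nodes:
            raise MorphologyError("morphology has no nodes")
        seen: set[int] = set()
        roots = 0
        for n in self.nodes:
            if n.label not in VALID_LABELS:
                raise MorphologyError(f"unknown label {n.label!r} on node {n.id}")
            if not (n.radius > 0):
                raise MorphologyError(f"nonpositive radius on node {n.id}")
            if not all(map(math.isfinite, (n.x, n.y, n.z, n.radius))):
                raise MorphologyError(f"non-finite coordinate on node {n.id}")
            if n.parent_id is None:
                roots += 1
            elif n.parent_id not in seen:
                raise MorphologyError(
                    f"node {n.id}: parent {n.parent_id} does not precede it"
                )
            seen.add(n.id)
        if len(seen) != len(self.nodes):
            raise MorphologyError("duplicate node ids")
        if roots != 1:
            raise MorphologyError(f"expected exactly one root, found {roots}")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> Node:
        return self.nodes[0]

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None:
                out[n.parent_id].append(n.id)
        return out

    def is_chain(self) -> bool:
        """True for an unbranched morphology (every node has <= 1 child)."""
        return all(len(c) <= 1 for c in self.children_map().values())

    def total_path_length(self) -> float:
        by_id = {n.id: n for n in self.nodes}
        total = 0.0
        for n in self.nodes:
            if n.parent_id is None:
                continue
            p = by_id[n.parent_id]
            total += math.dist((n.x, n.y, n.z), (p.x, p.y, p.z))
        return total


def _toposort(rows: list[tuple[int, int | None, float, float, float, float, int]]):
    """Order raw SWC rows parent-before-child; reject cycles/multi-roots."""
    by_id = {r[0]: r for r in rows}
    children: dict[int, list[int]] = {r[0]: [] for r in rows}
    roots = []
    for r in rows:
        pid = r[1]
        if pid is None:
            roots.append(r[0])
        else:
            if pid not in by_id:
                raise MorphologyError(f"node {r[0]} references missing parent {pid}")
            children[pid].append(r[0])
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root, found {len(roots)}")
    order: list[int] = []
    stack = [roots[0]]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(reversed(children[nid]))
    if len(order) != len(rows):
        raise MorphologyError("cycle detected in parent links")
    return [by_id[i] for i in order]


def read_swc(path) -> Morphology:
    """Read a 7-column SWC file (``#`` comments, 1-based ids, radii in um)."""
    rows: list[tuple[int, int | None, float, float, float, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 7:
                raise MorphologyError(
                    f"{path}: line {lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid_raw = int(parts[6])
            except ValueError as exc:
                raise MorphologyError(f"{path}: line {lineno}: {exc}") from exc
            if r <= 0:
                raise MorphologyError(
                    f"{path}: line {lineno}: nonpositive radius {r}"
                )
            pid = None if pid_raw == -1 else pid_raw
            rows.append((nid, pid, x, y, z, r, stype))
    ordered = _toposort(rows)
    nodes = [
        Node(
            id=nid,
            parent_id=pid,
            x=x,
            y=y,
            z=z,
            radius=r,
            label=_SWC_TO_LABEL.get(stype, "axon"),
        )
        for nid, pid, x, y, z, r, stype in ordered
    ]
    return Morphology(nodes=nodes, metadata={"source": str(path)})


def write_swc(morph: Morphology, path) -> None:
    """Write SWC; numeric content round-trips through :func:`read_swc`."""
    morph.validate()
    lines = ["# SWC written by axonwave", "# id type x y z radius parent"]
    for n in morph.nodes:
        stype = _LABEL_TO_SWC[n.label]
        pid = -1 if n.parent_id is None else n.parent_id
        lines.append(
            f"{n.id} {stype} {n.x:.6g} {n.y:.6g} {n.z:.6g} {n.radius:.6g} {pid}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class CompartmentGrid:
    """Iso-potential compartments with tree connectivity (Hines-ordered).

    ``parent[i] < i`` for every non-root compartment; ``parent[0] == -1``.
    ``r_half`` is each compartment's one-sided axial half-resistance (MOhm);
    the coupling resistance between compartment i and its parent is
    ``r_half[i] + r_half[parent[i]]``.
    """

    parent: np.ndarray        # (n,) int
    position: np.ndarray      # (n,) um, path distance of the center from root
    length: np.ndarray        # (n,) um
    diameter: np.ndarray      # (n,) um, mean frustum diameter
    area: np.ndarray          # (n,) um^2, frustum lateral area
    r_half: np.ndarray        # (n,) MOhm
    label: list[str] = field(default_factory=list)
    ra: float = 150.0         # Ohm*cm used to build r_half

    @property
    def n(self) -> int:
        return self.parent.size

    def total_area(self) -> float:
        return float(self.area.sum())

    def total_length(self) -> float:
        return float(self.length.sum())

    def index_at(self, position_um: float) -> int:
        """Compartment whose center is closest to a path distance from root."""
        return int(np.argmin(np.abs(self.position - position_um)))


def _axial_half_resistance(ra: float, length_um: float, d1: float, d2: float) -> float:
    """Half-resistance of a frustum segment, MOhm.

    Exact frustum axial resistance is 4*Ra*L/(pi*d1*d2); for a cylinder this
    is the familiar 4*Ra*L/(pi*d^2).  Ra in Ohm*cm, geometry in um:
    Ohm*cm * um / um^2 = Ohm * 1e4 -> MOhm factor 1e-2.
    """
    return 0.5 * 4.0 * ra * length_um / (math.pi * d1 * d2) * 1e-2


def discretize(morph: Morphology, max_seg_len: float = 1.0, ra: float = 150.0) -> CompartmentGrid:
    """Cut a morphology into compartments no longer than ``max_seg_len`` um.

    Diameters vary linearly between nodes (frustum pieces), so total membrane
    area and total path length are invariant under re-discretization.
    """
    if max_seg_len <= 0:
        raise ValueError("max_seg_len must be positive")
    by_id = {n.id: n for n in morph.nodes}
    # path distance of each node from root
    dist = {morph.root.id: 0.0}
    # map node id -> index of the compartment that abuts it on the child side,
    # so child edges can attach to the right compartment
    tail_comp: dict[int, int] = {}
    parent_idx: list[int] = []
    pos: list[float] = []
    length: list[float] = []
    diam: list[float] = []
    area: list[float] = []
    r_half: list[float] = []
    labels: list[str] = []

    for node in morph.nodes:
        if node.parent_id is None:
            tail_comp[node.id] = -1
            continue
        p = by_id[node.parent_id]
        edge_len = math.dist((node.x, node.y, node.z), (p.x, p.y, p.z))
        dist[node.id] = dist[p.id] + edge_len
        if edge_len == 0.0:
            tail_comp[node.id] = tail_comp[p.id]
            continue
        nseg = max(1, math.ceil(edge_len / max_seg_len - 1e-12))
        seg_len = edge_len / nseg
        prev = tail_comp[p.id]
        for k in range(nseg):
            f0 = k / nseg
            f1 = (k + 1) / nseg
            d0 = 2 * (p.radius + f0 * (node.radius - p.radius))
            d1 = 2 * (p.radius + f1 * (node.radius - p.radius))
            dm = 0.5 * (d0 + d1)
            slant = math.hypot(seg_len, 0.5 * (d1 - d0))
            idx = len(length)
            parent_idx.append(prev)
            pos.append(dist[p.id] + (k + 0.5) * seg_len)
            length.append(seg_len)
            diam.append(dm)
            area.append(math.pi * 0.5 * (d0 + d1) * slant)
            r_half.append(_axial_half_resistance(ra, seg_len, d0, d1))
            # label by the nearer original node
            labels.append(node.label if f0 + f1 >= 1.0 else p.label)
            prev = idx
        tail_comp[node.id] = prev

    grid = CompartmentGrid(
        parent=np.asarray(parent_idx, dtype=np.int64),
        position=np.asarray(pos),
        length=np.asarray(length),
        diameter=np.asarray(diam),
        area=np.asarray(area),
        r_half=np.asarray(r_half),
        label=labels,
        ra=ra,
    )
    if grid.n == 0:
        raise MorphologyError("morphology produced no compartments (single point?)")
    return grid


def local_capacitance(grid: CompartmentGrid, cm: float, index: int) -> float:
    """Membrane capacitance of one compartment, pF (cm in uF/cm^2).

    1 um^2 at 1 uF/cm^2 is 0.01 pF.
    """
    if not 0 <= index < grid.n:
        raise IndexError(f"compartment index {index} out of range")
    return cm * float(grid.area[index]) * 0.01


def capacitance_profile(grid: CompartmentGrid, cm: float) -> np.ndarray:
    """Per-compartment membrane capacitance, pF."""
    return cm * grid.area * 0.01


def detect_boutons(grid: CompartmentGrid, ratio: float = 1.5) -> list[np.ndarray]:
    """Segment boutons as maximal runs of swollen compartments.

    A bouton is a maximal contiguous run of compartments whose diameter
    exceeds ``ratio`` times the flanking shaft diameter.  The shaft diameter
    is taken as the median diameter of non-swollen compartments (robust to
    the boutons themselves).  Returns a list of index arrays, one per bouton,
    in path order.
    """
    d = grid.diameter
    shaft = float(np.median(d))
    swollen = d > ratio * shaft
    runs: list[np.ndarray] = []
    i = 0
    n = grid.n
    while i < n:
        if swollen[i]:
            j = i
            while j + 1 < n and swollen[j + 1] and grid.parent[j + 1] == j:
                j += 1
            runs.append(np.arange(i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs
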