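"""Reconstructed neurons as rooted geometric trees.

A neuron is stored as an ordered table of typed, radius-bearing 3D nodes
(soma, dendritic shaft, dendritic spine) connected into a single rooted tree,
mirroring a filament-style reconstruction of a biocytin fill.  Each
parent--child pair defines a conical frustum; the soma is a single sphere at
the root.  The module provides SWC round-trip I/O, along-cable geodesics,
compartment membrane areas, and the morphometric summaries used to compare
spiny projection neurons (SPNs) with fast-spiking interneurons (FSIs).

Units are micrometres throughout; coordinates live in a right-handed frame.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

# Standard SWC type codes; spines have no standard code, so a configurable
# custom one (default 10) is used to keep files loadable by generic tools.
SWC_SOMA = 1
SWC_SHAFT = 3
DEFAULT_SPINE_CODE = 10


class Compartment(enum.Enum):
    SOMA = "soma"
    SHAFT = "shaft"
    SPINE = "spine"


class CellLabel(enum.Enum):
    SPN = "SPN"
    FSI = "FSI"
    UNKNOWN = "UNKNOWN"


class MorphologyError(ValueError):
    """Structural problem in a morphology or SWC file."""


@dataclass(frozen=True)
class MorphNode:
    id: int
    compartment: Compartment
    position: np.ndarray  # shape (3,), µm
    radius: float  # µm
    parent_id: int  # -1 for the root

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise MorphologyError(f"node {self.id}: position must be a 3-vector")
        if self.radius < 0:
            raise MorphologyError(f"node {self.id}: negative radius")
        if self.compartment in (Compartment.SOMA, Compartment.SHAFT) and self.radius <= 0:
            raise MorphologyError(f"node {self.id}: {self.compartment.value} radius must be > 0")


@dataclass(frozen=True)
class Segment:
    """Frustum between a parent node and a child node."""

    id: int  # equals the child node id
    parent_node: int
    child_node: int
    p0: np.ndarray
    p1: np.ndarray
    r0: float
    r1: float
    compartment: Compartment  # the child's compartment

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    def point_at(self, fraction: float) -> np.ndarray:
        return self.p0 + fraction * (self.p1 - self.p0)

    def radius_at(self, fraction: float) -> float:
        return self.r0 + fraction * (self.r1 - self.r0)

    @property
    def lateral_area(self) -> float:
        """Lateral (side) surface area of the frustum, µm²."""
        dr = self.r0 - self.r1
        slant = math.hypot(self.length, dr)
        return math.pi * (self.r0 + self.r1) * slant


class NeuronMorphology:
    """A validated single-tree morphology.

    Nodes are stored in topological order (parents before children) with
    contiguous 1-based ids.  Derived per-segment arrays are cached for the
    vectorised geometry queries used by the puncta-assignment stage.
    """

    def __init__(
        self,
        nodes: Sequence[MorphNode],
        cell_label: CellLabel = CellLabel.UNKNOWN,
        metadata: dict | None = None,
    ) -> None:
        self.nodes = list(nodes)
        self.cell_label = cell_label
        self.metadata = dict(metadata or {})
        self._validate()
        self._build_segments()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        if not self.nodes:
            raise MorphologyError("empty morphology")
        ids = [n.id for n in self.nodes]
        if ids != list(range(1, len(ids) + 1)):
            raise MorphologyError("node ids must be contiguous 1..N in order")
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        if roots[0].id != 1:
            raise MorphologyError("root must be node 1")
        if roots[0].compartment is not Compartment.SOMA:
            raise MorphologyError("root node must be a soma node")
        seen = set()
        for n in self.nodes:
            if n.parent_id == n.id:
                raise MorphologyError(f"node {n.id} is its own parent")
            if n.parent_id != -1:
                if n.parent_id not in seen:
                    raise MorphologyError(
                        f"node {n.id}: parent {n.parent_id} does not precede it"
                    )
            seen.add(n.id)
        # spine subtrees must hang off shafts (or other spine nodes)
        by_id = {n.id: n for n in self.nodes}
        for n in self.nodes:
            if n.compartment is Compartment.SPINE:
                parent = by_id[n.parent_id]
                if parent.compartment is Compartment.SOMA:
                    raise MorphologyError(
                        f"spine node {n.id} attaches to the soma; spines must attach to shafts"
                    )

    def _build_segments(self) -> None:
        by_id = {n.id: n for n in self.nodes}
        segs: list[Segment] = []
        for n in self.nodes:
            if n.parent_id == -1:
                continue
            p = by_id[n.parent_id]
            # dendrites leave the soma at their own calibre: the soma is a
            # separate sphere, so a soma parent does not impose its radius on
            # the proximal frustum end
            r0 = n.radius if p.compartment is Compartment.SOMA else p.radius
            segs.append(
                Segment(
                    id=n.id,
                    parent_node=p.id,
                    child_node=n.id,
                    p0=p.position,
                    p1=n.position,
                    r0=r0,
                    r1=n.radius,
                    compartment=n.compartment,
                )
            )
        self.segments = segs
        self._seg_by_id = {s.id: s for s in segs}
        # cumulative geodesic distance from the root centre to each node centre
        dist = {1: 0.0}
        for s in segs:
            dist[s.child_node] = dist[s.parent_node] + s.length
        self._node_path_dist = dist
        # vectorised views
        if segs:
            self._seg_p0 = np.stack([s.p0 for s in segs])
            self._seg_p1 = np.stack([s.p1 for s in segs])
            self._seg_r0 = np.array([s.r0 for s in segs])
            self._seg_r1 = np.array([s.r1 for s in segs])
            self._seg_ids = np.array([s.id for s in segs])
            self._seg_comp = np.array([s.compartment.value for s in segs])
        else:
            self._seg_p0 = np.empty((0, 3))
            self._seg_p1 = np.empty((0, 3))
            self._seg_r0 = np.empty(0)
            self._seg_r1 = np.empty(0)
            self._seg_ids = np.empty(0, dtype=int)
            self._seg_comp = np.empty(0, dtype="U5")

    # -- basic accessors ---------------------------------------------------

    @property
    def root(self) -> MorphNode:
        return self.nodes[0]

    @property
    def soma_radius(self) -> float:
        return self.root.radius

    def segment(self, segment_id: int) -> Segment:
        try:
            return self._seg_by_id[segment_id]
        except KeyError:
            raise MorphologyError(f"no segment with id {segment_id}") from None

    @property
    def total_cable_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    def node_positions(self) -> np.ndarray:
        return np.stack([n.position for n in self.nodes])

    def segment_arrays(self, subset: Iterable[Compartment] | None = None):
        """(p0, p1, r0, r1, ids) for segments whose compartment is in *subset*."""
        if subset is None:
            mask = np.ones(len(self.segments), dtype=bool)
        else:
            wanted = {c.value for c in subset}
            mask = np.isin(self._seg_comp, sorted(wanted))
        return (
            self._seg_p0[mask],
            self._seg_p1[mask],
            self._seg_r0[mask],
            self._seg_r1[mask],
            self._seg_ids[mask],
        )

    # -- geometry ----------------------------------------------------------

    def path_distance(self, segment_id: int, fraction: float) -> float:
        """Geodesic distance (µm) from the root centre to a point on a segment.

        The point is addressed as ``(segment id, arc fraction)`` with the
        fraction running from the parent node (0) to the child node (1).
        """
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"arc fraction must be in [0, 1], got {fraction}")
        seg = self.segment(segment_id)
        return self._node_path_dist[seg.parent_node] + fraction * seg.length

    def node_path_distance(self, node_id: int) -> float:
        return self._node_path_dist[node_id]

    def membrane_area(self, which: Iterable[Compartment] | None = None) -> float:
        """Membrane surface area (µm²) of a compartment subset.

        The soma contributes a sphere of the root radius; shafts and spines
        contribute the lateral areas of their frusta.
        """
        subset = set(which) if which is not None else set(Compartment)
        if not subset:
            logger.warning("membrane_area called with an empty compartment subset")
            return 0.0
        area = 0.0
        if Compartment.SOMA in subset:
            area += 4.0 * math.pi * self.soma_radius**2
        for s in self.segments:
            if s.compartment in subset and s.compartment is not Compartment.SOMA:
                area += s.lateral_area
        return area

    def morphometrics(self) -> "Morphometrics":
        root = self.root
        primaries = sum(
            1
            for n in self.nodes
            if n.parent_id == root.id and n.compartment is Compartment.SHAFT
        )
        xyz = self.node_positions()
        xy = xyz[:, :2]
        field_diameter = float(pdist(xy).max()) if len(xy) > 1 else 0.0
        z_range = float(xyz[:, 2].max() - xyz[:, 2].min())
        return Morphometrics(
            primary_dendrite_count=primaries,
            soma_diameter=2.0 * root.radius,
            field_diameter=field_diameter,
            z_range=z_range,
            total_cable_length=self.total_cable_length,
            n_spine_nodes=sum(1 for n in self.nodes if n.compartment is Compartment.SPINE),
        )


@dataclass(frozen=True)
class Morphometrics:
    """Summary measurements of a single reconstruction.

    ``field_diameter`` is the largest pairwise distance between node positions
    in XY projection — the caliper diameter one would measure on a maximum
    projection image.  ``z_range`` is the node z extent.
    """

    primary_dendrite_count: int
    soma_diameter: float
    field_diameter: float
    z_range: float
    total_cable_length: float
    n_spine_nodes: int


# -- SWC I/O ---------------------------------------------------------------


def _compartment_from_code(code: int, spine_type_code: int) -> Compartment:
    if code == SWC_SOMA:
        return Compartment.SOMA
    if code == SWC_SHAFT:
        return Compartment.SHAFT
    if code == spine_type_code:
        return Compartment.SPINE
    raise MorphologyError(
        f"unknown SWC type code {code}; accepted codes: "
        f"{SWC_SOMA} (soma), {SWC_SHAFT} (shaft), {spine_type_code} (spine)"
    )


def _code_from_compartment(c: Compartment, spine_type_code: int) -> int:
    return {Compartment.SOMA: SWC_SOMA, Compartment.SHAFT: SWC_SHAFT, Compartment.SPINE: spine_type_code}[c]


def read_swc(
    path: str | Path,
    spine_type_code: int = DEFAULT_SPINE_CODE,
    cell_label: CellLabel = CellLabel.UNKNOWN,
    metadata: dict | None = None,
) -> NeuronMorphology:
    """Read a 7-column SWC file into a :class:`NeuronMorphology`.

    Node ids are remapped to contiguous ``1..N`` preserving file order;
    coordinates and radii are taken verbatim (µm).  Multi-node somata are
    merged onto the largest-radius soma node, which becomes the root sphere.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        rows.append(
            (
                int(parts[0]),
                int(parts[1]),
                float(parts[2]),
                float(parts[3]),
                float(parts[4]),
                float(parts[5]),
                int(parts[6]),
            )
        )
    if not rows:
        raise MorphologyError(f"{path}: no data rows")

    raw_ids = [r[0] for r in rows]
    if len(set(raw_ids)) != len(raw_ids):
        raise MorphologyError(f"{path}: duplicate node ids")

    # merge multi-node somata: keep the largest-radius soma node as the root,
    # re-parenting every child of any soma node onto it
    soma_rows = [r for r in rows if r[1] == SWC_SOMA]
    if not soma_rows:
        raise MorphologyError(f"{path}: no soma node")
    soma_ids = {r[0] for r in soma_rows}
    keep_soma = max(soma_rows, key=lambda r: r[5])[0]
    merged: list[tuple] = []
    for r in rows:
        nid, code, x, y, z, rad, pid = r
        if code == SWC_SOMA and nid != keep_soma:
            continue
        if code == SWC_SOMA:
            pid = -1  # the kept soma node becomes the root
        elif pid in soma_ids:
            pid = keep_soma
        merged.append((nid, code, x, y, z, rad, pid))
    merged.sort(key=lambda r: r[1] != SWC_SOMA)  # stable: root first, rest in file order

    id_map = {r[0]: i + 1 for i, r in enumerate(merged)}
    nodes = []
    for nid, code, x, y, z, rad, pid in merged:
        if pid == nid:
            raise MorphologyError(f"{path}: node {nid} is its own parent")
        if pid != -1 and pid not in id_map:
            raise MorphologyError(f"{path}: node {nid} references unknown parent {pid}")
        nodes.append(
            MorphNode(
                id=id_map[nid],
                compartment=_compartment_from_code(code, spine_type_code),
                position=np.array([x, y, z]),
                radius=rad,
                parent_id=-1 if pid == -1 else id_map[pid],
            )
        )
    return NeuronMorphology(nodes, cell_label=cell_label, metadata=metadata)


def write_swc(
    m: NeuronMorphology,
    path: str | Path,
    spine_type_code: int = DEFAULT_SPINE_CODE,
) -> None:
    """Write sorted, contiguous-id SWC.  Round-trips losslessly with read_swc."""
    lines = ["# id type x y z radius parent"]
    for n in m.nodes:
        code = _code_from_compartment(n.compartment, spine_type_code)
        x, y, z = n.position
        lines.append(f"{n.id} {code} {x:.17g} {y:.17g} {z:.17g} {n.radius:.17g} {n.parent_id}")
    Path(path).write_text("\n".join(lines) + "\n")
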