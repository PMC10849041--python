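"""Assignment of presynaptic puncta to a reconstructed neuron.

A punctum is a sphere (centre + diameter) detected in a cortical-projection
channel (M1, S1, or the synaptic marker VGLUT1).  A punctum counts as a
putative input when the clearance between its surface and the neuron's
membrane — the *edge distance* — is at most the configured threshold
(0.5 µm by default, inclusive; negative clearances mean overlap and are
legal).  Retained inputs are localized to a compartment with precedence
spine > soma > shaft, and to a geodesic distance from the soma measured
along the dendrite at the attachment point.

Edge distance to a frustum is evaluated as (distance from the punctum centre
to the nearest point of the segment axis) minus the shaft radius linearly
interpolated at that point, minus the punctum radius; the soma contributes a
sphere at the root.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .morphology import Compartment, NeuronMorphology

SOMA_SEGMENT_ID = 0  # sentinel attach segment for somatic inputs


class Channel(enum.Enum):
    M1 = "M1"
    S1 = "S1"
    VGLUT1 = "VGLUT1"


@dataclass(frozen=True)
class Punctum:
    channel: Channel
    center: np.ndarray  # (3,) µm
    diameter: float  # µm

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("punctum center must be a 3-vector")
        if self.diameter < 0:
            raise ValueError("punctum diameter must be non-negative")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class AssignedInput:
    punctum: Punctum
    compartment: Compartment
    attach: tuple[int, float]  # (segment id, arc fraction); (0, 0.0) for soma
    edge_distance: float  # µm, may be negative (overlap)
    soma_path_distance: float  # µm

    @property
    def channel(self) -> Channel:
        return self.punctum.channel

    @property
    def center(self) -> np.ndarray:
        return self.punctum.center


def _axis_clearance(
    centers: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    r0: np.ndarray,
    r1: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised clearance from each centre to each frustum surface.

    Returns ``(clearance, fraction)`` of shape (n_centers, n_segments):
    clearance excludes the punctum radius; fraction is the arc parameter of
    the nearest axis point.
    """
    d = p1 - p0  # (S,3)
    L2 = np.einsum("ij,ij->i", d, d)  # (S,)
    L2safe = np.where(L2 > 0, L2, 1.0)
    w = centers[:, None, :] - p0[None, :, :]  # (C,S,3)
    t = np.einsum("csj,sj->cs", w, d) / L2safe[None, :]
    t = np.clip(t, 0.0, 1.0)
    nearest = p0[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(centers[:, None, :] - nearest, axis=2)
    local_r = r0[None, :] + t * (r1[None, :] - r0[None, :])
    return dist - local_r, t


def edge_distance(
    p: Punctum,
    m: NeuronMorphology,
    subset: Iterable[Compartment] | None = None,
) -> tuple[float, tuple[int, float]]:
    """Minimum edge distance (µm) from one punctum to a compartment subset.

    Returns ``(distance, (segment id, arc fraction))``; somatic attachment is
    reported as segment id 0 with fraction 0.
    """
    dists, attaches = edge_distances(np.asarray([p.center]), np.asarray([p.radius]), m, subset)
    return float(dists[0]), (int(attaches[0][0]), float(attaches[0][1]))


def edge_distances(
    centers: np.ndarray,
    radii: np.ndarray,
    m: NeuronMorphology,
    subset: Iterable[Compartment] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`edge_distance` over many puncta.

    Returns ``(distances (C,), attach (C,2))`` where attach rows are
    ``(segment id, arc fraction)``.
    """
    subset_set = set(subset) if subset is not None else set(Compartment)
    if not subset_set:
        raise ValueError("empty compartment subset")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.asarray(radii, dtype=float)
    n = len(centers)

    best = np.full(n, np.inf)
    attach = np.zeros((n, 2))
    attach[:, 0] = SOMA_SEGMENT_ID

    if Compartment.SOMA in subset_set:
        soma_clear = np.linalg.norm(centers - m.root.position, axis=1) - m.soma_radius
        best = soma_clear
        # attach stays the soma sentinel

    frusta = subset_set - {Compartment.SOMA}
    if frusta:
        p0, p1, r0, r1, ids = m.segment_arrays(frusta)
        if len(ids):
            clear, t = _axis_clearance(centers, p0, p1, r0, r1)
            seg_best = clear.argmin(axis=1)
            seg_clear = clear[np.arange(n), seg_best]
            better = seg_clear < best
            best = np.where(better, seg_clear, best)
            attach[better, 0] = ids[seg_best[better]]
            attach[better, 1] = t[np.arange(n), seg_best][better]

    return best - radii, attach


def assign_compartment(
    center: np.ndarray,
    radius: float,
    m: NeuronMorphology,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[Compartment, tuple[int, float], float]:
    """Compartment label with precedence spine > soma > shaft.

    Mirrors the subtraction order of the original workflow: inputs touching a
    spine are spine inputs even when they also touch the parent shaft; inputs
    touching the soma (but no spine) are somatic; the remainder are shaft
    inputs.  Returns (compartment, attach, edge distance of the winning
    compartment query).
    """
    c = np.asarray([center], dtype=float)
    r = np.asarray([radius], dtype=float)
    for comp in (Compartment.SPINE, Compartment.SOMA):
        if comp is Compartment.SPINE and not any(
            s.compartment is Compartment.SPINE for s in m.segments
        ):
            continue
        d, a = edge_distances(c, r, m, {comp})
        if d[0] <= cfg.edge_threshold:
            return comp, (int(a[0][0]), float(a[0][1])), float(d[0])
    d, a = edge_distances(c, r, m, {Compartment.SHAFT})
    return Compartment.SHAFT, (int(a[0][0]), float(a[0][1])), float(d[0])


def _soma_path_distance(center: np.ndarray, m: NeuronMorphology) -> float:
    """Somatic inputs: Euclidean distance from the root centre to the attach
    point on the soma sphere (≈ the soma radius), placing them in the most
    proximal distance bin."""
    d = float(np.linalg.norm(np.asarray(center, dtype=float) - m.root.position))
    return min(d, m.soma_radius)


def filter_inputs(
    puncta: Sequence[Punctum],
    m: NeuronMorphology,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> list[AssignedInput]:
    """Retain puncta whose edge distance to the whole neuron is ≤ the
    threshold (inclusive) and localize each retained input.

    The returned list preserves input order.  Somatic inputs get a
    soma-path distance equal to their Euclidean offset from the root centre
    (capped at the soma radius); all others get the geodesic distance along
    the cable to their attachment point.
    """
    if not puncta:
        return []
    centers = np.stack([p.center for p in puncta])
    radii = np.array([p.radius for p in puncta])
    dists, _ = edge_distances(centers, radii, m)
    out: list[AssignedInput] = []
    for p, d in zip(puncta, dists):
        if d > cfg.edge_threshold:
            continue
        comp, attach, _ = assign_compartment(p.center, p.radius, m, cfg)
        if comp is Compartment.SOMA:
            spd = _soma_path_distance(p.center, m)
        else:
            spd = m.path_distance(attach[0], attach[1])
        out.append(
            AssignedInput(
                punctum=p,
                compartment=comp,
                attach=attach,
                edge_distance=float(d),
                soma_path_distance=spd,
            )
        )
    return out


def compartment_density(
    inputs: Sequence[AssignedInput],
    m: NeuronMorphology,
    which: Iterable[Compartment],
) -> float:
    """Input density in counts per 10 µm² of membrane.

    For the conventional "dendrite" density, pass ``{SHAFT, SPINE}``.
    """
    which = set(which)
    area = m.membrane_area(which)
    if area <= 0:
        raise ValueError(f"zero membrane area for compartments {sorted(c.value for c in which)}")
    count = sum(1 for i in inputs if i.compartment in which)
    return 10.0 * count / area


def coloc_fraction(
    a: Sequence[AssignedInput],
    b: Sequence[Punctum],
    thr: float,
) -> float | None:
    """Fraction of inputs in *a* with ≥1 punctum of *b* within edge-to-edge
    distance *thr* (centre distance minus both radii).  ``None`` when *a* is
    empty (undefined, not zero)."""
    if thr <= 0:
        raise ValueError("threshold must be positive")
    if not a:
        return None
    if not b:
        return 0.0
    ca = np.stack([i.center for i in a])
    ra = np.array([i.punctum.radius for i in a])
    cb = np.stack([p.center for p in b])
    rb = np.array([p.radius for p in b])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2) - ra[:, None] - rb[None, :]
    return float((d.min(axis=1) <= thr).mean())
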