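"""Synthetic morphologies, puncta, and current-clamp sweeps with known truth.

Every analysis stage in this package is validated by parameter recovery on
data generated here.  The generator's defaults are the reported group means
for striatal SPNs and FSIs: soma diameter 14.08 / 17.86 µm, dendritic field
diameter 256.1 / 242.0 µm, 5 / 7 primary dendrites, per-cell expected input
totals, an M1 input fraction of 61.66 % (SPN) vs 55.05 % (FSI) with
between-cell spread equal to the reported SEM·√N, compartment placement
probabilities (spines carry ~60 % of SPN inputs; FSI inputs split ~79/21
between dendrites and soma), an S1-near-M1 clustering probability of
78.07 % (SPN) vs 54.65 % (FSI), and AP templates with planted half-height
width and interspike intervals (FSI: 0.4043 ms / 13.65 ms).

Morphologies are grown by a seeded stochastic branching walk and rescaled to
the target field diameter; puncta are planted on the membrane surface with a
uniform edge offset in [−0.2, +0.5] µm plus rejection-sampled background
beyond the detection threshold; sweeps replicate an 11-step protocol
(−500…+500 pA, 100 pA, 500 ms) with piecewise-linear AP templates whose
threshold and peak vertices are aligned to the 20 kHz sample grid, so the
planted waveform is represented exactly by the sampled trace.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .morphology import CellLabel, Compartment, MorphNode, NeuronMorphology
from .puncta import Channel, Punctum, edge_distances
from .ephys import SweepRecording


class GenerationError(ValueError):
    pass


@dataclass
class EphysParams:
    hhw_ms: float
    isi_ms: float
    rmp_mv: float
    r_in_mohm: float
    isi_vector_ms: np.ndarray | None = None  # overrides the uniform train
    amplitude_mv: float = 60.0
    ahp_drop_mv: float = 10.0
    threshold_mv: float = -45.0
    rheobase_pa: float = 300.0
    sample_khz: float = 20.0
    first_spike_latency_ms: float = 20.0
    tau_membrane_ms: float = 15.0


@dataclass
class GenerationParams:
    """Planted parameters for one synthetic cell.

    Defaults (via :meth:`for_cell_type`) are the SPN / FSI group means; any
    field can be overridden for targeted experiments.
    """

    cell_type: CellLabel
    seed: int
    n_primary: int
    soma_diameter_um: float
    field_diameter_um: float
    z_range_um: float
    branch_prob_per_10um: float
    spine_density_per_um: float  # beyond the first branch point; 0 for FSIs
    total_input_mean: float  # expected M1+S1 inputs per cell
    m1_fraction_mean: float
    m1_fraction_sd: float  # between-cell spread of the M1 fraction
    compartment_probs: tuple[float, float, float]  # (spine, shaft, soma)
    p_cluster: float  # probability an S1 input is planted near an M1 input
    p_vglut: float  # probability an input gets a colocalized VGLUT1 punctum
    background_density_per_1000um3: float
    punctum_diameter_range: tuple[float, float]
    ephys: EphysParams
    fixed_counts: bool = False  # Poisson off: plant exact expected counts
    # cohort mode: draw this cell's M1 fraction at a fixed quantile of the
    # between-cell distribution instead of at random.  Passing stratified
    # quantiles (i + 0.5)/n across an n-cell cohort makes the cohort a
    # balanced sample of the planted spread (variance reduction; the
    # distribution itself is unchanged)
    m1_fraction_quantile: float | None = None
    # rejection-sample non-clustered S1 beyond the cluster threshold so the
    # planted colocalized fraction equals p_cluster exactly in expectation;
    # with False the remainder is plain-uniform and carries its natural
    # chance level of proximity
    subtract_chance_coloc: bool = True

    _SPN_DEFAULTS = dict(
        n_primary=5,
        soma_diameter_um=14.08,
        field_diameter_um=256.1,
        z_range_um=60.49,
        branch_prob_per_10um=0.35,
        spine_density_per_um=0.30,
        total_input_mean=352.4,
        m1_fraction_mean=0.6166,
        m1_fraction_sd=0.0882,  # reported SEM 2.545 % × √12
        compartment_probs=(0.6046, 0.1641, 0.2313),
        p_cluster=0.7807,
        p_vglut=0.1995,
    )
    _FSI_DEFAULTS = dict(
        n_primary=7,
        soma_diameter_um=17.86,
        field_diameter_um=242.0,
        z_range_um=67.49,
        branch_prob_per_10um=0.45,
        spine_density_per_um=0.0,
        total_input_mean=309.6,
        m1_fraction_mean=0.5505,
        m1_fraction_sd=0.2188,  # reported SEM 8.271 % × √7
        compartment_probs=(0.0, 0.7921, 0.2079),
        p_cluster=0.5465,
        p_vglut=0.1995,
    )
    _SPN_EPHYS = dict(hhw_ms=1.282, isi_ms=42.11, rmp_mv=-75.0, r_in_mohm=117.7)
    _FSI_EPHYS = dict(hhw_ms=0.4043, isi_ms=13.65, rmp_mv=-67.94, r_in_mohm=108.6)

    @classmethod
    def for_cell_type(cls, cell_type: CellLabel | str, seed: int, **overrides) -> "GenerationParams":
        if isinstance(cell_type, str):
            cell_type = CellLabel[cell_type.upper()]
        base = dict(cls._SPN_DEFAULTS if cell_type is CellLabel.SPN else cls._FSI_DEFAULTS)
        eph = dict(cls._SPN_EPHYS if cell_type is CellLabel.SPN else cls._FSI_EPHYS)
        eph.update(overrides.pop("ephys", {}))
        base.update(
            background_density_per_1000um3=0.045,
            punctum_diameter_range=(1.0, 1.6),
        )
        base.update(overrides)
        return cls(cell_type=cell_type, seed=seed, ephys=EphysParams(**eph), **base)

    def __post_init__(self) -> None:
        probs = np.asarray(self.compartment_probs, dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise GenerationError("compartment_probs must be non-negative and sum to 1")
        for name in ("p_cluster", "p_vglut", "m1_fraction_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1]")
        if self.field_diameter_um <= self.soma_diameter_um:
            raise GenerationError("field diameter must exceed the soma diameter")


@dataclass
class GroundTruth:
    """Planted facts about one synthetic cell, for recovery audits."""

    seed: int
    cell_type: str
    m1_fraction_planted: float
    p_cluster: float
    counts: dict  # channel -> compartment -> planted count
    n_background: int
    clustered_s1_indices: list[int]  # indices into the emitted puncta list
    planted_indices: list[int]  # non-background puncta
    punctum_compartments: list[str | None]  # per punctum; None for background
    ephys: dict = field(default_factory=dict)

    def total_planted(self, channel: str) -> int:
        return sum(self.counts.get(channel, {}).values())

    def self_audit(self, puncta: Sequence[Punctum]) -> None:
        """Verify internal consistency against the emitted puncta table."""
        n_inputs = sum(self.total_planted(ch) for ch in self.counts)
        if n_inputs + self.n_background != len(puncta):
            raise GenerationError("ground truth counts disagree with the puncta table")
        if len(self.punctum_compartments) != len(puncta):
            raise GenerationError("per-punctum compartment labels out of sync")
        for ch, by_comp in self.counts.items():
            for comp, n in by_comp.items():
                got = sum(
                    1
                    for i in self.planted_indices
                    if puncta[i].channel.value == ch and self.punctum_compartments[i] == comp
                )
                if got != n:
                    raise GenerationError(f"planted count mismatch for {ch}/{comp}")
        for i in self.clustered_s1_indices:
            if puncta[i].channel is not Channel.S1:
                raise GenerationError("clustered index does not point at an S1 punctum")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


# --------------------------------------------------------------------------
# morphology generation


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_unit(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        v -= v.dot(axis) * axis
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def generate_morphology(p: GenerationParams) -> NeuronMorphology:
    """Grow a seeded stochastic branching tree matching the cell-type targets.

    ``n_primary`` shafts leave the soma at evenly spread azimuths, advance in
    ~10 µm steps with angular jitter and occasional bifurcation, and stop at
    the target radial extent.  XY coordinates are rescaled so the measured
    field diameter equals the target exactly, and z is rescaled to the target
    depth.  SPNs receive single-node spine branches on shaft nodes distal to
    the first branch point at the configured linear density.
    """
    rng = np.random.default_rng([p.seed, 0x5C])
    soma_r = p.soma_diameter_um / 2.0
    target_r = p.field_diameter_um / 2.0

    nodes: list[MorphNode] = [
        MorphNode(1, Compartment.SOMA, np.zeros(3), soma_r, -1)
    ]
    children_count: dict[int, int] = {}
    node_radial: dict[int, float] = {1: 0.0}
    beyond_branch: dict[int, bool] = {1: False}

    def add_node(pos, radius, parent, compartment) -> int:
        nid = len(nodes) + 1
        nodes.append(MorphNode(nid, compartment, pos, radius, parent))
        children_count[parent] = children_count.get(parent, 0) + 1
        node_radial[nid] = float(np.linalg.norm(pos[:2]))
        return nid

    # each stack entry: (parent node id, direction, parent marked beyond-branch)
    step = 10.0
    branch_p = p.branch_prob_per_10um
    stack: list[tuple[int, np.ndarray]] = []
    for k in range(p.n_primary):
        az = 2 * math.pi * (k + rng.uniform(-0.15, 0.15)) / p.n_primary
        elev = rng.uniform(-0.12, 0.12)
        d = np.array([math.cos(az) * math.cos(elev), math.sin(az) * math.cos(elev), math.sin(elev)])
        start = d * soma_r
        nid = add_node(start + d * step * rng.uniform(0.8, 1.2), 1.1, 1, Compartment.SHAFT)
        beyond_branch[nid] = False
        stack.append((nid, d))

    while stack:
        parent, d = stack.pop()
        pos = nodes[parent - 1].position
        radial = node_radial[parent]
        if radial >= target_r * rng.uniform(0.9, 1.1):
            continue
        n_branches = 2 if rng.random() < branch_p else 1
        for _ in range(n_branches):
            jitter = rng.normal(scale=0.25, size=3)
            newd = _unit(d + jitter + 0.25 * _unit(np.append(pos[:2], 0.0) + 1e-9))
            length = step * rng.uniform(0.8, 1.2)
            newpos = pos + newd * length
            frac = min(node_radial[parent] / target_r, 1.0)
            radius = max(0.35, 1.1 * (1.0 - 0.7 * frac))
            nid = add_node(newpos, radius, parent, Compartment.SHAFT)
            beyond_branch[nid] = beyond_branch[parent] or n_branches == 2
            stack.append((nid, newd))

    # rescale XY to the exact target field diameter and z to the target range
    xyz = np.stack([n.position for n in nodes])
    from scipy.spatial.distance import pdist

    cur = pdist(xyz[:, :2]).max()
    sxy = p.field_diameter_um / cur
    z = xyz[:, 2]
    zspan = z.max() - z.min()
    sz = p.z_range_um / zspan if zspan > 0 else 1.0
    rescaled = []
    for n in nodes:
        pos = n.position.copy()
        if n.id != 1:
            pos[:2] *= sxy
            pos[2] *= sz
        rescaled.append(MorphNode(n.id, n.compartment, pos, n.radius, n.parent_id))
    nodes = rescaled

    # spines distal to the first ramification (SPN only)
    if p.spine_density_per_um > 0:
        by_id = {n.id: n for n in nodes}
        shaft_nodes = [n for n in nodes if n.compartment is Compartment.SHAFT]
        spine_rows = []
        lo_d, hi_d = p.spine_diameter_range if hasattr(p, "spine_diameter_range") else (0.6, 1.2)
        for n in shaft_nodes:
            if not beyond_branch.get(n.id, False):
                continue
            parent = by_id[n.parent_id]
            seg_len = float(np.linalg.norm(n.position - parent.position))
            n_sp = rng.poisson(p.spine_density_per_um * seg_len)
            axis = _unit(n.position - parent.position)
            for _ in range(n_sp):
                direction = _perp_unit(axis, rng)
                length = rng.uniform(0.8, 1.5)
                diam = rng.uniform(lo_d, hi_d)
                spine_rows.append((n.id, n.position + direction * (n.radius + length), diam / 2.0))
        next_id = len(nodes) + 1
        for parent_id, pos, radius in spine_rows:
            nodes.append(MorphNode(next_id, Compartment.SPINE, pos, radius, parent_id))
            next_id += 1

    return NeuronMorphology(nodes, cell_label=p.cell_type, metadata={"seed": p.seed})


# --------------------------------------------------------------------------
# puncta generation


def _sample_surface(
    m: NeuronMorphology,
    compartment: Compartment,
    rng: np.random.Generator,
    segment_pool: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform point on the compartment's surface: (point, outward normal)."""
    if compartment is Compartment.SOMA:
        u = _unit(rng.normal(size=3))
        return m.root.position + m.soma_radius * u, u
    segs = [s for s in m.segments if s.compartment is compartment]
    if not segs:
        raise GenerationError(f"morphology has no {compartment.value} segments")
    if segment_pool is not None:
        segs = [m.segment(int(i)) for i in segment_pool]
    areas = np.array([s.lateral_area for s in segs])
    seg = segs[rng.choice(len(segs), p=areas / areas.sum())]
    t = rng.uniform()
    axis = _unit(seg.p1 - seg.p0)
    normal = _perp_unit(axis, rng)
    return seg.point_at(t) + seg.radius_at(t) * normal, normal


def _place_input(
    m: NeuronMorphology,
    compartment: Compartment,
    rng: np.random.Generator,
    diam_range: tuple[float, float],
    segment_pool: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    surface, normal = _sample_surface(m, compartment, rng, segment_pool)
    diameter = rng.uniform(*diam_range)
    offset = rng.uniform(-0.2, 0.5)
    center = surface + (diameter / 2.0 + offset) * normal
    return center, diameter


def generate_puncta(
    m: NeuronMorphology,
    p: GenerationParams,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[list[Punctum], GroundTruth]:
    """Plant M1/S1 inputs (plus optional VGLUT1 validation spots) and
    background puncta on/around a morphology.

    Channel counts are Poisson around the planted per-cell means (exact with
    ``fixed_counts``); each input samples a compartment from the placement
    probabilities and a surface location with edge offset uniform in
    [−0.2, +0.5] µm.  With probability ``p_cluster`` an S1 input is relocated
    onto the membrane within the cluster threshold (Euclidean) of a random M1
    input; remaining S1 inputs are rejection-sampled to sit beyond that
    threshold from every M1 input.  Background puncta are placed uniformly in
    the bounding volume with edge distance > threshold + 0.5 µm.
    """
    rng = np.random.default_rng([p.seed, 0xB1])
    comp_names = (Compartment.SPINE, Compartment.SHAFT, Compartment.SOMA)
    probs = np.asarray(p.compartment_probs, dtype=float)
    has_spines = any(s.compartment is Compartment.SPINE for s in m.segments)
    if probs[0] > 0 and not has_spines:
        raise GenerationError("spine placement requested on an aspiny morphology")

    # planted per-cell M1 fraction: truncated normal around the group mean,
    # either drawn at random or pinned to a cohort quantile
    if p.m1_fraction_sd <= 0:
        m1_frac = p.m1_fraction_mean
    elif p.m1_fraction_quantile is not None:
        from scipy.stats import norm

        if not 0.0 < p.m1_fraction_quantile < 1.0:
            raise GenerationError("m1_fraction_quantile must be in (0, 1)")
        m1_frac = float(
            np.clip(
                norm.ppf(p.m1_fraction_quantile, p.m1_fraction_mean, p.m1_fraction_sd),
                0.05,
                0.95,
            )
        )
    else:
        while True:
            m1_frac = rng.normal(p.m1_fraction_mean, p.m1_fraction_sd)
            if 0.05 <= m1_frac <= 0.95:
                break

    lam_m1 = p.total_input_mean * m1_frac
    lam_s1 = p.total_input_mean * (1.0 - m1_frac)
    if p.fixed_counts:
        n_m1, n_s1 = int(round(lam_m1)), int(round(lam_s1))
    else:
        n_m1, n_s1 = int(rng.poisson(lam_m1)), int(rng.poisson(lam_s1))

    def draw_compartment() -> Compartment:
        return comp_names[rng.choice(3, p=probs)]

    puncta: list[Punctum] = []
    compartments: list[str | None] = []
    counts: dict[str, dict[str, int]] = {"M1": {}, "S1": {}, "VGLUT1": {}}

    m1_centers: list[np.ndarray] = []
    for _ in range(n_m1):
        comp = draw_compartment()
        center, diam = _place_input(m, comp, rng, p.punctum_diameter_range)
        puncta.append(Punctum(Channel.M1, center, diam))
        compartments.append(comp.value)
        counts["M1"][comp.value] = counts["M1"].get(comp.value, 0) + 1
        m1_centers.append(center)
    m1_arr = np.array(m1_centers).reshape(-1, 3)

    clustered_idx: list[int] = []
    thr = cfg.cluster_threshold
    for _ in range(n_s1):
        make_cluster = n_m1 > 0 and rng.random() < p.p_cluster
        if make_cluster:
            target = m1_arr[rng.integers(n_m1)]
            comp = _feasible_compartment(m, probs, comp_names, target, thr, rng)
            center, diam = _place_near(m, comp, rng, p.punctum_diameter_range, target, thr)
            clustered_idx.append(len(puncta))
        else:
            # the compartment is redrawn on every rejection try: a soma (or
            # short spine pool) saturated by M1 neighbours would otherwise
            # make the >thr condition unsatisfiable and bias the planted
            # colocalized fraction upward
            if p.subtract_chance_coloc:
                for _try in range(500):
                    comp = draw_compartment()
                    center, diam = _place_input(m, comp, rng, p.punctum_diameter_range)
                    if n_m1 == 0 or np.linalg.norm(m1_arr - center, axis=1).min() > thr:
                        break
            else:
                comp = draw_compartment()
                center, diam = _place_input(m, comp, rng, p.punctum_diameter_range)
        puncta.append(Punctum(Channel.S1, center, diam))
        compartments.append(comp.value)
        counts["S1"][comp.value] = counts["S1"].get(comp.value, 0) + 1

    # VGLUT1 validation spots colocalized with a subset of inputs
    n_inputs = len(puncta)
    if p.p_vglut > 0:
        for i in range(n_inputs):
            if rng.random() < p.p_vglut:
                host = puncta[i]
                diam = rng.uniform(*p.punctum_diameter_range)
                gap = rng.uniform(0.0, 0.8 * cfg.coloc_threshold_vglut)
                direction = _unit(rng.normal(size=3))
                center = host.center + (host.radius + diam / 2.0 + gap) * direction
                puncta.append(Punctum(Channel.VGLUT1, center, diam))
                compartments.append(compartments[i])
                counts["VGLUT1"][compartments[i]] = counts["VGLUT1"].get(compartments[i], 0) + 1
    n_planted = len(puncta)

    # background: uniform in the padded bounding box, beyond the edge filter
    xyz = m.node_positions()
    lo, hi = xyz.min(axis=0) - 5.0, xyz.max(axis=0) + 5.0
    vol = float(np.prod(hi - lo))
    n_bg = int(rng.poisson(p.background_density_per_1000um3 * vol / 1000.0))
    placed = 0
    while placed < n_bg:
        batch = max(32, 2 * (n_bg - placed))
        cand = rng.uniform(lo, hi, size=(batch, 3))
        diams = rng.uniform(*p.punctum_diameter_range, size=batch)
        d, _ = edge_distances(cand, diams / 2.0, m)
        ok = d > cfg.edge_threshold + 0.5
        for c, dm in zip(cand[ok], diams[ok]):
            if placed >= n_bg:
                break
            ch = Channel.M1 if rng.random() < 0.5 else Channel.S1
            puncta.append(Punctum(ch, c, dm))
            compartments.append(None)
            placed += 1

    gt = GroundTruth(
        seed=p.seed,
        cell_type=p.cell_type.value,
        m1_fraction_planted=float(m1_frac),
        p_cluster=p.p_cluster,
        counts=counts,
        n_background=n_bg,
        clustered_s1_indices=clustered_idx,
        planted_indices=list(range(n_planted)),
        punctum_compartments=compartments,
        ephys=dict(
            hhw_ms=p.ephys.hhw_ms,
            isi_ms=p.ephys.isi_ms,
            rmp_mv=p.ephys.rmp_mv,
            r_in_mohm=p.ephys.r_in_mohm,
        ),
    )
    gt.self_audit(puncta)
    return puncta, gt


def _feasible_compartment(
    m: NeuronMorphology,
    probs: np.ndarray,
    comp_names: tuple,
    target: np.ndarray,
    thr: float,
    rng: np.random.Generator,
) -> Compartment:
    """Draw a placement compartment restricted to those with membrane within
    Euclidean *thr* of *target* (renormalized probabilities)."""
    from .puncta import _axis_clearance

    feasible = np.zeros(3, dtype=bool)
    for k, comp in enumerate(comp_names):
        if probs[k] <= 0:
            continue
        if comp is Compartment.SOMA:
            feasible[k] = np.linalg.norm(target - m.root.position) - m.soma_radius <= thr
        else:
            p0, p1, r0, r1, ids = m.segment_arrays({comp})
            if len(ids):
                clear, _ = _axis_clearance(np.asarray([target]), p0, p1, r0, r1)
                feasible[k] = bool((clear[0] <= thr).any())
    w = probs * feasible
    if w.sum() <= 0:
        # target floats off-membrane beyond thr of everything it could pair
        # with; fall back to the unrestricted draw
        w = probs
    return comp_names[rng.choice(3, p=w / w.sum())]


def _place_near(
    m: NeuronMorphology,
    compartment: Compartment,
    rng: np.random.Generator,
    diam_range: tuple[float, float],
    target: np.ndarray,
    thr: float,
    max_tries: int = 60,
) -> tuple[np.ndarray, float]:
    """On-membrane placement within Euclidean *thr* of *target*.

    Samples locations restricted to segments whose axis passes near the
    target; falls back to the nearest membrane point when rejection fails.
    """
    p0, p1, r0, r1, ids = m.segment_arrays({compartment} - {Compartment.SOMA} or None)
    pool = None
    if compartment is not Compartment.SOMA and len(ids):
        from .puncta import _axis_clearance

        clear, _ = _axis_clearance(np.asarray([target]), p0, p1, r0, r1)
        near = ids[clear[0] <= thr]
        pool = near if len(near) else None
    for _ in range(max_tries):
        center, diam = _place_input(m, compartment, rng, diam_range, segment_pool=pool)
        if np.linalg.norm(center - target) <= thr:
            return center, diam
    # fallback: nearest membrane point to the target, any compartment
    d, attach = edge_distances(np.asarray([target]), np.asarray([0.0]), m)
    seg_id, frac = int(attach[0][0]), float(attach[0][1])
    diam = rng.uniform(*diam_range)
    offset = rng.uniform(-0.2, 0.5)
    if seg_id == 0:
        u = _unit(target - m.root.position)
        center = m.root.position + (m.soma_radius + diam / 2.0 + offset) * u
    else:
        seg = m.segment(seg_id)
        axis_pt = seg.point_at(frac)
        u = _unit(target - axis_pt)
        center = axis_pt + (seg.radius_at(frac) + diam / 2.0 + offset) * u
    return center, diam


# --------------------------------------------------------------------------
# sweep generation


PROTOCOL_STEPS_PA = tuple(range(-500, 501, 100))  # 11 sweeps


def generate_sweeps(p: GenerationParams) -> list[SweepRecording]:
    """Replicate the 11-sweep current-step protocol with planted features.

    Depolarizing sweeps at/above the rheobase carry piecewise-linear AP
    templates with the planted HHW and ISI vector (vertices grid-aligned, see
    module docstring); subthreshold and hyperpolarizing sweeps settle
    exponentially to ΔV = I·R_in around the planted resting potential.
    """
    e = p.ephys
    dt = 1.0 / e.sample_khz
    onset, offset, total = 100.0, 600.0, 700.0
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt

    def snap(x: float) -> float:
        return round(x / dt) * dt

    amp, drop = e.amplitude_mv, e.ahp_drop_mv
    # rise time a (grid-aligned) and fall time b solving
    # HHW = a/2 + b·(amp/2)/(amp+drop)
    a = snap(max(dt, 0.4 * e.hhw_ms))
    b = (e.hhw_ms - a / 2.0) * (amp + drop) / (amp / 2.0)
    if b <= 0:
        raise GenerationError("planted HHW too short for the template rise time")

    if e.isi_vector_ms is not None:
        isis = np.array([snap(x) for x in e.isi_vector_ms])
    else:
        isis = None  # fill per-sweep below
    if isis is not None and (a + b) >= isis.min():
        raise GenerationError("planted HHW implies an AP wider than the shortest ISI")

    peak_v = e.threshold_mv + amp
    ahp_v = e.threshold_mv - drop
    ramp_ms = 5.0  # subthreshold approach to AP threshold, slope < detection cut

    sweeps = []
    for sid, step_pa in enumerate(PROTOCOL_STEPS_PA):
        if step_pa >= e.rheobase_pa:
            tau1 = snap(onset + e.first_spike_latency_ms)
            if isis is None:
                isi = snap(e.isi_ms)
                count = int((offset - 10.0 - tau1) // isi) + 1
                train = np.full(max(count, 2) - 1, isi)
            else:
                train = isis
            thres_times = tau1 + np.concatenate([[0.0], np.cumsum(train)])
            thres_times = thres_times[thres_times + a + b < offset - 5.0]
            knots_t = [0.0, onset, onset + ramp_ms]
            knots_v = [e.rmp_mv, e.rmp_mv, e.threshold_mv]
            for k, tau in enumerate(thres_times):
                knots_t += [tau, tau + a, tau + a + b]
                knots_v += [e.threshold_mv, peak_v, ahp_v]
                recover_end = (
                    thres_times[k + 1] if k + 1 < len(thres_times) else min(tau + a + b + 5.0, offset - dt)
                )
                if recover_end > tau + a + b:
                    knots_t.append(recover_end)
                    knots_v.append(e.threshold_mv)
            knots_t += [offset, offset + dt, total]
            knots_v += [e.threshold_mv, e.rmp_mv, e.rmp_mv]
            v = np.interp(t, knots_t, knots_v)
        else:
            dv = step_pa * e.r_in_mohm * 1e-3  # pA·MΩ → mV
            v = np.full(n, e.rmp_mv)
            during = (t >= onset) & (t <= offset)
            v[during] += dv * (1.0 - np.exp(-(t[during] - onset) / e.tau_membrane_ms))
            after = t > offset
            v_end = dv * (1.0 - math.exp(-(offset - onset) / e.tau_membrane_ms))
            v[after] += v_end * np.exp(-(t[after] - offset) / e.tau_membrane_ms)
        sweeps.append(
            SweepRecording(time=t, voltage=v, current_step=float(step_pa), step_window=(onset, offset), sweep_id=sid)
        )
    return sweeps


def simulate_cell(
    p: GenerationParams,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[NeuronMorphology, list[Punctum], list[SweepRecording], GroundTruth]:
    """Morphology + puncta + sweeps + ground truth for one cell."""
    m = generate_morphology(p)
    puncta, gt = generate_puncta(m, p, cfg)
    sweeps = generate_sweeps(p)
    return m, puncta, sweeps, gt
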