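import math

import numpy as np
import pytest

from striamap.config import AnalysisConfig
from striamap.morphology import Compartment, MorphNode, NeuronMorphology
from striamap.puncta import (
    AssignedInput,
    Channel,
    Punctum,
    coloc_fraction,
    compartment_density,
    edge_distance,
    edge_distances,
    filter_inputs,
)

from conftest import make_chain, make_random_tree


def brute_force_edge_distance(p, m):
    """Exhaustive per-segment scan in plain python (independent oracle)."""
    import math as _m

    best = _m.inf
    # soma sphere
    c = p.center
    r = m.root.position
    best = _m.dist(c, r) - m.soma_radius
    for s in m.segments:
        ax, ay, az = s.p1 - s.p0
        wx, wy, wz = c - s.p0
        L2 = ax * ax + ay * ay + az * az
        t = (wx * ax + wy * ay + wz * az) / L2 if L2 > 0 else 0.0
        t = min(1.0, max(0.0, t))
        nx, ny, nz = s.p0[0] + t * ax, s.p0[1] + t * ay, s.p0[2] + t * az
        d = _m.sqrt((c[0] - nx) ** 2 + (c[1] - ny) ** 2 + (c[2] - nz) ** 2)
        best = min(best, d - (s.r0 + t * (s.r1 - s.r0)))
    return best - p.radius


class TestEdgeDistance:
    def test_on_axis_containment(self, straight_cable):
        p = Punctum(Channel.M1, (50.0, 0.0, 0.0), 1.0)
        d, _ = edge_distance(p, straight_cable, {Compartment.SHAFT})
        assert d == pytest.approx(-1.0)

    def test_off_axis_exact_geometry(self, straight_cable):
        p = Punctum(Channel.M1, (50.0, 2.0, 0.0), 1.0)
        d, attach = edge_distance(p, straight_cable, {Compartment.SHAFT})
        assert d == pytest.approx(1.0)
        seg = straight_cable.segment(attach[0])
        assert seg.point_at(attach[1])[0] == pytest.approx(50.0)

    def test_matches_brute_force_scan(self, rng):
        m = make_random_tree(rng, 80)
        lo = m.node_positions().min(axis=0) - 5
        hi = m.node_positions().max(axis=0) + 5
        for _ in range(200):
            p = Punctum(Channel.M1, rng.uniform(lo, hi), float(rng.uniform(1.0, 2.0)))
            d, _ = edge_distance(p, m)
            assert d == pytest.approx(brute_force_edge_distance(p, m), abs=1e-9)

    def test_empty_subset_rejected(self, straight_cable):
        p = Punctum(Channel.M1, (0.0, 0.0, 0.0), 1.0)
        with pytest.raises(ValueError, match="empty"):
            edge_distance(p, straight_cable, set())


class TestFilterInputs:
    def test_boundary_inclusive(self, straight_cable):
        # surface at y=0.5; edge distance exactly 0.5 for center at y=1.5, d=1
        p = Punctum(Channel.M1, (50.0, 1.5, 0.0), 1.0)
        kept = filter_inputs([p], straight_cable)
        assert len(kept) == 1
        assert kept[0].edge_distance == pytest.approx(0.5)

    def test_empty_input(self, straight_cable):
        assert filter_inputs([], straight_cable) == []

    def test_planted_vs_background(self, straight_cable, rng):
        touching = [
            Punctum(Channel.M1, (x, 0.5 + 0.5 + off, 0.0), 1.0)
            for x, off in zip(rng.uniform(20, 90, 100), rng.uniform(-0.5, 0.4, 100))
        ]
        background = [
            Punctum(Channel.S1, (x, 10.0 + y, 0.0), 1.0)
            for x, y in zip(rng.uniform(20, 90, 50), rng.uniform(0, 30, 50))
        ]
        kept = filter_inputs(touching + background, straight_cable)
        assert len(kept) == 100
        assert all(i.channel is Channel.M1 for i in kept)

    def test_idempotent_and_monotone_in_threshold(self, spn_cell):
        _, m, puncta, _ = spn_cell
        puncta = [p for p in puncta if p.channel is not Channel.VGLUT1][:200]
        cfg = AnalysisConfig()
        kept = filter_inputs(puncta, m, cfg)
        again = filter_inputs([i.punctum for i in kept], m, cfg)
        assert len(again) == len(kept)
        wider = filter_inputs(puncta, m, AnalysisConfig(edge_threshold=1.0))
        assert len(wider) >= len(kept)

    def test_soma_inputs_near_soma(self, spn_cell):
        _, m, puncta, _ = spn_cell
        cfg = AnalysisConfig()
        kept = filter_inputs([p for p in puncta if p.channel is not Channel.VGLUT1], m, cfg)
        for i in kept:
            if i.compartment is Compartment.SOMA:
                assert i.soma_path_distance <= m.soma_radius + cfg.edge_threshold


class TestCompartmentAssignment:
    def _spined_cable(self):
        pts = [(0, 0, 0), (10, 0, 0), (20, 0, 0), (30, 0, 0)]
        nodes = [
            MorphNode(1, Compartment.SOMA, pts[0], 5.0, -1),
            MorphNode(2, Compartment.SHAFT, pts[1], 0.5, 1),
            MorphNode(3, Compartment.SHAFT, pts[2], 0.5, 2),
            MorphNode(4, Compartment.SHAFT, pts[3], 0.5, 3),
            MorphNode(5, Compartment.SPINE, (20.0, 1.5, 0.0), 0.4, 3),
        ]
        return NeuronMorphology(nodes)

    def test_spine_precedence_over_shaft(self):
        m = self._spined_cable()
        # touches both the spine segment and the shaft below it
        p = Punctum(Channel.M1, (20.0, 1.2, 0.0), 1.0)
        kept = filter_inputs([p], m)
        assert len(kept) == 1
        assert kept[0].compartment is Compartment.SPINE

    def test_soma_only(self):
        m = self._spined_cable()
        p = Punctum(Channel.M1, (0.0, 5.8, 0.0), 1.0)
        kept = filter_inputs([p], m)
        assert kept[0].compartment is Compartment.SOMA

    def test_partition_sums_exactly(self, spn_cell):
        _, m, puncta, _ = spn_cell
        kept = filter_inputs([p for p in puncta if p.channel is not Channel.VGLUT1], m)
        by_comp = {c: sum(1 for i in kept if i.compartment is c) for c in Compartment}
        assert sum(by_comp.values()) == len(kept)


class TestDensity:
    def test_hand_computed_soma_density(self):
        r = math.sqrt(100.0 / (4 * math.pi))  # soma area exactly 100 µm²
        m = make_chain([(0, 0, 0), (10, 0, 0)], radii=[r, 0.5])
        inputs = [
            AssignedInput(
                punctum=Punctum(Channel.M1, (0, r, 0), 1.0),
                compartment=Compartment.SOMA,
                attach=(0, 0.0),
                edge_distance=0.0,
                soma_path_distance=r,
            )
            for _ in range(5)
        ]
        assert compartment_density(inputs, m, {Compartment.SOMA}) == pytest.approx(0.5)
        assert compartment_density(inputs * 2, m, {Compartment.SOMA}) == pytest.approx(1.0)

    def test_zero_area_rejected(self, straight_cable):
        with pytest.raises(ValueError, match="area"):
            compartment_density([], straight_cable, {Compartment.SPINE})


class TestColocFraction:
    def _inputs(self, xs):
        return [
            AssignedInput(
                punctum=Punctum(Channel.M1, (x, 0, 0), 1.0),
                compartment=Compartment.SHAFT,
                attach=(1, 0.0),
                edge_distance=0.0,
                soma_path_distance=x,
            )
            for x in xs
        ]

    def test_empty_reference_zero(self):
        assert coloc_fraction(self._inputs([0.0, 5.0]), [], 0.5) == 0.0

    def test_identical_coordinates_full(self):
        a = self._inputs([0.0, 5.0])
        b = [i.punctum for i in a]
        assert coloc_fraction(a, b, 0.5) == 1.0

    def test_empty_query_undefined(self):
        assert coloc_fraction([], [Punctum(Channel.VGLUT1, (0, 0, 0), 1.0)], 0.5) is None

    def test_planted_vglut_rate_recovered(self, spn_cell):
        p, m, puncta, gt = spn_cell
        vglut = [q for q in puncta if q.channel is Channel.VGLUT1]
        kept = filter_inputs([q for q in puncta if q.channel is not Channel.VGLUT1], m)
        m1 = [i for i in kept if i.channel is Channel.M1]
        frac = coloc_fraction(m1, vglut, 0.5)
        n = len(m1)
        tol = 3 * math.sqrt(p.p_vglut * (1 - p.p_vglut) / n)
        assert frac == pytest.approx(p.p_vglut, abs=tol + 0.02)
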