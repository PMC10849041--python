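import numpy as np
import pytest

from striamap.config import AnalysisConfig
from striamap.morphology import Compartment, write_swc
from striamap.puncta import Channel, edge_distances, filter_inputs
from striamap.ephys import compute_hhw, compute_passive, compute_train_features, detect_aps
from striamap.synth import (
    GenerationError,
    GenerationParams,
    generate_morphology,
    generate_puncta,
    generate_sweeps,
)


class TestMorphologyGeneration:
    def test_same_seed_byte_identical_swc(self, tmp_path):
        p = GenerationParams.for_cell_type("SPN", seed=7)
        f1, f2 = tmp_path / "a.swc", tmp_path / "b.swc"
        write_swc(generate_morphology(p), f1)
        write_swc(generate_morphology(p), f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_spn_morphometric_targets(self, spn_cell):
        p, m, _, _ = spn_cell
        mm = m.morphometrics()
        assert mm.primary_dendrite_count == 5
        assert mm.soma_diameter == pytest.approx(14.08)
        # spine tips may extend a little past the rescaled shaft envelope
        assert mm.field_diameter == pytest.approx(p.field_diameter_um, rel=0.05)
        assert mm.n_spine_nodes > 0

    def test_fsi_is_aspiny_with_seven_primaries(self, fsi_cell):
        _, m, _, _ = fsi_cell
        mm = m.morphometrics()
        assert mm.primary_dendrite_count == 7
        assert mm.n_spine_nodes == 0

    def test_spines_only_distal_to_first_branch(self, spn_cell):
        _, m, _, _ = spn_cell
        by_id = {n.id: n for n in m.nodes}
        children = {}
        for n in m.nodes:
            if n.parent_id != -1:
                children.setdefault(n.parent_id, []).append(n)
        for n in m.nodes:
            if n.compartment is not Compartment.SPINE:
                continue
            # walk to the root: some ancestor must be a branch point
            cur, saw_branch = by_id[n.parent_id], False
            while cur.parent_id != -1:
                shaft_kids = [
                    k for k in children.get(cur.id, []) if k.compartment is Compartment.SHAFT
                ]
                if len(shaft_kids) >= 2:
                    saw_branch = True
                    break
                cur = by_id[cur.parent_id]
            assert saw_branch

    def test_infeasible_field_rejected(self):
        with pytest.raises(GenerationError):
            GenerationParams.for_cell_type("SPN", seed=1, field_diameter_um=10.0)


class TestPunctaGeneration:
    def test_ground_truth_bookkeeping(self, spn_cell):
        _, m, puncta, gt = spn_cell
        gt.self_audit(puncta)  # raises on inconsistency
        planted = sum(gt.total_planted(ch) for ch in ("M1", "S1", "VGLUT1"))
        assert planted + gt.n_background == len(puncta)

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_filter_recovers_planted_not_background(self, seed):
        p = GenerationParams.for_cell_type("SPN", seed=seed, total_input_mean=150.0)
        m = generate_morphology(p)
        puncta, gt = generate_puncta(m, p)
        non_vglut = [
            (i, q) for i, q in enumerate(puncta) if q.channel is not Channel.VGLUT1
        ]
        kept = filter_inputs([q for _, q in non_vglut], m)
        n_planted = gt.total_planted("M1") + gt.total_planted("S1")
        assert len(kept) >= 0.99 * n_planted
        # no background survives: all background sit > threshold + 0.5 µm
        centers = np.array([q.center for i, q in non_vglut if gt.punctum_compartments[i] is None])
        if len(centers):
            radii = np.array(
                [q.radius for i, q in non_vglut if gt.punctum_compartments[i] is None]
            )
            d, _ = edge_distances(centers, radii, m)
            assert (d > 0.5).all()

    def test_poisson_off_gives_exact_counts(self):
        p = GenerationParams.for_cell_type(
            "SPN", seed=2, fixed_counts=True, m1_fraction_sd=0.0, total_input_mean=100.0
        )
        m = generate_morphology(p)
        _, gt = generate_puncta(m, p)
        assert gt.total_planted("M1") == round(100 * 0.6166)
        assert gt.total_planted("S1") == round(100 * (1 - 0.6166))

    def test_spine_placement_on_aspiny_cell_rejected(self, fsi_cell):
        _, m, _, _ = fsi_cell
        p = GenerationParams.for_cell_type("FSI", seed=1, compartment_probs=(0.5, 0.3, 0.2))
        with pytest.raises(GenerationError, match="aspiny"):
            generate_puncta(m, p)

    def test_unclustered_placement_has_chance_coloc(self):
        """With p_cluster = 0 and no chance subtraction, the S1→M1 5 µm
        fraction matches an independent uniform-placement simulation."""
        p = GenerationParams.for_cell_type(
            "SPN",
            seed=21,
            p_cluster=0.0,
            subtract_chance_coloc=False,
            p_vglut=0.0,
            background_density_per_1000um3=0.0,
        )
        m = generate_morphology(p)
        puncta, gt = generate_puncta(m, p)
        m1 = np.array([q.center for q in puncta if q.channel is Channel.M1])
        s1 = np.array([q.center for q in puncta if q.channel is Channel.S1])
        from striamap.spatial import nn_distances

        d, _ = nn_distances(s1, m1)
        measured = float((d <= 5.0).mean())

        # oracle: fresh uniform placements on the same morphology
        rng = np.random.default_rng(99)
        from striamap.synth import _place_input

        comp_names = (Compartment.SPINE, Compartment.SHAFT, Compartment.SOMA)
        probs = np.asarray(p.compartment_probs)
        sim = []
        for _ in range(400):
            comp = comp_names[rng.choice(3, p=probs)]
            c, _dm = _place_input(m, comp, rng, p.punctum_diameter_range)
            sim.append(float(np.linalg.norm(m1 - c, axis=1).min() <= 5.0))
        expected = float(np.mean(sim))
        se = np.sqrt(expected * (1 - expected) / 400 + measured * (1 - measured) / len(s1))
        assert abs(measured - expected) <= 4 * se + 0.02


class TestSweepGeneration:
    def test_protocol_shape(self):
        sweeps = generate_sweeps(GenerationParams.for_cell_type("FSI", seed=1))
        assert len(sweeps) == 11
        assert [s.current_step for s in sweeps] == list(range(-500, 501, 100))

    @pytest.mark.parametrize("cell_type,hhw", [("FSI", 0.4043), ("SPN", 1.282)])
    def test_planted_hhw_round_trip(self, cell_type, hhw):
        p = GenerationParams.for_cell_type(cell_type, seed=3)
        sweeps = generate_sweeps(p)
        spiking = [s for s in sweeps if s.current_step >= p.ephys.rheobase_pa]
        events = detect_aps(spiking[0])
        assert len(events) >= 2
        got = np.mean([compute_hhw(spiking[0], e) for e in events])
        duration = events[0].ahp[0] - events[0].threshold[0]
        assert got == pytest.approx(hhw, abs=2 * duration / 999)

    def test_planted_uniform_isi_gives_exact_iff(self):
        # 13.65 ms lies on the 20 kHz grid: 1000/13.65 = 73.26 Hz exactly
        p = GenerationParams.for_cell_type("FSI", seed=3)
        sweeps = generate_sweeps(p)
        s = [x for x in sweeps if x.current_step >= p.ephys.rheobase_pa][0]
        fs = compute_train_features(detect_aps(s))
        assert fs.mean_iff == pytest.approx(1000.0 / 13.65, abs=1e-9)
        assert fs.mff == pytest.approx(1000.0 / 13.65, abs=1e-9)

    def test_planted_input_resistance_within_one_percent(self):
        p = GenerationParams.for_cell_type("SPN", seed=4)
        sweeps = generate_sweeps(p)
        hyper = [s for s in sweeps if s.current_step < 0]
        rmp, rin = compute_passive(hyper)
        assert rin == pytest.approx(117.7, rel=0.01)
        assert rmp == pytest.approx(p.ephys.rmp_mv, abs=0.01)

    def test_hhw_longer_than_isi_rejected(self):
        p = GenerationParams.for_cell_type("FSI", seed=1)
        p.ephys.hhw_ms = 20.0
        p.ephys.isi_vector_ms = np.array([13.65, 13.65])
        with pytest.raises(GenerationError):
            generate_sweeps(p)
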