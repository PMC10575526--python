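import numpy as np
import pytest

import capnet
from capnet import SyntheticConfig
from capnet.errors import ConfigurationError, GenerationError
from capnet.network_model import JunctionKind
from capnet.synthetic_data import network_tables


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_feeders": 0},
            {"tree_depth": 0},
            {"vave_sd": -1.0},
            {"depth_mixture": ((150, 10, 0.5), (200, 10, 0.4))},  # weights != 1
            {"sampling_rate": 250},
            {"duration": 3.001},          # 200 Hz * 3.001 s not integer
            {"unorthodox_fraction": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(**kwargs).validate()


class TestNetworkGeneration:
    def test_minimal_tree(self):
        cfg = SyntheticConfig(seed=0, n_feeders=1, tree_depth=1)
        net, truth = capnet.generate_network(cfg)
        bifs = [j for j in net.junctions.values() if j.kind is JunctionKind.BIFURCATION]
        assert len(bifs) == 1
        feeder = net.feeder_ids()
        assert len(feeder) == 1
        assert net.segments[feeder[0]].diameter > cfg.feeder_diameter_min
        for d in bifs[0].minor_ids:
            assert truth.branch_order[d] == 2

    def test_junction_identity_exact_at_fixed_exponent(self):
        cfg = SyntheticConfig(seed=1, n_feeders=1, tree_depth=3, true_exponent=2.5)
        net, truth = capnet.generate_network(cfg)
        for j in net.junctions.values():
            rp = net.segments[j.major_id].radius
            r1 = net.segments[j.minor_ids[0]].radius
            r2 = net.segments[j.minor_ids[1]].radius
            assert rp**2.5 - (r1**2.5 + r2**2.5) == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_identical_tables(self):
        cfg = SyntheticConfig(seed=9, n_feeders=2, tree_depth=2, unorthodox_fraction=0.3)
        seg_a, edge_a = network_tables(*capnet.generate_network(cfg))
        seg_b, edge_b = network_tables(*capnet.generate_network(cfg))
        assert seg_a.to_csv(index=False) == seg_b.to_csv(index=False)
        assert edge_a.to_csv(index=False) == edge_b.to_csv(index=False)

    def test_ground_truth_keys_cover_segments_and_junctions(self, small_generated):
        _, net, truth = small_generated
        for mapping in (truth.diameter, truth.depth, truth.branch_order,
                        truth.feeder_distance, truth.capillary_type):
            assert set(mapping) == set(net.segments)
        assert set(truth.exponents) == set(net.junctions)

    def test_unorthodox_fraction_zero_gives_no_wc(self):
        cfg = SyntheticConfig(seed=4, n_feeders=2, tree_depth=3)
        _, truth = capnet.generate_network(cfg)
        assert "WC" not in set(truth.capillary_type.values())


class TestTraces:
    def test_sample_count_at_200hz_3s(self, small_generated):
        cfg, net, truth = small_generated
        traces = capnet.generate_velocity_traces(net, truth, cfg)
        assert all(t.samples.size == 600 for t in traces.values())
        assert set(traces) == set(net.segments)

    def test_noiseless_waveform_summary_is_exact(self):
        cfg = SyntheticConfig(
            seed=0, n_feeders=1, tree_depth=1,
            vave_base=1.0, vave_sd=0.0, pulsatility_at_feeder=0.5,
            pulsatility_decay=0.0, pulsatility_jitter=0.0, trace_noise_sd=0.0,
        )
        net, truth = capnet.generate_network(cfg)
        traces = capnet.generate_velocity_traces(net, truth, cfg)
        for sid, tr in traces.items():
            s = capnet.summarize_trace(tr)
            assert s.pulsatility == pytest.approx(0.5, abs=1e-9)
            assert s.v_ave == pytest.approx(1.0, abs=1e-9)
            assert s.v_min == pytest.approx(truth.flow[sid]["v_min"], abs=1e-9)

    def test_all_samples_positive(self, small_generated):
        cfg, net, truth = small_generated
        traces = capnet.generate_velocity_traces(net, truth, cfg)
        assert all((t.samples > 0).all() for t in traces.values())

    def test_same_seed_identical_traces(self, small_generated):
        cfg, net, truth = small_generated
        a = capnet.generate_velocity_traces(net, truth, cfg)
        b = capnet.generate_velocity_traces(net, truth, cfg)
        assert all(np.array_equal(a[s].samples, b[s].samples) for s in a)

    def test_missing_feeder_distance_raises(self, small_generated):
        cfg, net, truth = small_generated
        import copy

        broken = copy.deepcopy(truth)
        broken.feeder_distance.popitem()
        with pytest.raises(GenerationError):
            capnet.generate_velocity_traces(net, broken, cfg)

    def test_null_settings_decorrelate_pulsatility_from_distance(self):
        cfg = SyntheticConfig(
            seed=21, n_feeders=63, tree_depth=3,
            pulsatility_decay=0.0, vmin_slope=None,
        )
        net, truth = capnet.generate_network(cfg)
        traces = capnet.generate_velocity_traces(net, truth, cfg)
        sids = truth.voi_ids
        puls = [capnet.summarize_trace(traces[s]).pulsatility for s in sids]
        dist = [truth.feeder_distance[s] for s in sids]
        r, _, n = capnet.pearson(dist, puls)
        assert n >= 500 and abs(r) < 0.1


class TestDepthStack:
    def test_out_of_range_depth_rejected(self, small_generated):
        cfg, net, truth = small_generated
        import copy

        broken = copy.deepcopy(truth)
        sid = next(iter(broken.depth))
        broken.depth[sid] = 500.0
        with pytest.raises(GenerationError):
            capnet.generate_depth_stack(net, broken, cfg)

    def test_roi_profile_is_injected_bell_plus_noise(self):
        cfg = SyntheticConfig(seed=6, n_feeders=1, tree_depth=1, depth_noise_sd=0.0)
        net, truth = capnet.generate_network(cfg)
        stack, masks = capnet.generate_depth_stack(net, truth, cfg)
        sid = sorted(masks)[0]
        prof = capnet.extract_profile(stack, masks[sid], sid)
        expected = cfg.depth_background + cfg.depth_signal_amplitude * np.exp(
            -((stack.depth_labels - truth.depth[sid]) ** 2) / (2 * cfg.depth_sigma**2)
        )
        assert np.allclose(prof.mean_gray, expected, atol=1e-9)

    def test_masks_are_disjoint(self, small_generated):
        cfg, net, truth = small_generated
        _, masks = capnet.generate_depth_stack(net, truth, cfg)
        total = sum(m.sum() for m in masks.values())
        union = np.zeros_like(next(iter(masks.values())), dtype=int)
        for m in masks.values():
            union += m
        assert union.max() == 1 and union.sum() == total


class TestDivisionImage:
    def test_exact_band_width(self):
        v = capnet.generate_division_image(4.0, length_px=10, px_size=1.0, blur_sd=0.0, noise_sd=0.0)
        assert set((v.image == 1.0).sum(axis=1)) == {4}
        assert set(np.isin(v.image, [0.0, 1.0]).all(axis=1)) == {True}

    def test_subpixel_diameter_rejected(self):
        with pytest.raises(GenerationError):
            capnet.generate_division_image(0.4, px_size=0.5)

    def test_seeded_noise_reproducible(self):
        a = capnet.generate_division_image(4.0, noise_sd=0.2, seed=7)
        b = capnet.generate_division_image(4.0, noise_sd=0.2, seed=7)
        c = capnet.generate_division_image(4.0, noise_sd=0.2, seed=8)
        assert np.array_equal(a.image, b.image)
        assert not np.array_equal(a.image, c.image)
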