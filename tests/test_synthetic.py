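"""Synthetic cohort generator: construction identities, determinism,
effect injection, and the fiber-record inverse."""

import numpy as np
import pytest

from fanet import (
    CohortConfig,
    build_connectivity,
    calibrate_default_profile,
    fit_weight_scale,
    generate_cars,
    generate_cohort,
    generate_subject_matrix,
    generate_topology,
    matrix_to_fibers,
)
from fanet.config import derive_seed
from fanet.construction import ConnectivityMatrix
from fanet.metrics import (
    characteristic_path_length,
    degree,
    global_efficiency,
    is_connected,
    shortest_path_lengths,
)

SMALL = dict(n_nodes=30, base_degree=6, rewire_prob=0.1,
             target_nodes=(1, 2, 3, 4))


class TestGenerateTopology:
    def test_zero_rewiring_gives_exact_ring_lattice_degrees(self):
        A = generate_topology(20, 6, 0.0, seed=0)
        np.testing.assert_array_equal(degree(A), 6)

    def test_full_rewiring_conserves_edge_count(self):
        A = generate_topology(40, 6, 1.0, seed=1)
        assert np.count_nonzero(np.triu(A, 1)) == 40 * 6 // 2

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_90_node_substrate_connected_with_540_edges(self, seed):
        A = generate_topology(90, 12, 0.055, seed=seed)
        assert np.count_nonzero(np.triu(A, 1)) == 540
        assert is_connected(A)
        np.testing.assert_allclose(degree(A).mean(), 12.0)

    def test_odd_degree_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_topology(20, 5, 0.1)

    def test_deterministic(self):
        np.testing.assert_array_equal(generate_topology(30, 6, 0.2, seed=9),
                                      generate_topology(30, 6, 0.2, seed=9))


class TestGenerateSubjectMatrix:
    def test_shape_symmetry_range(self):
        topo = generate_topology(30, 6, 0.1, seed=0)
        cfg = CohortConfig(**SMALL)
        W = generate_subject_matrix(topo, cfg, "ASD", seed=1)
        np.testing.assert_allclose(W, W.T)
        assert not np.diag(W).any()
        assert W.max() <= 1.0 and W[W > 0].min() > 0
        assert ((W > 0) == (topo > 0)).all()

    def test_null_configuration_groups_match_in_expectation(self):
        topo = generate_topology(30, 6, 0.1, seed=0)
        cfg = CohortConfig(**SMALL, asd_global_scale=1.0, nodal_boost=1.0)
        asd = np.mean([generate_subject_matrix(topo, cfg, "ASD", seed=i).sum()
                       for i in range(40)])
        hc = np.mean([generate_subject_matrix(topo, cfg, "HC", seed=100 + i).sum()
                      for i in range(40)])
        assert asd == pytest.approx(hc, rel=0.05)

    def test_global_scale_multiplies_expected_weight(self):
        # low weight level so that clipping at 1 never bites
        topo = generate_topology(30, 6, 0.1, seed=0)
        base = CohortConfig(**SMALL, weight_shape_a=2.0, weight_shape_b=8.0,
                            nodal_boost=1.0, asd_global_scale=1.05)
        asd = np.mean([generate_subject_matrix(topo, base, "ASD", seed=i).mean()
                       for i in range(60)])
        hc = np.mean([generate_subject_matrix(topo, base, "HC", seed=i).mean()
                      for i in range(60)])
        assert asd / hc == pytest.approx(1.05, abs=0.01)

    def test_boost_elevates_target_incident_edges_only(self):
        topo = generate_topology(30, 6, 0.1, seed=0)
        cfg = CohortConfig(**SMALL, weight_shape_a=2.0, weight_shape_b=8.0,
                           asd_global_scale=1.0, nodal_boost=1.5)
        t0 = [t - 1 for t in cfg.target_nodes]
        others = np.setdiff1d(np.arange(30), t0)
        ratios_t, ratios_o = [], []
        for i in range(40):
            Wa = generate_subject_matrix(topo, cfg, "ASD", seed=i)
            Wh = generate_subject_matrix(topo, cfg, "HC", seed=i)
            ratios_t.append(Wa[t0].sum() / Wh[t0].sum())
            inner = np.ix_(others, others)
            ratios_o.append(Wa[inner].sum() / Wh[inner].sum())
        assert np.mean(ratios_t) == pytest.approx(1.5, abs=0.06)
        assert np.mean(ratios_o) == pytest.approx(1.0, abs=0.03)

    def test_calibrated_cohort_asd_has_shorter_paths(self):
        """With the packaged effect sizes, mean L^w is lower in ASD."""
        cfg = calibrate_default_profile()
        topo = generate_topology(cfg.n_nodes, cfg.base_degree,
                                 cfg.rewire_prob, seed=3)
        lw = {}
        for group, n in (("ASD", 12), ("HC", 12)):
            lw[group] = np.mean([
                characteristic_path_length(shortest_path_lengths(
                    generate_subject_matrix(topo, cfg, group, seed=i)))
                for i in range(n)])
        assert lw["ASD"] < lw["HC"]


class TestGenerateCohort:
    def test_default_cohort_counts(self, default_cohort):
        matrices, metas = default_cohort
        assert len(matrices) == 58
        assert sum(m.group == "ASD" for m in metas) == 39
        assert all(m.n_nodes == 90 for m in matrices)

    def test_cars_only_for_asd_and_in_range(self, default_cohort):
        _, metas = default_cohort
        for m in metas:
            if m.group == "ASD":
                assert 15 <= m.cars <= 60
            else:
                assert m.cars is None

    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_asd=3, n_hc=2, **SMALL)
        m1, meta1 = generate_cohort(cfg)
        m2, meta2 = generate_cohort(cfg)
        assert meta1 == meta2
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_tiny_cohort_size(self):
        cfg = CohortConfig(n_asd=2, n_hc=2, **SMALL)
        matrices, metas = generate_cohort(cfg)
        assert len(matrices) == 4


class TestGenerateCars:
    def test_noiseless_limit_gives_unit_correlation(self):
        cfg = CohortConfig(cars_r_target=0.999)
        rng = np.random.default_rng(0)
        e = rng.uniform(0.2, 0.3, 39)
        cars = generate_cars(e, cfg, seed=1)
        assert np.corrcoef(e, cars)[0, 1] > 0.99

    def test_constant_efficiencies_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            generate_cars(np.full(10, 0.25), CohortConfig(), seed=0)

    def test_marginal_moments_over_replicates(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(2)
        means, sds, rs = [], [], []
        for rep in range(300):
            e = rng.normal(0.26, 0.03, 39)
            cars = generate_cars(e, cfg, seed=int(rng.integers(2**31 - 1)))
            means.append(cars.mean())
            sds.append(cars.std(ddof=1))
            rs.append(np.corrcoef(e, cars)[0, 1])
        assert np.mean(means) == pytest.approx(33.67, abs=0.05)
        assert np.mean(sds) == pytest.approx(1.49, abs=0.05)
        # sample r carries the usual small-n attenuation; allow 2 MC SEs
        assert np.mean(rs) == pytest.approx(0.343, abs=0.03)


class TestMatrixToFibers:
    def test_single_exact_fiber_per_edge(self, triangle):
        recs = matrix_to_fibers(ConnectivityMatrix(triangle, subject_id="s"),
                                fibers_per_edge=1, spread=0.0)
        assert len(recs) == 3
        assert all(r.fa == 0.5 for r in recs)

    def test_record_count_scales_with_fibers_per_edge(self):
        cfg = calibrate_default_profile()
        topo = generate_topology(90, cfg.base_degree, cfg.rewire_prob, seed=5)
        W = ConnectivityMatrix(
            generate_subject_matrix(topo, cfg, "HC", seed=6), subject_id="s")
        recs = matrix_to_fibers(W, fibers_per_edge=3, spread=0.05, seed=7)
        assert len(recs) == 3 * 540

    @pytest.mark.parametrize("spread", [0.0, 0.05, 0.4])
    def test_roundtrip_recovers_matrix(self, spread):
        cfg = CohortConfig(**SMALL)
        topo = generate_topology(30, 6, 0.1, seed=8)
        W = ConnectivityMatrix(
            generate_subject_matrix(topo, cfg, "HC", seed=9), subject_id="s")
        recs = matrix_to_fibers(W, fibers_per_edge=4, spread=spread, seed=10)
        assert all(0 < r.fa <= 1 for r in recs)
        back = build_connectivity(recs, n_nodes=30)
        np.testing.assert_allclose(back.weights, W.weights, atol=1e-9)


class TestCalibration:
    def test_default_profile_is_packaged_config(self):
        assert calibrate_default_profile() == CohortConfig()

    def test_fit_weight_scale_reaches_target(self):
        cfg = CohortConfig(**SMALL, subject_jitter_sd=0.0, node_jitter_sd=0.0)
        target = 0.30
        fitted = fit_weight_scale(cfg, target, n_subjects=6, seed=1)
        topo = generate_topology(30, 6, 0.1, seed=99)
        eg = np.mean([global_efficiency(shortest_path_lengths(
            generate_subject_matrix(topo, fitted, "HC", seed=i)))
            for i in range(10)])
        assert eg == pytest.approx(target, rel=0.06)
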