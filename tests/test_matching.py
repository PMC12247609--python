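"""Exact 1-NN matcher vs its brute-force oracle, Wilson intervals, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reidsim as rs
from reidsim import matching


def _make_instance(seed, n_gallery=None, n_features=None, n_probes=8, sigma=1.5):
    rng = np.random.default_rng(seed)
    P = n_gallery or int(rng.integers(2, 30))
    d = n_features or int(rng.integers(2, 15))
    cfg = rs.PopulationConfig(P, d, seed=seed)
    gallery = rs.generate_gallery(cfg)
    idx = rng.integers(0, P, n_probes)
    probes = rs.generate_probes(gallery, rs.NoiseModel(sigma), idx, seed=seed + 1)
    return gallery, probes


def _probe_set(values, true_indices, sigma=0.0, seed=0):
    return rs.ProbeSet(
        values=np.asarray(values, dtype=np.float64),
        true_indices=np.asarray(true_indices),
        sigma=sigma,
        seed=seed,
    )


class TestNearestNeighbor:
    def test_zero_noise_perfect_accuracy(self, small_gallery):
        probes = rs.generate_probes(
            small_gallery, rs.NoiseModel(0.0), np.arange(157), seed=1
        )
        result = rs.nearest_neighbor_identify(probes, small_gallery)
        assert result.correct_flags.all()
        assert rs.estimate_accuracy(result).accuracy == 1.0

    def test_hand_enumerable_instance(self):
        # 5 gallery points in the plane, probes with known nearest rows
        cfg = rs.PopulationConfig(5, 2, seed=0)
        gallery = rs.FeatureMatrix(
            values=np.array(
                [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0], [5.0, 5.0]]
            ),
            config=cfg,
        )
        probes = _probe_set(
            [[1.0, 1.0], [9.0, 1.0], [4.9, 5.2], [10.0, 9.0], [-3.0, 0.1]],
            [0, 1, 4, 3, 0],
        )
        fast = rs.nearest_neighbor_identify(probes, gallery)
        slow = rs.brute_force_identify(probes, gallery)
        assert np.array_equal(fast.predicted_indices, [0, 1, 4, 3, 0])
        assert np.array_equal(slow.predicted_indices, fast.predicted_indices)
        assert fast.correct_flags.all()

    def test_equivalence_with_brute_force_on_random_instances(self):
        for seed in range(30):
            gallery, probes = _make_instance(seed)
            fast = rs.nearest_neighbor_identify(probes, gallery)
            slow = rs.brute_force_identify(probes, gallery)
            assert np.array_equal(fast.predicted_indices, slow.predicted_indices)

    def test_float32_scan_path_matches_brute_force(self, monkeypatch):
        # force the large-problem float32 scan on small instances, where the
        # float64 top-2 decision must still give exact argmin results
        monkeypatch.setattr(matching, "_FLOAT32_PAIR_THRESHOLD", 1)
        for seed in range(20):
            gallery, probes = _make_instance(seed + 1000, n_features=10)
            fast = rs.nearest_neighbor_identify(probes, gallery, chunk_rows=7)
            slow = rs.brute_force_identify(probes, gallery)
            assert np.array_equal(fast.predicted_indices, slow.predicted_indices)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(chunk=st.integers(1, 35), block=st.integers(1, 9))
    def test_chunk_invariance(self, chunk, block):
        gallery, probes = _make_instance(77, n_gallery=29, n_features=6)
        ref = rs.nearest_neighbor_identify(probes, gallery)
        out = rs.nearest_neighbor_identify(
            probes, gallery, chunk_rows=chunk, probe_block=block
        )
        assert np.array_equal(out.predicted_indices, ref.predicted_indices)

    def test_streamed_config_gallery_equals_materialised(self):
        cfg = rs.PopulationConfig(200, 25, seed=4)
        gallery = rs.generate_gallery(cfg)
        probes = rs.generate_probes(gallery, rs.NoiseModel(2.0), np.arange(0, 200, 3), seed=5)
        a = rs.nearest_neighbor_identify(probes, gallery, chunk_rows=64)
        b = rs.nearest_neighbor_identify(probes, cfg, chunk_rows=17)
        assert np.array_equal(a.predicted_indices, b.predicted_indices)

    def test_tie_broken_by_lowest_index(self):
        # probe exactly equidistant from rows 0 and 2 (collinear points)
        cfg = rs.PopulationConfig(3, 2, seed=0)
        gallery = rs.FeatureMatrix(
            values=np.array([[0.0, 0.0], [50.0, 50.0], [2.0, 0.0]]), config=cfg
        )
        probes = _probe_set([[1.0, 0.0]], [0])
        for fn in (rs.nearest_neighbor_identify, rs.brute_force_identify):
            assert fn(probes, gallery).predicted_indices[0] == 0

    def test_single_probe_single_row_gallery(self):
        cfg = rs.PopulationConfig(1, 4, seed=0)
        gallery = rs.generate_gallery(cfg)
        probes = _probe_set(gallery.values + 5.0, [0])
        assert rs.brute_force_identify(probes, gallery).predicted_indices[0] == 0
        assert rs.nearest_neighbor_identify(probes, gallery).predicted_indices[0] == 0

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(perm_seed=st.integers(0, 10_000))
    def test_permutation_equivariance(self, perm_seed):
        gallery, probes = _make_instance(55, n_gallery=20, n_features=8)
        base = rs.nearest_neighbor_identify(probes, gallery)
        perm = np.random.default_rng(perm_seed).permutation(20)
        inv = np.argsort(perm)
        permuted = rs.FeatureMatrix(values=gallery.values[perm], config=gallery.config)
        probes_p = _probe_set(probes.values, inv[probes.true_indices])
        out = rs.nearest_neighbor_identify(probes_p, permuted)
        assert np.array_equal(out.predicted_indices, inv[base.predicted_indices])

    def test_dimension_mismatch_and_empty_gallery_rejected(self, small_gallery):
        bad = _probe_set(np.zeros((2, 3)), [0, 1])
        with pytest.raises(ValueError):
            rs.nearest_neighbor_identify(bad, small_gallery)
        with pytest.raises(ValueError):
            rs.ProbeSet(values=np.zeros((0, 3)), true_indices=np.array([]), sigma=0, seed=0)

    def test_brute_force_rejects_large_instances(self):
        cfg = rs.PopulationConfig(2000, 1000, seed=0)
        gallery = rs.generate_gallery(cfg)
        probes = rs.generate_probes(gallery, rs.NoiseModel(1.0), np.arange(100), seed=1)
        with pytest.raises(ValueError):
            rs.brute_force_identify(probes, gallery)

    def test_chance_floor_at_extreme_noise(self):
        # accuracy ~ 1/P when the noise swamps the signal
        P, n = 5, 4000
        cfg = rs.PopulationConfig(P, 60, seed=8)
        gallery = rs.generate_gallery(cfg)
        idx = np.tile(np.arange(P), n // P)
        probes = rs.generate_probes(gallery, rs.NoiseModel(1e4), idx, seed=9)
        acc = rs.estimate_accuracy(rs.nearest_neighbor_identify(probes, gallery)).accuracy
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(acc - 1.0 / P) < 4 * se


def _wilson_oracle(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval, written out independently."""
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


class TestAccuracyEstimate:
    @pytest.mark.parametrize("k, n", [(0, 100), (59, 157), (157, 157), (1, 3)])
    def test_wilson_interval_matches_closed_form(self, k, n):
        result = rs.MatchResult(
            predicted_indices=np.zeros(n, dtype=np.int64),
            correct_flags=np.arange(n) < k,
            n_probes=n,
            gallery_size=157,
        )
        est = rs.estimate_accuracy(result, label="check")
        lo, hi = _wilson_oracle(k, n)
        assert est.accuracy == pytest.approx(k / n)
        assert est.ci_low == pytest.approx(lo, abs=1e-10)
        assert est.ci_high == pytest.approx(hi, abs=1e-10)
        assert est.ci_low <= est.accuracy <= est.ci_high

    def test_boundary_cases(self):
        zero = rs.MatchResult(np.zeros(100, dtype=np.int64), np.zeros(100, dtype=bool), 100, 5)
        est = rs.estimate_accuracy(zero)
        assert est.accuracy == 0.0 and est.ci_low == 0.0
        assert est.rule_of_three_upper == pytest.approx(0.03)
        full = rs.MatchResult(np.zeros(157, dtype=np.int64), np.ones(157, dtype=bool), 157, 157)
        est = rs.estimate_accuracy(full)
        assert est.accuracy == 1.0 and est.ci_high == 1.0
        assert est.rule_of_three_upper is None

    def test_estimates_csv_roundtrip(self, tmp_path):
        import pandas as pd

        res = rs.MatchResult(np.zeros(10, dtype=np.int64), np.arange(10) < 4, 10, 50)
        est = rs.estimate_accuracy(res, label="demo", sigma=2.0, seed=7)
        path = tmp_path / "acc.csv"
        rs.save_estimates_csv([est], path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "label", "gallery_size", "n_probes", "n_correct",
            "accuracy", "ci_low", "ci_high", "sigma", "seed",
        ]
        assert df.loc[0, "accuracy"] == pytest.approx(0.4)
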