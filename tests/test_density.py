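"""Map I/O, density simulation and map-model score behaviour."""

import numpy as np
import pytest

from slicefit.density import (DensityMap, FormatError, GeometryError,
                              cross_correlation, feature_vector, fsc_average,
                              mutual_information, overlap_scores, read_map,
                              simulate_map, simulate_on_grid, smoc, write_map)
from slicefit.synthetic import make_target_map
from slicefit.fitting import Placement

from conftest import build_model


def _random_map(shape=(32, 32, 32), seed=0, voxel=1.0):
    rng = np.random.default_rng(seed)
    return DensityMap(rng.standard_normal(shape).astype(np.float32),
                      np.full(3, voxel), np.zeros(3))


class TestMapIO:
    def test_round_trip_bit_faithful(self, tmp_path):
        dmap = _random_map((16, 16, 16), seed=3)
        back = read_map(write_map(dmap, tmp_path / "m.mrc"))
        np.testing.assert_array_equal(back.grid, dmap.grid)
        np.testing.assert_allclose(back.voxel_size, dmap.voxel_size,
                                   atol=1e-6)

    def test_anisotropic_voxels_and_origin_preserved(self, tmp_path):
        rng = np.random.default_rng(1)
        dmap = DensityMap(rng.random((8, 10, 12)).astype(np.float32),
                          [1.0, 1.5, 2.0], [5.0, -3.0, 7.5])
        back = read_map(write_map(dmap, tmp_path / "m.mrc"))
        np.testing.assert_allclose(back.voxel_size, [1.0, 1.5, 2.0],
                                   atol=1e-5)
        np.testing.assert_allclose(back.origin, [5.0, -3.0, 7.5], atol=1e-5)

    def test_non_mrc_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.mrc"
        bad.write_text("this is not a density map")
        with pytest.raises(FormatError):
            read_map(bad)


class TestSimulate:
    def test_single_atom_peak_at_node(self):
        model = build_model([80.0])
        model.chains[0].residues[0].atoms = \
            [model.chains[0].residues[0].atoms[0]]  # CA only
        ca = model.chains[0].residues[0].atoms[0]
        ca.xyz = np.array([10.0, 10.0, 10.0])
        dmap = simulate_map(model, voxel_size=1.0, resolution=4.0,
                            padding=6.0)
        peak = np.unravel_index(np.argmax(dmap.grid), dmap.shape)
        pos = dmap.origin + np.array(peak) * dmap.voxel_size
        np.testing.assert_allclose(pos, [10.0, 10.0, 10.0], atol=1e-6)

    def test_density_sum_is_atom_count(self):
        model = build_model([80.0] * 7)
        dmap = simulate_map(model, 1.0, 4.0, padding=8.0)
        assert dmap.grid.sum() == pytest.approx(model.n_atoms, rel=1e-3)

    def test_doubling_atoms_doubles_density(self):
        m1 = build_model([80.0] * 5)
        m2 = build_model([80.0] * 10)
        template = simulate_map(m2, 1.0, 4.0, padding=8.0)
        d1 = simulate_on_grid(m1, template, 4.0)
        d2 = simulate_on_grid(m2, template, 4.0)
        assert d2.grid.sum() == pytest.approx(2 * d1.grid.sum(), rel=1e-3)

    def test_linearity_in_atom_set(self):
        model = build_model([80.0] * 10)
        half1 = model.select(model.residue_keys()[:5])
        half2 = model.select(model.residue_keys()[5:])
        template = simulate_map(model, 1.5, 5.0, padding=8.0)
        total = simulate_on_grid(model, template, 5.0)
        parts = simulate_on_grid(half1, template, 5.0).grid + \
            simulate_on_grid(half2, template, 5.0).grid
        np.testing.assert_allclose(total.grid, parts, atol=1e-5)

    def test_whole_voxel_shift_moves_grid(self):
        model = build_model([80.0] * 4)
        template = simulate_map(model, 1.0, 4.0, padding=10.0)
        base = simulate_on_grid(model, template, 4.0)
        shifted_model = model.copy()
        for _, res in shifted_model.iter_residues():
            for a in res.atoms:
                a.xyz = a.xyz + np.array([1.0, 0.0, 0.0])
        shifted = simulate_on_grid(shifted_model, template, 4.0)
        np.testing.assert_allclose(shifted.grid[6:-6, 6:-6, 6:-6],
                                   base.grid[5:-7, 6:-6, 6:-6], atol=1e-5)

    def test_sub_nyquist_resolution_rejected(self):
        with pytest.raises(GeometryError):
            simulate_map(build_model([80.0]), voxel_size=2.0, resolution=3.0)


class TestCrossCorrelation:
    def test_self_is_one(self):
        a = _random_map()
        assert cross_correlation(a, a) == pytest.approx(1.0, abs=1e-10)

    def test_negation_is_minus_one(self):
        a = _random_map()
        neg = DensityMap(-a.grid, a.voxel_size, a.origin)
        assert cross_correlation(a, neg) == pytest.approx(-1.0, abs=1e-10)

    def test_independent_noise_near_zero(self):
        ccs = [abs(cross_correlation(_random_map(seed=2 * i),
                                     _random_map(seed=2 * i + 1)))
               for i in range(100)]
        assert max(ccs) < 0.05

    def test_zero_variance_rejected(self):
        a = _random_map((8, 8, 8))
        flat = DensityMap(np.ones((8, 8, 8)), a.voxel_size, a.origin)
        with pytest.raises(ValueError):
            cross_correlation(a, flat)

    def test_symmetry(self):
        a, b = _random_map(seed=5), _random_map(seed=6)
        assert cross_correlation(a, b) == pytest.approx(
            cross_correlation(b, a), abs=1e-12)


class TestMutualInformation:
    def test_self_equals_histogram_entropy(self):
        a = _random_map(seed=9)
        hist, _ = np.histogram(a.grid.ravel(), bins=20)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mutual_information(a, a, bins=20) == pytest.approx(
            entropy, abs=1e-9)

    def test_independent_noise_near_zero(self):
        vals = [mutual_information(_random_map(seed=100 + 2 * i),
                                   _random_map(seed=101 + 2 * i), bins=20)
                for i in range(100)]
        assert max(vals) < 0.05

    def test_symmetric_and_nonnegative(self):
        a, b = _random_map(seed=11), _random_map(seed=12)
        mab = mutual_information(a, b)
        assert mab == pytest.approx(mutual_information(b, a), abs=1e-12)
        assert mab >= 0

    def test_constant_map_is_zero(self):
        a = _random_map((8, 8, 8))
        flat = DensityMap(np.zeros((8, 8, 8)), a.voxel_size, a.origin)
        assert mutual_information(a, flat) == 0.0


class TestFSC:
    def test_self_is_one(self):
        a = _random_map((24, 24, 24), seed=13)
        assert fsc_average(a, a) == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_near_zero(self):
        vals = [fsc_average(_random_map(seed=300 + 2 * i),
                            _random_map(seed=301 + 2 * i))
                for i in range(20)]
        assert abs(np.mean(vals)) < 0.05

    def test_decreases_with_noise(self):
        model = build_model([80.0] * 20)
        clean = simulate_map(model, 1.0, 4.0, padding=6.0)
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(clean.shape).astype(np.float32)
        scale = float(clean.grid.std())
        prev = 1.1
        for amp in (0.0, 0.25, 0.5, 1.0, 2.0):
            noisy = DensityMap(clean.grid + amp * scale * noise,
                               clean.voxel_size, clean.origin,
                               clean.nominal_resolution)
            val = fsc_average(clean, noisy)
            assert val < prev
            prev = val


class TestSMOCAndOverlap:
    def test_self_smoc_is_one(self, planted_two_domain):
        model, _, _ = planted_two_domain
        ident = Placement("m", np.eye(3), np.zeros(3), 0.0)
        dmap = make_target_map([(model, ident)], voxel=2.0, resolution=6.0)
        per_res, mean = smoc(model, dmap)
        assert mean == pytest.approx(1.0, abs=1e-6)
        assert len(per_res) == model.n_residues
        assert all(v == pytest.approx(1.0, abs=1e-6)
                   for v in per_res.values())

    def test_zero_map_gives_zero(self, toy_model):
        sim = simulate_map(toy_model, 1.5, 5.0)
        zero = DensityMap(np.zeros(sim.shape), sim.voxel_size, sim.origin, 5.0)
        _, mean = smoc(toy_model, zero)
        assert mean == 0.0

    def test_displaced_domain_scores_drop_locally(self, planted_two_domain):
        model, labels, _ = planted_two_domain
        ident = Placement("m", np.eye(3), np.zeros(3), 0.0)
        dmap = make_target_map([(model, ident)], voxel=2.0, resolution=6.0)
        moved = model.copy()
        for cid, res in moved.iter_residues():
            if labels[(cid, res.number, res.insertion_code)] == 2:
                for a in res.atoms:
                    a.xyz = a.xyz + np.array([0.0, 20.0, 0.0])
        per_res, _ = smoc(moved, dmap)
        dom1 = [v for k, v in per_res.items() if labels[k] == 1]
        dom2 = [v for k, v in per_res.items() if labels[k] == 2]
        assert np.mean(dom1) > 0.9
        assert np.mean(dom2) < 0.5

    def test_overlap_saturation(self, planted_two_domain):
        model, _, _ = planted_two_domain
        ident = Placement("m", np.eye(3), np.zeros(3), 0.0)
        dmap = make_target_map([(model, ident)], voxel=2.0, resolution=6.0)
        omap, omodel = overlap_scores(model, dmap)
        assert omap == pytest.approx(1.0, abs=0.02)
        assert omodel == pytest.approx(1.0, abs=0.02)

    def test_half_model_covers_half_map(self, planted_two_domain):
        """A model for one of two equal domains: overlap_model ~ 1,
        overlap_map ~ 0.5."""
        model, labels, _ = planted_two_domain
        ident = Placement("m", np.eye(3), np.zeros(3), 0.0)
        dmap = make_target_map([(model, ident)], voxel=2.0, resolution=6.0)
        dom1 = model.select([k for k, v in labels.items() if v == 1])
        omap, omodel = overlap_scores(dom1, dmap)
        assert omodel > 0.85
        assert 0.3 < omap < 0.7

    def test_model_outside_footprint(self, planted_two_domain):
        model, _, _ = planted_two_domain
        ident = Placement("m", np.eye(3), np.zeros(3), 0.0)
        dmap = make_target_map([(model, ident)], voxel=2.0, resolution=6.0)
        far = model.copy()
        for _, res in far.iter_residues():
            for a in res.atoms:
                a.xyz = a.xyz + np.array([500.0, 0.0, 0.0])
        omap, omodel = overlap_scores(far, dmap)
        assert omap == 0.0 and omodel == 0.0


class TestFeatureVector:
    def test_perfect_placement_composite(self, planted_two_domain):
        model, _, _ = planted_two_domain
        ident = Placement("m", np.eye(3), np.zeros(3), 0.0)
        dmap = make_target_map([(model, ident)], voxel=2.0, resolution=6.0)
        vec = feature_vector(model, dmap)
        assert vec.cc == pytest.approx(1.0, abs=1e-3)
        assert vec.fsc_avg == pytest.approx(1.0, abs=1e-3)
        assert vec.smoc == pytest.approx(1.0, abs=1e-3)
        assert vec.overlap_map > 0.95 and vec.overlap_model > 0.95

    def test_far_placement_scores_low(self, planted_two_domain):
        model, _, _ = planted_two_domain
        ident = Placement("m", np.eye(3), np.zeros(3), 0.0)
        dmap = make_target_map([(model, ident)], voxel=2.0, resolution=6.0,
                               noise_sd=0.002)
        far = model.copy()
        for _, res in far.iter_residues():
            for a in res.atoms:
                a.xyz = a.xyz + np.array([0.0, 150.0, 0.0])
        vec = feature_vector(far, dmap)
        assert abs(vec.cc) < 0.1
        assert vec.overlap_map < 0.05 and vec.overlap_model < 0.05

    def test_field_order_is_stable(self):
        from slicefit.density import ScoreVector
        assert ScoreVector.FEATURES == ("fsc_avg", "mi", "cc", "smoc",
                                        "overlap_map", "overlap_model")
        v = ScoreVector(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, resolution=4.0)
        np.testing.assert_array_equal(v.as_array(),
                                      [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        np.testing.assert_array_equal(v.as_array(use_resolution=True),
                                      [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 4.0])
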