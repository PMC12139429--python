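"""The LCC engine against literal brute-force evaluation, plus its contracts."""

import numpy as np
import pytest

from tomopick import (
    RotationSet,
    Volume,
    default_template,
    generate_rotation_set,
    insert_density,
    local_std_map,
    make_spherical_mask,
    phase_randomize_template,
    prepare_template,
    run_template_matching,
    run_with_phase_randomization,
)
from tomopick.matching_engine import _embed_centered, _padded_rfftn

from _oracles import literal_lcc_map, sliding_local_std

import scipy.fft as sfft


def identity_rotation_set():
    return RotationSet(np.zeros((1, 3)), 180.0, 1, 1)


def rotation_set_with_identity(increment: float) -> RotationSet:
    """A coarse search set guaranteed to contain the identity triplet.

    HEALPix pixel centers never sit on the poles, so the generated sets do
    not include (0, 0, 0); self-match tests prepend it explicitly.
    """
    base = generate_rotation_set(increment).triplets
    triplets = np.vstack([np.zeros((1, 3)), base])
    return RotationSet(triplets, increment, len(triplets), 1)


class TestSphericalMask:
    def test_huge_radius_all_ones(self):
        m = make_spherical_mask(16, 16 * np.sqrt(3), smooth_sigma=0.0)
        assert np.all(m.data == 1.0)

    def test_center_voxel_always_inside(self):
        assert make_spherical_mask(16, 1.0).data[8, 8, 8] == 1.0

    def test_volume_matches_sphere_formula(self):
        m = make_spherical_mask(64, 20.0)
        expected = 4.0 / 3.0 * np.pi * 20.0 ** 3
        assert m.data.sum() == pytest.approx(expected, rel=0.02)

    def test_soft_edge_bounded(self):
        m = make_spherical_mask(24, 8.0, smooth_sigma=2.0)
        assert m.data.max() <= 1.0 and m.data.min() >= 0.0

    def test_radius_too_large(self):
        with pytest.raises(ValueError, match="too large"):
            make_spherical_mask(16, 40.0)


class TestPreparedTemplate:
    def test_normalization_contract(self, rng):
        t = Volume(rng.standard_normal((12, 12, 12)).astype(np.float32), 10.0)
        m = make_spherical_mask(12, 5.0)
        prep = prepare_template(t, m)
        p = m.data.sum()
        mean = (prep.data * m.data).sum() / p
        var = (prep.data ** 2 * m.data).sum() / p  # data is mask*(t-mean)/sigma
        assert abs(mean) < 1e-6
        assert var == pytest.approx(1.0, abs=1e-5)
        assert prep.P == pytest.approx(p)

    def test_zero_template_rejected(self):
        t = Volume(np.zeros((12, 12, 12), np.float32), 10.0)
        m = make_spherical_mask(12, 5.0)
        with pytest.raises(ValueError, match="variance"):
            prepare_template(t, m)

    def test_low_pass_weight_removes_high_frequencies(self, rng):
        """Parseval check: power above the cut-off shell is annihilated."""
        from tomopick.psf_models import FourierWeight
        box = 16
        t = Volume(rng.standard_normal((box,) * 3).astype(np.float32), 10.0)
        k = np.fft.fftfreq(box) * box
        r = np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2
                    + k[None, None, :] ** 2)
        weight = FourierWeight((r <= 4).astype(np.float64), box, 10.0, "composite")
        prep = prepare_template(t, make_spherical_mask(box, box, 0.0), weight)
        f = np.abs(sfft.fftn(prep.data)) ** 2
        assert f[r > 4.5].sum() / f.sum() < 1e-10


class TestLocalStdMap:
    def test_matches_brute_force(self, rng):
        v = rng.standard_normal((24, 24, 24)).astype(np.float32)
        m = make_spherical_mask(8, 3.0).data
        sigma, valid = local_std_map(v, m)
        ref = sliding_local_std(v, m)
        c = 4
        sl = (slice(c, 24 - c),) * 3
        np.testing.assert_allclose(sigma[sl], ref[sl], rtol=1e-5)
        assert valid[sl].all()

    def test_constant_tomogram_all_invalid(self):
        v = np.full((16, 16, 16), 3.0, dtype=np.float32)
        m = make_spherical_mask(8, 3.0).data
        sigma, valid = local_std_map(v, m)
        assert not valid.any()

    def test_single_voxel_mask_no_spread(self, rng):
        v = rng.standard_normal((16, 16, 16)).astype(np.float32)
        m = np.zeros((5, 5, 5), np.float32)
        m[2, 2, 2] = 1.0
        sigma, valid = local_std_map(v, m)
        assert not valid.any()

    def test_empty_mask_rejected(self, rng):
        v = rng.standard_normal((16, 16, 16)).astype(np.float32)
        with pytest.raises(ValueError, match="P = 0"):
            local_std_map(v, np.zeros((4, 4, 4), np.float32))


class TestPaddedFft:
    def test_equals_fft_of_embedded(self, rng):
        small = rng.standard_normal((12, 12, 12)).astype(np.float32)
        shape = (32, 24, 40)
        direct = sfft.rfftn(_embed_centered(small, shape).astype(np.float32))
        staged = _padded_rfftn(small, shape)
        np.testing.assert_allclose(staged, direct, atol=1e-4)


class TestRunTemplateMatching:
    def test_self_match_identity(self):
        t = default_template(16)
        mask = make_spherical_mask(16, 6.0, smooth_sigma=1.0)
        canvas = Volume(np.zeros((48, 48, 48), np.float32), 10.0)
        insert_density(canvas, t, (24, 24, 24))
        prep = prepare_template(t, mask)
        rots = rotation_set_with_identity(90.0)
        res = run_template_matching(canvas, prep, rots)
        assert res.lcc_max.data[24, 24, 24] >= 0.999
        best = res.best_rotation_index[24, 24, 24]
        np.testing.assert_allclose(rots.triplets[best], 0.0, atol=1e-9)

    def test_lcc_bounded(self, rng):
        v = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 10.0)
        t = Volume(rng.standard_normal((12, 12, 12)).astype(np.float32), 10.0)
        prep = prepare_template(t, make_spherical_mask(12, 5.0))
        rots = RotationSet(generate_rotation_set(60.0).triplets[:24], 60.0, 24, 1)
        res = run_template_matching(v, prep, rots)
        assert np.abs(res.lcc_max.data).max() <= 1.0 + 1e-3

    def test_fft_equals_literal_equation(self, random_volume, small_template,
                                         small_mask):
        """Oracle equivalence on a seeded 24-box with multiple rotations."""
        rots = generate_rotation_set(120.0).triplets[:4]
        prep = prepare_template(small_template, small_mask)
        res = run_template_matching(
            random_volume, prep, RotationSet(rots, 120.0, 4, 1))
        ref, ref_idx, _ = literal_lcc_map(
            random_volume.data, small_template.data, small_mask.data, rots)
        sl = res.region_slices()
        np.testing.assert_allclose(res.lcc_max.data[sl], ref[sl], atol=1e-5)

    def test_sigma_equals_direct_std(self, random_volume, small_template,
                                     small_mask):
        """Tracked sigma is the rms of all LCC values over the search."""
        rots = generate_rotation_set(120.0).triplets[:4]
        prep = prepare_template(small_template, small_mask)
        res = run_template_matching(
            random_volume, prep, RotationSet(rots, 120.0, 4, 1))
        _, _, values = literal_lcc_map(
            random_volume.data, small_template.data, small_mask.data, rots)
        direct = np.sqrt(np.mean(np.square(values)))
        assert res.sigma_background == pytest.approx(direct, rel=1e-4)

    def test_noise_ladder_degrades_score(self, rng):
        """lcc_max at the true site decreases as noise variance grows."""
        t = default_template(16)
        mask = make_spherical_mask(16, 6.0, smooth_sigma=1.0)
        scores = []
        for noise in (0.2, 0.8, 2.0):
            r = np.random.default_rng(11)
            canvas = Volume(
                r.normal(0, noise, (40, 40, 40)).astype(np.float32), 10.0)
            insert_density(canvas, t, (20, 20, 20))
            prep = prepare_template(t, mask)
            res = run_template_matching(canvas, prep, identity_rotation_set())
            scores.append(float(res.lcc_max.data[20, 20, 20]))
        assert scores[0] > scores[1] > scores[2]

    def test_template_larger_than_tomogram_rejected(self, rng):
        t = Volume(rng.standard_normal((16, 16, 16)).astype(np.float32), 10.0)
        v = Volume(rng.standard_normal((12, 12, 12)).astype(np.float32), 10.0)
        prep = prepare_template(t, make_spherical_mask(16, 6.0))
        with pytest.raises(ValueError, match="exceeds"):
            run_template_matching(v, prep, identity_rotation_set())

    def test_empty_rotation_set_rejected(self, random_volume, small_template,
                                         small_mask):
        prep = prepare_template(small_template, small_mask)
        with pytest.raises(ValueError, match="empty"):
            run_template_matching(
                random_volume, prep, RotationSet(np.zeros((0, 3)), 10.0, 0, 0))


class TestSelfMatchOrientation:
    def test_best_rotation_near_insertion_orientation(self):
        """The best rotation found is within one increment of the truth."""
        from tomopick.angular_search import euler_to_matrix
        t = default_template(16)
        mask = make_spherical_mask(16, 6.0, smooth_sigma=1.0)
        rots = generate_rotation_set(20.0)
        true_trip = tuple(rots.triplets[317])
        canvas = Volume(np.zeros((48, 48, 48), np.float32), 10.0)
        insert_density(canvas, t, (24, 24, 24), true_trip)
        prep = prepare_template(t, mask)
        res = run_template_matching(canvas, prep, rots)
        found = tuple(rots.triplets[res.best_rotation_index[24, 24, 24]])
        r_true = euler_to_matrix(*true_trip)
        r_found = euler_to_matrix(*found)
        angle = np.degrees(np.arccos(
            np.clip((np.trace(r_true.T @ r_found) - 1) / 2, -1, 1)))
        assert angle <= 20.0


class TestPhaseRandomization:
    def test_amplitudes_preserved(self, rng):
        t = Volume(rng.standard_normal((16, 16, 16)).astype(np.float32), 10.0)
        out = phase_randomize_template(t, seed=3)
        a0 = np.abs(np.fft.fftn(t.data.astype(np.float64)))
        a1 = np.abs(np.fft.fftn(out.data.astype(np.float64)))
        np.testing.assert_allclose(a1, a0, rtol=1e-5, atol=1e-4)

    def test_deterministic_under_seed(self, rng):
        t = Volume(rng.standard_normal((16, 16, 16)).astype(np.float32), 10.0)
        a = phase_randomize_template(t, seed=5)
        b = phase_randomize_template(t, seed=5)
        c = phase_randomize_template(t, seed=6)
        np.testing.assert_array_equal(a.data, b.data)
        assert np.any(a.data != c.data)

    def test_output_decorrelated_from_input(self):
        """Zero-lag normalized correlation collapses for a structured blob."""
        t = default_template(32)
        base = t.data - t.data.mean()
        corrs = []
        for seed in range(20):
            out = phase_randomize_template(t, seed=seed).data
            out = out - out.mean()
            corrs.append(abs(
                (base * out).sum()
                / np.sqrt((base ** 2).sum() * (out ** 2).sum())
            ))
        assert np.quantile(corrs, 0.95) < 0.2

    def test_non_cubic_rejected(self, rng):
        t = Volume(rng.standard_normal((8, 8, 10)).astype(np.float32), 10.0)
        with pytest.raises(ValueError, match="cubic"):
            phase_randomize_template(t, seed=0)


class TestRunWithPhaseRandomization:
    def test_mean_recentering(self, rng):
        """Corrected map keeps the original map's mean over the region."""
        v = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 10.0)
        t = default_template(12)
        prep = prepare_template(t, make_spherical_mask(12, 5.0, 1.0))
        corrected, original = run_with_phase_randomization(
            v, prep, identity_rotation_set(), seed=2)
        sl = corrected.region_slices()
        assert corrected.lcc_max.data[sl].mean() == pytest.approx(
            original.lcc_max.data[sl].mean(), abs=1e-6)

    def test_sigma_and_n_total_from_original(self, rng):
        v = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 10.0)
        t = default_template(12)
        prep = prepare_template(t, make_spherical_mask(12, 5.0, 1.0))
        corrected, original = run_with_phase_randomization(
            v, prep, identity_rotation_set(), seed=2)
        assert corrected.sigma_background == original.sigma_background
        assert corrected.n_total == original.n_total
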