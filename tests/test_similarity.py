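"""Hybrid similarity: log-Gabor bank, phase congruency, the five measures."""

import numpy as np
import pytest

from myodetect.similarity import (
    RegionSummary,
    SimilarityConfig,
    build_log_gabor_bank,
    hybrid_similarity,
    normalize_image,
    patch_stats,
    phase_congruency,
    region_summary,
    s_cm,
    s_dm,
    s_im,
    s_pm,
    s_sm,
)


class TestLogGaborBank:
    def test_unit_response_at_center_frequency(self):
        # a filter evaluated exactly at (omega0, theta_j) has both exponents 0
        bank = build_log_gabor_bank((64, 64), n_scales=1, n_orientations=1,
                                    min_wavelength=8.0)
        fy = np.fft.fftfreq(64)[:, None]
        fx = np.fft.fftfreq(64)[None, :]
        radius = np.hypot(fy, fx)
        # frequency bin closest to omega0=1/8 on the positive x axis (theta=0)
        idx = np.argmin(np.abs(np.fft.fftfreq(64) - 1 / 8))
        assert bank.filters[0, 0, 0, idx] == pytest.approx(1.0, abs=5e-2)
        assert bank.filters[0, 0].max() <= 1.0 + 1e-12

    def test_dc_bin_is_zero(self):
        bank = build_log_gabor_bank((32, 32))
        assert np.all(bank.filters[:, :, 0, 0] == 0.0)

    def test_filters_real_nonnegative(self):
        bank = build_log_gabor_bank((32, 48))
        assert np.isrealobj(bank.filters)
        assert bank.filters.min() >= 0.0

    def test_orientation_sum_rotation_invariant(self):
        # summed over orientations and antipodal pairs, the angular coverage
        # at a fixed radius is flat up to grid discretization
        bank = build_log_gabor_bank((64, 64), n_scales=1, n_orientations=6,
                                    min_wavelength=6.0)
        total = bank.filters[0].sum(axis=0)
        total = total + np.roll(np.roll(total[::-1, :], 1, 0)[:, ::-1], 1, 1)  # add antipode
        fy = np.fft.fftfreq(64)[:, None]
        fx = np.fft.fftfreq(64)[None, :]
        radius = np.hypot(fy, fx)
        ring = np.abs(radius - 1 / 6) < 0.01
        vals = total[ring]
        assert vals.std() / vals.mean() < 0.05

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            build_log_gabor_bank((32, 32), min_wavelength=0.0)


class TestPhaseCongruency:
    def test_flat_image_near_zero(self):
        pc = phase_congruency(np.full((64, 64), 0.5))
        assert pc.max() < 1e-6

    def test_step_edge_peaks_at_edge(self):
        img = np.zeros((128, 128))
        img[:, 64:] = 1.0
        pc = phase_congruency(img)
        row = pc[64]
        # interior columns only: FFT periodicity puts a second edge at the
        # image boundary
        interior = row[10:118]
        assert 52 <= np.argmax(interior) <= 55
        assert interior.max() > row[44]  # decays away from the edge

    def test_contrast_invariance_exact(self):
        img = np.zeros((128, 128))
        img[:, 64:] = 1.0
        pc1 = phase_congruency(img)
        pc2 = phase_congruency(3.7 * img + 11.0)
        assert np.abs(pc1 - pc2).max() < 1e-12

    def test_range_and_shape_guard(self):
        img = np.random.default_rng(0).uniform(size=(64, 64))
        pc = phase_congruency(img)
        assert pc.min() >= 0.0 and pc.max() <= 1.0
        bank = build_log_gabor_bank((32, 32))
        with pytest.raises(ValueError):
            phase_congruency(img, bank)


class TestPointMeasures:
    def test_spm_identical_and_zero(self):
        assert s_pm(0.4, 0.4, 0.01) == pytest.approx(1.0)
        assert s_pm(0.0, 0.0, 0.01) == pytest.approx(1.0)

    def test_spm_worked_example(self):
        assert s_pm(1.0, 0.0, 0.01) == pytest.approx(0.01 / 1.01, rel=1e-12)

    def test_sim_worked_example(self):
        assert s_im(0.7, 0.7, 1e-4) == pytest.approx(1.0)
        assert s_im(3.0, 1.0, 1e-12) == pytest.approx(0.6, rel=1e-9)

    def test_sim_monotone_in_difference(self):
        # fixed sum, growing gap -> decreasing similarity
        vals = [s_im(2 + d, 2 - d, 1e-4) for d in np.linspace(0, 1.5, 10)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_scm_examples(self):
        assert s_cm(1.3, 1.3, 1e-4) == pytest.approx(1.0)
        assert s_cm(2.0, 0.0, 0.01) == pytest.approx(0.01 / 4.01, rel=1e-12)

    def test_scm_high_base_contrast_less_sensitive(self):
        assert s_cm(10, 11, 0.01) > s_cm(1, 2, 0.01)

    def test_sdm(self):
        assert s_dm((3, 4), (3, 4), 0.5) == pytest.approx(1.0)
        assert s_dm((1, 1), (9, 9), 0.0) == pytest.approx(1.0)
        assert s_dm((0, 0), (0, 1), np.log(2)) == pytest.approx(0.5, rel=1e-12)


class TestStructureMeasure:
    def test_self_similarity(self, rng):
        p = rng.uniform(size=(5, 5))
        assert s_sm(p, p, 1e-4) == pytest.approx(1.0, abs=1e-3)

    def test_anticorrelation_is_full_similarity(self, rng):
        p = rng.uniform(size=(5, 5))
        q = -p + 2.0
        assert s_sm(p, q, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_patterns_near_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert s_sm(a, b, 1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            s_sm(np.ones(4), np.ones(9))


class TestPatchStats:
    def test_constant_patch(self):
        img = np.full((20, 20), 0.5)
        st = patch_stats(img, (10, 10), p=9)
        assert st.mean == pytest.approx(0.5)
        assert st.std == pytest.approx(0.0)

    def test_hand_arithmetic_3x3(self):
        img = np.zeros((9, 9))
        img[3:6, 3:6] = np.arange(1, 10).reshape(3, 3)
        st = patch_stats(img, (4, 4), p=3)
        assert st.mean == pytest.approx(5.0)
        assert st.std**2 == pytest.approx(7.5)  # d-1 = 8 denominator

    def test_mirror_border_symmetry(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(16, 16))
        corner = patch_stats(img, (0, 0), p=5)
        # mirroring reflects interior values: the mean uses only valid pixels
        # duplicated symmetrically, so it matches the reflected interior patch
        inner = patch_stats(img, (2, 2), p=5)
        assert corner.patch.shape == inner.patch.shape == (5, 5)
        assert corner.mean == pytest.approx(
            np.mean(np.pad(img, 2, mode="reflect")[0:5, 0:5])
        )

    def test_even_patch_rejected(self):
        with pytest.raises(ValueError):
            patch_stats(np.ones((8, 8)), (4, 4), p=4)


class TestHybridSimilarity:
    def test_self_similarity_is_one(self, default_slice):
        _, s = default_slice
        img = normalize_image(s.image)
        pc = phase_congruency(img)
        cfg = SimilarityConfig(alpha=0.01)
        val = hybrid_similarity((40, 40), (40, 40), cfg, image=img, pc_map=pc)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_zero_exponents_give_one(self, default_slice):
        _, s = default_slice
        img = normalize_image(s.image)
        pc = phase_congruency(img)
        cfg = SimilarityConfig(beta=(0, 0, 0, 0, 0))
        assert hybrid_similarity((30, 30), (80, 90), cfg, image=img, pc_map=pc) == 1.0

    def test_equals_product_of_terms(self, default_slice):
        _, s = default_slice
        img = normalize_image(s.image)
        pc = phase_congruency(img)
        cfg = SimilarityConfig(alpha=0.005)
        u, v = (40, 45), (52, 60)
        su = patch_stats(img, u, cfg.p)
        sv = patch_stats(img, v, cfg.p)
        expected = (
            s_pm(pc[u], pc[v], cfg.c1)
            * s_im(su.mean, sv.mean, cfg.c2)
            * s_cm(su.std, sv.std, cfg.c3)
            * s_sm(su.patch, sv.patch, cfg.c4)
            * s_dm(np.array(u, float), np.array(v, float), cfg.alpha)
        )
        got = hybrid_similarity(u, v, cfg, image=img, pc_map=pc)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_patch_and_region(self, default_slice, rng):
        _, s = default_slice
        img = normalize_image(s.image)
        pc = phase_congruency(img)
        cfg = SimilarityConfig(alpha=0.01)
        for _ in range(10):
            u = tuple(rng.integers(5, 120, 2))
            v = tuple(rng.integers(5, 120, 2))
            assert hybrid_similarity(u, v, cfg, image=img, pc_map=pc) == pytest.approx(
                hybrid_similarity(v, u, cfg, image=img, pc_map=pc), rel=1e-12
            )
        m1 = img > 0.5
        m2 = ~m1
        ra = region_summary(img, m1, pc)
        rb = region_summary(img, m2, pc)
        assert hybrid_similarity(ra, rb, cfg, mode="region") == pytest.approx(
            hybrid_similarity(rb, ra, cfg, mode="region"), rel=1e-12
        )

    def test_range_property(self, default_slice, rng):
        _, s = default_slice
        img = normalize_image(s.image)
        pc = phase_congruency(img)
        cfg = SimilarityConfig(alpha=0.02)
        for _ in range(20):
            u = tuple(rng.integers(5, 120, 2))
            v = tuple(rng.integers(5, 120, 2))
            val = hybrid_similarity(u, v, cfg, image=img, pc_map=pc)
            assert 0.0 < val <= 1.0

    def test_empty_region_rejected(self, default_slice):
        _, s = default_slice
        img = normalize_image(s.image)
        with pytest.raises(ValueError):
            region_summary(img, np.zeros_like(img, dtype=bool), img)
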