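"""Optical flow, optical strain, LBP and apex-spotting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from mexflow import (
    FlowField,
    FrameSequence,
    InputError,
    RoiSpec,
    StrainMap,
    SyntheticSpec,
    chi2_distance,
    compute_optical_flow,
    flow_to_triplet,
    lbp_histogram,
    locate_apex,
    make_sequence,
    optical_strain,
    preprocess_sample,
    true_apex_index,
)
from mexflow.preprocess import (
    DegenerateSignalWarning,
    N_LBP_BINS,
    PreprocessConfig,
    _NEIGHBOURS,
    _UNIFORM_LUT,
)


def _texture(rng, shape=(64, 64)):
    img = gaussian_filter(rng.standard_normal(shape), 2.0)
    return (img - img.min()) / (img.max() - img.min())


# ---------------------------------------------------------------------------
# optical flow
# ---------------------------------------------------------------------------

class TestOpticalFlow:
    def test_identical_frames_give_zero_flow(self, rng):
        img = _texture(rng)
        flow = compute_optical_flow(img, img)
        assert np.abs(flow.u).max() < 1e-3
        assert np.abs(flow.v).max() < 1e-3

    def test_integer_translation_recovered(self, rng):
        img = _texture(rng)
        shifted = np.roll(img, 2, axis=1)  # content moves +2 columns
        flow = compute_optical_flow(img, shifted)
        interior = (slice(8, -8), slice(8, -8))
        assert abs(np.median(flow.u[interior]) - 2.0) <= 0.25
        assert abs(np.median(flow.v[interior])) <= 0.25

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            compute_optical_flow(np.zeros((64, 64)), np.zeros((32, 32)))

    def test_constant_images_give_zero_field(self):
        flow = compute_optical_flow(np.full((16, 16), 0.5), np.full((16, 16), 0.5))
        assert np.all(flow.u == 0) and np.all(flow.v == 0)


# ---------------------------------------------------------------------------
# optical strain
# ---------------------------------------------------------------------------

class TestOpticalStrain:
    def test_rigid_translation_has_zero_strain(self):
        flow = FlowField(u=np.full((16, 16), 1.7), v=np.full((16, 16), -0.3))
        assert np.all(optical_strain(flow).os == 0)

    def test_linear_field_closed_form(self):
        # u = 0.1 x, v = 0.2 y: e_xx = 0.1, e_yy = 0.2, e_xy = 0
        yy, xx = np.mgrid[0:16, 0:16].astype(float)
        strain = optical_strain(FlowField(u=0.1 * xx, v=0.2 * yy))
        expected = np.sqrt(0.01 + 0.04)
        assert np.allclose(strain.os, expected, atol=1e-9)

    def test_simple_shear_closed_form(self):
        # u = 0.2 y, v = 0: e_xy = 0.1, os = sqrt(2 * 0.01)
        yy, xx = np.mgrid[0:16, 0:16].astype(float)
        strain = optical_strain(FlowField(u=0.2 * yy, v=np.zeros((16, 16))))
        assert np.allclose(strain.os, np.sqrt(0.02), atol=1e-9)

    def test_polynomial_field_matches_analytic_gradient(self):
        # quadratic field: central differences are exact for degree <= 2
        yy, xx = np.mgrid[0:24, 0:24].astype(float)
        u = 0.01 * xx ** 2 + 0.02 * xx * yy
        v = -0.015 * yy ** 2 + 0.005 * xx
        e_xx = 0.02 * xx + 0.02 * yy
        e_yy = -0.03 * yy
        e_xy = 0.5 * ((0.02 * xx) + 0.005)
        expected = np.sqrt(e_xx ** 2 + e_yy ** 2 + 2 * e_xy ** 2)
        got = optical_strain(FlowField(u=u, v=v)).os
        interior = (slice(1, -1), slice(1, -1))
        assert np.allclose(got[interior], expected[interior], atol=1e-9)

    def test_too_small_field_rejected(self):
        with pytest.raises(InputError):
            optical_strain(FlowField(u=np.zeros((2, 2)), v=np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# triplet assembly
# ---------------------------------------------------------------------------

class TestFlowToTriplet:
    def test_contract_shape_and_range(self, rng):
        u = rng.standard_normal((40, 40))
        v = rng.standard_normal((40, 40))
        flow = FlowField(u=u, v=v)
        trip = flow_to_triplet(flow, optical_strain(flow), size=28)
        assert trip.channels.shape == (3, 28, 28)
        assert trip.channels.min() >= 0 and trip.channels.max() <= 1

    def test_constant_channel_maps_to_half(self):
        flow = FlowField(u=np.full((30, 30), 5.0), v=np.zeros((30, 30)))
        trip = flow_to_triplet(flow, optical_strain(flow), size=28)
        assert np.allclose(trip.channels, 0.5)

    def test_minmax_endpoints_without_resize(self):
        u = np.zeros((28, 28))
        u[3, 4] = -1.0
        u[20, 21] = 1.0
        flow = FlowField(u=u, v=np.zeros((28, 28)))
        trip = flow_to_triplet(flow, optical_strain(flow), size=28)
        assert trip.channels[0, 3, 4] == 0.0
        assert trip.channels[0, 20, 21] == 1.0

    def test_normalization_is_idempotent_in_range(self, rng):
        u = rng.random((28, 28))
        flow = FlowField(u=u, v=rng.random((28, 28)))
        strain = optical_strain(flow)
        t1 = flow_to_triplet(flow, strain, size=28)
        f2 = FlowField(u=t1.channels[0].astype(float),
                       v=t1.channels[1].astype(float))
        t2 = flow_to_triplet(f2, StrainMap(os=t1.channels[2].astype(float)),
                             size=28)
        assert np.allclose(t1.channels[:2], t2.channels[:2], atol=1e-6)


# ---------------------------------------------------------------------------
# LBP + chi-squared
# ---------------------------------------------------------------------------

def _brute_force_lbp_histogram(region: np.ndarray) -> np.ndarray:
    """Independent per-pixel oracle for the uniform LBP(8, 1) histogram."""
    h, w = region.shape
    hist = np.zeros(N_LBP_BINS)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for bit, (dr, dc) in enumerate(_NEIGHBOURS):
                if region[r + dr, c + dc] >= region[r, c]:
                    code |= 1 << bit
            hist[_UNIFORM_LUT[code]] += 1
    return hist / hist.sum()


class TestLBP:
    def test_histogram_is_normalized_and_nonnegative(self, rng):
        h = lbp_histogram(rng.random((12, 12)))
        assert h.shape == (59,)
        assert np.all(h >= 0)
        assert np.isclose(h.sum(), 1.0)

    def test_constant_region_concentrates_in_all_ones_bin(self):
        h = lbp_histogram(np.full((10, 10), 3.0))
        all_ones_bin = _UNIFORM_LUT[255]
        assert h[all_ones_bin] == 1.0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(3, 8), st.integers(3, 8))
    def test_matches_brute_force_on_random_images(self, seed, h, w):
        region = np.random.default_rng(seed).integers(0, 256, size=(h, w))
        assert np.allclose(lbp_histogram(region),
                           _brute_force_lbp_histogram(region))

    def test_too_small_region_rejected(self):
        with pytest.raises(InputError):
            lbp_histogram(np.zeros((2, 5)))


class TestChi2:
    def test_identical_histograms_give_zero(self, rng):
        h = rng.random(59)
        h /= h.sum()
        assert chi2_distance(h, h) == 0.0

    def test_disjoint_one_hots_give_two(self):
        h1 = np.zeros(59)
        h2 = np.zeros(59)
        h1[0] = 1.0
        h2[1] = 1.0
        assert np.isclose(chi2_distance(h1, h2), 2.0, atol=1e-8)

    def test_symmetry(self, rng):
        a, b = rng.random(59), rng.random(59)
        a /= a.sum()
        b /= b.sum()
        assert np.isclose(chi2_distance(a, b), chi2_distance(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            chi2_distance(np.ones(59) / 59, np.ones(10) / 10)


# ---------------------------------------------------------------------------
# apex spotting
# ---------------------------------------------------------------------------

class TestLocateApex:
    def test_tent_ramp_sequence_found_within_one_frame(self):
        spec = SyntheticSpec(image_size=(68, 56), seq_len=20, apex_frac=0.6,
                             seed=5)
        seq = make_sequence(spec, 0, 0, np.random.default_rng(5))
        est = locate_apex(seq)
        assert abs(est - true_apex_index(spec)) <= 1

    def test_two_frames_rejected(self):
        frames = [np.zeros((10, 10)), np.ones((10, 10))]
        seq = FrameSequence(frames=frames, subject_id="s")
        with pytest.raises(InputError):
            locate_apex(seq)

    def test_monotone_signal_returns_last_index(self, rng, monkeypatch):
        # bypass image analysis: feed a strictly increasing difference signal
        from mexflow import preprocess as pp

        d = np.linspace(0, 1, 15)[None, :].repeat(3, axis=0)
        monkeypatch.setattr(pp, "_roi_difference_signal", lambda s, r: d)
        frames = [rng.random((12, 12)) for _ in range(15)]
        seq = FrameSequence(frames=frames, subject_id="s")
        assert locate_apex(seq) == 14

    def test_dc_equals_exhaustive_argmax_on_unimodal_signals(self, rng,
                                                             monkeypatch):
        from mexflow import preprocess as pp

        frames = [rng.random((12, 12)) for _ in range(24)]
        seq = FrameSequence(frames=frames, subject_id="s")
        for peak in range(2, 23):
            t = np.arange(24, dtype=float)
            sig = 1.0 - np.abs(t - peak) / 24.0
            sig[0] = 0.0
            d = sig[None, :].repeat(3, axis=0)
            monkeypatch.setattr(pp, "_roi_difference_signal", lambda s, r, d=d: d)
            assert locate_apex(seq) == int(np.argmax(sig[1:])) + 1

    def test_identical_frames_warn_and_return_one(self):
        frames = [np.full((20, 20), 0.3)] * 6
        seq = FrameSequence(frames=frames, subject_id="s")
        with pytest.warns(DegenerateSignalWarning):
            assert locate_apex(seq) == 1


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

class TestPreprocessSample:
    def test_given_apex_skips_spotting(self, rng, monkeypatch):
        from mexflow import preprocess as pp

        calls = {"n": 0}
        real = pp.locate_apex

        def counting(*a, **k):
            calls["n"] += 1
            return real(*a, **k)

        monkeypatch.setattr(pp, "locate_apex", counting)
        frames = [_texture(rng, (34, 28)) for _ in range(4)]
        seq = FrameSequence(frames=frames, subject_id="s", apex_idx=2)
        pp.preprocess_sample(seq, PreprocessConfig(frame_size=(34, 28)))
        assert calls["n"] == 0

    def test_onset_equals_apex_gives_all_half_triplet(self, rng):
        img = _texture(rng, (34, 28))
        seq = FrameSequence(frames=[img, img.copy(), img.copy()],
                            subject_id="s", apex_idx=1)
        trip = preprocess_sample(seq, PreprocessConfig(frame_size=(34, 28)))
        assert np.allclose(trip.channels, 0.5, atol=1e-3)

    def test_moving_region_dominates_u_channel(self):
        spec = SyntheticSpec(image_size=(68, 56), seed=11, noise_sd=0.0,
                             subject_effect_sd=0.0,
                             motion_loci=[[(0.5, 0.3, 0.12, 0.0)]] * 3)
        seq = make_sequence(spec, 0, 0, np.random.default_rng(11))
        trip = preprocess_sample(seq, PreprocessConfig(frame_size=(68, 56)))
        u = trip.channels[0]
        moved = u[10:18, 4:12]     # around the locus (0.5, 0.3) at 28x28
        static = u[2:8, 20:26]
        assert moved.mean() > static.mean()
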