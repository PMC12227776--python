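"""Synthetic task generators: Gabor rendering and label bookkeeping,
corruptions, and visuomotor streams."""

import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate

from laminar.tasks import (
    GaborTaskSpec,
    VisuomotorSpec,
    admissible_contexts,
    corrupt_noise,
    gabor_sequence,
    occlude,
    render_gabor,
    shift_position,
    visuomotor_stream,
)


class TestRenderGabor:
    def test_pixels_in_unit_interval(self):
        img = render_gabor(36.0, 0.2, 4.0, 6.0)
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert img.shape == (784,)

    def test_half_turn_symmetry(self):
        a = render_gabor(20.0, 0.25, 5.0, 3.0)
        b = render_gabor(200.0, 0.25, 5.0, 3.0)
        assert np.allclose(a, b, atol=1e-12)

    def test_rotation_oracle(self):
        """Rendering at 18 deg matches rotating the 0-deg image by -18 deg
        (up to interpolation error near the borders)."""
        base = render_gabor(0.0, 0.2, 5.0, 5.0).reshape(28, 28)
        target = render_gabor(18.0, 0.2, 5.0, 5.0).reshape(28, 28)
        rotated = nd_rotate(base, -18.0, reshape=False, order=3, mode="nearest")
        inner = np.s_[6:22, 6:22]
        assert np.abs(rotated[inner] - target[inner]).mean() < 0.05

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            render_gabor(0.0, 0.2, 0.0, 5.0)

    def test_deterministic(self):
        assert np.array_equal(
            render_gabor(54.0, 0.18, 4.2, 7.1), render_gabor(54.0, 0.18, 4.2, 7.1)
        )


class TestGaborSequence:
    def test_transition_rule_replay(self):
        """Independent replay of the context-driven orientation walk."""
        seq = gabor_sequence(GaborTaskSpec(seed=5), 500)
        for t in range(499):
            shift = seq.context_labels[t] - 1
            assert seq.orientation_labels[t + 1] == seq.orientation_labels[t] + shift
            assert 0 <= seq.orientation_labels[t + 1] < 10

    def test_boundary_classes_have_two_successors(self):
        seq = gabor_sequence(GaborTaskSpec(seed=1), 3000)
        at0 = seq.context_labels[seq.orientation_labels == 0]
        at9 = seq.context_labels[seq.orientation_labels == 9]
        assert at0.size > 0 and at9.size > 0
        assert set(np.unique(at0)) <= {1, 2}  # never rotate below 0
        assert set(np.unique(at9)) <= {0, 1}  # never rotate past the top
        assert list(admissible_contexts(0, 10)) == [1, 2]
        assert list(admissible_contexts(9, 10)) == [0, 1]

    def test_context_frequencies_uniform_within_3_sigma(self):
        seq = gabor_sequence(GaborTaskSpec(seed=2), 9000)
        interior = (seq.orientation_labels > 0) & (seq.orientation_labels < 9)
        ctx = seq.context_labels[interior]
        n = ctx.size
        for k in range(3):
            p_hat = np.mean(ctx == k)
            assert abs(p_hat - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_bitwise_deterministic_in_seed(self):
        a = gabor_sequence(GaborTaskSpec(seed=3), 50)
        b = gabor_sequence(GaborTaskSpec(seed=3), 50)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.context_labels, b.context_labels)

    def test_triples_use_generating_context(self):
        seq = gabor_sequence(GaborTaskSpec(seed=4), 10)
        for k, (x_prev, x_t, itd) in enumerate(seq.triples()):
            t = k + 1
            assert np.array_equal(x_prev, seq.frames[t - 1])
            assert np.array_equal(x_t, seq.frames[t])
            assert itd[seq.context_labels[t - 1]] == 1.0

    def test_round_trip_save_load(self, tmp_path):
        seq = gabor_sequence(GaborTaskSpec(seed=6), 20)
        from laminar.tasks import GaborSequence

        seq.save(tmp_path / "seq.h5")
        back = GaborSequence.load(tmp_path / "seq.h5")
        assert np.array_equal(back.frames, seq.frames)
        assert back.spec == seq.spec


class TestCorruptions:
    def test_zero_noise_is_identity_and_nondestructive(self):
        frames = gabor_sequence(GaborTaskSpec(seed=7), 5).frames
        orig = frames.copy()
        out = corrupt_noise(frames, 0.0)
        assert np.array_equal(out, frames)
        out2 = corrupt_noise(frames, 0.8, seed=1)
        assert np.array_equal(frames, orig)
        assert not np.array_equal(out2, frames)

    def test_noise_variance_matches_level(self):
        frames = np.zeros((40, 784))
        lam = 1.0
        out = corrupt_noise(frames, lam, seed=2)
        n = out.size
        var = out.var()
        assert abs(var - lam**2) < 3 * np.sqrt(2.0 / n)  # chi^2 bound

    def test_occlusion_zeroes_patch_exactly(self):
        frames = np.full((6, 784), 0.7)
        out, coords = occlude(frames, patch_size=10, seed=0)
        for k, (r, c) in enumerate(coords):
            img = out[k].reshape(28, 28)
            assert np.all(img[r : r + 10, c : c + 10] == 0.0)
            n_zero = (img == 0).sum()
            assert n_zero == 100

    def test_full_occlusion_blanks_frame(self):
        frames = np.full((2, 784), 0.3)
        out, _ = occlude(frames, patch_size=28, seed=0)
        assert np.all(out == 0.0)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            occlude(np.zeros((1, 784)), patch_size=29)

    def test_occluded_fraction_matches_patch_area(self):
        frames = np.full((400, 784), 0.5)
        out, _ = occlude(frames, patch_size=10, seed=3)
        frac = (out == 0).mean()
        assert frac == pytest.approx(100 / 784, abs=1e-9)


class TestShiftPosition:
    def test_zero_shift_equals_plain_sequence(self):
        spec = GaborTaskSpec(seed=8)
        a = shift_position(spec, 15, shift_range=0.0)
        b = gabor_sequence(spec, 15)
        assert np.array_equal(a.frames, b.frames)

    def test_labels_unaffected_by_shifting(self):
        spec = GaborTaskSpec(seed=8)
        a = shift_position(spec, 30, shift_range=5.0)
        b = gabor_sequence(spec, 30)
        assert np.array_equal(a.orientation_labels, b.orientation_labels)
        assert np.array_equal(a.context_labels, b.context_labels)
        assert not np.array_equal(a.frames, b.frames)

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValueError):
            shift_position(GaborTaskSpec(seed=0), 5, shift_range=20.0)


class TestVisuomotor:
    def test_speed_increments_uniform_within_3_sigma(self):
        spec = VisuomotorSpec(seed=0, mismatch_rate=0.0, speed_max=1e9)
        s = visuomotor_stream(spec, 9001).speed
        inc = np.rint(np.diff(s)).astype(int)
        n = inc.size
        for k in (-1, 0, 1):
            p_hat = np.mean(inc == k)
            assert abs(p_hat - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_speed_reflected_into_range(self):
        spec = VisuomotorSpec(seed=1, mismatch_rate=0.0)
        s = visuomotor_stream(spec, 5000).speed
        assert s.min() >= 0.0 and s.max() <= spec.speed_max

    def test_noiseless_linear_coupling_broadcasts_speed(self):
        spec = VisuomotorSpec(seed=2, noise_sd=0.0, mismatch_rate=0.0)
        st = visuomotor_stream(spec, 1000)
        assert np.allclose(st.flow, st.speed[:, None])

    def test_mismatch_windows_exact_length_and_zero_flow(self):
        spec = VisuomotorSpec(seed=3, mismatch_rate=0.01, mismatch_len=600)
        st = visuomotor_stream(spec, 20000)
        mask = st.mismatch_mask
        assert mask.any()
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        lengths = edges[1::2] - edges[::2]
        assert np.all(lengths == 600)
        assert np.all(st.flow[mask] == 0.0)

    def test_open_loop_probe_structure(self):
        spec = VisuomotorSpec(
            seed=4, loop_mode="open", mismatch_rate=0.01, mismatch_len=60
        )
        st = visuomotor_stream(spec, 8000)
        assert st.mismatch_mask.any()
        assert st.baseline_exclude is not None
        # zero-flow stretch right before each probe; flow on inside
        starts = np.flatnonzero(np.diff(st.mismatch_mask.astype(int)) == 1) + 1
        for s0 in starts:
            assert np.all(st.flow[s0 - 60 : s0] == 0.0)
            assert np.any(st.flow[s0 : s0 + 60] != 0.0)

    def test_sine_coupling(self):
        spec = VisuomotorSpec(
            seed=5, coupling="sine", noise_sd=0.0, mismatch_rate=0.0, mismatch_len=100
        )
        st = visuomotor_stream(spec, 1000)
        assert np.allclose(st.flow, np.sin(st.speed)[:, None])

    def test_deterministic_in_seed(self):
        spec = VisuomotorSpec(seed=6)
        a = visuomotor_stream(spec, 3000)
        b = visuomotor_stream(spec, 3000)
        assert np.array_equal(a.flow, b.flow)
        assert np.array_equal(a.mismatch_mask, b.mismatch_mask)

    def test_too_short_stream_rejected(self):
        with pytest.raises(ValueError):
            visuomotor_stream(VisuomotorSpec(seed=0), 100)
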