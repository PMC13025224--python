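"""Time-frequency images: scalogram localisation, STFT configuration,
aggregate-spectrogram linearity, normalisation, fusion, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegtfr.synthetic import ToneSpec, generate_tones
from eegtfr.tfr import (CWTConfig, STFTConfig, TFImage,
                        aggregate_vmd_spectrogram, cwt_scalogram, fuse,
                        image_filename, jet_lut, minmax_normalise,
                        parse_image_filename, render_rgb, resample_image,
                        stft_spectrogram)


def _img(values, repr="CWT", **meta):
    values = np.asarray(values, float)
    return TFImage(values=values, time_axis=np.arange(values.shape[1], dtype=float),
                   freq_axis=np.arange(values.shape[0], dtype=float) + 1.0,
                   repr=repr, **meta)


class TestCWT:
    def test_tone_row_within_half_voice(self):
        x = generate_tones(ToneSpec(frequencies=[10.0], fs=512.0, duration_s=15.0))
        img = cwt_scalogram(x, 512.0)
        peak_freq = img.freq_axis[img.values.mean(axis=1).argmax()]
        assert 10.0 / 2 ** (1 / 12) <= peak_freq <= 10.0 * 2 ** (1 / 12)

    def test_zero_signal_and_homogeneity(self):
        z = cwt_scalogram(np.zeros(4096), 512.0)
        assert np.all(z.values == 0)
        x = generate_tones(ToneSpec(frequencies=[7.0, 30.0], fs=512.0, duration_s=8.0))
        a = cwt_scalogram(x, 512.0)
        b = cwt_scalogram(2 * x, 512.0)
        np.testing.assert_allclose(b.values, 2 * a.values, rtol=1e-12)

    def test_energy_concentrated_near_tone_row(self):
        """At least half of the scalogram energy lies within two voices of a
        pure tone's row.  (The omega0=6 Morlet has a relative frequency
        resolution of 1/6, i.e. about three voices at 12 voices/octave, so a
        one-voice window cannot hold half the energy for any input.)"""
        x = generate_tones(ToneSpec(frequencies=[12.0], fs=512.0, duration_s=15.0))
        img = cwt_scalogram(x, 512.0)
        e = (img.values ** 2).sum(axis=1)
        near = np.abs(np.log2(img.freq_axis / 12.0)) <= 2 / 12 + 1e-9
        assert e[near].sum() / e.sum() >= 0.5

    def test_grid_covers_requested_band_log_spaced(self):
        img = cwt_scalogram(np.zeros(2048), 512.0, CWTConfig())
        assert img.freq_axis[0] >= 2.0 and img.freq_axis[-1] == 60.0
        ratios = img.freq_axis[1:] / img.freq_axis[:-1]
        np.testing.assert_allclose(ratios, 2 ** (1 / 12), rtol=1e-9)

    def test_fmax_above_nyquist_clipped(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            img = cwt_scalogram(np.zeros(2048), 100.0,
                                CWTConfig(fmin=2.0, fmax=60.0))
        assert img.freq_axis[-1] <= 50.0


class TestSTFT:
    def test_default_hop_is_6_samples(self):
        assert STFTConfig().hop == 6

    def test_tone_bin_accuracy(self):
        x = generate_tones(ToneSpec(frequencies=[20.0], fs=512.0, duration_s=15.0))
        s, freqs, _ = stft_spectrogram(x, STFTConfig())
        peak = freqs[np.abs(s).mean(axis=1).argmax()]
        assert abs(peak - 20.0) <= 512.0 / 7680.0

    def test_zero_signal_and_short_input(self):
        s, _, _ = stft_spectrogram(np.zeros(1000), STFTConfig())
        assert np.all(s == 0)
        with pytest.raises(ValueError, match="window"):
            stft_spectrogram(np.zeros(100), STFTConfig())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            STFTConfig(win_len=256, overlap=256)
        with pytest.raises(ValueError):
            STFTConfig(win_len=256, nfft=128)


class TestAggregateSpectrogram:
    def test_single_mode_equals_plain_stft(self, rng):
        x = rng.standard_normal(2000)
        cfg = STFTConfig()
        img = aggregate_vmd_spectrogram(x[None, :], cfg)
        s, freqs, _ = stft_spectrogram(x, cfg)
        keep = freqs <= cfg.fmax_display
        np.testing.assert_array_equal(img.values, np.abs(s[keep]))

    def test_linearity_identity_for_arbitrary_modes(self, rng):
        """|sum_k STFT(u_k)| equals |STFT(sum_k u_k)| to 1e-10 relative."""
        modes = rng.standard_normal((5, 3000))
        cfg = STFTConfig()
        img = aggregate_vmd_spectrogram(modes, cfg)
        s, freqs, _ = stft_spectrogram(modes.sum(axis=0), cfg)
        ref = np.abs(s[freqs <= cfg.fmax_display])
        assert np.abs(img.values - ref).max() <= 1e-10 * ref.max()

    def test_two_tone_modes_give_two_ridges(self, two_tone_signal):
        from eegtfr.vmd import VMDConfig, vmd_decompose

        x, spec = two_tone_signal
        res = vmd_decompose(x, spec.fs, VMDConfig(K=2, alpha=2000.0))
        img = aggregate_vmd_spectrogram(res.modes, STFTConfig(fs=spec.fs))
        profile = img.values.mean(axis=1)
        # local maxima of the frequency profile sit at the tone frequencies
        top2 = img.freq_axis[np.argsort(profile)[-2:]]
        assert min(abs(f - 5.0) for f in top2) < 0.5
        assert min(abs(f - 40.0) for f in top2) < 0.5

    def test_mode_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            aggregate_vmd_spectrogram(
                np.array([rng.standard_normal(500),
                          rng.standard_normal(400)], dtype=object))


class TestNormaliseAndFuse:
    def test_minmax_closed_form(self):
        img = _img([[1.0, 3.0], [5.0, 9.0]])
        np.testing.assert_allclose(minmax_normalise(img).values,
                                   [[0.0, 0.25], [0.5, 1.0]])

    def test_minmax_idempotent_on_unit_range(self):
        img = _img([[0.0, 0.4], [0.7, 1.0]])
        np.testing.assert_allclose(minmax_normalise(img).values, img.values)

    def test_constant_image_guard(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalise(_img(np.full((3, 3), 7.0)))
        assert np.all(out.values == 0)

    def test_fuse_self_is_minmax(self, rng):
        a = _img(rng.random((8, 8)), subject_id="s", channel_label="O1")
        b = a.copy_with(repr="VMD")
        fused = fuse(a, b)
        np.testing.assert_allclose(fused.values, minmax_normalise(a).values)
        assert fused.repr == "FUSION"

    def test_fuse_midpoint_and_bounds(self, rng):
        ones = _img(np.eye(6), subject_id="s", channel_label="O1")
        other = _img(rng.random((6, 6)), repr="VMD", subject_id="s",
                     channel_label="O1")
        fused = fuse(ones, other)
        na, nb = minmax_normalise(ones).values, minmax_normalise(other).values
        assert np.all(fused.values >= np.minimum(na, nb) - 1e-12)
        assert np.all(fused.values <= np.maximum(na, nb) + 1e-12)
        assert fused.values.min() >= 0 and fused.values.max() <= 1

    def test_fuse_identity_mismatch_names_key(self, rng):
        a = _img(rng.random((4, 4)), subject_id="s1", channel_label="O1")
        b = _img(rng.random((4, 4)), repr="VMD", subject_id="s2",
                 channel_label="O1")
        with pytest.raises(ValueError, match="subject_id"):
            fuse(a, b)

    def test_fuse_shape_mismatch_rejected(self, rng):
        a = _img(rng.random((4, 4)), subject_id="s", channel_label="O1")
        b = _img(rng.random((5, 4)), repr="VMD", subject_id="s",
                 channel_label="O1")
        with pytest.raises(ValueError, match="shape"):
            fuse(a, b)


class TestRender:
    def test_output_is_224_rgb(self, rng):
        rgb = render_rgb(_img(rng.random((59, 100))), size=224)
        assert rgb.shape == (224, 224, 3) and rgb.dtype == np.uint8

    def test_constant_image_is_uniform_bottom_colour(self):
        rgb = render_rgb(_img(np.full((10, 10), 3.0)), size=32)
        assert (rgb == rgb[0, 0]).all()
        np.testing.assert_array_equal(rgb[0, 0], jet_lut()[0])

    def test_extreme_pixels_hit_lut_endpoints(self):
        vals = np.zeros((16, 16))
        vals[0, 0] = 1.0   # row 0 = lowest frequency -> rendered at bottom
        rgb = render_rgb(_img(vals), size=16)
        np.testing.assert_array_equal(rgb[-1, 0], jet_lut()[-1])  # max: dark red
        np.testing.assert_array_equal(rgb[0, -1], jet_lut()[0])   # min: dark blue
        r, g, b = jet_lut()[-1]
        assert r > 100 and g < 50 and b < 50
        r0, g0, b0 = jet_lut()[0]
        assert b0 > 100 and r0 < 50 and g0 < 50


class TestFilenames:
    @given(subject=st.from_regex(r"[A-Za-z0-9\-]{1,12}", fullmatch=True),
           epoch=st.integers(0, 999),
           channel=st.sampled_from(["Fp1", "Cz", "O2", "T5"]),
           repr_tag=st.sampled_from(["CWT", "VMD", "FUSION"]))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, subject, epoch, channel, repr_tag):
        meta = parse_image_filename(image_filename(subject, epoch, channel, repr_tag))
        assert meta == {"subject_id": subject, "epoch_index": epoch,
                        "channel_label": channel, "repr": repr_tag}

    def test_malformed_name_rejected(self):
        with pytest.raises(ValueError):
            parse_image_filename("nounderscores.png")


def test_resample_preserves_range_and_axes(rng):
    img = _img(rng.random((59, 7680)))
    out = resample_image(img, (224, 224))
    assert out.values.shape == (224, 224)
    assert out.freq_axis[0] == img.freq_axis[0]
    assert out.freq_axis[-1] == img.freq_axis[-1]
    assert out.values.min() >= img.values.min() - 1e-9
    assert out.values.max() <= img.values.max() + 1e-9
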