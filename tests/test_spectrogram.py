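"""Mel transform geometry, normalization conventions, and image contracts."""

import numpy as np
import pytest

from voicescreen.segmentation import AudioWindow
from voicescreen.spectrogram import (
    MelMatrix, MelParams, ParameterError, colormap_lut, mel_filterbank,
    mel_spectrogram, render_rgb, render_three_channel, window_to_image,
)

SR = 44100


def _tone(freq, duration=0.5, sr=SR, amp=0.8):
    t = np.arange(int(duration * sr)) / sr
    return AudioWindow(samples=amp * np.sin(2 * np.pi * freq * t), start_s=0.0,
                       clip_id="tone", window_index=0, sample_rate=sr)


def _zero_window(n=22050):
    return AudioWindow(samples=np.zeros(n), start_s=0.0, clip_id="z",
                       window_index=0, sample_rate=SR)


def test_half_second_window_gives_eleven_frames():
    m = mel_spectrogram(_tone(440), 2048, MelParams())
    assert m.values.shape == (512, 11)  # 1 + floor(22050 / 2048)
    assert np.all(np.isfinite(m.values))


def test_zero_window_hits_db_floor_everywhere():
    params = MelParams()
    m = mel_spectrogram(_zero_window(), 2048, params)
    assert np.all(m.values == -params.top_db)
    image = render_rgb(m, params)
    lut0 = colormap_lut()[0]
    assert np.allclose(image.pixels, np.broadcast_to(lut0, image.pixels.shape))
    three = render_three_channel(_zero_window(), params)
    assert np.all(three.pixels == 0.0)


@pytest.mark.parametrize("fft_length", [1024, 2048, 4096])
def test_tone_localized_at_resolution_limit(fft_length):
    params = MelParams()
    m = mel_spectrogram(_tone(1000.0), fft_length, params)
    _, centers = mel_filterbank(SR, fft_length, params.n_mels, params.f_min)
    brightest = int(np.argmax(m.values.mean(axis=1)))
    bin_width = SR / fft_length
    band_spacing = float(np.diff(centers).max())
    assert abs(centers[brightest] - 1000.0) <= max(bin_width, band_spacing)


@pytest.mark.parametrize("fft_length", [1024, 2048, 4096])
def test_brightest_band_tracks_tone_frequency(fft_length):
    rows = []
    for freq in (500.0, 1000.0, 2000.0):
        m = mel_spectrogram(_tone(freq), fft_length, MelParams())
        rows.append(int(np.argmax(m.values.mean(axis=1))))
    assert rows[0] < rows[1] < rows[2]


def test_images_are_deterministic_and_bounded(rng):
    w = AudioWindow(samples=rng.uniform(-0.8, 0.8, 22050), start_s=0.0,
                    clip_id="r", window_index=0, sample_rate=SR)
    for mode in ("rgb", "three_channel"):
        a = window_to_image(w, mode)
        b = window_to_image(w, mode)
        assert a.pixels.shape == (224, 224, 3)
        assert a.pixels.min() >= 0.0 and a.pixels.max() <= 1.0
        assert np.array_equal(a.pixels, b.pixels)


def test_three_channel_order_matches_independent_recomputation(rng):
    # seeded linear chirp: different FFT lengths trade time for frequency
    sr = SR
    t = np.arange(22050) / sr
    chirp = 0.7 * np.sin(2 * np.pi * (300 * t + (3000 - 300) / (2 * t[-1]) * t ** 2))
    w = AudioWindow(samples=chirp, start_s=0.0, clip_id="ch", window_index=0,
                    sample_rate=sr)
    params = MelParams()
    image = render_three_channel(w, params)
    # channels must differ somewhere
    assert not np.array_equal(image.pixels[:, :, 0], image.pixels[:, :, 1])
    assert not np.array_equal(image.pixels[:, :, 1], image.pixels[:, :, 2])
    # channel 0 recomputed independently from fft_lengths_3ch[0]
    m = mel_spectrogram(w, params.fft_lengths_3ch[0], params)
    v = m.values
    norm = (v - v.min()) / (v.max() - v.min())
    from voicescreen.spectrogram import _resize_bilinear
    expected = _resize_bilinear(norm[::-1, :], params.image_size)
    assert np.allclose(image.pixels[:, :, 0], np.clip(expected, 0, 1))


def test_bright_row_lands_at_flipped_scaled_position():
    n_mels, n_frames, band = 512, 11, 100
    values = np.full((n_mels, n_frames), -80.0)
    values[band, :] = 0.0
    m = MelMatrix(values=values, sample_rate=SR, fft_length=2048, hop_length=2048,
                  f_min=20.0, f_max=SR / 2)
    image = render_rgb(m, MelParams())
    # mel band `band` sits at flipped row (n_mels-1-band), scaled to 224
    luminance = image.pixels.sum(axis=2).mean(axis=1)
    expected_row = (n_mels - 1 - band + 0.5) / n_mels * 224
    assert abs(int(np.argmax(luminance)) - expected_row) <= 2


def test_constant_matrix_normalizes_to_zero_entry():
    values = np.full((512, 11), -37.2)
    m = MelMatrix(values=values, sample_rate=SR, fft_length=2048, hop_length=2048,
                  f_min=20.0, f_max=SR / 2)
    image = render_rgb(m, MelParams())
    lut0 = colormap_lut()[0]
    assert np.allclose(image.pixels, np.broadcast_to(lut0, image.pixels.shape))


def test_fft_longer_than_padded_input_raises():
    w = AudioWindow(samples=np.zeros(512), start_s=0.0, clip_id="s",
                    window_index=0, sample_rate=SR)
    with pytest.raises(ParameterError):
        mel_spectrogram(w, 2048, MelParams())


def test_colormap_lut_shape_and_range():
    lut = colormap_lut()
    assert lut.shape == (256, 3)
    assert lut.min() >= 0.0 and lut.max() <= 1.0
    # luminance increases monotonically along the ramp
    lum = lut @ np.array([0.2126, 0.7152, 0.0722])
    assert np.all(np.diff(lum) > -1e-9)
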