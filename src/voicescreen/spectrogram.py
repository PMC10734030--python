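"""Mel-spectrogram imaging of audio windows.

Converts 0.5 s audio windows into 224x224x3 images two ways:

* **rgb** — a single Mel-spectrogram (FFT 2048) min-max normalized and mapped
  through a fixed 256-entry perceptual colormap.
* **three_channel** — three monochrome Mel-spectrograms at FFT lengths
  1024/2048/4096, each normalized independently, stacked depth-wise in
  ascending FFT-length order.

STFT frames are centered with reflection padding (Hamming analysis window,
hop 2048 samples), so a window of n samples yields ``1 + floor(n/hop)``
frames. The mel filterbank has 512 triangular, area-normalized filters from
20 Hz to Nyquist; magnitudes are converted to dB relative to the per-window
maximum with an 80 dB floor. All-zero input maps to the floor image by
convention, and normalization of an all-equal matrix maps to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from PIL import Image
from scipy.signal import get_window

from .segmentation import AudioWindow


class ParameterError(ValueError):
    """Raised when transform parameters are incompatible with the input."""


@dataclass(frozen=True)
class MelParams:
    hop_length: int = 2048
    n_mels: int = 512
    f_min: float = 20.0
    fft_length: int = 2048
    fft_lengths_3ch: tuple[int, int, int] = (1024, 2048, 4096)
    image_size: int = 224
    window_function: str = "hamming"
    top_db: float = 80.0

    def __post_init__(self) -> None:
        if self.hop_length <= 0 or self.n_mels <= 0 or self.image_size <= 0:
            raise ValueError("hop_length, n_mels and image_size must be positive")
        if self.f_min < 0:
            raise ValueError("f_min must be non-negative")
        if self.top_db <= 0:
            raise ValueError("top_db must be positive")


@dataclass
class MelMatrix:
    """dB-scaled mel magnitudes, shape (n_mels, n_frames)."""

    values: np.ndarray
    sample_rate: int
    fft_length: int
    hop_length: int
    f_min: float
    f_max: float

    @property
    def n_mels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.hop_length / self.sample_rate


@dataclass
class SpectrogramImage:
    """image_size x image_size x 3 pixels in [0, 1]."""

    pixels: np.ndarray
    mode: str
    clip_id: str = ""
    window_index: int = 0


# --- mel scale (HTK formula) -------------------------------------------------

def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    sample_rate: int, fft_length: int, n_mels: int, f_min: float, f_max: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular, area-normalized mel filterbank.

    Returns ``(weights, centers)`` where weights has shape
    ``(n_mels, 1 + fft_length//2)`` and centers are the filters' center
    frequencies in Hz. Filters are normalized to constant area (gain
    ``2 / (f_hi - f_lo)``); at high mel counts and short FFTs some filters
    span no bin and stay empty, producing floor values downstream.
    """
    if f_max is None:
        f_max = sample_rate / 2.0
    weights, centers = _cached_filterbank(int(sample_rate), int(fft_length),
                                          int(n_mels), float(f_min), float(f_max))
    return weights.copy(), centers.copy()


@lru_cache(maxsize=32)
def _cached_filterbank(
    sample_rate: int, fft_length: int, n_mels: int, f_min: float, f_max: float
) -> tuple[np.ndarray, np.ndarray]:
    mel_pts = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_mels + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    bin_freqs = np.linspace(0.0, sample_rate / 2.0, 1 + fft_length // 2)
    weights = np.zeros((n_mels, bin_freqs.size), dtype=np.float64)
    for k in range(n_mels):
        f_lo, f_c, f_hi = hz_pts[k], hz_pts[k + 1], hz_pts[k + 2]
        up = (bin_freqs - f_lo) / max(f_c - f_lo, 1e-12)
        down = (f_hi - bin_freqs) / max(f_hi - f_c, 1e-12)
        tri = np.maximum(0.0, np.minimum(up, down))
        weights[k] = tri * (2.0 / (f_hi - f_lo))
    return weights, hz_pts[1:-1]


# --- STFT + mel --------------------------------------------------------------

def _frame_centered(x: np.ndarray, fft_length: int, hop: int) -> np.ndarray:
    """Centered frames with reflection padding; returns (n_frames, fft_length)."""
    n = x.size
    pad = fft_length // 2
    if pad >= n:
        raise ParameterError(
            f"fft_length {fft_length} too long for input of {n} samples "
            "(reflection padding requires fft_length//2 < n)"
        )
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + n // hop
    idx = np.arange(fft_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return xp[idx]


def mel_spectrogram(
    window: AudioWindow, fft_length: Optional[int] = None, params: MelParams = MelParams()
) -> MelMatrix:
    """Compute one dB-scaled Mel-spectrogram of an audio window.

    Magnitude STFT (Hamming window of ``fft_length`` samples, centered
    frames, hop ``params.hop_length``), mel filterbank applied to the power
    spectrum, then ``10*log10(power / max(power))`` floored at ``-top_db``.
    An all-zero window maps to a constant ``-top_db`` matrix.
    """
    if fft_length is None:
        fft_length = params.fft_length
    x = np.asarray(window.samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot transform an empty window")
    frames = _frame_centered(x, fft_length, params.hop_length)
    win = get_window(params.window_function, fft_length, fftbins=True)
    spectrum = np.fft.rfft(frames * win[None, :], axis=1)
    power = (spectrum.real ** 2 + spectrum.imag ** 2).T  # (bins, frames)
    fb, _ = _cached_filterbank(window.sample_rate, fft_length, params.n_mels,
                               params.f_min, window.sample_rate / 2.0)
    mel_power = fb @ power
    ref = float(mel_power.max())
    if ref <= 0.0:
        values = np.full(mel_power.shape, -params.top_db)
    else:
        values = 10.0 * np.log10(np.maximum(mel_power, ref * 10.0 ** (-params.top_db / 10.0)) / ref)
    return MelMatrix(
        values=values,
        sample_rate=window.sample_rate,
        fft_length=fft_length,
        hop_length=params.hop_length,
        f_min=params.f_min,
        f_max=window.sample_rate / 2.0,
    )


# --- colormap ----------------------------------------------------------------

# Fixed perceptual ramp: dark -> violet -> magenta -> orange -> pale yellow,
# with monotonically increasing luminance. Vendored as anchors + linear
# interpolation so rendering never depends on a plotting library's default.
_COLOR_ANCHORS = np.array(
    [
        [0.000, 0.00, 0.00, 0.02],
        [0.125, 0.10, 0.03, 0.35],
        [0.250, 0.33, 0.06, 0.42],
        [0.375, 0.53, 0.13, 0.42],
        [0.500, 0.73, 0.21, 0.33],
        [0.625, 0.89, 0.35, 0.20],
        [0.750, 0.98, 0.55, 0.04],
        [0.875, 0.99, 0.77, 0.19],
        [1.000, 0.99, 0.99, 0.75],
    ]
)


def colormap_lut(n_entries: int = 256) -> np.ndarray:
    """The fixed (n_entries, 3) colormap lookup table in [0, 1]."""
    pos = np.linspace(0.0, 1.0, n_entries)
    lut = np.stack(
        [np.interp(pos, _COLOR_ANCHORS[:, 0], _COLOR_ANCHORS[:, 1 + c]) for c in range(3)],
        axis=1,
    )
    return lut


_LUT = colormap_lut()


def _normalize01(values: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; an all-equal matrix maps to 0."""
    lo = float(values.min())
    hi = float(values.max())
    if hi <= lo:
        return np.zeros_like(values, dtype=np.float64)
    return (values - lo) / (hi - lo)


def _resize_bilinear(plane: np.ndarray, size: int) -> np.ndarray:
    img = Image.fromarray(plane.astype(np.float32), mode="F")
    resized = img.resize((size, size), resample=Image.BILINEAR)
    return np.asarray(resized, dtype=np.float64)


def render_rgb(matrix: MelMatrix, params: MelParams = MelParams()) -> SpectrogramImage:
    """Render one mel matrix as an RGB image.

    dB values are min-max normalized over the matrix, mapped through the
    fixed colormap at native resolution, then each channel is resized with
    bilinear interpolation. Vertical axis is mel bands with low frequency at
    the bottom; horizontal axis is time.
    """
    norm = _normalize01(matrix.values)
    rgb = _LUT[np.round(norm * (_LUT.shape[0] - 1)).astype(np.intp)]  # (mels, frames, 3)
    rgb = rgb[::-1, :, :]  # low frequency at bottom row of the image
    pixels = np.stack(
        [_resize_bilinear(rgb[:, :, c], params.image_size) for c in range(3)], axis=2
    )
    return SpectrogramImage(pixels=np.clip(pixels, 0.0, 1.0), mode="rgb")


def render_three_channel(
    window: AudioWindow, params: MelParams = MelParams()
) -> SpectrogramImage:
    """Depth-wise stack of three monochrome Mel-spectrograms.

    Channel k is computed with ``params.fft_lengths_3ch[k]`` (ascending FFT
    length), normalized to [0, 1] independently, and resized to
    ``image_size``.
    """
    planes = []
    for fft_length in params.fft_lengths_3ch:
        matrix = mel_spectrogram(window, fft_length, params)
        norm = _normalize01(matrix.values)[::-1, :]
        planes.append(_resize_bilinear(norm, params.image_size))
    pixels = np.clip(np.stack(planes, axis=2), 0.0, 1.0)
    return SpectrogramImage(
        pixels=pixels, mode="three_channel",
        clip_id=window.clip_id, window_index=window.window_index,
    )


def window_to_image(
    window: AudioWindow, mode: str = "rgb", params: MelParams = MelParams()
) -> SpectrogramImage:
    """Featurize one audio window in the requested mode."""
    if mode == "rgb":
        matrix = mel_spectrogram(window, params.fft_length, params)
        image = render_rgb(matrix, params)
        image.clip_id = window.clip_id
        image.window_index = window.window_index
        return image
    if mode == "three_channel":
        return render_three_channel(window, params)
    raise ValueError(f"unknown spectrogram mode {mode!r} (expected 'rgb' or 'three_channel')")


def save_png(image: SpectrogramImage, path) -> None:
    """8-bit PNG export (lossy: quantizes to 1/255 steps)."""
    arr = np.round(image.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def save_float(image: SpectrogramImage, path) -> None:
    """Exact float32 tensor cache (``.npy``), lossless for training."""
    np.save(path, image.pixels.astype(np.float32))


def load_float(path) -> np.ndarray:
    return np.load(path)
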