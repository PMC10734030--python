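"""Sliding-window segmentation and silence rejection.

Each vocalization clip is sliced into fixed-duration windows (default 0.5 s)
with fractional overlap (default 50 %). Clips shorter than one window are
rejected outright. Within each clip, windows whose mean-square power falls
more than ``power_reject_sd`` (default 1.5) sample standard deviations below
the clip's mean window power are rejected, so stretches of silence never
reach the classifier.

The stride is computed in samples as ``round(window_s * sr * (1 - overlap))``
to avoid cumulative drift, and windows are emitted only where they fit
entirely inside the clip — no zero padding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio_io import AudioClip


@dataclass(frozen=True)
class WindowingParams:
    window_s: float = 0.5
    overlap_fraction: float = 0.5
    power_reject_sd: float = 1.5

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError("window_s must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.power_reject_sd < 0:
            raise ValueError("power_reject_sd must be non-negative")


@dataclass
class AudioWindow:
    """One fixed-duration slice of a clip, with its mean-square power."""

    samples: np.ndarray
    start_s: float
    clip_id: str
    window_index: int
    sample_rate: int
    power: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.power is None:
            self.power = window_power(self)

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class SegmentedClip:
    """Windows of one clip plus the short-clip rejection flag."""

    clip_id: str
    windows: list[AudioWindow]
    rejected_short: bool

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)


def window_power(window: AudioWindow) -> float:
    """Mean of squared amplitudes (unitless, deterministic)."""
    x = np.asarray(window.samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot compute power of an empty window")
    return float(np.mean(x * x))


def segment_windows(clip: AudioClip, params: WindowingParams = WindowingParams()) -> SegmentedClip:
    """Slice a clip into overlapping fixed-length windows.

    Start times are 0, s, 2s, ... with stride ``s = window_s*(1-overlap)``;
    a window is emitted only if it fits entirely within the clip. Clips
    shorter than ``window_s`` yield an empty list with ``rejected_short``
    set — a flagged empty result, not an error.
    """
    sr = clip.sample_rate
    n_win = int(round(params.window_s * sr))
    stride = int(round(params.window_s * sr * (1.0 - params.overlap_fraction)))
    stride = max(stride, 1)
    n = clip.n_samples
    if n < n_win:
        return SegmentedClip(clip_id=clip.clip_id, windows=[], rejected_short=True)
    windows: list[AudioWindow] = []
    index = 0
    start = 0
    while start + n_win <= n:
        windows.append(
            AudioWindow(
                samples=clip.samples[start : start + n_win],
                start_s=start / sr,
                clip_id=clip.clip_id,
                window_index=index,
                sample_rate=sr,
            )
        )
        index += 1
        start += stride
    return SegmentedClip(clip_id=clip.clip_id, windows=windows, rejected_short=False)


def filter_windows(
    windows: list[AudioWindow], params: WindowingParams = WindowingParams()
) -> list[AudioWindow]:
    """Reject low-power windows of one clip.

    Keeps window i iff ``power_i >= mean(powers) - power_reject_sd * sd``,
    where mean/sd are over the clip's own windows and sd is the sample
    (n-1) standard deviation. Clips with fewer than 2 windows keep all
    windows (sd undefined). Relative order is preserved.
    """
    if not windows:
        return []
    clip_ids = {w.clip_id for w in windows}
    if len(clip_ids) > 1:
        raise ValueError(f"filter_windows operates per clip; got clip_ids {sorted(clip_ids)}")
    if len(windows) < 2:
        return list(windows)
    powers = np.array([w.power for w in windows], dtype=np.float64)
    threshold = powers.mean() - params.power_reject_sd * powers.std(ddof=1)
    return [w for w, p in zip(windows, powers) if p >= threshold]


def write_window_index(
    segmented: SegmentedClip, kept: list[AudioWindow], path: str | Path
) -> Path:
    """Sidecar CSV ``clip_id,window_index,start_s,power,kept`` for one clip."""
    kept_ids = {w.window_index for w in kept}
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["clip_id", "window_index", "start_s", "power", "kept"])
        for w in segmented.windows:
            writer.writerow(
                [w.clip_id, w.window_index, f"{w.start_s:.6f}", f"{w.power:.10g}",
                 int(w.window_index in kept_ids)]
            )
    return path
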