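"""WAV audio and cohort-manifest I/O.

Defines the canonical in-memory model for one labeled vocalization
(:class:`AudioClip`) and for a study cohort (:class:`CohortManifest`), plus
readers/writers for 16-bit PCM WAV files and the manifest CSV dialect
``clip_path,participant_id,vocalization,label[,vowel]``.

Amplitudes are normalized by the integer full-scale value only — no per-clip
peak normalization — so recordings keep their real-world level differences.
The canonical sampling rate is 44.1 kHz; other rates are accepted with a
warning and all downstream parameters are interpreted in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

CANONICAL_RATE = 44100
VOCALIZATIONS = ("vowel", "word", "sentence", "continuous")
VOWELS = ("a", "e", "i", "o", "u")
LABELS = ("pass", "fail")

#: positive (screen-positive) class for every reported metric
POSITIVE_LABEL = "fail"


class AudioFormatError(ValueError):
    """Raised for files that are not readable PCM WAV."""


class ManifestError(ValueError):
    """Raised for malformed or inconsistent cohort manifests."""


@dataclass
class AudioClip:
    """A labeled mono waveform for one vocalization of one participant."""

    samples: np.ndarray
    sample_rate: int
    participant_id: str
    vocalization: str = "vowel"
    label: str = "pass"
    clip_id: str = ""
    vowel_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not int(self.sample_rate) > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        self.sample_rate = int(self.sample_rate)
        amax = float(np.max(np.abs(self.samples)))
        if amax > 1.0 + 2.0 ** -15:
            raise ValueError(f"amplitudes must lie in [-1, 1]; max |x| = {amax:.4f}")
        if self.vocalization not in VOCALIZATIONS:
            raise ValueError(f"unknown vocalization {self.vocalization!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.vowel_symbol is not None and self.vowel_symbol not in VOWELS:
            raise ValueError(f"unknown vowel symbol {self.vowel_symbol!r}")
        if self.sample_rate != CANONICAL_RATE:
            logger.warning(
                "clip %s has sample rate %d Hz (canonical is %d Hz); "
                "window/hop parameters are interpreted in seconds",
                self.clip_id or "<unnamed>", self.sample_rate, CANONICAL_RATE,
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size


def read_wav(
    path: str | Path,
    *,
    participant_id: str = "unknown",
    vocalization: str = "vowel",
    label: str = "pass",
    clip_id: str | None = None,
    vowel_symbol: str | None = None,
) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    Integer PCM is divided by the type's full-scale value (``2**15`` for
    16-bit), multi-channel input is averaged to mono, and the sample rate is
    preserved as read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise AudioFormatError(f"not a readable PCM WAV file: {path} ({exc})") from exc

    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 2.0 ** 15
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2.0 ** 31
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype} in {path}")

    if samples.ndim == 2:  # stereo -> mono by arithmetic mean
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioClip(
        samples=samples,
        sample_rate=int(rate),
        participant_id=participant_id,
        vocalization=vocalization,
        label=label,
        clip_id=clip_id if clip_id is not None else path.stem,
        vowel_symbol=vowel_symbol,
    )


def write_wav(clip: AudioClip, path: str | Path) -> Path:
    """Write a clip as 16-bit PCM WAV; deterministic bytes for identical input.

    Amplitudes are quantized as ``round(x * 2**15)`` clipped to the int16
    range, which bounds the read-back error at one LSB (``2**-15``) per
    sample. Out-of-range amplitudes raise instead of clipping silently.
    """
    path = Path(path)
    x = np.asarray(clip.samples, dtype=np.float64)
    amax = float(np.max(np.abs(x)))
    if amax > 1.0:
        raise ValueError(f"amplitudes out of [-1, 1] (max |x| = {amax:.6f}); refusing to clip")
    quantized = np.clip(np.round(x * 2.0 ** 15), -(2 ** 15), 2 ** 15 - 1).astype(np.int16)
    try:
        wavfile.write(str(path), clip.sample_rate, quantized)
    except OSError as exc:
        raise OSError(f"cannot write WAV to {path}: {exc}") from exc
    return path


@dataclass(frozen=True)
class ManifestRecord:
    clip_path: Path
    participant_id: str
    vocalization: str
    label: str
    vowel: Optional[str] = None


@dataclass
class CohortManifest:
    """Validated mapping from recordings to participants and screen labels."""

    records: list[ManifestRecord]
    cohort_name: str = "cohort"

    @property
    def participants(self) -> list[str]:
        """Participant ids in order of first appearance (enrollment order)."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.participant_id, None)
        return list(seen)

    def label_of(self, participant_id: str) -> str:
        for rec in self.records:
            if rec.participant_id == participant_id:
                return rec.label
        raise KeyError(participant_id)

    def by_participant(self) -> dict[str, list[ManifestRecord]]:
        out: dict[str, list[ManifestRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.participant_id, []).append(rec)
        return out

    def load_clip(self, record: ManifestRecord) -> AudioClip:
        return read_wav(
            record.clip_path,
            participant_id=record.participant_id,
            vocalization=record.vocalization,
            label=record.label,
            vowel_symbol=record.vowel,
        )

    def iter_clips(self) -> Iterable[AudioClip]:
        for rec in self.records:
            yield self.load_clip(rec)


_REQUIRED_COLUMNS = ("clip_path", "participant_id", "vocalization", "label")


def load_manifest(path: str | Path, *, check_files: bool = True) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Validation errors name the offending row; participants listed with
    conflicting labels raise a consistency error (labels are constant per
    participant by construction of the screening protocol).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing columns: {missing}")
    if len(df) == 0:
        raise ManifestError(f"manifest {path} is empty")

    base = path.parent
    records: list[ManifestRecord] = []
    labels_seen: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        voc = str(row.vocalization)
        lab = str(row.label)
        if voc not in VOCALIZATIONS:
            raise ManifestError(f"row {i}: unknown vocalization token {voc!r}")
        if lab not in LABELS:
            raise ManifestError(f"row {i}: unknown label token {lab!r}")
        vowel = getattr(row, "vowel", None)
        if vowel is not None and (pd.isna(vowel) or vowel == ""):
            vowel = None
        if vowel is not None and vowel not in VOWELS:
            raise ManifestError(f"row {i}: unknown vowel token {vowel!r}")
        pid = str(row.participant_id)
        prev = labels_seen.setdefault(pid, lab)
        if prev != lab:
            raise ManifestError(
                f"row {i}: participant {pid!r} listed with conflicting labels "
                f"{prev!r} and {lab!r}"
            )
        clip_path = Path(str(row.clip_path))
        if not clip_path.is_absolute():
            clip_path = base / clip_path
        if check_files and not clip_path.exists():
            raise FileNotFoundError(f"row {i}: clip file not found: {clip_path}")
        records.append(ManifestRecord(clip_path, pid, voc, lab, vowel))
    return CohortManifest(records=records, cohort_name=path.stem)


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    """Write a manifest CSV (paths relative to the CSV's directory if possible)."""
    path = Path(path)
    base = path.parent
    rows = []
    for rec in manifest.records:
        p = rec.clip_path
        try:
            p = p.relative_to(base)
        except ValueError:
            pass
        rows.append(
            {
                "clip_path": str(p),
                "participant_id": rec.participant_id,
                "vocalization": rec.vocalization,
                "label": rec.label,
                "vowel": rec.vowel if rec.vowel is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
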