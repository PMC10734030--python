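"""Seeded synthetic vocal cohorts for offline end-to-end testing.

Generates two-class cohorts of sustained-vowel (and optional pseudo-speech)
WAV recordings whose classes differ in voice-quality parameters — jitter
(cycle-to-cycle pitch perturbation), shimmer (cycle-to-cycle amplitude
perturbation), additive breath noise and spectral tilt — the classic
acoustic correlates of dysphonic voice. The premise mirrors the screening
setting: swallowing-screen failure is audible as voice-quality change, so a
"fail" profile sounds rougher and breathier than a "pass" profile.

Synthesis is source-filter: an impulse-train glottal source at f0 with
per-cycle jitter/shimmer, low-pass tilt shaping, a cascade of second-order
formant resonators per vowel, and formant-shaped additive noise. Every
waveform is a deterministic function of (spec, vowel, seed); participants
draw their voice from per-index seed substreams, so regenerating a cohort —
or growing it — never changes already-generated participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .audio_io import (
    VOWELS, AudioClip, CohortManifest, ManifestRecord, save_manifest, write_wav,
)

#: mean adult formant targets (center Hz, bandwidth Hz), three per vowel
DEFAULT_FORMANTS: dict[str, tuple[tuple[float, float], ...]] = {
    "a": ((730.0, 90.0), (1090.0, 110.0), (2440.0, 140.0)),
    "e": ((530.0, 80.0), (1840.0, 120.0), (2480.0, 150.0)),
    "i": ((270.0, 60.0), (2290.0, 150.0), (3010.0, 200.0)),
    "o": ((570.0, 80.0), (840.0, 100.0), (2410.0, 150.0)),
    "u": ((300.0, 60.0), (870.0, 100.0), (2240.0, 150.0)),
}

_WARMUP_S = 0.5  # generated then trimmed, so filter transients never reach the clip


@dataclass(frozen=True)
class VoiceSpec:
    """Voice-quality parameters of one synthetic speaker."""

    f0: float = 120.0                      # fundamental, Hz
    jitter: float = 0.005                  # fractional cycle-to-cycle f0 perturbation
    shimmer: float = 0.03                  # fractional amplitude perturbation
    breath_noise_db: float = -35.0         # noise RMS re: voiced RMS, dB (-inf = none)
    spectral_tilt_db_per_octave: float = -12.0
    duration_s: float = 3.0
    sample_rate: int = 44100
    formants: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_FORMANTS)
    )

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("f0, duration_s and sample_rate must be positive")
        if self.jitter < 0 or self.shimmer < 0:
            raise ValueError("jitter and shimmer must be non-negative")


@dataclass(frozen=True)
class VoiceProfile:
    """Parameter distribution (mean, sd) one class's speakers are drawn from."""

    f0: tuple[float, float] = (120.0, 20.0)
    jitter: tuple[float, float] = (0.005, 0.002)
    shimmer: tuple[float, float] = (0.03, 0.01)
    breath_noise_db: tuple[float, float] = (-35.0, 3.0)
    spectral_tilt_db_per_octave: tuple[float, float] = (-12.0, 1.5)
    duration_s: tuple[float, float] = (3.0, 0.25)

    def sample(self, rng: np.random.Generator, sample_rate: int = 44100) -> VoiceSpec:
        def draw(pair, lo, hi):
            m, s = pair
            return float(np.clip(m + s * rng.standard_normal(), lo, hi))

        return VoiceSpec(
            f0=draw(self.f0, 70.0, 300.0),
            jitter=draw(self.jitter, 0.0, 0.2),
            shimmer=draw(self.shimmer, 0.0, 0.5),
            breath_noise_db=draw(self.breath_noise_db, -80.0, 0.0),
            spectral_tilt_db_per_octave=draw(self.spectral_tilt_db_per_octave, -30.0, 0.0),
            duration_s=draw(self.duration_s, 1.0, 6.0),
            sample_rate=sample_rate,
        )


#: healthy-sounding voice: near-periodic, little breath noise, steep tilt
PASS_PROFILE = VoiceProfile()

#: dysphonic-sounding voice: rough (high jitter/shimmer), breathy, flat tilt
FAIL_PROFILE = VoiceProfile(
    jitter=(0.03, 0.01),
    shimmer=(0.12, 0.03),
    breath_noise_db=(-16.0, 3.0),
    spectral_tilt_db_per_octave=(-6.0, 1.5),
)


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort (sizes, class profiles, protocol)."""

    n_pass: int = 10
    n_fail: int = 10
    pass_profile: VoiceProfile = PASS_PROFILE
    fail_profile: VoiceProfile = FAIL_PROFILE
    vowels_per_participant: int = 3          # repetitions of each of the 5 vowels
    include_speech_proxies: bool = False
    silence_gap_s: float = 0.75
    silence_fraction: float = 1.0 / 3.0      # fraction of clips with leading silence
    seed: int = 0
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        if self.n_pass < 0 or self.n_fail < 0:
            raise ValueError("participant counts must be non-negative")
        if self.vowels_per_participant < 1:
            raise ValueError("need at least one repetition per vowel")
        if not 0.0 <= self.silence_fraction <= 1.0:
            raise ValueError("silence_fraction must lie in [0, 1]")

    @staticmethod
    def from_yaml(path: str | Path) -> "CohortSpec":
        """Load a cohort design from YAML; profile entries are
        ``{field: [mean, sd], ...}`` mappings."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("pass_profile", "fail_profile"):
            if key in raw:
                raw[key] = VoiceProfile(
                    **{k: tuple(v) for k, v in raw[key].items()})
        return CohortSpec(**raw)


# --- waveform synthesis ------------------------------------------------------

def _tilt_filter(x: np.ndarray, tilt_db_per_octave: float, f0: float, sr: int) -> np.ndarray:
    """Approximate spectral tilt with cascaded one-pole low-passes (~-6 dB/oct each)."""
    n_stages = max(1, int(round(abs(tilt_db_per_octave) / 6.0)))
    a = np.exp(-2.0 * np.pi * f0 / sr)
    for _ in range(n_stages):
        x = lfilter([1.0 - a], [1.0, -a], x)
    return x


def _formant_cascade(x: np.ndarray, formants, sr: int) -> np.ndarray:
    for f_center, bw in formants:
        r = np.exp(-np.pi * bw / sr)
        theta = 2.0 * np.pi * f_center / sr
        x = lfilter([1.0], [1.0, -2.0 * r * np.cos(theta), r * r], x)
    return x


def _glottal_source(
    n_total: int, spec: VoiceSpec, rng: np.random.Generator
) -> np.ndarray:
    """Impulse train with per-cycle period jitter and amplitude shimmer.

    With jitter = shimmer = 0 every period is exactly
    ``round(sample_rate / f0)`` samples, so the source (and after filter
    warm-up, the output) is exactly periodic.
    """
    base_period = max(2, int(round(spec.sample_rate / spec.f0)))
    source = np.zeros(n_total)
    pos = 0
    while pos < n_total:
        amp = max(0.1, 1.0 + spec.shimmer * rng.standard_normal())
        source[pos] = amp
        period = max(2, int(round(base_period * (1.0 + spec.jitter * rng.standard_normal()))))
        pos += period
    return source


def synth_vowel(spec: VoiceSpec, vowel: str, seed: int) -> AudioClip:
    """Synthesize one sustained vowel; deterministic given (spec, vowel, seed)."""
    if vowel not in VOWELS:
        raise ValueError(f"unknown vowel token {vowel!r}; expected one of {VOWELS}")
    rng = np.random.default_rng(seed)
    sr = spec.sample_rate
    n_dur = int(round(spec.duration_s * sr))
    n_warm = int(round(_WARMUP_S * sr))
    n_total = n_dur + n_warm

    source = _glottal_source(n_total, spec, rng)
    source = _tilt_filter(source, spec.spectral_tilt_db_per_octave, spec.f0, sr)
    voiced = _formant_cascade(source, spec.formants[vowel], sr)

    if np.isfinite(spec.breath_noise_db):
        noise = _formant_cascade(rng.standard_normal(n_total), spec.formants[vowel], sr)
        rms_v = np.sqrt(np.mean(voiced[n_warm:] ** 2))
        rms_n = np.sqrt(np.mean(noise[n_warm:] ** 2))
        if rms_n > 0:
            noise *= rms_v * 10.0 ** (spec.breath_noise_db / 20.0) / rms_n
        voiced = voiced + noise

    x = voiced[n_warm:n_warm + n_dur]
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (0.9 / peak)
    return AudioClip(samples=x, sample_rate=sr, participant_id="synthetic",
                     vocalization="vowel", vowel_symbol=vowel)


_PROXY_SYLLABLES = {"word": 2, "sentence": 6, "continuous": 10}


def synth_speech_proxy(spec: VoiceSpec, kind: str, seed: int) -> AudioClip:
    """Pseudo-speech: a run of formant-glide syllables with amplitude modulation.

    Stands in for the word/sentence/continuous-speech categories; no
    phonetic realism is attempted — only category handling and the
    segmentation/featurization path are exercised.
    """
    if kind not in _PROXY_SYLLABLES:
        raise ValueError(f"unknown speech proxy kind {kind!r}")
    rng = np.random.default_rng(seed)
    sr = spec.sample_rate
    syllable_s, gap_s = 0.22, 0.03
    pieces: list[np.ndarray] = []
    for i in range(_PROXY_SYLLABLES[kind]):
        vowel = VOWELS[rng.integers(len(VOWELS))]
        f0 = spec.f0 * (1.0 - 0.1 * i / max(1, _PROXY_SYLLABLES[kind] - 1))  # declination
        syl_spec = dataclasses.replace(spec, f0=f0, duration_s=syllable_s)
        syl = synth_vowel(syl_spec, vowel, seed=int(rng.integers(2 ** 31))).samples
        envelope = np.sin(np.pi * np.arange(syl.size) / syl.size) ** 2
        pieces.append(syl * envelope)
        pieces.append(np.zeros(int(gap_s * sr)))
    x = np.concatenate(pieces[:-1])
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (0.9 / peak)
    return AudioClip(samples=x, sample_rate=sr, participant_id="synthetic",
                     vocalization=kind)


# --- cohort assembly ---------------------------------------------------------

def _participant_id(index: int) -> str:
    return f"p{index:03d}"


def synth_participant(
    cohort: CohortSpec, participant_index: int, label: str
) -> list[AudioClip]:
    """All clips of one participant, drawn from the label's voice profile.

    Uses a participant-specific seed substream of the cohort seed, so clips
    are unchanged when the cohort grows. A ``silence_fraction`` share of
    clips carries ``silence_gap_s`` of leading silence to exercise the
    power filter.
    """
    profile = cohort.pass_profile if label == "pass" else cohort.fail_profile
    rng = np.random.default_rng([cohort.seed, participant_index])
    spec = profile.sample(rng, cohort.sample_rate)
    pid = _participant_id(participant_index)
    n_silence = int(round(cohort.silence_gap_s * cohort.sample_rate))

    clips: list[AudioClip] = []

    def finish(clip: AudioClip, clip_id: str, vocalization: str,
               vowel: Optional[str]) -> None:
        samples = clip.samples
        if cohort.silence_fraction > 0 and rng.random() < cohort.silence_fraction:
            samples = np.concatenate([np.zeros(n_silence), samples])
        clips.append(AudioClip(
            samples=samples, sample_rate=clip.sample_rate, participant_id=pid,
            vocalization=vocalization, label=label, clip_id=clip_id,
            vowel_symbol=vowel,
        ))

    for vowel in VOWELS:
        for rep in range(cohort.vowels_per_participant):
            dur = float(np.clip(spec.duration_s + 0.15 * rng.standard_normal(), 1.0, 6.0))
            clip_spec = dataclasses.replace(spec, duration_s=dur)
            wav_seed = int(rng.integers(2 ** 31))
            clip = synth_vowel(clip_spec, vowel, wav_seed)
            finish(clip, f"{pid}_{vowel}{rep}", "vowel", vowel)

    if cohort.include_speech_proxies:
        for kind, count in (("word", 2), ("sentence", 1), ("continuous", 1)):
            for rep in range(count):
                wav_seed = int(rng.integers(2 ** 31))
                clip = synth_speech_proxy(spec, kind, wav_seed)
                finish(clip, f"{pid}_{kind}{rep}", kind, None)
    return clips


def cohort_labels(cohort: CohortSpec) -> list[str]:
    """Enrollment-order labels: classes interleaved (mirrors rolling intake),
    so chronological train/test splits contain both classes."""
    labels: list[str] = []
    remaining = {"pass": cohort.n_pass, "fail": cohort.n_fail}
    turn = "pass"
    while remaining["pass"] or remaining["fail"]:
        if remaining[turn] == 0:
            turn = "fail" if turn == "pass" else "pass"
        labels.append(turn)
        remaining[turn] -= 1
        turn = "fail" if turn == "pass" else "pass"
    return labels


def synth_cohort(cohort: CohortSpec, out_dir: str | Path) -> CohortManifest:
    """Write all WAVs and the manifest CSV; byte-identical under one seed."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cohort output directory is not writable: {out_dir} ({exc})") from exc

    records: list[ManifestRecord] = []
    for index, label in enumerate(cohort_labels(cohort)):
        for clip in synth_participant(cohort, index, label):
            wav_path = out_dir / f"{clip.clip_id}.wav"
            write_wav(clip, wav_path)
            records.append(ManifestRecord(
                clip_path=wav_path, participant_id=clip.participant_id,
                vocalization=clip.vocalization, label=clip.label,
                vowel=clip.vowel_symbol,
            ))
    manifest = CohortManifest(records=records, cohort_name=out_dir.name)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
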