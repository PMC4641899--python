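"""Turn raw sung productions into validated pitch-class responses.

A sung continuation is a single note.  Its mean fundamental frequency is
rounded to the closest equal-tempered semitone, with the signed
deviation recorded in cents; the response is then expressed as a pitch
class and scale degree in the stem's key (analyses generalize across
octaves).  Participants are screened out if any pitch-matching
calibration trial rounds to a different note than presented, or if at
least 25% of their experimental trials land more than 40 cents from the
nearest semitone.  Response onsets are located on an intensity envelope:
the first stretch at least 50 ms long that stays within 25 dB of the
track's maximum level.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .io_formats import ParticipantRecord, ResponseTableRow
from .melody_core import (
    DegreeLabel,
    MelodicStem,
    Pitch,
    frequency_to_nearest_pitch,
    scale_degree,
)

__all__ = [
    "SungResponse",
    "IntensityTrack",
    "ExclusionReport",
    "OFF_PITCH_CENTS",
    "OFF_PITCH_FRACTION",
    "ONSET_DROP_DB",
    "ONSET_MIN_MS",
    "process_response",
    "process_table",
    "detect_onset",
    "intensity_track_from_wav",
    "screen_participant",
    "autocorrelation_f0",
    "f0_from_wav",
]

#: exclusion rule constants
OFF_PITCH_CENTS = 40.0       # |cents| beyond this counts a trial as off-pitch
OFF_PITCH_FRACTION = 0.25    # "at least 25%" of trials -> excluded
#: onset rule constants
ONSET_DROP_DB = 25.0         # onset level threshold: max intensity - 25 dB
ONSET_MIN_MS = 50.0          # minimum sustained duration above threshold


@dataclass(frozen=True)
class SungResponse:
    """One validated single-note production (participant x stem)."""

    participant_id: str
    stem_id: str
    pitch: Pitch | None
    pitch_class: int | None
    degree: DegreeLabel | None
    onset_latency_ms: float | None = None
    sung_duration_ms: float | None = None
    confidence: int | None = None
    valid: bool = True
    condition: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.valid:
            assert self.pitch is not None and self.pitch_class is not None
            if self.pitch_class != self.pitch.semitone_index % 12:
                raise ValueError("pitch_class inconsistent with pitch")


@dataclass(frozen=True)
class IntensityTrack:
    """Regularly sampled intensity envelope in dB."""

    samples: np.ndarray
    dt_ms: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if s.size < 1:
            raise ValueError("intensity track needs at least one sample")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class ExclusionReport:
    participant_id: str
    excluded: bool
    reasons: tuple[str, ...]
    off_pitch_fraction: float

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded flag must match presence of reasons")


# -- response conversion -----------------------------------------------------


def process_response(row: ResponseTableRow, stem: MelodicStem) -> SungResponse:
    """Round one raw response to a pitch / pitch class / scale degree.

    A directly supplied ``sung_index`` passes through with 0 cents; an
    invalid f0 (nonpositive or out of the accepted range) yields a
    flagged-invalid response that downstream distributions drop.
    """
    pitch: Pitch | None = None
    if row.mean_f0_hz is not None:
        try:
            if row.mean_f0_hz <= 0:
                raise ValueError("nonpositive f0")
            pitch = frequency_to_nearest_pitch(row.mean_f0_hz)
        except ValueError:
            pitch = None
    elif row.sung_index is not None:
        try:
            pitch = Pitch(row.sung_index)
        except ValueError:
            pitch = None
    if pitch is None:
        return SungResponse(
            participant_id=row.participant_id,
            stem_id=row.stem_id,
            pitch=None,
            pitch_class=None,
            degree=None,
            onset_latency_ms=row.onset_latency_ms,
            sung_duration_ms=row.sung_duration_ms,
            confidence=row.confidence,
            valid=False,
            condition=stem.condition,
        )
    return SungResponse(
        participant_id=row.participant_id,
        stem_id=row.stem_id,
        pitch=pitch,
        pitch_class=pitch.pitch_class,
        degree=scale_degree(pitch.pitch_class, stem.key),
        onset_latency_ms=row.onset_latency_ms,
        sung_duration_ms=row.sung_duration_ms,
        confidence=row.confidence,
        valid=True,
        condition=stem.condition,
    )


def process_table(
    rows: Iterable[ResponseTableRow],
    stems: dict[str, MelodicStem],
) -> list[SungResponse]:
    """Process every row against its stem (unknown stem ids raise)."""
    out = []
    for row in rows:
        if row.stem_id not in stems:
            raise KeyError(f"response references unknown stem {row.stem_id!r}")
        out.append(process_response(row, stems[row.stem_id]))
    return out


# -- onset detection ---------------------------------------------------------


def detect_onset(track: IntensityTrack) -> float | None:
    """Start time (ms) of the sound onset, or None if never detected.

    The onset is the start of the first contiguous run of samples at a
    level of at least (max intensity - 25 dB) lasting at least 50 ms.
    """
    levels = track.samples
    threshold = levels.max() - ONSET_DROP_DB
    min_samples = int(np.ceil(ONSET_MIN_MS / track.dt_ms))
    above = levels >= threshold
    run_start = None
    run_len = 0
    for i, hot in enumerate(above):
        if hot:
            if run_start is None:
                run_start = i
            run_len += 1
            if run_len >= min_samples:
                return run_start * track.dt_ms
        else:
            run_start = None
            run_len = 0
    # a run reaching the end of the track counts if it is long enough
    return None


def intensity_track_from_wav(
    path: str | Path, frame_ms: float = 1.0
) -> IntensityTrack:
    """RMS intensity envelope (dB) of a mono 16-bit PCM WAV."""
    samples, rate = _read_wav(path)
    frame = max(1, int(round(rate * frame_ms / 1000.0)))
    n_frames = len(samples) // frame
    if n_frames == 0:
        raise ValueError(f"{path}: shorter than one frame")
    chunks = samples[: n_frames * frame].reshape(n_frames, frame)
    rms = np.sqrt((chunks.astype(float) ** 2).mean(axis=1))
    db = 20.0 * np.log10(np.maximum(rms, 1e-10))
    return IntensityTrack(samples=db, dt_ms=frame_ms)


# -- participant screening ---------------------------------------------------


def screen_participant(
    record: ParticipantRecord,
    responses: Sequence[SungResponse],
    octave_equivalent: bool = True,
) -> ExclusionReport:
    """Apply the two exclusion rules to one participant.

    Rule 1 (pitch matching): every calibration trial's sung f0 must
    round to the presented note.  By default the comparison is
    octave-equivalent (pitch classes), since participants sang in a
    comfortable register; ``octave_equivalent=False`` requires the exact
    index.

    Rule 2 (off-pitch rate): excluded if at least 25% of experimental
    trials deviate strictly more than 40 cents from the nearest
    semitone.
    """
    if not record.pitch_matching_trials:
        raise ValueError(
            f"participant {record.participant_id}: no pitch-matching trials"
        )
    reasons: list[str] = []
    for presented, sung_f0 in record.pitch_matching_trials:
        try:
            sung = frequency_to_nearest_pitch(sung_f0)
        except ValueError:
            reasons.append("pitch_match_failure")
            break
        if octave_equivalent:
            ok = sung.pitch_class == presented % 12
        else:
            ok = sung.semitone_index == presented
        if not ok:
            reasons.append("pitch_match_failure")
            break

    own = [r for r in responses if r.participant_id == record.participant_id]
    rated = [r for r in own if r.valid and r.pitch is not None]
    if rated:
        # strictly more than 40 cents; epsilon guards float round-trip noise
        off = sum(
            1 for r in rated
            if abs(r.pitch.cents_deviation) > OFF_PITCH_CENTS + 1e-9
        )
        frac = off / len(rated)
    else:
        frac = 0.0
    if rated and frac >= OFF_PITCH_FRACTION:
        reasons.append("off_pitch_rate")
    return ExclusionReport(
        participant_id=record.participant_id,
        excluded=bool(reasons),
        reasons=tuple(reasons),
        off_pitch_fraction=frac,
    )


# -- optional f0 backend (WAV -> mean f0) ------------------------------------


def _read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    with wave.open(str(path), "rb") as w:
        if w.getnchannels() != 1:
            raise ValueError(f"{path}: only mono WAV supported")
        if w.getsampwidth() != 2:
            raise ValueError(f"{path}: only 16-bit PCM supported")
        rate = w.getframerate()
        raw = w.readframes(w.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(float) / 32768.0
    return samples, rate


def autocorrelation_f0(
    samples: np.ndarray,
    rate: int,
    fmin: float = 60.0,
    fmax: float = 1200.0,
) -> float | None:
    """f0 of a frame by the autocorrelation peak in the plausible lag band."""
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    if len(x) < int(rate / fmin) or not x.any():
        return None
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    # unbiased normalization removes the linear taper that biases the peak
    ac = ac / np.arange(len(x), 0, -1)
    lag_min = max(1, int(rate / fmax))
    lag_max = min(len(ac) - 1, int(rate / fmin))
    if lag_max <= lag_min:
        return None
    seg = ac[lag_min : lag_max + 1]
    best = seg.max()
    if best <= 0 or ac[0] <= 0:
        return None
    # the fundamental is the FIRST strong peak: later period multiples reach
    # comparable height and must not capture the argmax (subharmonic errors)
    peak = None
    for i in range(1, len(seg) - 1):
        if seg[i] >= seg[i - 1] and seg[i] >= seg[i + 1] and seg[i] >= 0.9 * best:
            peak = i + lag_min
            break
    if peak is None:
        peak = int(np.argmax(seg)) + lag_min
    # parabolic interpolation around the peak for sub-sample lag
    if 1 <= peak < len(ac) - 1:
        a, b, c = ac[peak - 1], ac[peak], ac[peak + 1]
        denom = a - 2 * b + c
        if denom != 0:
            peak = peak + 0.5 * (a - c) / denom
    return rate / peak


F0Backend = Callable[[np.ndarray, int], "float | None"]


def f0_from_wav(
    path: str | Path,
    backend: F0Backend | None = None,
    frame_ms: float = 40.0,
    hop_ms: float = 10.0,
) -> float | None:
    """Mean f0 over the voiced middle 50% of a sung note recording.

    The default backend estimates per-frame f0 by autocorrelation; the
    mean is over frames where the backend reports a pitch.  A custom
    ``backend(samples, rate) -> f0 | None`` (e.g. wrapping an external
    pitch tracker) may be supplied.
    """
    samples, rate = _read_wav(path)
    n = len(samples)
    mid = samples[n // 4 : n - n // 4]  # middle 50%
    if backend is not None:
        return backend(mid, rate)
    frame = int(rate * frame_ms / 1000.0)
    hop = max(1, int(rate * hop_ms / 1000.0))
    if len(mid) < frame:
        return autocorrelation_f0(mid, rate)
    f0s = []
    for start in range(0, len(mid) - frame + 1, hop):
        f0 = autocorrelation_f0(mid[start : start + frame], rate)
        if f0 is not None:
            f0s.append(f0)
    return float(np.mean(f0s)) if f0s else None
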