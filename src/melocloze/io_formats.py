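"""Readers and writers for stems, response tables and participant metadata.

Interchange formats are deliberately plain: stems travel as JSON (or are
imported from monophonic single-track MIDI), behavioral tables as UTF-8
comma-separated CSV with mandatory header rows.  Audio is referenced by
path only; WAV handling lives in :mod:`melocloze.response_processing`.

JSON stem schema (one object per stem, file holds ``{"stems": [...]}``)::

    {"stem_id": str, "pair_id": str, "condition": "AC"|"NC"|"unlabeled",
     "key": {"tonic": 0-11, "mode": "major"|"minor"},
     "meter": "4/4", "tempo_bpm": float,
     "notes": [{"midi": int, "onset_beats": float, "duration_beats": float}]}

Participant CSV columns: ``participant_id, voice_octave_shift,
years_formal_training, pitch_matching_trials`` — the last a JSON-encoded
list of ``[presented_index, sung_f0_hz]`` pairs.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .melody_core import (
    KeyContext,
    MelodicStem,
    NoteEvent,
    Pitch,
)

__all__ = [
    "StemValidationError",
    "MidiFormatError",
    "ResponseTableRow",
    "ParticipantRecord",
    "read_stems",
    "write_stems",
    "stem_to_dict",
    "stem_from_dict",
    "read_midi",
    "write_midi",
    "read_responses",
    "write_responses",
    "read_participants",
    "write_participants",
]


class StemValidationError(ValueError):
    """A stems file violated the documented schema."""


class MidiFormatError(ValueError):
    """A MIDI file is unreadable or not a monophonic single-voice track."""


# -- behavioral record types -------------------------------------------------


@dataclass(frozen=True)
class ResponseTableRow:
    """One raw sung-response record as read from the response CSV."""

    participant_id: str
    stem_id: str
    mean_f0_hz: float | None = None
    sung_index: int | None = None
    onset_latency_ms: float | None = None
    sung_duration_ms: float | None = None
    confidence: int | None = None

    def __post_init__(self) -> None:
        if self.mean_f0_hz is None and self.sung_index is None:
            raise StemValidationError(
                f"response ({self.participant_id}, {self.stem_id}): "
                "needs mean_f0_hz or sung_index"
            )
        if self.confidence is not None and not (1 <= self.confidence <= 7):
            raise StemValidationError(
                f"response ({self.participant_id}, {self.stem_id}): "
                f"confidence {self.confidence} outside 1..7"
            )


@dataclass(frozen=True)
class ParticipantRecord:
    """Participant metadata plus their pitch-matching calibration trials."""

    participant_id: str
    voice_octave_shift: int = 0
    years_formal_training: float = 0.0
    pitch_matching_trials: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.years_formal_training < 0:
            raise StemValidationError(
                f"participant {self.participant_id}: negative years of training"
            )


# -- JSON stems --------------------------------------------------------------

_CONDITIONS = ("AC", "NC", "unlabeled")


def stem_to_dict(stem: MelodicStem) -> dict:
    return {
        "stem_id": stem.stem_id,
        "pair_id": stem.pair_id,
        "condition": stem.condition,
        "key": {"tonic": stem.key.tonic_pitch_class, "mode": stem.key.mode},
        "meter": stem.key.meter,
        "tempo_bpm": stem.key.tempo_bpm,
        "notes": [
            {
                "midi": n.pitch.semitone_index,
                "onset_beats": n.onset_beats,
                "duration_beats": n.duration_beats,
            }
            for n in stem.notes
        ],
    }


def _require(obj: dict, name: str, context: str):
    if name not in obj:
        raise StemValidationError(f"{context}: missing field {name!r}")
    return obj[name]


def stem_from_dict(obj: dict) -> MelodicStem:
    ctx = f"stem {obj.get('stem_id', '<no id>')!r}"
    condition = obj.get("condition", "unlabeled")
    if condition not in _CONDITIONS:
        raise StemValidationError(f"{ctx}: bad condition {condition!r}")
    key_obj = _require(obj, "key", ctx)
    try:
        key = KeyContext(
            tonic_pitch_class=int(_require(key_obj, "tonic", ctx)),
            mode=_require(key_obj, "mode", ctx),
            meter=obj.get("meter", "4/4"),
            tempo_bpm=float(obj.get("tempo_bpm", 120.0)),
        )
        notes = tuple(
            NoteEvent(
                pitch=Pitch(int(_require(n, "midi", ctx))),
                onset_beats=float(_require(n, "onset_beats", ctx)),
                duration_beats=float(_require(n, "duration_beats", ctx)),
            )
            for n in _require(obj, "notes", ctx)
        )
        return MelodicStem(
            stem_id=str(_require(obj, "stem_id", ctx)),
            notes=notes,
            key=key,
            condition=condition,
            pair_id=str(obj.get("pair_id", "")),
        )
    except StemValidationError:
        raise
    except (ValueError, TypeError) as exc:
        raise StemValidationError(f"{ctx}: {exc}") from exc


def read_stems(path: str | Path) -> list[MelodicStem]:
    """Read a stems JSON file (or import a MIDI file by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".mid", ".midi"):
        return [read_midi(path)]
    data = json.loads(path.read_text())
    if isinstance(data, dict):
        data = _require(data, "stems", str(path))
    if not isinstance(data, list):
        raise StemValidationError(f"{path}: expected a list of stems")
    return [stem_from_dict(obj) for obj in data]


def write_stems(stems: Iterable[MelodicStem], path: str | Path) -> None:
    payload = {"stems": [stem_to_dict(s) for s in stems]}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# -- MIDI import (minimal monophonic SMF reader) -----------------------------
#
# Only what the stem format needs: one note-bearing track, note on/off,
# tempo / time-signature / key-signature meta events.  Ticks are assumed
# PPQ (SMPTE division is rejected).


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        if pos >= len(data):
            raise MidiFormatError("truncated variable-length quantity")
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def _key_signature_tonic(sf: int, minor: bool) -> int:
    # circle of fifths: each sharp raises the major tonic by a fifth
    tonic = (sf * 7) % 12
    return (tonic + 9) % 12 if minor else tonic


def read_midi(
    path: str | Path,
    sidecar: str | Path | None = None,
    stem_id: str | None = None,
) -> MelodicStem:
    """Import a monophonic single-voice MIDI file as a stem.

    Key/meter/tempo come from meta events when present; a sidecar JSON
    (same schema as a stem object, ``notes`` ignored) overrides them.
    Overlapping notes or notes spread over several tracks raise
    :class:`MidiFormatError`.
    """
    path = Path(path)
    raw = path.read_bytes()
    if raw[:4] != b"MThd":
        raise MidiFormatError(f"{path}: not a Standard MIDI File")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", raw[4:14])
    if division & 0x8000:
        raise MidiFormatError(f"{path}: SMPTE time division not supported")
    pos = 8 + hlen
    tempo_bpm = 120.0
    meter = "4/4"
    key_tonic: int | None = None
    key_mode = "major"
    note_tracks = 0
    notes: list[tuple[int, int, int]] = []  # (onset_ticks, off_ticks, pitch)

    for _ in range(ntrks):
        if raw[pos : pos + 4] != b"MTrk":
            raise MidiFormatError(f"{path}: malformed track chunk")
        (tlen,) = struct.unpack(">I", raw[pos + 4 : pos + 8])
        data = raw[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen
        tick = 0
        i = 0
        status = 0
        active: dict[int, int] = {}  # pitch -> onset tick
        track_notes: list[tuple[int, int, int]] = []
        while i < len(data):
            delta, i = _read_varint(data, i)
            tick += delta
            b = data[i]
            if b & 0x80:
                status = b
                i += 1
            if status == 0xFF:
                mtype = data[i]
                length, i2 = _read_varint(data, i + 1)
                payload = data[i2 : i2 + length]
                i = i2 + length
                if mtype == 0x51 and length == 3:
                    usec = int.from_bytes(payload, "big")
                    tempo_bpm = 60_000_000.0 / usec
                elif mtype == 0x58 and length >= 2:
                    meter = f"{payload[0]}/{2 ** payload[1]}"
                elif mtype == 0x59 and length >= 2:
                    sf = struct.unpack("b", payload[:1])[0]
                    key_mode = "minor" if payload[1] else "major"
                    key_tonic = _key_signature_tonic(sf, bool(payload[1]))
                elif mtype == 0x2F:
                    break
            elif status in (0xF0, 0xF7):  # sysex
                length, i2 = _read_varint(data, i)
                i = i2 + length
            else:
                kind = status & 0xF0
                if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
                    d1, d2 = data[i], data[i + 1]
                    i += 2
                elif kind in (0xC0, 0xD0):
                    d1, d2 = data[i], 0
                    i += 1
                else:
                    raise MidiFormatError(f"{path}: bad status byte 0x{status:02x}")
                if kind == 0x90 and d2 > 0:
                    if active:
                        raise MidiFormatError(
                            f"{path}: polyphonic track (overlapping notes)"
                        )
                    active[d1] = tick
                elif kind == 0x80 or (kind == 0x90 and d2 == 0):
                    if d1 in active:
                        track_notes.append((active.pop(d1), tick, d1))
        if active:
            raise MidiFormatError(f"{path}: note without matching note-off")
        if track_notes:
            note_tracks += 1
            notes = track_notes
    if note_tracks == 0:
        raise MidiFormatError(f"{path}: no notes found")
    if note_tracks > 1:
        raise MidiFormatError(f"{path}: notes on multiple tracks (not monophonic)")

    side: dict = {}
    if sidecar is not None:
        side = json.loads(Path(sidecar).read_text())
    key_obj = side.get("key", {})
    tonic = key_obj.get("tonic", key_tonic)
    if tonic is None:
        raise MidiFormatError(
            f"{path}: no key signature and no sidecar key; cannot build KeyContext"
        )
    key = KeyContext(
        tonic_pitch_class=int(tonic),
        mode=key_obj.get("mode", key_mode),
        meter=side.get("meter", meter),
        tempo_bpm=float(side.get("tempo_bpm", tempo_bpm)),
    )
    notes.sort()
    first = notes[0][0]
    events = tuple(
        NoteEvent(
            pitch=Pitch(p),
            onset_beats=(on - first) / division,
            duration_beats=(off - on) / division,
        )
        for on, off, p in notes
    )
    return MelodicStem(
        stem_id=str(side.get("stem_id", stem_id or path.stem)),
        notes=events,
        key=key,
        condition=side.get("condition", "unlabeled"),
        pair_id=str(side.get("pair_id", "")),
    )


def write_midi(stem: MelodicStem, path: str | Path, division: int = 480) -> None:
    """Write a stem as a single-track SMF (used for fixtures/interchange)."""

    def varint(v: int) -> bytes:
        out = [v & 0x7F]
        v >>= 7
        while v:
            out.append(0x80 | (v & 0x7F))
            v >>= 7
        return bytes(reversed(out))

    events: list[bytes] = []
    usec = round(60_000_000 / stem.key.tempo_bpm)
    events.append(b"\x00\xff\x51\x03" + usec.to_bytes(3, "big"))
    num, den = (int(x) for x in stem.key.meter.split("/"))
    events.append(b"\x00\xff\x58\x04" + bytes([num, den.bit_length() - 1, 24, 8]))
    # sharps on the circle of fifths for the major/minor tonic
    rel_major = stem.key.tonic_pitch_class if stem.key.mode == "major" else (
        stem.key.tonic_pitch_class + 3) % 12
    sf = ((rel_major * 7) % 12 + 5) % 12 - 5  # -5..6 accidentals
    events.append(
        b"\x00\xff\x59\x02"
        + struct.pack("b", sf)
        + bytes([1 if stem.key.mode == "minor" else 0])
    )
    tick = 0
    for n in stem.notes:
        on = round(n.onset_beats * division)
        off = round(n.offset_beats * division)
        events.append(varint(on - tick) + bytes([0x90, n.pitch.semitone_index, 64]))
        events.append(varint(off - on) + bytes([0x80, n.pitch.semitone_index, 0]))
        tick = off
    events.append(b"\x00\xff\x2f\x00")
    track = b"".join(events)
    out = (
        b"MThd" + struct.pack(">IHHH", 6, 0, 1, division)
        + b"MTrk" + struct.pack(">I", len(track)) + track
    )
    Path(path).write_bytes(out)


# -- behavioral CSVs ---------------------------------------------------------

_RESPONSE_COLUMNS = [
    "participant_id",
    "stem_id",
    "mean_f0_hz",
    "sung_index",
    "onset_latency_ms",
    "sung_duration_ms",
    "confidence",
]
_MANDATORY_RESPONSE = ["participant_id", "stem_id"]
_PARTICIPANT_COLUMNS = [
    "participant_id",
    "voice_octave_shift",
    "years_formal_training",
    "pitch_matching_trials",
]


def _check_columns(df: pd.DataFrame, mandatory: Sequence[str], path) -> None:
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise StemValidationError(f"{path}: missing column(s) {', '.join(missing)}")


def _opt(value, cast):
    return None if pd.isna(value) else cast(value)


def read_responses(path: str | Path) -> list[ResponseTableRow]:
    df = pd.read_csv(path)
    _check_columns(df, _MANDATORY_RESPONSE, path)
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            ResponseTableRow(
                participant_id=str(rec["participant_id"]),
                stem_id=str(rec["stem_id"]),
                mean_f0_hz=_opt(rec.get("mean_f0_hz"), float),
                sung_index=_opt(rec.get("sung_index"), lambda v: int(round(float(v)))),
                onset_latency_ms=_opt(rec.get("onset_latency_ms"), float),
                sung_duration_ms=_opt(rec.get("sung_duration_ms"), float),
                confidence=_opt(rec.get("confidence"), lambda v: int(round(float(v)))),
            )
        )
    return rows


def write_responses(rows: Iterable[ResponseTableRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "stem_id": r.stem_id,
                "mean_f0_hz": r.mean_f0_hz,
                "sung_index": r.sung_index,
                "onset_latency_ms": r.onset_latency_ms,
                "sung_duration_ms": r.sung_duration_ms,
                "confidence": r.confidence,
            }
            for r in rows
        ],
        columns=_RESPONSE_COLUMNS,
    ).to_csv(path, index=False)


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id"], path)
    records = []
    for rec in df.to_dict("records"):
        trials_raw = rec.get("pitch_matching_trials")
        trials: tuple[tuple[int, float], ...] = ()
        if isinstance(trials_raw, str) and trials_raw.strip():
            trials = tuple(
                (int(t[0]), float(t[1])) for t in json.loads(trials_raw)
            )
        records.append(
            ParticipantRecord(
                participant_id=str(rec["participant_id"]),
                voice_octave_shift=int(rec.get("voice_octave_shift", 0) or 0),
                years_formal_training=float(rec.get("years_formal_training", 0.0)),
                pitch_matching_trials=trials,
            )
        )
    return records


def write_participants(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "voice_octave_shift": r.voice_octave_shift,
                "years_formal_training": r.years_formal_training,
                "pitch_matching_trials": json.dumps(
                    [[i, f] for i, f in r.pitch_matching_trials]
                ),
            }
            for r in records
        ],
        columns=_PARTICIPANT_COLUMNS,
    ).to_csv(path, index=False)
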