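"""Symbolic pitch/time arithmetic and the melodic-stem data model.

Pitches are equal-tempered chromatic indices (A4 = 69, A4 = 440 Hz by
default) with an optional cents deviation recording how far a measured
frequency fell from the nearest chromatic scale tone.  Melodic stems are
monophonic, rest-free note sequences carrying a key/meter/tempo context
and an authentic-cadence (AC) / non-cadence (NC) condition label; matched
AC/NC stems form a :class:`StemPair` sharing length, rhythm and contour.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence, Union

__all__ = [
    "A4_INDEX",
    "A4_HZ",
    "MIN_INDEX",
    "MAX_INDEX",
    "MAJOR_DEGREE_CLASSES",
    "MINOR_DEGREE_CLASSES",
    "Pitch",
    "KeyContext",
    "NoteEvent",
    "MelodicStem",
    "StemPair",
    "DegreeLabel",
    "note_name_to_index",
    "index_to_note_name",
    "index_to_frequency",
    "frequency_to_nearest_pitch",
    "scale_degree",
    "beats_to_ms",
    "ms_to_beats",
    "transpose",
    "contour",
    "pair_difference_stats",
]

# -- conventions -------------------------------------------------------------

A4_INDEX = 69
A4_HZ = 440.0
#: accepted chromatic range (A0..C8) for vocal/instrumental material
MIN_INDEX = 21
MAX_INDEX = 108

#: pitch classes of the diatonic degrees, relative to the tonic
MAJOR_DEGREE_CLASSES = (0, 2, 4, 5, 7, 9, 11)
MINOR_DEGREE_CLASSES = (0, 2, 3, 5, 7, 8, 10)  # natural minor

_NOTE_RE = re.compile(r"^([A-Ga-g])([#b]?)(-?\d+)$")
_LETTER_CLASS = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}

Mode = Literal["major", "minor"]
Condition = Literal["AC", "NC", "unlabeled"]
DegreeLabel = Union[int, str]


# -- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class Pitch:
    """A chromatic pitch: semitone index plus signed cents deviation.

    ``cents_deviation`` is the signed distance (in hundredths of a
    semitone) from the equal-tempered frequency of ``semitone_index``;
    it is 0 for symbolic material and populated when a measured
    frequency is rounded to the nearest semitone.
    """

    semitone_index: int
    cents_deviation: float = 0.0

    def __post_init__(self) -> None:
        if not (MIN_INDEX <= self.semitone_index <= MAX_INDEX):
            raise ValueError(
                f"semitone index {self.semitone_index} outside accepted "
                f"range [{MIN_INDEX}, {MAX_INDEX}]"
            )
        if abs(self.cents_deviation) > 50.0:
            raise ValueError(
                f"cents deviation {self.cents_deviation} outside half-semitone band"
            )

    @property
    def pitch_class(self) -> int:
        return self.semitone_index % 12

    def frequency(self, reference_hz: float = A4_HZ) -> float:
        """Exact frequency of this pitch including its cents deviation."""
        return index_to_frequency(self.semitone_index, reference_hz) * 2.0 ** (
            self.cents_deviation / 1200.0
        )


@dataclass(frozen=True)
class KeyContext:
    """Key, meter and tempo context of a stem."""

    tonic_pitch_class: int
    mode: Mode = "major"
    meter: str = "4/4"
    tempo_bpm: float = 120.0

    def __post_init__(self) -> None:
        if not (0 <= self.tonic_pitch_class <= 11):
            raise ValueError("tonic_pitch_class must be in 0..11")
        if self.mode not in ("major", "minor"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tempo_bpm <= 0:
            raise ValueError("tempo_bpm must be positive")

    @property
    def degree_classes(self) -> tuple[int, ...]:
        return MAJOR_DEGREE_CLASSES if self.mode == "major" else MINOR_DEGREE_CLASSES


@dataclass(frozen=True)
class NoteEvent:
    pitch: Pitch
    onset_beats: float
    duration_beats: float

    def __post_init__(self) -> None:
        if self.onset_beats < 0:
            raise ValueError("onset_beats must be nonnegative")
        if self.duration_beats <= 0:
            raise ValueError("duration_beats must be positive")

    @property
    def offset_beats(self) -> float:
        return self.onset_beats + self.duration_beats


@dataclass(frozen=True)
class MelodicStem:
    """A monophonic melodic opening (stem) with key context.

    Hard invariants (raised): notes ordered by onset, non-overlapping.
    Soft style checks matching the norming stimuli (warned, not
    rejected): 5-9 notes, no internal rests, all pitches diatonic.
    """

    stem_id: str
    notes: tuple[NoteEvent, ...]
    key: KeyContext
    condition: Condition = "unlabeled"
    pair_id: str = ""

    def __post_init__(self) -> None:
        notes = tuple(self.notes)
        object.__setattr__(self, "notes", notes)
        if not notes:
            raise ValueError(f"stem {self.stem_id!r} has no notes")
        prev_off = None
        for n in notes:
            if prev_off is not None and n.onset_beats < prev_off - 1e-9:
                raise ValueError(
                    f"stem {self.stem_id!r}: overlapping/unordered notes "
                    f"(onset {n.onset_beats} before previous offset {prev_off})"
                )
            prev_off = n.offset_beats
        if not (5 <= len(notes) <= 9):
            warnings.warn(
                f"stem {self.stem_id!r} has {len(notes)} notes "
                "(norming stimuli are 5-9 notes)",
                stacklevel=2,
            )
        gaps = [
            b.onset_beats - a.offset_beats
            for a, b in zip(notes, notes[1:])
            if b.onset_beats - a.offset_beats > 1e-6
        ]
        if gaps:
            warnings.warn(
                f"stem {self.stem_id!r} contains rests (norming stimuli have none)",
                stacklevel=2,
            )
        degset = set(self.key.degree_classes)
        if any((n.pitch.pitch_class - self.key.tonic_pitch_class) % 12 not in degset
               for n in notes):
            warnings.warn(
                f"stem {self.stem_id!r} contains non-diatonic pitches",
                stacklevel=2,
            )

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(n.pitch.semitone_index for n in self.notes)

    @property
    def final_index(self) -> int:
        return self.notes[-1].pitch.semitone_index

    @property
    def final_degree(self) -> DegreeLabel:
        return scale_degree(self.notes[-1].pitch.pitch_class, self.key)

    @property
    def total_beats(self) -> float:
        return self.notes[-1].offset_beats - self.notes[0].onset_beats


@dataclass(frozen=True)
class StemPair:
    """A matched AC/NC stem pair: same length, rhythm, contour and key."""

    ac: MelodicStem
    nc: MelodicStem
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not self.pair_id:
            object.__setattr__(self, "pair_id", self.ac.pair_id or self.nc.pair_id)
        ac, nc = self.ac, self.nc
        if len(ac.notes) != len(nc.notes):
            raise ValueError(
                f"pair {self.pair_id!r}: note counts differ "
                f"({len(ac.notes)} vs {len(nc.notes)})"
            )
        for i, (a, b) in enumerate(zip(ac.notes, nc.notes)):
            if abs(a.duration_beats - b.duration_beats) > 1e-9:
                raise ValueError(
                    f"pair {self.pair_id!r}: rhythm differs at note {i}"
                )
        if contour(ac) != contour(nc):
            raise ValueError(f"pair {self.pair_id!r}: melodic contours differ")
        if (ac.key.tonic_pitch_class, ac.key.mode) != (
            nc.key.tonic_pitch_class,
            nc.key.mode,
        ):
            raise ValueError(f"pair {self.pair_id!r}: keys differ")


# -- pitch arithmetic --------------------------------------------------------


def note_name_to_index(name: str) -> int:
    """Scientific pitch name -> chromatic index (A4 -> 69).

    Accepts an optional single sharp (#) or flat (b); enharmonic
    spellings map to the same index.
    """
    m = _NOTE_RE.match(name.strip())
    if m is None:
        raise ValueError(f"malformed note name {name!r}")
    letter, accidental, octave = m.groups()
    pc = _LETTER_CLASS[letter.upper()]
    if accidental == "#":
        pc += 1
    elif accidental == "b":
        pc -= 1
    return pc + 12 * (int(octave) + 1)


_SHARP_NAMES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")


def index_to_note_name(index: int) -> str:
    """Chromatic index -> sharp-spelled scientific pitch name (69 -> 'A4')."""
    return f"{_SHARP_NAMES[index % 12]}{index // 12 - 1}"


def index_to_frequency(index: int, reference_hz: float = A4_HZ) -> float:
    """Equal-tempered frequency of a chromatic index (A4 = ``reference_hz``)."""
    if reference_hz <= 0:
        raise ValueError("reference_hz must be positive")
    return reference_hz * 2.0 ** ((index - A4_INDEX) / 12.0)


def frequency_to_nearest_pitch(f: float, reference_hz: float = A4_HZ) -> Pitch:
    """Round a frequency to the closest chromatic scale tone.

    Returns the nearest semitone index together with the signed cents
    deviation 1200*log2(f / f_nearest).  A frequency exactly halfway
    between two semitones rounds to the upper one.
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    fractional = A4_INDEX + 12.0 * math.log2(f / reference_hz)
    index = math.floor(fractional + 0.5)  # half-up: exact ties go to upper tone
    cents = 100.0 * (fractional - index)
    return Pitch(semitone_index=index, cents_deviation=cents)


def scale_degree(pitch_class: int, key: KeyContext) -> DegreeLabel:
    """Scale degree of a pitch class in a key.

    Diatonic classes map to integers 1..7; anything else returns the
    chromatic label ``"chromatic:<pc relative to tonic>"``.  Octave
    shifts of the input are irrelevant by construction (pitch classes).
    """
    rel = (pitch_class - key.tonic_pitch_class) % 12
    classes = key.degree_classes
    if rel in classes:
        return classes.index(rel) + 1
    return f"chromatic:{rel}"


# -- time arithmetic ---------------------------------------------------------


def beats_to_ms(beats: float, tempo_bpm: float) -> float:
    if tempo_bpm <= 0:
        raise ValueError("tempo_bpm must be positive")
    return beats * 60000.0 / tempo_bpm


def ms_to_beats(ms: float, tempo_bpm: float) -> float:
    if tempo_bpm <= 0:
        raise ValueError("tempo_bpm must be positive")
    return ms * tempo_bpm / 60000.0


# -- stem operations ---------------------------------------------------------


def transpose(stem: MelodicStem, semitones: int) -> MelodicStem:
    """Shift every note by ``semitones``; the key tonic shifts mod 12.

    Raises if any resulting index leaves the accepted range (the Pitch
    constructor enforces it).
    """
    notes = tuple(
        replace(n, pitch=Pitch(n.pitch.semitone_index + semitones,
                               n.pitch.cents_deviation))
        for n in stem.notes
    )
    key = replace(stem.key,
                  tonic_pitch_class=(stem.key.tonic_pitch_class + semitones) % 12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return replace(stem, notes=notes, key=key)


def contour(stem: MelodicStem) -> tuple[int, ...]:
    """Sign (-1, 0, +1) of each successive melodic interval."""
    idx = stem.indices
    if len(idx) < 2:
        raise ValueError("contour requires at least 2 notes")
    return tuple(int(math.copysign(1, b - a)) if b != a else 0
                 for a, b in zip(idx, idx[1:]))


def pair_difference_stats(pair: StemPair) -> tuple[float, float]:
    """(fraction of note positions differing, mean |semitone gap| there).

    The gap is averaged over differing positions only; identical stems
    return ``(0.0, 0.0)`` by convention.  Differences are exact index
    inequalities (an octave-displaced note counts as different).
    """
    a, b = pair.ac.indices, pair.nc.indices
    if len(a) != len(b):
        raise ValueError("stems differ in length")
    gaps = [abs(x - y) for x, y in zip(a, b) if x != y]
    if not gaps:
        return 0.0, 0.0
    return len(gaps) / len(a), sum(gaps) / len(gaps)
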