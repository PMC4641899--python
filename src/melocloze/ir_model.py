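"""Simplified Implication-Realization melodic-expectancy model.

Scores every candidate continuation within two octaves of a stem's
final note on three factors:

* **pitch proximity** — listeners expect the next tone close in pitch to
  the last tone heard; scored linearly decreasing in interval size.
* **pitch reversal** — after a large interval (a leap of at least 7
  semitones by default) listeners expect a change of direction, and a
  return to the pitch region of the penultimate tone (registral
  return).
* **tonality** — tonally stable continuations are more expected; scored
  by the Krumhansl-Kessler probe-tone rating of the candidate's pitch
  class in the stem's key.

The three factors are weighted evenly by equalizing their maxima: each
raw factor is divided by its maximum over the candidate set before the
(default equal) weights are applied.  The exact numeric coding of the
two melodic factors is a reconstruction of the published two-factor
formulation; every threshold and weight is exposed in
:class:`ModelConfig` so alternative codings can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .melody_core import KeyContext, MelodicStem
from .key_finding import KK_MAJOR_PROFILE, KK_MINOR_PROFILE

__all__ = [
    "ModelConfig",
    "ExpectancyTable",
    "proximity_raw",
    "reversal_raw",
    "tonality_raw",
    "expectancy_table",
]


@dataclass(frozen=True)
class ModelConfig:
    """Tunable parameters of the simplified I-R model.

    ``candidate_range_semitones`` — candidates span the stem's final
    note plus/minus this many semitones (24 = two octaves, 49
    candidates).  ``weights`` multiply the max-equalized (proximity,
    reversal, tonality) factors; set a weight to 0 to ablate a factor.
    ``large_interval_threshold_semitones`` — smallest implicative
    interval treated as a leap (7 st, a perfect fifth).
    ``registral_return_window_semitones`` — how close to the penultimate
    tone a candidate must land to earn the registral-return bonus.
    """

    candidate_range_semitones: int = 24
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    large_interval_threshold_semitones: int = 7
    registral_return_window_semitones: int = 2

    def __post_init__(self) -> None:
        if self.candidate_range_semitones < 1:
            raise ValueError("candidate_range_semitones must be >= 1")
        if any(w < 0 for w in self.weights) or not any(self.weights):
            raise ValueError("weights must be nonnegative and not all zero")


@dataclass(frozen=True)
class ExpectancyTable:
    """Per-candidate factor scores and combined expectancies for one stem.

    ``candidates`` maps each candidate semitone index to
    ``(proximity_raw, reversal_raw, tonality_raw, combined)``.
    ``predicted`` lists the argmax candidate(s) after deterministic
    tie-breaking (nearest the final note, then the lower pitch).
    """

    stem_id: str
    final_index: int
    candidates: dict[int, tuple[float, float, float, float]]
    predicted: tuple[int, ...]

    @property
    def predicted_index(self) -> int:
        return self.predicted[0]

    @property
    def predicted_pitch_class(self) -> int:
        return self.predicted[0] % 12

    def combined_scores(self) -> dict[int, float]:
        return {c: v[3] for c, v in self.candidates.items()}


def proximity_raw(
    realized_interval: int, config: ModelConfig = ModelConfig()
) -> float:
    """Linear proximity score: maximal at the unison, decreasing with
    interval size, floored at 0."""
    return float(max(0, config.candidate_range_semitones - abs(realized_interval)))


def reversal_raw(
    implicative_interval: int,
    realized_interval: int,
    config: ModelConfig = ModelConfig(),
) -> float:
    """Pitch-reversal score: direction component + registral return.

    The direction component is +1 when a leap (|implicative| >= the
    large-interval threshold) is followed by a change of direction, -1
    when a leap continues in the same direction, and 0 for small
    implicative intervals or a repeated tone.  The registral-return
    component adds +1.5 when the candidate lands within the return
    window of the penultimate tone.  A constant +1 shift keeps the score
    nonnegative.
    """
    thresh = config.large_interval_threshold_semitones
    if abs(implicative_interval) < thresh or realized_interval == 0:
        direction = 0.0
    elif np.sign(realized_interval) == -np.sign(implicative_interval):
        direction = 1.0
    else:
        direction = -1.0
    # candidate position relative to the penultimate tone:
    # candidate - penultimate = (candidate - final) + (final - penultimate)
    from_penultimate = realized_interval + implicative_interval
    ret = 1.5 if abs(from_penultimate) <= config.registral_return_window_semitones else 0.0
    return direction + ret + 1.0


def tonality_raw(candidate_pitch_class: int, key: KeyContext) -> float:
    """Krumhansl-Kessler stability of the candidate's pitch class in key."""
    profile = KK_MAJOR_PROFILE if key.mode == "major" else KK_MINOR_PROFILE
    return float(profile[(candidate_pitch_class - key.tonic_pitch_class) % 12])


def expectancy_table(
    stem: MelodicStem, config: ModelConfig = ModelConfig()
) -> ExpectancyTable:
    """Score all candidate continuations of a stem.

    Candidates are the concrete pitches within the candidate range of
    the final note (proximity and reversal are octave-sensitive;
    tonality depends only on pitch class).  Each factor is normalized by
    its maximum over the candidate set ("max-equalized"), weighted, and
    summed.
    """
    if len(stem.notes) < 2:
        raise ValueError(
            f"stem {stem.stem_id!r}: expectancy needs >= 2 notes "
            "(the implicative interval requires a penultimate tone)"
        )
    final = stem.final_index
    penultimate = stem.notes[-2].pitch.semitone_index
    implicative = final - penultimate
    rng = config.candidate_range_semitones
    cands = list(range(final - rng, final + rng + 1))

    prox = np.array([proximity_raw(c - final, config) for c in cands])
    rev = np.array([reversal_raw(implicative, c - final, config) for c in cands])
    ton = np.array([tonality_raw(c % 12, stem.key) for c in cands])

    combined = np.zeros(len(cands))
    for w, raw in zip(config.weights, (prox, rev, ton)):
        mx = raw.max()
        if mx > 0:
            combined += w * raw / mx

    best = combined.max()
    tied = [c for c, s in zip(cands, combined) if s >= best - 1e-12]
    # deterministic tie-break: nearest the final note, then the lower pitch
    tied.sort(key=lambda c: (abs(c - final), c))
    table = {
        c: (float(p), float(r), float(t), float(s))
        for c, p, r, t, s in zip(cands, prox, rev, ton, combined)
    }
    return ExpectancyTable(
        stem_id=stem.stem_id,
        final_index=final,
        candidates=table,
        predicted=tuple(tied),
    )
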