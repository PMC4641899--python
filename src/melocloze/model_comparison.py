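"""Compare I-R model predictions with behavioral modal responses.

Only high-constraint stems are compared (default threshold: constraint
strictly above 0.69, the AC-condition mean), since those are the cases
where listeners held a strong shared expectation.  A prediction is
correct when its pitch class equals the behaviorally most common pitch
class (responses were octave-generalized, so the comparison is too).
For mismatches, the distance between prediction and modal response is
reported both folded onto the pitch-class circle (0-6 st, the default)
and as the raw distance from the predicted concrete pitch to the modal
class lifted to the nearest octave — the two coincide; both are kept
because published mismatch distances do not state their octave
convention.  Mismatches whose predicted class is the behavioral
runner-up are also counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cloze_stats import ConstraintResult, ResponseDistribution
from .ir_model import ExpectancyTable

__all__ = [
    "ComparisonResult",
    "select_high_constraint",
    "evaluate",
    "pitch_class_distance",
    "distance_histogram",
]

HIGH_CONSTRAINT_THRESHOLD = 0.69


@dataclass(frozen=True)
class ComparisonResult:
    selected_stem_ids: tuple[str, ...]
    n_selected: int
    n_correct: int
    proportion_correct: float
    mismatch_distances_semitones: tuple[float, ...]
    mean_distance: float
    sd_distance: float
    second_choice_hits: int

    def __post_init__(self) -> None:
        if self.n_correct + len(self.mismatch_distances_semitones) != self.n_selected:
            raise ValueError("correct + mismatches must cover all selected stems")


def select_high_constraint(
    results: Sequence[ConstraintResult],
    threshold: float = HIGH_CONSTRAINT_THRESHOLD,
) -> list[ConstraintResult]:
    """Stems with constraint strictly greater than ``threshold``."""
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    return [r for r in results if r.constraint > threshold]


def pitch_class_distance(index_a: int, pitch_class_b: int) -> int:
    """Semitone distance from a concrete pitch to the nearest-octave lift
    of a pitch class (equivalently, distance on the pitch-class circle)."""
    d = (index_a - pitch_class_b) % 12
    return min(d, 12 - d)


def evaluate(
    predictions: Mapping[str, ExpectancyTable],
    behavior: Sequence[ConstraintResult],
    distributions: Mapping[str, ResponseDistribution] | None = None,
    tie_policy: str = "permissive",
) -> ComparisonResult:
    """Score model predictions against behavioral modal notes.

    ``behavior`` holds the (already selected) stems to compare;
    ``predictions`` must contain an expectancy table for each.  With the
    default permissive tie policy a behavioral tie counts as correct if
    the predicted class is any tied class ("strict" requires a unique
    modal class equal to the prediction).  ``distributions`` enable the
    runner-up check on mismatches.
    """
    if tie_policy not in ("permissive", "strict"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    ids = []
    n_correct = 0
    distances: list[float] = []
    second_hits = 0
    for res in behavior:
        if res.stem_id not in predictions:
            raise KeyError(f"no prediction for stem {res.stem_id!r}")
        pred = predictions[res.stem_id]
        pred_pc = pred.predicted_pitch_class
        ids.append(res.stem_id)
        modal = res.modal_pitch_classes
        if tie_policy == "permissive":
            correct = pred_pc in modal
        else:
            correct = len(modal) == 1 and pred_pc == modal[0]
        if correct:
            n_correct += 1
            continue
        # distance to the (first) modal class, folded to the nearest octave
        distances.append(float(pitch_class_distance(pred.predicted_index, modal[0])))
        if distributions is not None and res.stem_id in distributions:
            dist = distributions[res.stem_id]
            counts = sorted(dist.counts.items(), key=lambda kv: -kv[1])
            runner_count = next(
                (c for pc, c in counts if pc not in modal), None
            )
            if runner_count is not None:
                runners = {pc for pc, c in counts if c == runner_count}
                if pred_pc in runners:
                    second_hits += 1
    n = len(ids)
    return ComparisonResult(
        selected_stem_ids=tuple(ids),
        n_selected=n,
        n_correct=n_correct,
        proportion_correct=n_correct / n if n else 0.0,
        mismatch_distances_semitones=tuple(distances),
        mean_distance=float(np.mean(distances)) if distances else 0.0,
        sd_distance=float(np.std(distances, ddof=1)) if len(distances) > 1 else 0.0,
        second_choice_hits=second_hits,
    )


def distance_histogram(result: ComparisonResult) -> dict[int, int]:
    """Counts of mismatch distances (semitones), for CSV export."""
    hist: dict[int, int] = {}
    for d in result.mismatch_distances_semitones:
        hist[int(round(d))] = hist.get(int(round(d)), 0) + 1
    return dict(sorted(hist.items()))
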