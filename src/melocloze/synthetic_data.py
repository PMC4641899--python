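"""Study-shaped synthetic corpora: AC/NC stem pairs and sung responses.

The norming study's hand-composed stimuli and participant audio are not
machine-reproducible, so this module generates structurally equivalent
material: 45 matched AC/NC stem pairs (same length, rhythm, contour and
key; AC stems end on scale degree 2, 5 or 7 before a strong beat; NC
stems avoid degrees 2 and 7) and simulated singers whose responses are
drawn from per-stem ground-truth expectancy distributions with vocal
pitch jitter, reaction times, confidence ratings and pitch-matching
calibration trials.

Ground-truth response distributions ("harmonic" source, the default)
place a planted modal probability — drawn per stem from the
condition-level constraint distributions (AC mean 0.692, SD 0.171; NC
mean 0.415, SD 0.153) — on a harmonically motivated modal note (the
tonic nearest the final note for AC stems), with the residual mass
spread over candidates in proportion to a softmax of the I-R model's
combined expectancy.  This makes the behavior harmonically driven, as
in real listeners, while the I-R model sees only local interval
structure.  Alternative sources: "model-softmax" (the model's own
softmax with the temperature calibrated per stem so its maximum equals
the planted constraint) and "explicit" (user-supplied distributions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    ParticipantRecord,
    ResponseTableRow,
    write_participants,
    write_responses,
    write_stems,
)
from .ir_model import ModelConfig, expectancy_table
from .key_finding import KK_MAJOR_PROFILE
from .melody_core import (
    MAJOR_DEGREE_CLASSES,
    KeyContext,
    MelodicStem,
    NoteEvent,
    Pitch,
    StemPair,
    index_to_frequency,
    scale_degree,
)

__all__ = [
    "CorpusSpec",
    "BehaviorSpec",
    "PITCH_MATCHING_INDICES",
    "generate_stem_pair",
    "generate_corpus",
    "ground_truth_distribution",
    "calibrate_temperature",
    "generate_responses",
    "end_to_end_fixture",
]

#: pitch-matching tone set (F4, A4, B3, G#4, A#3, D4, C#4, Eb4)
PITCH_MATCHING_INDICES = (65, 69, 59, 68, 58, 62, 61, 63)

_DUR_CHOICES = (0.5, 1.0, 1.5, 2.0)  # eighth to half note, in beats
_LEN_PROBS = {5: 0.02, 6: 0.04, 7: 0.10, 8: 0.22, 9: 0.62}  # mean 8.38 notes
_BAR_BEATS = {"3/4": 3.0, "4/4": 4.0, "6/8": 3.0}


@dataclass(frozen=True)
class CorpusSpec:
    """Stimulus-set parameters of a norming corpus."""

    n_pairs: int = 45
    tempo_bpm: float = 120.0
    meters: tuple[str, ...] = ("3/4", "4/4", "6/8")
    register_center: int = 64  # near E4, the stimuli's mean pitch
    p_keep_note: float = 0.15  # chance an NC note deliberately reuses the AC
    # pitch (the stability-weighted choice often lands on it anyway; this
    # value puts the corpus-mean differing-note fraction near 0.48)
    max_retries: int = 200


@dataclass(frozen=True)
class BehaviorSpec:
    """Simulated-cohort parameters.

    Defaults are the retained cohort of the norming study: 50 singers,
    24 AC + 21 NC stems each, condition-level constraint, reaction-time
    and confidence distributions as measured there.  Setting
    ``off_pitch_fraction`` > 0 (e.g. 8/58 with ``n_participants=58``)
    adds singers with heavy pitch jitter who fail the exclusion screen.
    """

    n_participants: int = 50
    n_ac_per_participant: int = 24
    expectancy_source: str = "harmonic"  # harmonic | model-softmax | explicit
    explicit_distributions: Mapping[str, Mapping[int, float]] | None = None
    ac_constraint_mean: float = 0.692
    ac_constraint_sd: float = 0.171
    #: AC tonic-response probability by final scale degree (mean, SD);
    #: leading-tone endings pull far more tonic responses than 2 or 5
    ac_constraint_by_degree: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {7: (0.81, 0.12), 5: (0.56, 0.14), 2: (0.58, 0.14)}
    )
    nc_constraint_mean: float = 0.415
    nc_constraint_sd: float = 0.153
    #: within-pair correlation of planted AC/NC constraint: matched stems
    #: share melodic material, so their predictability co-varies
    constraint_pair_correlation: float = 0.5
    residual_temperature: float = 0.8
    vocal_jitter_sd_cents: float = 15.0
    off_pitch_fraction: float = 0.0
    off_pitch_jitter_sd_cents: float = 60.0
    male_fraction: float = 0.42
    #: per-condition (mean, between-participant SD) of mean reaction time
    rt_ms: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"AC": (767.0, 265.0), "NC": (1033.0, 302.0)}
    )
    rt_trial_sd: float = 150.0
    #: SD of the participant-specific AC-vs-NC reaction-time effect
    rt_condition_effect_sd: float = 190.0
    confidence_mean: Mapping[str, float] = field(
        default_factory=lambda: {"AC": 5.14, "NC": 4.36}
    )
    confidence_between_sd: float = 0.93
    confidence_condition_effect_sd: float = 0.5
    confidence_sd: float = 0.8
    duration_ms: tuple[float, float] = (1896.0, 808.0)
    training_years: tuple[float, float] = (9.0, 4.8)
    #: added tonic probability per SD of training, by AC final degree
    training_slopes: Mapping[int, float] = field(
        default_factory=lambda: {7: 0.065, 5: 0.045, 2: 0.0}
    )


# -- stem-pair generation ----------------------------------------------------


def _ladder_to_index(pos: int, tonic: int) -> int:
    """Diatonic ladder position -> chromatic index (pos 0 = tonic, octave -1)."""
    octave, deg = divmod(pos, 7)
    return 12 * (octave + 1) + tonic + MAJOR_DEGREE_CLASSES[deg]


def _nearest_ladder(index: int, tonic: int) -> int:
    """Ladder position of the diatonic pitch closest to a chromatic index."""
    approx = round((index - 12 - tonic) * 7 / 12)
    return min(
        range(approx - 3, approx + 4),
        key=lambda pos: (abs(_ladder_to_index(pos, tonic) - index), pos),
    )


def _rhythm(length: int, meter: str, rng: np.random.Generator) -> list[float] | None:
    """Durations whose total fills whole bars, so the continuation falls
    on a strong beat (the next downbeat)."""
    bar = _BAR_BEATS[meter]
    durs = list(rng.choice(_DUR_CHOICES, size=length - 1))
    total = sum(durs)
    target = math.ceil((total + 0.5) / bar) * bar
    last = target - total
    if last < min(_DUR_CHOICES) or last > max(_DUR_CHOICES):
        return None  # remainder not singable as one note; caller retries
    return durs + [last]


_AC_FINAL_DEGREES = (2, 5, 7)


def _walk(
    length: int,
    tonic: int,
    spec: CorpusSpec,
    rng: np.random.Generator,
) -> list[int] | None:
    """Constrained random walk over the diatonic ladder (chromatic out).

    Steps are biased toward small intervals, reversal after leaps, the
    register center, and tonally stable landing degrees (probe-tone
    weighting), so generated stems project their key the way composed
    tonal melodies do."""
    center = _nearest_ladder(spec.register_center, tonic)
    # open on a tonic-triad tone near the register center
    pos = center + int(rng.integers(-2, 3))
    while pos % 7 not in (0, 2, 4):
        pos += int(rng.choice([-1, 1]))
    positions = [pos]
    last_step = 0
    for _ in range(length - 2):
        # step bias with occasional leaps; leaps tend to reverse
        steps = np.array([-4, -3, -2, -1, 0, 1, 2, 3, 4])
        w = np.array([0.03, 0.06, 0.16, 0.22, 0.06, 0.22, 0.16, 0.06, 0.03])
        if abs(last_step) >= 3:  # reversal tendency after a leap
            w = np.where(np.sign(steps) == -np.sign(last_step), w * 3.0, w)
        # keep the walk near the register center
        drift = center - pos
        w = np.where(np.sign(steps) == np.sign(drift), w * 1.6, w) if drift else w
        # favor tonally stable landing degrees
        stability = np.array(
            [KK_MAJOR_PROFILE[MAJOR_DEGREE_CLASSES[(pos + s) % 7]] for s in steps]
        )
        w = w * (stability / stability.max()) ** 2.5
        w = w / w.sum()
        step = int(rng.choice(steps, p=w))
        pos += step
        last_step = step
        positions.append(pos)
    # final note: nearest position with a cadential scale degree
    final_opts = [
        p
        for p in range(positions[-1] - 5, positions[-1] + 6)
        if (p % 7) + 1 in _AC_FINAL_DEGREES and p != positions[-1]
    ]
    if not final_opts:
        return None
    dist = np.array([1.0 / (1 + abs(p - positions[-1])) for p in final_opts])
    positions.append(int(rng.choice(final_opts, p=dist / dist.sum())))
    indices = [_ladder_to_index(p, tonic) for p in positions]
    if min(indices) < 50 or max(indices) > 81:  # D3..A5 stimulus range
        return None
    return positions


def _nc_from_ac(
    ac_positions: list[int],
    tonic: int,
    spec: CorpusSpec,
    rng: np.random.Generator,
) -> list[int] | None:
    """Derive an NC diatonic line with the same contour as the AC line."""
    ac_idx = [_ladder_to_index(p, tonic) for p in ac_positions]
    signs = [int(np.sign(b - a)) for a, b in zip(ac_idx, ac_idx[1:])]
    # the first note may itself differ (matched pairs differ anywhere)
    if rng.random() < spec.p_keep_note:
        nc = [ac_positions[0]]
    else:
        nc = [ac_positions[0] + int(rng.choice([-1, 1]))]
    allow_degree5 = rng.random() < 0.1
    for i in range(1, len(ac_positions)):
        is_final = i == len(ac_positions) - 1
        sign = signs[i - 1]
        cands = []
        for p in range(ac_positions[i] - 2, ac_positions[i] + 3):
            step_sign = int(np.sign(_ladder_to_index(p, tonic) - _ladder_to_index(nc[-1], tonic)))
            if step_sign != sign:
                continue
            if is_final:
                deg = (p % 7) + 1
                if deg in (2, 7) or (deg == 5 and not allow_degree5):
                    continue
            cands.append(p)
        if not cands:
            return None
        if not is_final and ac_positions[i] in cands and rng.random() < spec.p_keep_note:
            nc.append(ac_positions[i])
        else:
            # proximity to the AC note, tempered by tonal stability so the
            # NC line projects its key as strongly as the AC line
            stab = np.array(
                [KK_MAJOR_PROFILE[MAJOR_DEGREE_CLASSES[p % 7]] for p in cands]
            )
            weights = np.array(
                [1.0 / (1 + abs(p - ac_positions[i])) ** 2 for p in cands]
            ) * (stab / stab.max()) ** 2.0
            nc.append(int(rng.choice(cands, p=weights / weights.sum())))
    idx = [_ladder_to_index(p, tonic) for p in nc]
    if min(idx) < 50 or max(idx) > 81:
        return None
    return nc


def generate_stem_pair(
    spec: CorpusSpec, rng: np.random.Generator, pair_index: int = 0
) -> StemPair:
    """One matched AC/NC pair satisfying the stimulus construction rules."""
    for _ in range(spec.max_retries):
        tonic = int(rng.integers(0, 12))
        meter = str(rng.choice(spec.meters))
        length = int(rng.choice(list(_LEN_PROBS), p=list(_LEN_PROBS.values())))
        durs = _rhythm(length, meter, rng)
        if durs is None:
            continue
        ac_pos = _walk(length, tonic, spec, rng)
        if ac_pos is None:
            continue
        nc_pos = _nc_from_ac(ac_pos, tonic, spec, rng)
        if nc_pos is None:
            continue
        key = KeyContext(tonic_pitch_class=tonic, mode="major", meter=meter,
                         tempo_bpm=spec.tempo_bpm)
        pair_id = f"pair{pair_index:03d}"

        # agogic emphasis: longer durations sit on tonally stabler degrees
        # (shared rhythm, assigned from the AC line; the final bar-filling
        # duration stays in place)
        head_durs = sorted(durs[:-1], reverse=True)
        stab = [
            KK_MAJOR_PROFILE[MAJOR_DEGREE_CLASSES[p % 7]] + rng.normal(0, 1.0)
            for p in ac_pos[:-1]
        ]
        order = np.argsort(stab)[::-1]
        reordered = [0.0] * (length - 1)
        for rank, idx in enumerate(order):
            reordered[idx] = head_durs[rank]
        durs = reordered + [durs[-1]]

        def build(positions: list[int], cond: str) -> MelodicStem:
            onsets = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
            notes = tuple(
                NoteEvent(Pitch(_ladder_to_index(p, tonic)), float(o), float(d))
                for p, o, d in zip(positions, onsets, durs)
            )
            return MelodicStem(
                stem_id=f"{pair_id}_{cond}", notes=notes, key=key,
                condition=cond, pair_id=pair_id,
            )

        pair = StemPair(ac=build(ac_pos, "AC"), nc=build(nc_pos, "NC"),
                        pair_id=pair_id)
        # construction rule: stems must clearly project a major key (the
        # stimuli are unambiguously tonal); reject lines whose best
        # Krumhansl-Schmuckler match is a minor key
        from .key_finding import duration_weighted_distribution, key_correlations

        if any(
            key_correlations(duration_weighted_distribution(s)).best_key[1]
            != "major"
            for s in (pair.ac, pair.nc)
        ):
            continue
        return pair
    raise RuntimeError(
        f"stem-pair generation failed after {spec.max_retries} retries "
        f"(pair {pair_index})"
    )


def generate_corpus(
    spec: CorpusSpec, rng: np.random.Generator
) -> list[StemPair]:
    return [generate_stem_pair(spec, rng, i) for i in range(spec.n_pairs)]


# -- ground-truth expectancy distributions -----------------------------------


def _softmax(scores: np.ndarray, temperature: float) -> np.ndarray:
    z = (scores - scores.max()) / temperature
    e = np.exp(z)
    return e / e.sum()


def calibrate_temperature(
    scores: np.ndarray, target_max_prob: float,
    lo: float = 1e-3, hi: float = 50.0,
) -> float:
    """Bisect the softmax temperature so max prob equals the target.

    Max probability decreases monotonically in temperature; the target
    is clamped to the achievable band (uniform at hot, winner-take-all
    at cold, shared among exact ties)."""
    scores = np.asarray(scores, dtype=float)
    pmax_cold = _softmax(scores, lo).max()
    pmax_hot = _softmax(scores, hi).max()
    target = min(max(target_max_prob, pmax_hot), pmax_cold)
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if _softmax(scores, mid).max() > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _tonic_candidate_near(
    stem: MelodicStem, candidates: Sequence[int]
) -> int | None:
    """The tonic-pitch-class candidate closest to the stem's final note
    (None when the candidate set contains no tonic octave)."""
    tonic_cands = [c for c in candidates if c % 12 == stem.key.tonic_pitch_class]
    if not tonic_cands:
        return None
    return min(tonic_cands, key=lambda c: (abs(c - stem.final_index), c))


def ground_truth_distribution(
    stem: MelodicStem,
    behavior: BehaviorSpec,
    rng: np.random.Generator,
    model_config: ModelConfig = ModelConfig(),
    pair_latent: float | None = None,
) -> dict[int, float]:
    """Planted response distribution over candidate pitches for one stem.

    ``pair_latent`` (a standard-normal draw shared by the two stems of a
    pair) induces the within-pair constraint correlation; when None the
    stem's target is drawn independently.
    """
    if behavior.expectancy_source == "explicit":
        if behavior.explicit_distributions is None:
            raise ValueError("explicit source requires explicit_distributions")
        dist = behavior.explicit_distributions[stem.stem_id]
        total = sum(dist.values())
        return {int(c): p / total for c, p in dist.items()}

    table = expectancy_table(stem, model_config)
    cands = np.array(sorted(table.candidates))
    scores = np.array([table.candidates[c][3] for c in cands])
    if stem.condition == "AC":
        deg = stem.final_degree
        mean, sd = behavior.ac_constraint_by_degree.get(
            deg if isinstance(deg, int) else -1,
            (behavior.ac_constraint_mean, behavior.ac_constraint_sd),
        )
    else:
        mean, sd = behavior.nc_constraint_mean, behavior.nc_constraint_sd
    if pair_latent is None:
        z = rng.normal()
    else:
        rho = behavior.constraint_pair_correlation
        z = rho * pair_latent + math.sqrt(1.0 - rho**2) * rng.normal()
    target = float(np.clip(mean + sd * z, 0.15, 0.95))

    if behavior.expectancy_source == "model-softmax":
        temp = calibrate_temperature(scores, target)
        probs = _softmax(scores, temp)
        return {int(c): float(p) for c, p in zip(cands, probs)}

    if behavior.expectancy_source != "harmonic":
        raise ValueError(f"unknown expectancy source {behavior.expectancy_source!r}")

    # harmonic source: planted modal note + model-shaped residual mass
    if stem.condition == "AC":
        modal = _tonic_candidate_near(stem, cands)
    else:
        # a diatonic candidate near the final note, weighted by expectancy
        degset = set(stem.key.degree_classes)
        near = [
            c for c in cands
            if abs(c - stem.final_index) <= 5
            and (c % 12 - stem.key.tonic_pitch_class) % 12 in degset
        ]
        w = _softmax(np.array([table.candidates[c][3] for c in near]), 1.0)
        modal = int(rng.choice(near, p=w))
    residual = _softmax(scores, behavior.residual_temperature)
    probs = {int(c): float((1.0 - target) * p)
             for c, p in zip(cands, residual) if c != modal}
    scale = (1.0 - target) / max(sum(probs.values()), 1e-12)
    probs = {c: p * scale for c, p in probs.items()}
    probs[int(modal)] = target
    return probs


# -- response generation -----------------------------------------------------


def _jittered_f0(index: int, jitter_cents: float) -> float:
    return index_to_frequency(index) * 2.0 ** (jitter_cents / 1200.0)


def generate_responses(
    pairs: Sequence[StemPair],
    behavior: BehaviorSpec,
    rng: np.random.Generator,
    model_config: ModelConfig = ModelConfig(),
) -> tuple[list[ResponseTableRow], list[ParticipantRecord],
           dict[str, dict[int, float]]]:
    """Simulate a cohort singing one stem from every pair.

    Each participant hears the AC member of ``n_ac_per_participant``
    randomly chosen pairs and the NC member of the rest.  Returns the
    raw response rows, the participant records (with pitch-matching
    trials), and the per-stem ground-truth distributions used.
    """
    if behavior.n_ac_per_participant > len(pairs):
        raise ValueError(
            f"n_ac_per_participant ({behavior.n_ac_per_participant}) exceeds "
            f"the number of pairs ({len(pairs)})"
        )
    stems: dict[str, MelodicStem] = {}
    truth: dict[str, dict[int, float]] = {}
    for p in pairs:
        latent = float(rng.normal())
        for stem in (p.ac, p.nc):
            stems[stem.stem_id] = stem
            truth[stem.stem_id] = ground_truth_distribution(
                stem, behavior, rng, model_config, pair_latent=latent
            )
    cands = {sid: np.array(sorted(d)) for sid, d in truth.items()}
    probs = {sid: np.array([truth[sid][c] for c in cands[sid]]) for sid in truth}
    tonic_near = {
        sid: _tonic_candidate_near(stems[sid], cands[sid]) for sid in truth
    }

    n = behavior.n_participants
    n_off = int(round(behavior.off_pitch_fraction * n))
    off_flags = np.zeros(n, dtype=bool)
    off_flags[rng.choice(n, size=n_off, replace=False)] = True
    male_flags = rng.random(n) < behavior.male_fraction
    training = np.clip(rng.normal(*behavior.training_years, size=n), 0.0, None)
    z_train = (training - training.mean()) / max(training.std(), 1e-9)

    # between-participant variance components: a shared speed/confidence
    # baseline per singer plus a participant-specific condition effect,
    # so paired AC-vs-NC tests see realistic across-subject spread
    ac_rt_sd = behavior.rt_ms["AC"][1]
    rt_base_sd = math.sqrt(
        max(ac_rt_sd**2 - behavior.rt_trial_sd**2 / behavior.n_ac_per_participant, 0.0)
    )
    rt_base = rng.normal(0.0, rt_base_sd, size=n)
    rt_effect = rng.normal(0.0, behavior.rt_condition_effect_sd, size=n)
    conf_base = rng.normal(0.0, behavior.confidence_between_sd, size=n)
    conf_effect = rng.normal(0.0, behavior.confidence_condition_effect_sd, size=n)

    rows: list[ResponseTableRow] = []
    participants: list[ParticipantRecord] = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        shift = -12 if male_flags[i] else 0
        jitter_sd = (
            behavior.off_pitch_jitter_sd_cents if off_flags[i]
            else behavior.vocal_jitter_sd_cents
        )
        trials = tuple(
            (idx + shift,
             _jittered_f0(idx + shift, float(rng.normal(0, jitter_sd))))
            for idx in PITCH_MATCHING_INDICES
        )
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                voice_octave_shift=shift,
                years_formal_training=round(float(training[i]), 1),
                pitch_matching_trials=trials,
            )
        )
        ac_pairs = set(rng.choice(len(pairs), size=behavior.n_ac_per_participant,
                                  replace=False))
        order = rng.permutation(len(pairs))
        for j in order:
            pair = pairs[j]
            stem = pair.ac if j in ac_pairs else pair.nc
            sid = stem.stem_id
            cond = stem.condition
            # musical-training effect: trained singers favor the tonic after
            # cadential stems ending on the leading tone (and, less, degree 5)
            sung = None
            if cond == "AC" and tonic_near[sid] is not None:
                deg = stem.final_degree
                slope = behavior.training_slopes.get(deg, 0.0) if isinstance(deg, int) else 0.0
                if slope and tonic_near[sid] in truth[sid]:
                    base = truth[sid][tonic_near[sid]]
                    p_tonic = float(np.clip(base + slope * z_train[i], 0.02, 0.98))
                    if rng.random() < p_tonic:
                        sung = tonic_near[sid]
                    else:
                        others = cands[sid][cands[sid] != tonic_near[sid]]
                        w = np.array([truth[sid][c] for c in others])
                        sung = int(rng.choice(others, p=w / w.sum()))
            if sung is None:
                sung = int(rng.choice(cands[sid], p=probs[sid]))
            jitter = float(rng.normal(0, jitter_sd))
            rt_mu = behavior.rt_ms[cond][0] + rt_base[i]
            conf_mu = behavior.confidence_mean[cond] + conf_base[i]
            if cond == "NC":
                rt_mu += rt_effect[i]
                conf_mu += conf_effect[i]
            rows.append(
                ResponseTableRow(
                    participant_id=pid,
                    stem_id=sid,
                    mean_f0_hz=round(_jittered_f0(sung + shift, jitter), 4),
                    onset_latency_ms=round(
                        max(150.0, float(rng.normal(rt_mu, behavior.rt_trial_sd))), 1
                    ),
                    sung_duration_ms=round(
                        max(200.0, float(rng.normal(*behavior.duration_ms))), 1
                    ),
                    confidence=int(
                        np.clip(round(rng.normal(conf_mu, behavior.confidence_sd)), 1, 7)
                    ),
                )
            )
    return rows, participants, truth


def end_to_end_fixture(
    seed: int,
    out_dir: str | Path | None = None,
    corpus_spec: CorpusSpec | None = None,
    behavior_spec: BehaviorSpec | None = None,
):
    """Deterministic full bundle: stem pairs + responses + participants.

    With ``out_dir`` set, writes ``stems.json``, ``responses.csv`` and
    ``participants.csv`` there.  Returns (pairs, rows, participants,
    ground_truth).
    """
    corpus_spec = corpus_spec or CorpusSpec()
    behavior_spec = behavior_spec or BehaviorSpec()
    rng = np.random.default_rng(seed)
    pairs = generate_corpus(corpus_spec, rng)
    rows, participants, truth = generate_responses(pairs, behavior_spec, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stems = [s for p in pairs for s in (p.ac, p.nc)]
        write_stems(stems, out / "stems.json")
        write_responses(rows, out / "responses.csv")
        write_participants(participants, out / "participants.csv")
    return pairs, rows, participants, truth
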