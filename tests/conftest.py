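import numpy as np
import pytest

from melocloze import (
    KeyContext,
    MelodicStem,
    NoteEvent,
    Pitch,
    StemPair,
)
from melocloze.synthetic_data import BehaviorSpec, CorpusSpec, generate_corpus


def make_stem(
    indices,
    stem_id="s1",
    tonic=0,
    condition="unlabeled",
    pair_id="",
    durations=None,
    meter="4/4",
    tempo=120.0,
):
    """Build a stem from chromatic indices with unit-beat durations."""
    durations = durations or [1.0] * len(indices)
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    notes = tuple(
        NoteEvent(Pitch(i), float(o), float(d))
        for i, o, d in zip(indices, onsets, durations)
    )
    key = KeyContext(tonic_pitch_class=tonic, meter=meter, tempo_bpm=tempo)
    return MelodicStem(
        stem_id=stem_id, notes=notes, key=key, condition=condition, pair_id=pair_id
    )


@pytest.fixture
def d_major_stem():
    """An 8-note D-major stem ending on the supertonic (cadential shape)."""
    return make_stem(
        [62, 66, 69, 67, 71, 74, 73, 64],
        stem_id="dmaj_ac",
        tonic=2,
        condition="AC",
        pair_id="p1",
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Six generated AC/NC pairs (seeded, reused across tests)."""
    rng = np.random.default_rng(20240901)
    return generate_corpus(CorpusSpec(n_pairs=6), rng)


@pytest.fixture(scope="session")
def study_bundle():
    """A small end-to-end bundle: 12 pairs x 20 participants (seeded)."""
    from melocloze.synthetic_data import end_to_end_fixture

    return end_to_end_fixture(
        77,
        corpus_spec=CorpusSpec(n_pairs=12),
        behavior_spec=BehaviorSpec(n_participants=20, n_ac_per_participant=6),
    )
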