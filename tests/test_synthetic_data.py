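import numpy as np
import pytest

from melocloze import (
    build_distributions,
    contour,
    pair_difference_stats,
    process_table,
)
from melocloze.melody_core import MelodicStem
from melocloze.synthetic_data import (
    BehaviorSpec,
    CorpusSpec,
    calibrate_temperature,
    end_to_end_fixture,
    generate_corpus,
    generate_responses,
    generate_stem_pair,
    ground_truth_distribution,
)


class TestStemPairGeneration:
    def test_pairs_satisfy_invariants_over_seeds(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            pair = generate_stem_pair(CorpusSpec(), rng, seed)
            assert contour(pair.ac) == contour(pair.nc)
            assert 5 <= len(pair.ac.notes) <= 9
            assert pair.ac.key == pair.nc.key
            assert all(n.duration_beats > 0 for n in pair.ac.notes)

    def test_cadential_final_degrees(self, small_corpus):
        for pair in small_corpus:
            assert pair.ac.final_degree in (2, 5, 7)
            assert pair.nc.final_degree not in (2, 7)

    def test_final_note_precedes_strong_beat(self, small_corpus):
        bar = {"3/4": 3.0, "4/4": 4.0, "6/8": 3.0}
        for pair in small_corpus:
            total = pair.ac.notes[-1].offset_beats
            assert total % bar[pair.ac.key.meter] == pytest.approx(0.0, abs=1e-9)

    def test_difference_fraction_in_calibration_band(self):
        rng = np.random.default_rng(7)
        pairs = generate_corpus(CorpusSpec(n_pairs=45), rng)
        fracs = [pair_difference_stats(p)[0] for p in pairs]
        gaps = [pair_difference_stats(p)[1] for p in pairs if pair_difference_stats(p)[0] > 0]
        assert 0.3 <= np.mean(fracs) <= 0.65
        assert 1.0 <= np.mean(gaps) <= 3.0

    def test_stimulus_pitch_range(self, small_corpus):
        for pair in small_corpus:
            for stem in (pair.ac, pair.nc):
                assert min(stem.indices) >= 50  # D3
                assert max(stem.indices) <= 81  # A5


class TestTemperatureCalibration:
    def test_hits_target_max_probability(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 3, size=49)
        for target in (0.3, 0.5, 0.8):
            temp = calibrate_temperature(scores, target)
            z = np.exp((scores - scores.max()) / temp)
            assert (z / z.sum()).max() == pytest.approx(target, abs=1e-4)

    def test_unreachable_target_clamped(self):
        scores = np.zeros(10)  # all tied: max prob is always 1/10
        temp = calibrate_temperature(scores, 0.9)
        assert np.isfinite(temp)


class TestGroundTruth:
    def test_distribution_normalized(self, small_corpus):
        rng = np.random.default_rng(1)
        spec = BehaviorSpec()
        for pair in small_corpus:
            dist = ground_truth_distribution(pair.ac, spec, rng)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(p >= 0 for p in dist.values())

    def test_ac_modal_is_tonic_class(self, small_corpus):
        rng = np.random.default_rng(2)
        spec = BehaviorSpec()
        for pair in small_corpus:
            dist = ground_truth_distribution(pair.ac, spec, rng)
            modal = max(dist, key=dist.get)
            assert modal % 12 == pair.ac.key.tonic_pitch_class

    def test_model_softmax_source(self, small_corpus):
        rng = np.random.default_rng(3)
        spec = BehaviorSpec(expectancy_source="model-softmax")
        dist = ground_truth_distribution(small_corpus[0].ac, spec, rng)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_explicit_source(self, small_corpus):
        stem = small_corpus[0].ac
        spec = BehaviorSpec(
            expectancy_source="explicit",
            explicit_distributions={stem.stem_id: {62: 0.7, 64: 0.3}},
        )
        rng = np.random.default_rng(4)
        dist = ground_truth_distribution(stem, spec, rng)
        assert dist == {62: pytest.approx(0.7), 64: pytest.approx(0.3)}


class TestResponseGeneration:
    def test_row_count_and_split(self, small_corpus):
        rng = np.random.default_rng(5)
        spec = BehaviorSpec(n_participants=10, n_ac_per_participant=3)
        rows, participants, _ = generate_responses(small_corpus, spec, rng)
        assert len(rows) == 10 * len(small_corpus)
        assert len(participants) == 10
        ac_rows = [r for r in rows if r.stem_id.endswith("_AC")]
        assert len(ac_rows) == 10 * 3

    def test_deterministic_truth_recovers_constraint_one(self, small_corpus):
        # degenerate limit: all probability mass on one candidate
        stems = {s.stem_id: s for p in small_corpus for s in (p.ac, p.nc)}
        explicit = {sid: {stems[sid].final_index: 1.0} for sid in stems}
        spec = BehaviorSpec(
            n_participants=8,
            n_ac_per_participant=3,
            expectancy_source="explicit",
            explicit_distributions=explicit,
            vocal_jitter_sd_cents=5.0,
        )
        rng = np.random.default_rng(6)
        rows, participants, _ = generate_responses(small_corpus, spec, rng)
        from melocloze.cloze_stats import constraint

        processed = process_table(rows, stems)
        for sid, dist in build_distributions(processed).items():
            assert constraint(dist).constraint == 1.0

    def test_planted_probability_within_binomial_ci(self, small_corpus):
        # planted modal probability 0.9 at n = 200 respondents: the
        # empirical constraint must fall inside the 99% binomial interval
        from scipy import stats as sps

        stems = {s.stem_id: s for p in small_corpus for s in (p.ac, p.nc)}
        explicit = {
            sid: {stems[sid].final_index: 0.9, stems[sid].final_index + 2: 0.1}
            for sid in stems
        }
        spec = BehaviorSpec(
            n_participants=200,
            n_ac_per_participant=3,
            expectancy_source="explicit",
            explicit_distributions=explicit,
            vocal_jitter_sd_cents=5.0,
        )
        rng = np.random.default_rng(7)
        rows, _, _ = generate_responses(small_corpus, spec, rng)
        processed = process_table(rows, stems)
        from melocloze.cloze_stats import constraint

        lo_hi = {}
        for sid, dist in build_distributions(processed).items():
            n = dist.n_valid
            lo, hi = sps.binom.interval(0.99, n, 0.9)
            assert lo / n <= constraint(dist).constraint <= hi / n

    def test_off_pitch_singers_get_excluded(self, small_corpus):
        from melocloze import screen_participant

        spec = BehaviorSpec(
            n_participants=29, n_ac_per_participant=3, off_pitch_fraction=4 / 29
        )
        rng = np.random.default_rng(8)
        rows, participants, _ = generate_responses(small_corpus, spec, rng)
        stems = {s.stem_id: s for p in small_corpus for s in (p.ac, p.nc)}
        processed = process_table(rows, stems)
        reports = [screen_participant(p, processed) for p in participants]
        n_excluded = sum(r.excluded for r in reports)
        assert 2 <= n_excluded <= 8  # targets 4, binomial slack


class TestEndToEnd:
    def test_same_seed_byte_identical(self, tmp_path):
        spec_c = CorpusSpec(n_pairs=4)
        spec_b = BehaviorSpec(n_participants=6, n_ac_per_participant=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        end_to_end_fixture(42, out_dir=d1, corpus_spec=spec_c, behavior_spec=spec_b)
        end_to_end_fixture(42, out_dir=d2, corpus_spec=spec_c, behavior_spec=spec_b)
        for name in ("stems.json", "responses.csv", "participants.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_bundle_passes_all_readers(self, tmp_path):
        from melocloze import read_participants, read_responses, read_stems

        end_to_end_fixture(
            43, out_dir=tmp_path,
            corpus_spec=CorpusSpec(n_pairs=4),
            behavior_spec=BehaviorSpec(n_participants=6, n_ac_per_participant=2),
        )
        stems = read_stems(tmp_path / "stems.json")
        rows = read_responses(tmp_path / "responses.csv")
        participants = read_participants(tmp_path / "participants.csv")
        assert len(stems) == 8
        assert len(rows) == 6 * 4
        assert len(participants) == 6

    def test_condition_gap_flows_through_pipeline(self, study_bundle):
        from melocloze.pipeline import analyze

        pairs, rows, participants, _ = study_bundle
        results = analyze(pairs, rows, participants)
        cs = results.constraint_summary
        assert cs.ac_mean > cs.nc_mean
        assert cs.df == len(pairs) - 1

    def test_constraint_recovery_improves_with_n(self, small_corpus):
        # consistency: empirical constraint approaches the planted modal
        # probability as the cohort grows
        stems = {s.stem_id: s for p in small_corpus for s in (p.ac, p.nc)}
        explicit = {
            sid: {stems[sid].final_index: 0.7, stems[sid].final_index + 1: 0.3}
            for sid in stems
        }
        errors = []
        for n in (50, 200, 1000):
            spec = BehaviorSpec(
                n_participants=n,
                n_ac_per_participant=3,
                expectancy_source="explicit",
                explicit_distributions=explicit,
                vocal_jitter_sd_cents=5.0,
            )
            rng = np.random.default_rng(10)
            rows, _, _ = generate_responses(small_corpus, spec, rng)
            processed = process_table(rows, stems)
            from melocloze.cloze_stats import constraint

            dists = build_distributions(processed)
            err = np.mean(
                [abs(constraint(d).constraint - 0.7) for d in dists.values()]
            )
            errors.append(err)
        assert errors[2] < errors[0]
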