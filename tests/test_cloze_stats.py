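import math

import numpy as np
import pytest
from scipy import stats as sps

from melocloze import (
    KeyContext,
    SungResponse,
    build_distribution,
    build_distributions,
    cloze_probability,
    compare_conditions,
    constraint,
    fisher_z,
    fisher_z_inverse,
    paired_t,
    scale_degree_profile,
    training_tonic_correlation,
)
from melocloze.melody_core import Pitch
from melocloze.cloze_stats import ResponseDistribution

from conftest import make_stem


def resp(pid, sid, index, valid=True, condition="AC", confidence=None, rt=None):
    return SungResponse(
        participant_id=pid,
        stem_id=sid,
        pitch=Pitch(index) if valid else None,
        pitch_class=index % 12 if valid else None,
        degree=None if not valid else ((index - 2) % 12),
        onset_latency_ms=rt,
        confidence=confidence,
        valid=valid,
        condition=condition,
    )


class TestDistribution:
    def test_modal_proportion(self):
        responses = [resp(f"P{i}", "s", 62) for i in range(23)] + [
            resp("P23", "s", 69),
            resp("P24", "s", 61),
        ]
        dist = build_distribution(responses, "s")
        assert dist.n_valid == 25
        assert cloze_probability(dist, 2) == pytest.approx(0.92)

    def test_octaves_collapse(self):
        responses = [resp("P0", "s", 50), resp("P1", "s", 62), resp("P2", "s", 74)]
        dist = build_distribution(responses, "s")
        assert dist.counts == {2: 3}

    def test_single_response(self):
        dist = build_distribution([resp("P0", "s", 60)], "s")
        assert cloze_probability(dist, 0) == 1.0

    def test_invalid_dropped_from_denominator(self):
        responses = [resp("P0", "s", 62), resp("P1", "s", 0, valid=False)]
        dist = build_distribution(responses, "s")
        assert dist.n_valid == 1

    def test_no_valid_responses_errors_with_stem_id(self):
        with pytest.raises(ValueError, match="sX"):
            build_distribution([resp("P0", "sX", 0, valid=False)], "sX")

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        responses = [resp(f"P{i}", "s", int(rng.integers(55, 80))) for i in range(40)]
        dist = build_distribution(responses, "s")
        total = sum(cloze_probability(dist, pc) for pc in range(12))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestConstraint:
    def test_modal_class_and_value(self):
        counts = {2: 10, 9: 5, 1: 5, 6: 5}
        dist = ResponseDistribution("s", counts, 25)
        res = constraint(dist)
        assert res.constraint == pytest.approx(0.40)
        assert res.modal_pitch_classes == (2,)

    def test_tie_reported(self):
        counts = {1: 6, 9: 6, 2: 5, 4: 4, 7: 4}
        res = constraint(ResponseDistribution("s", counts, 25))
        assert res.constraint == pytest.approx(0.24)
        assert res.modal_pitch_classes == (1, 9)

    def test_constraint_bounds_every_cloze(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            raw = rng.multinomial(30, np.ones(12) / 12)
            counts = {pc: int(c) for pc, c in enumerate(raw) if c}
            dist = ResponseDistribution("s", counts, 30)
            res = constraint(dist)
            assert all(
                res.constraint >= cloze_probability(dist, pc) for pc in range(12)
            )
            assert res.constraint >= 1 / 12

    def test_invariant_under_joint_transposition(self):
        responses = [resp(f"P{i}", "s", 60 + (i % 3)) for i in range(12)]
        shifted = [resp(f"P{i}", "s", 65 + (i % 3)) for i in range(12)]
        c0 = constraint(build_distribution(responses, "s")).constraint
        c1 = constraint(build_distribution(shifted, "s")).constraint
        assert c0 == c1

    def test_modal_degree_labels(self):
        key = KeyContext(tonic_pitch_class=2)
        res = constraint(ResponseDistribution("s", {2: 9, 4: 1}, 10), key)
        assert res.modal_degrees == (1,)


class TestDegreeProfile:
    def _dists_and_stems(self):
        stems, dists = {}, {}
        # two AC stems fully on tonic; two NC spread over degrees 1 and 5
        for i, (cond, counts) in enumerate(
            [
                ("AC", {2: 10}),
                ("AC", {2: 6, 9: 4}),
                ("NC", {9: 5, 2: 5}),
                ("NC", {4: 6, 2: 4}),
            ]
        ):
            sid = f"s{i}"
            stems[sid] = make_stem(
                [62, 64, 66, 67, 69], stem_id=sid, tonic=2,
                condition=cond, pair_id=f"p{i % 2}",
            )
            dists[sid] = ResponseDistribution(sid, counts, sum(counts.values()))
        return dists, stems

    def test_rows_sum_to_one(self):
        dists, stems = self._dists_and_stems()
        profile = scale_degree_profile(dists, stems)
        assert profile.ac_profile.sum() == pytest.approx(1.0, abs=1e-12)
        assert profile.nc_profile.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unweighted_mean_of_stem_vectors(self):
        dists, stems = self._dists_and_stems()
        profile = scale_degree_profile(dists, stems)
        # AC degree-1 proportions are 1.0 and 0.6 -> mean 0.8
        assert profile.ac_profile[0] == pytest.approx(0.8)

    def test_all_tonic_profile(self):
        stems = {
            "a": make_stem([62, 64, 66, 67, 69], stem_id="a", tonic=2,
                           condition="AC", pair_id="pa"),
            "b": make_stem([62, 64, 66, 67, 69], stem_id="b", tonic=2,
                           condition="NC", pair_id="pb"),
        }
        dists = {
            "a": ResponseDistribution("a", {2: 5}, 5),
            "b": ResponseDistribution("b", {2: 7}, 7),
        }
        profile = scale_degree_profile(dists, stems)
        assert profile.ac_profile[0] == 1.0
        assert profile.nc_profile[0] == 1.0


class TestPairedT:
    def test_identical_samples_zero(self):
        t, df, p = paired_t([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == 0.0
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_formula_oracle(self):
        x = [0.9, 0.8, 0.7]
        y = [0.4, 0.5, 0.3]
        d = np.array(x) - np.array(y)
        expected = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        t, df, p = paired_t(x, y)
        assert t == pytest.approx(expected)
        assert df == 2

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.7, 0.15, size=45)
        y = rng.normal(0.4, 0.15, size=45)
        t, df, p = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert df == 44

    def test_df_is_pairs_minus_one(self):
        rng = np.random.default_rng(9)
        t, df, p = paired_t(rng.normal(size=45), rng.normal(size=45))
        assert df == 44

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [0.5])


class TestCompareConditions:
    def test_summary_fields(self):
        ac = [0.9, 0.8, 0.7, 0.6]
        nc = [0.5, 0.4, 0.45, 0.3]
        s = compare_conditions(ac, nc)
        assert s.ac_mean == pytest.approx(np.mean(ac))
        assert s.nc_sd == pytest.approx(np.std(nc, ddof=1))
        assert s.df == 3
        assert s.t_statistic > 0


class TestTrainingCorrelation:
    def _setup(self, freqs_by_training):
        stems = {
            "s7": make_stem([62, 64, 66, 67, 61], stem_id="s7", tonic=2,
                            condition="AC"),
        }
        years, responses = {}, []
        for i, (training, f) in enumerate(freqs_by_training):
            pid = f"P{i}"
            years[pid] = training
            n = 20
            k = round(f * n)
            for j in range(n):
                index = 62 if j < k else 69
                r = SungResponse(
                    participant_id=pid, stem_id="s7",
                    pitch=Pitch(index), pitch_class=index % 12,
                    degree=1 if index == 62 else 5,
                    valid=True, condition="AC",
                )
                responses.append(r)
        return years, responses, stems

    def test_perfect_linear_relation(self):
        years, responses, stems = self._setup(
            [(0, 0.2), (5, 0.45), (10, 0.7), (15, 0.95)]
        )
        r, p, freqs = training_tonic_correlation(years, responses, stems, 7)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_errors(self):
        years, responses, stems = self._setup([(5, 0.5), (5, 0.5), (5, 0.5)])
        with pytest.raises(ValueError, match="variance"):
            training_tonic_correlation(years, responses, stems, 7)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(21)
        data = []
        for _ in range(50):
            yrs = float(rng.uniform(0, 15))
            f = np.clip(0.3 + 0.03 * yrs + rng.normal(0, 0.05), 0, 1)
            data.append((yrs, float(f)))
        years, responses, stems = self._setup(data)
        r, p, _ = training_tonic_correlation(years, responses, stems, 7)
        assert r > 0.5
        assert p < 0.001


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form(self):
        assert fisher_z(0.70) == pytest.approx(math.atanh(0.70))
        assert fisher_z(0.70) == pytest.approx(0.8673, abs=5e-5)

    def test_round_trip(self):
        for r in (-0.95, -0.3, 0.0, 0.5, 0.99):
            assert fisher_z_inverse(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)
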