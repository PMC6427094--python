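"""Scoring, percentile norms, reliability, and correlation statistics."""

import itertools

import numpy as np
import pytest

from mint.errors import InputError, ManifestError
from mint.scoring import (
    ResponseRecord,
    check_normality,
    compare_dependent_correlations,
    correlate_measures,
    load_norms,
    overall_reliability,
    percentile_lookup,
    score_session,
    spearman_brown,
    split_half_reliability,
)
from mint.simulate import ResponderModel, simulate_responses


def perfect_responses(session):
    return [
        ResponseRecord(t.trial_id, "match" if t.is_match else "mismatch")
        for t in session.all_trials()
        if not t.familiarization
    ]


class TestScoreSession:
    def test_all_correct_gives_ones(self, session):
        rep = score_session(perfect_responses(session), session)
        assert rep.mint_average == 1.0
        assert all(v == 1.0 for v in rep.by_condition.values())
        assert all(v == 1.0 for v in rep.by_snr.values())
        assert rep.missing_trials == []

    def test_known_fraction_in_one_block(self, session):
        # 15 of baseline's 20 answered correctly -> 0.75 for that condition
        responses = []
        for i, t in enumerate(session.blocks["baseline"]):
            correct = i < 15
            truth = "match" if t.is_match else "mismatch"
            flip = "mismatch" if t.is_match else "match"
            responses.append(ResponseRecord(t.trial_id, truth if correct else flip))
        rep = score_session(responses, session)
        assert rep.by_condition["baseline"] == pytest.approx(0.75)
        assert len(rep.missing_trials) == 120 - 20

    def test_coin_flip_near_chance(self, session):
        model = ResponderModel(base_sensitivity=0.5, lapse_rate=0.5, seed=17)
        rep = score_session(simulate_responses(model, session), session)
        n = 120
        assert abs(rep.mint_average - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_order_invariance(self, session):
        resp = perfect_responses(session)
        shuffled = list(reversed(resp))
        a = score_session(resp, session)
        b = score_session(shuffled, session)
        assert a.by_condition == b.by_condition

    def test_duplicate_and_unknown_ids_rejected(self, session):
        resp = perfect_responses(session)
        with pytest.raises(InputError):
            score_session(resp + [resp[0]], session)
        with pytest.raises(ManifestError):
            score_session([ResponseRecord("nope", "match")], session)


class TestPercentiles:
    @pytest.mark.parametrize(
        "score,pct", [(0.78, 50.0), (0.52, 5.0), (1.0, 90.0), (0.95, 80.0)]
    )
    def test_published_rows(self, score, pct):
        assert percentile_lookup(score) == pytest.approx(pct)

    def test_interpolates_between_rows(self):
        assert 50.0 < percentile_lookup(0.80) < 55.0

    def test_monotone_nondecreasing(self):
        norms = load_norms()
        grid = np.linspace(0.0, 1.0, 101)
        vals = [percentile_lookup(s, norms) for s in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_raises(self):
        with pytest.raises(InputError):
            percentile_lookup(1.2)


class TestSplitHalf:
    def test_single_split_closed_form(self):
        assert spearman_brown(0.5) == pytest.approx(2 * 0.5 / 1.5)

    def test_matches_exhaustive_enumeration_on_four_items(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 2, size=(30, 4)).astype(float)
        # exhaustive oracle: all 3 balanced partitions of 4 items
        rs = []
        for half in itertools.combinations(range(4), 2):
            other = tuple(i for i in range(4) if i not in half)
            a = scores[:, half].mean(axis=1)
            b = scores[:, other].mean(axis=1)
            rs.append(np.corrcoef(a, b)[0, 1])
        # unordered pairs are counted twice in the ordered enumeration,
        # symmetrically, so the plain mean matches the sampling estimand
        exact = spearman_brown(float(np.mean(rs)))
        est = split_half_reliability(scores, n_splits=4000, seed=2)
        assert est == pytest.approx(exact, abs=0.05)

    def test_independent_noise_items_near_zero(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 2, size=(200, 20)).astype(float)
        coef = split_half_reliability(scores, n_splits=1000, seed=4)
        assert abs(coef) < 0.1

    def test_consistent_subjects_reach_one(self):
        abilities = np.linspace(0.2, 0.9, 12)
        scores = np.tile(abilities[:, None], (1, 20))
        coef = split_half_reliability(scores, n_splits=200, seed=5)
        assert coef == pytest.approx(1.0)

    def test_invariant_to_item_and_subject_relabeling(self):
        rng = np.random.default_rng(6)
        ability = rng.uniform(0.5, 1.0, size=40)
        scores = (rng.random((40, 20)) < ability[:, None]).astype(float)
        base = split_half_reliability(scores, 500, seed=7)
        shuffled = scores[rng.permutation(40)][:, rng.permutation(20)]
        again = split_half_reliability(shuffled, 500, seed=7)
        # same distribution of splits; estimates agree within Monte-Carlo error
        assert again == pytest.approx(base, abs=0.1)

    def test_more_item_noise_lowers_reliability(self):
        rng = np.random.default_rng(8)
        ability = rng.uniform(0.55, 0.95, size=150)
        coefs = []
        for noise_w in (0.0, 0.5, 1.0):
            p = (1 - noise_w) * ability[:, None] + noise_w * 0.75
            scores = (rng.random((150, 20)) < p).astype(float)
            coefs.append(split_half_reliability(scores, 400, seed=9))
        assert coefs[0] > coefs[1] > coefs[2]

    def test_zero_variance_splits_dropped_and_counted(self):
        # items 0 and 1 vary across subjects, items 2 and 3 are constant:
        # splits pairing the two constant items give a zero-variance half
        scores = np.ones((5, 4))
        scores[0, 0] = 0.0
        scores[1, 1] = 0.0
        coef, detail = split_half_reliability(
            scores, n_splits=60, seed=10, return_detail=True
        )
        assert detail["n_dropped"] > 0
        assert detail["n_used"] > 0
        assert detail["n_used"] + detail["n_dropped"] == 60
        assert -1.0 <= coef <= 1.0

    def test_all_splits_degenerate_raises(self):
        # item 0 is the only varying item, so one half is always constant
        scores = np.ones((5, 4))
        scores[0, 0] = 0.0
        with pytest.raises(InputError):
            split_half_reliability(scores, n_splits=20, seed=10)

    def test_input_validation(self):
        with pytest.raises(InputError):
            split_half_reliability(np.ones((2, 4)))
        with pytest.raises(InputError):
            split_half_reliability(np.ones((5, 5)))


class TestOverallReliability:
    def test_identical_conditions_equal_single_condition(self):
        rng = np.random.default_rng(11)
        scores = rng.integers(0, 2, size=(40, 20)).astype(float)
        single = split_half_reliability(scores, 300, seed=12)
        overall = overall_reliability({c: scores for c in "abcde"}, 300, seed=12)
        assert overall == pytest.approx(single)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(InputError):
            overall_reliability({"a": np.ones((5, 20)), "b": np.ones((6, 20))})


class TestNormality:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0.78, 0.09, size=67)
        out = check_normality(x)
        assert out["mean"] == pytest.approx(0.78, abs=2 * 0.09 / np.sqrt(67))
        assert out["sd"] == pytest.approx(0.09, abs=2 * 0.09 / np.sqrt(2 * 66))
        assert out["shapiro_p"] > 0.01

    def test_constant_vector_flagged_degenerate(self):
        assert check_normality(np.full(10, 0.8))["degenerate"] is True


class TestCorrelations:
    def test_perfect_and_inverse(self):
        x = np.arange(10, dtype=float)
        assert correlate_measures(x, x)[0] == pytest.approx(1.0)
        assert correlate_measures(x, -x)[0] == pytest.approx(-1.0)
        assert correlate_measures(x, x * 2, method="pearson")[0] == pytest.approx(1.0)

    def test_bivariate_normal_estimate_in_sampling_band(self):
        rng = np.random.default_rng(14)
        cov = [[1, 0.5], [0.5, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=70)
        r, p = correlate_measures(xy[:, 0], xy[:, 1], method="pearson")
        assert abs(r - 0.5) < 0.2  # approx 2 / sqrt(n) sampling band
        assert p < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(InputError):
            correlate_measures(np.ones(10), np.arange(10.0))


class TestDependentCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_dependent_correlations(0.4, 0.4, 0.3, 50)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetric_under_swap(self):
        z1, _ = compare_dependent_correlations(0.56, 0.18, 0.4, 67)
        z2, _ = compare_dependent_correlations(0.18, 0.56, 0.4, 67)
        assert z1 == pytest.approx(-z2)
        assert z1 > 0

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(15)
        cov = np.array([[1, 0.4, 0.4], [0.4, 1, 0.5], [0.4, 0.5, 1]])
        hits = 0
        nsim = 400
        for _ in range(nsim):
            x = rng.multivariate_normal(np.zeros(3), cov, size=60)
            r = np.corrcoef(x, rowvar=False)
            z, _ = compare_dependent_correlations(r[0, 1], r[0, 2], r[1, 2], 60)
            hits += abs(z) > 1.959964
        rate = hits / nsim
        assert 0.02 <= rate <= 0.09  # nominal 0.05 within binomial error

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            compare_dependent_correlations(1.0, 0.5, 0.5, 50)
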