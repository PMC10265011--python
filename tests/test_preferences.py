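"""Utility function, softmax choice rule and joint likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from inequifit.errors import DataError, InvalidInputError
from inequifit.games import Allocation, DecisionContext, build_dg_contexts, build_ug_responder_contexts
from inequifit.preferences import (
    ChoiceRecord,
    CompiledSchedule,
    PreferenceParams,
    choice_probabilities,
    context_utilities,
    deterministic_choice,
    log_likelihood,
    records_from_frame,
    records_to_frame,
    utility,
)

PARAMS = st.builds(
    PreferenceParams,
    alpha=st.floats(-0.5, 3),
    beta=st.floats(-0.5, 2),
    lam=st.floats(0, 20),
)


class TestUtility:
    def test_equal_split_is_pure_payoff(self):
        for a, b in [(0.0, 0.0), (2.0, -1.0), (0.5, 0.5)]:
            assert utility(Allocation(500, 500), PreferenceParams(a, b, 1)) == 500

    def test_disadvantage_penalty(self):
        # behind by 500 relative to the midpoint, weighted by alpha
        p = PreferenceParams(0.5, 0.5, 1)
        assert utility(Allocation(0, 1000), p) == -250

    def test_advantage_penalty(self):
        p = PreferenceParams(0.5, 0.2, 1)
        assert utility(Allocation(1000, 0), p) == 900

    @given(
        x=st.floats(0, 3000),
        y=st.floats(0, 3000),
        params=PARAMS,
    )
    def test_at_most_one_penalty_active(self, x, y, params):
        alloc = Allocation(x, y)
        base = utility(alloc, PreferenceParams(0, 0, params.lam))
        u = utility(alloc, params)
        if x == y:
            assert u == base
        elif x < y:
            assert u == pytest.approx(base - params.alpha * ((x + y) / 2 - x))
        else:
            assert u == pytest.approx(base - params.beta * (x - (x + y) / 2))

    def test_lambda_must_be_nonnegative(self):
        with pytest.raises(InvalidInputError):
            PreferenceParams(0.5, 0.5, -1.0)


class TestChoiceProbabilities:
    def test_zero_inverse_temperature_is_uniform(self, schedule):
        p = PreferenceParams(0.7, 0.3, 0.0)
        for ctx in schedule:
            probs = choice_probabilities(ctx, p)
            assert probs == pytest.approx(np.full(len(ctx.options), 1 / len(ctx.options)))

    def test_equal_utilities_split_evenly(self):
        # offer 0 with no inequity aversion: accepting (0, 1500) and
        # rejecting (0, 0) both yield utility 0
        ctx = build_ug_responder_contexts()[0]
        probs = choice_probabilities(ctx, PreferenceParams(0.0, 0.0, 5.0))
        assert probs == pytest.approx([0.5, 0.5])

    @given(params=PARAMS, idx=st.integers(0, 36))
    def test_probabilities_normalize(self, schedule, params, idx):
        probs = choice_probabilities(schedule[idx], params)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs > 0).all()

    def test_extreme_utilities_do_not_overflow(self):
        (ctx,) = build_dg_contexts([1000])
        # lam * U spans hundreds on the raw-JPY scale
        probs = choice_probabilities(ctx, PreferenceParams(0, 0, 700.0), scale=1.0)
        assert np.isfinite(probs).all()
        assert probs.sum() == pytest.approx(1.0)

    def test_shifting_all_utilities_leaves_probabilities_unchanged(self):
        # two DG endowments where options differ by a constant self-payoff
        params = PreferenceParams(0.0, 0.0, 5.0)
        base = DecisionContext(
            "DG", 1.0, tuple((a, Allocation(1000 - a, a)) for a in range(0, 401, 100))
        )
        shifted = DecisionContext(
            "DG", 2.0, tuple((a, Allocation(1500 - a, a + 500)) for a in range(0, 401, 100))
        )
        # with alpha = beta = 0 the utilities differ by exactly +0.5 kJPY
        u0 = context_utilities(base, params)
        u1 = context_utilities(shifted, params)
        assert u1 - u0 == pytest.approx(np.full(5, 0.5))
        assert choice_probabilities(base, params) == pytest.approx(
            choice_probabilities(shifted, params), abs=1e-12
        )

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0, 2.0])
    def test_responder_threshold_matches_closed_form(self, alpha):
        # at lam -> inf an offer is accepted iff U(o, 1500 - o) > 0, i.e.
        # o > 750 * alpha / (1 + alpha)
        threshold = 750 * alpha / (1 + alpha)
        sharp = PreferenceParams(alpha, 0.0, 5000.0)
        for ctx in build_ug_responder_contexts():
            offer = ctx.context_param
            probs = choice_probabilities(ctx, sharp)
            if offer > threshold + 1:
                assert probs[0] > 0.999
            elif offer < threshold - 1:
                assert probs[0] < 0.001
        assert deterministic_choice(
            build_ug_responder_contexts()[7], PreferenceParams(alpha, 0, 1)
        ) == ("accept" if 700 > threshold else "reject")

    def test_acceptance_monotone_in_offer_below_even_split(self):
        p = PreferenceParams(1.2, 0.0, 4.0)
        accept = [
            choice_probabilities(ctx, p)[0]
            for ctx in build_ug_responder_contexts()
            if ctx.context_param <= 750
        ]
        assert np.all(np.diff(accept) >= -1e-12)

    def test_probability_of_best_option_rises_with_lambda(self, schedule):
        ctx = schedule[0]
        best = deterministic_choice(ctx, PreferenceParams(0.4, 0.6, 1.0))
        i = ctx.labels.index(best)
        probs = [
            choice_probabilities(ctx, PreferenceParams(0.4, 0.6, lam))[i]
            for lam in (0.0, 1.0, 5.0, 20.0, 100.0, 400.0)
        ]
        assert np.all(np.diff(probs) > 0)
        assert probs[-1] > 0.999


class TestDeterministicChoice:
    def test_strong_advantage_aversion_picks_equal_split(self):
        (ctx,) = build_dg_contexts([1000])
        assert deterministic_choice(ctx, PreferenceParams(0.5, 1.5, 1)) == 500

    def test_pure_self_interest_keeps_everything(self):
        (ctx,) = build_dg_contexts([1000])
        assert deterministic_choice(ctx, PreferenceParams(0, 0, 1)) == 0

    def test_ties_break_to_lowest_label(self):
        # offer 0, inequity-blind responder: both options give utility 0
        ctx = build_ug_responder_contexts()[0]
        assert deterministic_choice(ctx, PreferenceParams(0, 0, 1)) == "accept"


def _brute_force_log_likelihood(records, contexts, params):
    """Independent per-record reimplementation with plain Python loops."""
    index = {c.key: c for c in contexts}
    total = 0.0
    for rec in records:
        ctx = index[(rec.game, round(float(rec.context_param), 6))]
        weights = ctx.accept_probs or [1.0] * len(ctx.options)
        us = []
        for (lab, alloc), w in zip(ctx.options, weights):
            x, y = alloc.x / 1000, alloc.y / 1000
            u = x - params.alpha * max((x + y) / 2 - x, 0) - params.beta * max(
                x - (x + y) / 2, 0
            )
            us.append(params.lam * u * w)
        m = max(us)
        denom = sum(math.exp(u - m) for u in us)
        i = ctx.labels.index(rec.chosen_label)
        total += us[i] - m - math.log(denom)
    return total


class TestLogLikelihood:
    def test_empty_record_list_scores_zero(self, schedule):
        assert log_likelihood([], PreferenceParams(1, 1, 1), schedule) == 0.0

    def test_random_chooser_on_binary_context(self, schedule):
        rec = ChoiceRecord("p1", "UG_RESPONDER", 700.0, "accept")
        ll = log_likelihood([rec], PreferenceParams(0.4, 0.2, 0.0), schedule)
        assert ll == pytest.approx(math.log(0.5))

    @given(params=PARAMS)
    def test_full_schedule_matches_brute_force(self, schedule, small_study, params):
        behaviour = small_study["behaviour"]
        records = records_from_frame(
            behaviour[behaviour.participant_id == "P0001"]
        )
        expected = _brute_force_log_likelihood(records, schedule, params)
        assert log_likelihood(records, params, schedule) == pytest.approx(expected)

    @given(params=PARAMS)
    def test_compiled_batch_matches_per_record_path(
        self, schedule, compiled, small_study, params
    ):
        behaviour = small_study["behaviour"]
        records = records_from_frame(behaviour[behaviour.participant_id == "P0002"])
        chosen = compiled.encode_records(records)
        batched = compiled.log_likelihood(
            [params.alpha], [params.beta], [params.lam], chosen
        )[0]
        assert batched == pytest.approx(log_likelihood(records, params, schedule))

    def test_unknown_context_raises_data_error(self, schedule):
        rec = ChoiceRecord("p1", "DG", 900.0, 0)
        with pytest.raises(DataError):
            log_likelihood([rec], PreferenceParams(1, 1, 1), schedule)

    def test_unknown_label_raises_data_error(self, schedule):
        rec = ChoiceRecord("p1", "DG", 1000.0, 150)
        with pytest.raises(DataError):
            log_likelihood([rec], PreferenceParams(1, 1, 1), schedule)


class TestRecordsSerialization:
    def test_round_trip(self, small_study):
        behaviour = small_study["behaviour"]
        records = records_from_frame(behaviour)
        back = records_to_frame(records)
        assert len(back) == len(behaviour)
        again = records_from_frame(back)
        assert again == records
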