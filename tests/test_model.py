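"""Generative trial model: learning curve, program mixture, RTs, simulation."""

import math

import numpy as np
import pytest

from seqmem.architectures import QUEUE, STACK, retrieve_schedule
from seqmem.grammar import CENTER_EMBEDDED, CROSS_SERIAL, GrammarSpec, is_grammatical
from seqmem.model import (
    ModelParams,
    PROGRAM_BLUE_THEN_RED,
    PROGRAM_CORRECT,
    PROGRAM_LAPSE,
    gompertz_p_correct,
    rt_for_touch,
    sample_program,
    simulate_trial,
)

NOISELESS = ModelParams(p_mem=0.0, p_lapse=0.0, gompertz_a=1.0, gompertz_b=0.0, sigma_rt=1e-9)


def test_gompertz_limits():
    assert gompertz_p_correct(3, 0.8, 0.0, 0.1) == pytest.approx(0.8)  # B=0 -> A
    assert gompertz_p_correct(1e6, 0.8, 2.0, 0.1) == pytest.approx(0.8)  # asymptote
    assert gompertz_p_correct(0, 1.0, 1.0, 1.0) == pytest.approx(math.exp(-1))


def test_gompertz_monotone_in_training():
    t = np.arange(0, 100)
    g = gompertz_p_correct(t, 0.9, 3.0, 0.1)
    assert np.all(np.diff(g) > 0)


def test_sample_program_mixture_frequencies():
    # g == 0.5 at all t when A=0.5, B=0
    params = ModelParams(p_lapse=0.1, gompertz_a=0.5, gompertz_b=0.0)
    rng = np.random.default_rng(7)
    draws = [sample_program(10, params, rng) for _ in range(100_000)]
    freq = {p: draws.count(p) / len(draws) for p in set(draws)}
    assert freq[PROGRAM_LAPSE] == pytest.approx(0.10, abs=0.01)
    assert freq[PROGRAM_CORRECT] == pytest.approx(0.45, abs=0.01)
    assert freq[PROGRAM_BLUE_THEN_RED] == pytest.approx(0.45, abs=0.01)
    assert sample_program(0, params.with_(p_lapse=1.0), rng) == PROGRAM_LAPSE


def test_rt_for_touch_deterministic_limit_and_median():
    params = ModelParams(t_base=300.0, t_op=200.0, sigma_rt=1e-12)
    rng = np.random.default_rng(0)
    assert rt_for_touch(3, params, rng) == pytest.approx(900.0)
    params = params.with_(sigma_rt=0.3)
    draws = [rt_for_touch(1, params, rng) for _ in range(50_000)]
    assert np.median(draws) == pytest.approx(500.0, rel=0.01)  # lognormal median = scale
    with pytest.raises(ValueError):
        rt_for_touch(0, params, rng)


@pytest.mark.parametrize("architecture", [STACK, QUEUE])
@pytest.mark.parametrize("condition", [CENTER_EMBEDDED, CROSS_SERIAL])
def test_noiseless_trials_grammatical(architecture, condition):
    rng = np.random.default_rng(3)
    grammar = GrammarSpec(condition, 3)
    for _ in range(20):
        tr = simulate_trial(grammar, architecture, NOISELESS, 0, feedback=True, rng=rng)
        assert tr.complete
        assert is_grammatical(tr.touches, grammar)


def test_wrong_program_hits_blue_first_baseline():
    """With g=0 the completion rate equals the blue-then-red baseline 1/n!."""
    params = ModelParams(p_mem=0.0, p_lapse=0.0, gompertz_a=0.05, gompertz_b=8.0, gompertz_c=0.0)
    # gompertz a*exp(-b) ~ 1.7e-5: effectively always the wrong program
    rng = np.random.default_rng(5)
    grammar = GrammarSpec(CENTER_EMBEDDED, 3)
    ok = sum(
        is_grammatical(
            simulate_trial(grammar, QUEUE, params, 0, feedback=False, rng=rng).touches, grammar
        )
        for _ in range(3000)
    )
    # binomial 3 sigma around 1/6
    se = math.sqrt((1 / 6) * (5 / 6) / 3000)
    assert ok / 3000 == pytest.approx(1 / 6, abs=3 * se)


def test_feedback_truncation_contract():
    """Feedback trials end exactly at the first ungrammatical touch."""
    params = ModelParams(p_mem=0.3, p_lapse=0.2, gompertz_a=0.6, gompertz_b=1.0)
    rng = np.random.default_rng(9)
    grammar = GrammarSpec(CROSS_SERIAL, 3)
    saw_error = False
    for _ in range(200):
        tr = simulate_trial(grammar, QUEUE, params, 0, feedback=True, rng=rng)
        if tr.first_error_index is None:
            assert tr.complete and len(tr.touches) == 6
        else:
            saw_error = True
            assert not tr.complete
            assert len(tr.touches) == tr.first_error_index
            assert len(tr.rts) == len(tr.touches)
    assert saw_error


def _mean_second_half_rts(architecture, condition, n, params, n_trials=400, seed=0):
    rng = np.random.default_rng(seed)
    grammar = GrammarSpec(condition, n)
    sums = np.zeros(n)
    count = 0
    while count < n_trials:
        tr = simulate_trial(grammar, architecture, params, 0, feedback=False, rng=rng,
                            program=PROGRAM_CORRECT)
        if not is_grammatical(tr.touches, grammar):
            continue
        sums += np.asarray(tr.rts[n:])
        count += 1
    return sums / count


def test_rt_signatures_by_architecture():
    """Queue/CE second-half RTs decrease with position; stack/CE are flat;
    stack/CS pays a first-touch reversal cost of about t_op * n."""
    params = NOISELESS.with_(sigma_rt=0.1, t_base=400.0, t_op=150.0, p_mem=0.0)
    n = 4
    q_ce = _mean_second_half_rts(QUEUE, CENTER_EMBEDDED, n, params)
    assert np.all(np.diff(q_ce[1:]) < 0)  # positions 2..n strictly decreasing
    s_ce = _mean_second_half_rts(STACK, CENTER_EMBEDDED, n, params)
    assert np.ptp(s_ce) < 0.1 * params.t_op
    s_cs = _mean_second_half_rts(STACK, CROSS_SERIAL, n, params)
    first_excess = s_cs[0] - s_cs[1:].mean()
    assert first_excess == pytest.approx(params.t_op * n, rel=0.15)
    s_cs_small = _mean_second_half_rts(STACK, CROSS_SERIAL, 2, params)
    assert s_cs[0] - s_cs[1:].mean() > s_cs_small[0] - s_cs_small[1:].mean()


def _error_rate(architecture, condition, n, p_mem, n_trials=600, seed=1):
    rng = np.random.default_rng(seed)
    params = NOISELESS.with_(p_mem=p_mem)
    grammar = GrammarSpec(condition, n)
    errs = sum(
        simulate_trial(grammar, architecture, params, 0, feedback=True, rng=rng,
                       program=PROGRAM_CORRECT).first_error_index is not None
        for _ in range(n_trials)
    )
    return errs / n_trials


def test_error_rate_monotone_in_noise_and_length():
    """More corruption chances (higher p_mem, more stores) mean more errors."""
    assert _error_rate(QUEUE, CENTER_EMBEDDED, 3, 0.12) > _error_rate(QUEUE, CENTER_EMBEDDED, 3, 0.03)
    assert _error_rate(QUEUE, CENTER_EMBEDDED, 4, 0.08) > _error_rate(QUEUE, CENTER_EMBEDDED, 2, 0.08)
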