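"""Simulation-based likelihood, fitting machinery, and error decomposition."""

import math

import numpy as np
import pytest
from scipy.stats import lognorm

from seqmem.cohort import ExperimentDesign, simulate_participant
from seqmem.grammar import A, B, CENTER_EMBEDDED, GrammarSpec, ItemToken
from seqmem.inference import (
    FitConfig,
    FitResult,
    aic_compare,
    decompose_errors,
    exact_response_distribution,
    fit_participant,
    mc_response_distribution,
    trial_loglik,
)
from seqmem.model import ModelParams, TrialRecord, gompertz_p_correct, program_weights

QUIET = ModelParams(p_mem=0.0, p_lapse=0.0, gompertz_a=1.0, gompertz_b=0.0, sigma_rt=1e-6)

PARAM_SETTINGS = [
    ModelParams(p_mem=0.15, p_lapse=0.05, gompertz_a=0.8, gompertz_b=1.0, gompertz_c=0.2),
    ModelParams(p_mem=0.02, p_lapse=0.2, gompertz_a=0.95, gompertz_b=3.0, gompertz_c=0.05),
    ModelParams(p_mem=0.3, p_lapse=0.0, gompertz_a=0.5, gompertz_b=0.5, gompertz_c=0.5),
]

PREFIXES = ([], [A(1)], [A(1), A(2)], [A(1), A(2), B(2)])


@pytest.mark.parametrize("params", PARAM_SETTINGS)
@pytest.mark.parametrize("architecture", ["queue", "stack"])
def test_mc_matches_exact_enumeration(params, architecture):
    """The MC next-touch distribution agrees with brute-force enumeration."""
    grammar = GrammarSpec(CENTER_EMBEDDED, 2)
    M = 20_000
    for prefix in PREFIXES:
        ex = exact_response_distribution(prefix, params, architecture, grammar, 5)
        mc = mc_response_distribution(
            prefix, params, architecture, grammar, 5, M, np.random.default_rng(77)
        )
        assert np.isclose(mc.probs.sum(), 1.0, atol=1e-9)
        tol = np.maximum(3 * np.sqrt(ex.probs * (1 - ex.probs) / M), 0.004)
        assert np.all(np.abs(ex.probs - mc.probs) <= tol)


def test_mc_error_shrinks_with_sample_size():
    """The MC estimator is consistent: error decreases from M=1e3 to M=1e5."""
    grammar = GrammarSpec(CENTER_EMBEDDED, 2)
    params = PARAM_SETTINGS[0]

    def worst_err(M):
        errs = []
        for prefix in PREFIXES:
            ex = exact_response_distribution(prefix, params, "queue", grammar, 5)
            mc = mc_response_distribution(
                prefix, params, "queue", grammar, 5, M, np.random.default_rng(12345)
            )
            errs.append(np.abs(ex.probs - mc.probs).max())
        return max(errs)

    e3, e4, e5 = worst_err(1000), worst_err(10_000), worst_err(100_000)
    assert e5 < e3
    assert e5 < 0.005
    assert e4 < 0.02


def test_exact_distribution_degenerate_and_errors():
    grammar = GrammarSpec(CENTER_EMBEDDED, 2)
    ex = exact_response_distribution([A(1), A(2)], QUIET, "queue", grammar, 5)
    assert ex.prob(B(2)) == pytest.approx(1.0)  # noiseless: deterministic next B
    assert ex.probs.sum() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        exact_response_distribution([], QUIET, "queue", GrammarSpec(CENTER_EMBEDDED, 3), 5)


def test_mc_distribution_contracts():
    grammar = GrammarSpec(CENTER_EMBEDDED, 2)
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        mc_response_distribution([], QUIET, "queue", grammar, 5, 50, rng)
    lapse_only = QUIET.with_(p_lapse=1.0, sigma_rt=0.2)
    d = mc_response_distribution([A(1)], lapse_only, "queue", grammar, 5, 20_000, rng)
    assert np.allclose(d.probs, 0.25, atol=0.02)  # uniform over the 4-item array
    noiseless = mc_response_distribution([A(1), A(2)], QUIET, "queue", grammar, 5, 5000, rng)
    assert noiseless.prob(B(2)) > 0.995  # 1 minus smoothing


def _manual_trial(touches, rts, n=2, gompertz_t=5.0):
    return TrialRecord(
        condition=CENTER_EMBEDDED, n_pairs=n, trial_index=1, feedback=True,
        touches=touches, rts=rts, first_error_index=None, complete=True,
        gompertz_t=gompertz_t,
    )


def test_trial_loglik_closed_form_without_corruption():
    """At p_mem=0 the trial likelihood has a closed form: a three-program
    mixture of products of uniform choice probabilities and lognormal RT
    densities with schedule op counts (queue/CE ops are [1,1,2,1] at n=2)."""
    params = ModelParams(p_mem=0.0, p_lapse=0.1, gompertz_a=0.8, gompertz_b=1.0,
                         gompertz_c=0.2, t_base=400.0, t_op=150.0, sigma_rt=0.3)
    rts = [620.0, 480.0, 710.0, 533.0]
    trial = _manual_trial([A(1), A(2), B(2), B(1)], rts)

    def f(rt, ops):
        return lognorm(s=params.sigma_rt, scale=params.t_base + params.t_op * ops).pdf(rt)

    w = program_weights(5.0, params)
    l_correct = 0.5 * 1.0 * 1.0 * 1.0 * f(rts[0], 1) * f(rts[1], 1) * f(rts[2], 2) * f(rts[3], 1)
    l_wrong = 0.5 * 1.0 * 0.5 * 1.0 * np.prod([f(r, 1) for r in rts])
    l_lapse = 0.25 ** 4 * np.prod([f(r, 1) for r in rts])
    expected = math.log(
        w["correct"] * l_correct + w["blue_then_red"] * l_wrong + w["lapse"] * l_lapse
    )
    got = trial_loglik(trial, params, "queue", M=20_000, rng=np.random.default_rng(3))
    assert got == pytest.approx(expected, abs=0.01)


def test_trial_loglik_invariant_under_pair_relabeling():
    params = PARAM_SETTINGS[0]
    rts = [620.0, 480.0, 710.0, 533.0]
    t1 = _manual_trial([A(1), A(2), B(2), B(1)], rts)
    t2 = _manual_trial([A(2), A(1), B(1), B(2)], rts)  # pair ids 1 <-> 2
    ll1 = trial_loglik(t1, params, "queue", M=50_000, rng=np.random.default_rng(4))
    ll2 = trial_loglik(t2, params, "queue", M=50_000, rng=np.random.default_rng(4))
    # equality is exact for the estimand; the MC estimate matches up to the
    # sampling error of the exhausted-buffer fallback draws
    assert ll1 == pytest.approx(ll2, abs=0.01)


def test_aic_compare():
    base = dict(architecture="queue", params_hat=QUIET)
    fq = FitResult(**base, log_likelihood=-100.0)
    fs = FitResult(architecture="stack", params_hat=QUIET, log_likelihood=-100.0)
    assert aic_compare(fq, fs) == 0.0
    fq2 = FitResult(**base, log_likelihood=-95.0)  # logL_q = logL_s + 5
    assert aic_compare(fq2, fs) == pytest.approx(-10.0)
    fs_bad = FitResult(architecture="stack", params_hat=QUIET,
                       log_likelihood=-100.0, n_free_params=9)
    with pytest.raises(ValueError):
        aic_compare(fq, fs_bad)


@pytest.fixture(scope="module")
def small_participant():
    design = ExperimentDesign(condition=CENTER_EMBEDDED, lengths=(2,),
                              training_trials_per_length={2: 12},
                              test_trials_per_length=2)
    true = ModelParams(p_mem=0.08, p_lapse=0.01, gompertz_a=0.9, gompertz_b=1.0,
                       gompertz_c=0.2, t_base=400.0, t_op=150.0, sigma_rt=0.25)
    return simulate_participant(true, design, "queue", np.random.default_rng(21), "P1")


def test_fit_is_deterministic_under_common_random_numbers(small_participant):
    config = FitConfig(p_mem_grid=(0.0, 0.08), n_starts=2, maxfev=80, seed=5)
    f1 = fit_participant(small_participant, "queue", M=500, config=config)
    f2 = fit_participant(small_participant, "queue", M=500, config=config)
    assert f1.params_hat == f2.params_hat
    assert f1.log_likelihood == f2.log_likelihood
    assert f1.aic == pytest.approx(2 * 8 - 2 * f1.log_likelihood)


def test_fit_requires_training_trials():
    with pytest.raises(ValueError):
        fit_participant([], "queue")


def test_decompose_errors_memory_only():
    """With no lapses and the correct program guaranteed, every error is a
    memory error, and memory errors grow with array size."""
    fit = FitResult(architecture="queue",
                    params_hat=QUIET.with_(p_mem=0.1, sigma_rt=0.25),
                    log_likelihood=0.0)
    design = ExperimentDesign(condition=CENTER_EMBEDDED)
    dec = decompose_errors(fit, design, M=2000, rng=np.random.default_rng(2))
    dec = dec.set_index("n_pairs")
    assert (dec["rate_wrong_program"] == 0).all()
    assert (dec["rate_lapse"] == 0).all()
    assert dec.loc[4, "rate_memory"] > dec.loc[2, "rate_memory"] > 0


def test_decompose_errors_wrong_program_closed_form():
    """With only the wrong-program source on, the per-trial error rate is the
    mean of (1 - g(t)) * (1 - 1/n!) over that length's training window."""
    params = ModelParams(p_mem=0.0, p_lapse=0.0, gompertz_a=0.8, gompertz_b=2.0,
                         gompertz_c=0.05, sigma_rt=0.25)
    fit = FitResult(architecture="queue", params_hat=params, log_likelihood=0.0)
    design = ExperimentDesign(condition=CENTER_EMBEDDED)
    dec = decompose_errors(fit, design, M=4000, rng=np.random.default_rng(6)).set_index("n_pairs")
    windows = {2: np.arange(0, 20), 3: np.arange(20, 60), 4: np.arange(60, 100)}
    for n, ts in windows.items():
        g = gompertz_p_correct(ts, 0.8, 2.0, 0.05)
        expected = np.mean((1 - g) * (1 - 1 / math.factorial(n)))
        assert dec.loc[n, "rate_wrong_program"] == pytest.approx(expected, abs=0.03)
        assert dec.loc[n, "rate_memory"] == 0.0
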