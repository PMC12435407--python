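"""Simulation-based likelihood, per-participant MLE, AIC comparison, and
error-source decomposition.

The likelihood of an observed further-training trial factorizes over the
three latent programs: the trial likelihood is

    L = p_lapse * L_lapse + (1-p_lapse) * g(t) * L_correct
        + (1-p_lapse) * (1-g(t)) * L_blue_then_red

where each program term is a product over touches of P(item | prefix,
program) * f(rt | item, program).  Lapse and blue-then-red item probabilities
are analytic (uniform choices, one op per touch).  The correct program's
second-half terms depend on the latent corruption history of the memory
buffer; they are estimated by forward-simulating M corruption histories of
the observed A-touch stores and filtering on the observed B touches (the
observed A order pins down the stores, so no rejection is needed for the
first half).  RT densities are lognormal mixtures over the op counts the
surviving histories incurred.

Fitting profiles the corruption rate p_mem over a grid (the only parameter
the particle simulation depends on) and maximizes the remaining seven
parameters by bounded Nelder-Mead with Latin-hypercube multi-start.  Common
random numbers — one particle seed per participant x architecture, reused at
every p_mem value — make the Monte Carlo likelihood surface deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .architectures import QUEUE, STACK
from .grammar import B, CENTER_EMBEDDED, CROSS_SERIAL, GrammarSpec, ItemToken
from .model import (
    ModelParams,
    TrialRecord,
    gompertz_p_correct,
    program_weights,
    simulate_trial,
    PROGRAM_BLUE_THEN_RED,
    PROGRAM_CORRECT,
    PROGRAM_LAPSE,
)

N_FREE_PARAMS = 8
_LOG_2PI = math.log(2.0 * math.pi)

# inner optimization order: p_lapse, gompertz_a, gompertz_b, gompertz_c,
# t_base, t_op, sigma_rt
INNER_PARAM_NAMES = (
    "p_lapse",
    "gompertz_a",
    "gompertz_b",
    "gompertz_c",
    "t_base",
    "t_op",
    "sigma_rt",
)
INNER_BOUNDS = (
    (1e-4, 0.5),
    (0.05, 1.0),
    (0.0, 8.0),
    (0.005, 1.0),
    (50.0, 1500.0),
    (0.0, 600.0),
    (0.02, 1.5),
)
DEFAULT_P_MEM_GRID = tuple(np.round(np.linspace(0.0, 0.24, 13), 4))


def _lognorm_logpdf(rt: np.ndarray, log_scale: np.ndarray, sigma: float) -> np.ndarray:
    z = (np.log(rt) - log_scale) / sigma
    return -np.log(rt) - math.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z * z


# ---------------------------------------------------------------------------
# vectorized particle filter over corruption histories (correct program)
# ---------------------------------------------------------------------------


def _delete_at(buf: np.ndarray, rows: np.ndarray, victim: np.ndarray, n: int) -> None:
    """Remove column ``victim[r]`` from each row in ``rows``, shifting left."""
    idx = np.arange(n)[None, :]
    gather = idx + (idx >= victim[:, None])
    gather = np.minimum(gather, n - 1)
    buf[rows] = np.take_along_axis(buf[rows], gather, axis=1)


def _simulate_stores(
    a_order: list[int], n: int, p_mem: float, M: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Store the observed A order into M particle buffers with corruption."""
    buf = np.full((M, n), -1, dtype=np.int64)
    lengths = np.zeros(M, dtype=np.int64)
    ar = np.arange(M)
    for pid in a_order:
        buf[ar, lengths] = pid
        lengths += 1
        u = rng.random(M)
        w = rng.random(M)
        swap = (u < 0.5 * p_mem) & (lengths >= 2)
        rows = np.nonzero(swap)[0]
        if rows.size:
            c1, c2 = lengths[rows] - 1, lengths[rows] - 2
            tmp = buf[rows, c1].copy()
            buf[rows, c1] = buf[rows, c2]
            buf[rows, c2] = tmp
        dele = (u >= 0.5 * p_mem) & (u < p_mem)
        rows = np.nonzero(dele)[0]
        if rows.size:
            victim = np.minimum((w[rows] * lengths[rows]).astype(np.int64), lengths[rows] - 1)
            _delete_at(buf, rows, victim, n)
            lengths[rows] -= 1
    return buf, lengths


def _retrieve_step(
    buf: np.ndarray,
    lengths: np.ndarray,
    condition: str,
    architecture: str,
    step: int,
    remaining: list[int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One vectorized second-half retrieval across all particles.

    ``remaining`` is the set of B pair_ids not yet covered by the observed
    prefix, used by the exhausted-buffer fallback.  Mutates buf/lengths.
    """
    M, n = buf.shape
    fb = rng.random(M)  # drawn unconditionally: keeps random streams aligned
    items = np.zeros(M, dtype=np.int64)
    ops = np.ones(M, dtype=np.int64)
    empty = lengths == 0
    ne = np.nonzero(~empty)[0]
    if ne.size:
        L = lengths[ne]
        if architecture == QUEUE and condition == CENTER_EMBEDDED:
            items[ne] = buf[ne, L - 1]  # traverse from the front to the back
            ops[ne] = L
            lengths[ne] -= 1
        elif architecture == QUEUE and condition == CROSS_SERIAL:
            items[ne] = buf[ne, 0]
            _delete_at(buf, ne, np.zeros(ne.size, dtype=np.int64), n)
            lengths[ne] -= 1
        elif architecture == STACK and condition == CENTER_EMBEDDED:
            items[ne] = buf[ne, L - 1]
            lengths[ne] -= 1
        else:  # stack + cross-serial
            if step == 1:  # one-time reversal onto the auxiliary stack
                gather = np.maximum(L[:, None] - 1 - np.arange(n)[None, :], 0)
                buf[ne] = np.take_along_axis(buf[ne], gather, axis=1)
                ops[ne] = L + 1
            items[ne] = buf[ne, lengths[ne] - 1]
            lengths[ne] -= 1
    er = np.nonzero(empty)[0]
    if er.size:
        if remaining:
            pool = np.asarray(remaining, dtype=np.int64)
            items[er] = pool[np.minimum((fb[er] * len(pool)).astype(np.int64), len(pool) - 1)]
        else:
            items[er] = -1
    return items, ops


def _b_half_filter(
    grammar: GrammarSpec,
    architecture: str,
    a_order: list[int],
    observed_b: list[ItemToken],
    p_mem: float,
    M: int,
    rng: np.random.Generator,
    predict_next: bool = False,
):
    """Filter M corruption histories on the observed second-half touches.

    Returns ``(p_obs, ops_counts, alive_frac, pred)`` where ``p_obs[j]`` is
    the fraction of histories consistent with the observed prefix that emit
    the j-th observed touch, ``ops_counts[j]`` the op-count histogram
    (indices 1..n+1) among those, ``alive_frac`` the final surviving
    fraction, and ``pred`` (when ``predict_next``) the predictive item/op
    distribution at the position after the observed prefix.
    """
    n = grammar.n_pairs
    buf, lengths = _simulate_stores(a_order, n, p_mem, M, rng)
    alive = np.ones(M, dtype=bool)
    seen_b: list[int] = []
    p_obs: list[float] = []
    ops_counts: list[np.ndarray] = []
    pred = None
    n_steps = len(observed_b) + (1 if predict_next else 0)
    for j in range(min(n_steps, n)):
        remaining = [i for i in range(1, n + 1) if i not in seen_b]
        items, ops = _retrieve_step(buf, lengths, grammar.condition, architecture, j + 1, remaining, rng)
        if j < len(observed_b):
            obs = observed_b[j]
            if obs.item_class == "B":
                match = alive & (items == obs.pair_id)
            else:
                match = np.zeros(M, dtype=bool)
            n_alive = int(alive.sum())
            p_obs.append(float(match.sum()) / n_alive if n_alive else 0.0)
            counts = np.bincount(ops[match], minlength=n + 2).astype(float)
            ops_counts.append(counts[1 : n + 2])
            alive = match
            if obs.item_class == "B":
                seen_b.append(obs.pair_id)
        else:
            pred_items: dict[int, float] = {}
            pred_ops: dict[int, np.ndarray] = {}
            rows = np.nonzero(alive)[0]
            for pid in np.unique(items[rows]):
                mask = rows[items[rows] == pid]
                pred_items[int(pid)] = float(mask.size)
                pred_ops[int(pid)] = np.bincount(ops[mask], minlength=n + 2).astype(float)[1 : n + 2]
            pred = (pred_items, pred_ops, int(alive.sum()))
    alive_frac = float(alive.sum()) / M
    return p_obs, ops_counts, alive_frac, pred


# ---------------------------------------------------------------------------
# per-participant likelihood tables (fixed p_mem, fixed particle draws)
# ---------------------------------------------------------------------------


@dataclass
class _LikTables:
    """Per-touch quantities that do not depend on the seven inner parameters."""

    logp_correct: np.ndarray  # (T,)
    logp_wrong: np.ndarray  # (T,)
    logp_lapse: np.ndarray  # (T,)
    ops_weights: np.ndarray  # (T, ops_max) correct-program op mixture
    rt: np.ndarray  # (T,)
    trial_ptr: np.ndarray  # (n_trials + 1,) offsets into the touch axis
    g_t: np.ndarray  # (n_trials,) learning-curve clocks
    ops_max: int


def _analytic_touch_logps(trial: TrialRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Item log-probabilities under the analytic branches of each program.

    Returns (logp_correct_first_half_extended, logp_wrong, logp_lapse); the
    correct-program entries for second-half positions are placeholders (0)
    to be overwritten by the particle filter.
    """
    n = trial.n_pairs
    K = len(trial.touches)
    lp_c = np.zeros(K)
    lp_w = np.zeros(K)
    lp_l = np.full(K, -math.log(2 * n))
    remaining_a = set(range(1, n + 1))
    remaining_b = set(range(1, n + 1))
    for k, touch in enumerate(trial.touches):
        if k < n:  # first half: both non-lapse programs pick an untouched A
            if touch.item_class == "A" and touch.pair_id in remaining_a:
                lp = -math.log(len(remaining_a))
                lp_c[k] = lp
                lp_w[k] = lp
                remaining_a.discard(touch.pair_id)
            else:
                lp_c[k] = -np.inf
                lp_w[k] = -np.inf
        else:  # second half: blue-then-red picks any untouched B
            if touch.item_class == "B" and touch.pair_id in remaining_b:
                lp_w[k] = -math.log(len(remaining_b))
                remaining_b.discard(touch.pair_id)
            else:
                lp_w[k] = -np.inf
    return lp_c, lp_w, lp_l


def build_likelihood_tables(
    trials: list[TrialRecord],
    architecture: str,
    p_mem: float,
    M: int,
    rng: np.random.Generator,
) -> _LikTables:
    """Assemble the p_mem-conditional per-touch tables for a set of trials."""
    if not trials:
        raise ValueError("no trials to build tables for")
    ops_max = max(t.n_pairs for t in trials) + 1
    lc, lw, ll, ws, rts, ptr, g_t = [], [], [], [], [], [0], []
    for trial in trials:
        n = trial.n_pairs
        K = len(trial.touches)
        grammar = GrammarSpec(trial.condition, n)
        t_lc, t_lw, t_ll = _analytic_touch_logps(trial)
        t_ws = np.zeros((K, ops_max))
        t_ws[:, 0] = 1.0  # default: one op per touch
        if K > n:
            eps = 1.0 / (M + 2 * n)
            a_order = [t.pair_id for t in trial.touches[:n]]
            observed_b = list(trial.touches[n:])
            p_obs, ops_counts, _, _ = _b_half_filter(
                grammar, architecture, a_order, observed_b, p_mem, M, rng
            )
            for j, (p, counts) in enumerate(zip(p_obs, ops_counts)):
                k = n + j
                t_lc[k] = math.log((1.0 - 2 * n * eps) * p + eps)
                total = counts.sum()
                if total > 0:
                    t_ws[k, :] = 0.0
                    t_ws[k, : n + 1] = counts / total
        lc.append(t_lc)
        lw.append(t_lw)
        ll.append(t_ll)
        ws.append(t_ws)
        rts.append(np.asarray(trial.rts, dtype=float))
        ptr.append(ptr[-1] + K)
        g_t.append(trial.gompertz_t)
    return _LikTables(
        logp_correct=np.concatenate(lc),
        logp_wrong=np.concatenate(lw),
        logp_lapse=np.concatenate(ll),
        ops_weights=np.vstack(ws),
        rt=np.concatenate(rts),
        trial_ptr=np.asarray(ptr),
        g_t=np.asarray(g_t, dtype=float),
        ops_max=ops_max,
    )


def _loglik_from_tables(theta: np.ndarray, tables: _LikTables) -> float:
    """Summed trial log-likelihood given the seven inner parameters."""
    p_lapse, g_a, g_b, g_c, t_base, t_op, sigma = theta
    ops_values = np.arange(1, tables.ops_max + 1, dtype=float)
    log_scales = np.log(t_base + t_op * ops_values)
    with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
        logf = _lognorm_logpdf(tables.rt[:, None], log_scales[None, :], sigma)
        f = np.exp(logf)
        f_correct = (tables.ops_weights * f).sum(axis=1)
        lc = tables.logp_correct + np.log(f_correct)
        lw = tables.logp_wrong + logf[:, 0]
        ll = tables.logp_lapse + logf[:, 0]
        starts = tables.trial_ptr[:-1]
        Lc = np.add.reduceat(lc, starts)
        Lw = np.add.reduceat(lw, starts)
        Ll = np.add.reduceat(ll, starts)
        g = gompertz_p_correct(tables.g_t, g_a, g_b, g_c)
        a = np.log(p_lapse) + Ll
        b = np.log((1.0 - p_lapse) * g) + Lc
        c = np.log((1.0 - p_lapse) * (1.0 - g)) + Lw
        total = np.logaddexp(np.logaddexp(a, b), c).sum()
    if np.isnan(total):
        return -np.inf
    return float(total)


def trial_loglik(
    trial: TrialRecord,
    params: ModelParams,
    architecture: str,
    M: int = 5000,
    rng: np.random.Generator | None = None,
) -> float:
    """Log-likelihood of one further-training trial under one architecture."""
    rng = rng if rng is not None else np.random.default_rng(0)
    tables = build_likelihood_tables([trial], architecture, params.p_mem, M, rng)
    theta = np.array([getattr(params, name) for name in INNER_PARAM_NAMES])
    return _loglik_from_tables(theta, tables)


def participant_loglik(
    trials: list[TrialRecord],
    params: ModelParams,
    architecture: str,
    M: int = 5000,
    seed: int = 0,
) -> float:
    """Summed training-trial log-likelihood at fixed parameters (CRN seeded)."""
    training = [t for t in trials if t.feedback]
    rng = np.random.default_rng(seed)
    tables = build_likelihood_tables(training, architecture, params.p_mem, M, rng)
    theta = np.array([getattr(params, name) for name in INNER_PARAM_NAMES])
    return _loglik_from_tables(theta, tables)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings: p_mem profile grid, multi-start count, CRN seed."""

    p_mem_grid: tuple[float, ...] = DEFAULT_P_MEM_GRID
    n_starts: int = 5
    maxfev: int = 400
    seed: int = 0


@dataclass
class FitResult:
    """Fitted parameters, log-likelihood and AIC for one participant/architecture."""

    architecture: str
    params_hat: ModelParams
    log_likelihood: float
    n_free_params: int = N_FREE_PARAMS
    converged: bool = True
    detail: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.log_likelihood


def fit_participant(
    trials: list[TrialRecord],
    architecture: str,
    M: int = 5000,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Maximum-likelihood fit of one participant's training trials.

    p_mem is profiled over ``config.p_mem_grid``; at each grid value the
    remaining parameters are maximized by bounded Nelder-Mead, warm-started
    from the best solution so far plus Latin-hypercube restarts.  The
    particle rng is reseeded identically at every p_mem value (common random
    numbers), so the fit is a deterministic function of the data and config.
    """
    training = [t for t in trials if t.feedback]
    if not training:
        raise ValueError("fit_participant requires at least one training trial")
    lo = np.array([b[0] for b in INNER_BOUNDS])
    hi = np.array([b[1] for b in INNER_BOUNDS])
    sampler = qmc.LatinHypercube(d=len(INNER_BOUNDS), seed=config.seed + 1)
    n_extra = max(len(config.p_mem_grid) - 1, 0)
    lhs = lo + sampler.random(config.n_starts + n_extra) * (hi - lo)

    best_ll = -np.inf
    best_theta = None
    best_p_mem = None
    warm = None
    any_success = False
    for i, p_mem in enumerate(config.p_mem_grid):
        rng = np.random.default_rng(config.seed)  # CRN across p_mem values
        tables = build_likelihood_tables(training, architecture, p_mem, M, rng)

        def neg(theta: np.ndarray) -> float:
            return -_loglik_from_tables(np.clip(theta, lo, hi), tables)

        if i == 0:
            starts = [lhs[s] for s in range(config.n_starts)]
        else:
            starts = ([warm] if warm is not None else []) + [lhs[config.n_starts + i - 1]]
        for x0 in starts:
            res = minimize(
                neg,
                x0,
                method="Nelder-Mead",
                bounds=INNER_BOUNDS,
                options={"maxfev": config.maxfev, "xatol": 1e-3, "fatol": 1e-3},
            )
            any_success = any_success or bool(res.success)
            ll = -float(res.fun)
            if best_theta is None or ll > best_ll:
                best_ll = ll
                best_theta = np.clip(res.x, lo, hi)
                best_p_mem = p_mem
        if best_theta is not None:
            warm = best_theta.copy()

    kwargs = dict(zip(INNER_PARAM_NAMES, (float(v) for v in best_theta)))
    params_hat = ModelParams(p_mem=float(best_p_mem), **kwargs)
    return FitResult(
        architecture=architecture,
        params_hat=params_hat,
        log_likelihood=best_ll,
        converged=bool(any_success and np.isfinite(best_ll)),
        detail={"p_mem_grid": list(config.p_mem_grid), "M": M, "seed": config.seed},
    )


def aic_compare(fit_queue: FitResult, fit_stack: FitResult) -> float:
    """Delta AIC = AIC(queue) - AIC(stack); negative values favor the queue."""
    if fit_queue.n_free_params != fit_stack.n_free_params:
        raise ValueError("architectures must have equal numbers of free parameters")
    return fit_queue.aic - fit_stack.aic


# ---------------------------------------------------------------------------
# next-touch response distributions (MC and exact oracle)
# ---------------------------------------------------------------------------


@dataclass
class ResponseDistribution:
    """Next-touch item probabilities plus per-item op-count RT mixtures."""

    items: list[ItemToken]
    probs: np.ndarray
    ops_mixture: dict[ItemToken, dict[int, float]]

    def prob(self, item: ItemToken) -> float:
        return float(self.probs[self.items.index(item)])

    def rt_logpdf(self, item: ItemToken, rt: float, params: ModelParams) -> float:
        """Log density of ``rt`` given the item, mixing over latent op counts."""
        mix = self.ops_mixture.get(item, {1: 1.0})
        dens = 0.0
        for ops, w in mix.items():
            scale = params.t_base + params.t_op * ops
            dens += w * math.exp(
                _lognorm_logpdf(np.array(rt), np.log(scale), params.sigma_rt)
            )
        return math.log(dens)


def _smooth(probs: np.ndarray, eps: float) -> np.ndarray:
    return (1.0 - len(probs) * eps) * probs + eps


def _prefix_split(prefix: list[ItemToken], n: int):
    """Split a prefix into its A half and B half with validity bookkeeping."""
    first = prefix[: min(len(prefix), n)]
    second = prefix[min(len(prefix), n) :]
    return first, second


def _analytic_prefix_logliks(prefix: list[ItemToken], n: int) -> tuple[float, float, float]:
    """(logL_lapse, logL_wrong, logL_correct_first_half) of an item prefix."""
    ll_lapse = -len(prefix) * math.log(2 * n)
    ll_wrong = 0.0
    ll_first = 0.0
    remaining_a = set(range(1, n + 1))
    remaining_b = set(range(1, n + 1))
    for k, touch in enumerate(prefix):
        if k < n:
            if touch.item_class == "A" and touch.pair_id in remaining_a:
                lp = -math.log(len(remaining_a))
                ll_wrong += lp
                ll_first += lp
                remaining_a.discard(touch.pair_id)
            else:
                ll_wrong = -np.inf
                ll_first = -np.inf
        else:
            if touch.item_class == "B" and touch.pair_id in remaining_b:
                ll_wrong += -math.log(len(remaining_b))
                remaining_b.discard(touch.pair_id)
            else:
                ll_wrong = -np.inf
    return ll_lapse, ll_wrong, ll_first


def mc_response_distribution(
    trial_prefix: list[ItemToken],
    params: ModelParams,
    architecture: str,
    grammar: GrammarSpec,
    trial_index: float,
    M: int,
    rng: np.random.Generator,
) -> ResponseDistribution:
    """Monte Carlo next-touch distribution conditioned on an observed prefix.

    The latent program is conditioned exactly (its prefix likelihood is
    analytic except for the correct program's second half, estimated by the
    surviving-particle fraction); corruption histories are marginalized by
    forward simulation from the observed A order.
    """
    if M < 100:
        raise ValueError("M must be >= 100")
    prefix = list(trial_prefix)
    n = grammar.n_pairs
    if len(prefix) >= 2 * n:
        raise ValueError("prefix is already a complete trial")
    items = grammar.items
    eps = 1.0 / (M + 2 * n)
    ll_lapse, ll_wrong, ll_first = _analytic_prefix_logliks(prefix, n)

    first, second = _prefix_split(prefix, n)
    pred = None
    ll_correct = ll_first
    if len(prefix) >= n and np.isfinite(ll_first):
        a_order = [t.pair_id for t in first]
        _, _, alive_frac, pred = _b_half_filter(
            grammar, architecture, a_order, second, params.p_mem, M, rng, predict_next=True
        )
        ll_correct += math.log(alive_frac) if alive_frac > 0 else -np.inf

    prior = program_weights(trial_index, params)
    post = {
        PROGRAM_LAPSE: prior[PROGRAM_LAPSE] * math.exp(ll_lapse),
        PROGRAM_BLUE_THEN_RED: prior[PROGRAM_BLUE_THEN_RED]
        * (math.exp(ll_wrong) if np.isfinite(ll_wrong) else 0.0),
        PROGRAM_CORRECT: prior[PROGRAM_CORRECT]
        * (math.exp(ll_correct) if np.isfinite(ll_correct) else 0.0),
    }
    z = sum(post.values())
    if z <= 0:  # impossible prefix under these parameters: uniform fallback
        post = {p: 1.0 / 3.0 for p in post}
    else:
        post = {p: v / z for p, v in post.items()}

    probs = np.zeros(len(items))
    ops_acc: dict[ItemToken, dict[int, float]] = {it: {} for it in items}

    def add(item: ItemToken, mass: float, ops: int) -> None:
        probs[items.index(item)] += mass
        ops_acc[item][ops] = ops_acc[item].get(ops, 0.0) + mass

    # lapse: uniform over everything, one op
    for it in items:
        add(it, post[PROGRAM_LAPSE] / (2 * n), 1)
    # analytic halves of the structured programs
    touched_a = {t.pair_id for t in first}
    touched_b = {t.pair_id for t in second if t.item_class == "B"}
    if len(prefix) < n:
        pool = [it for it in items if it.item_class == "A" and it.pair_id not in touched_a]
        for prog in (PROGRAM_BLUE_THEN_RED, PROGRAM_CORRECT):
            for it in pool:
                add(it, post[prog] / len(pool), 1)
    else:
        pool = [it for it in items if it.item_class == "B" and it.pair_id not in touched_b]
        if pool:
            for it in pool:
                add(it, post[PROGRAM_BLUE_THEN_RED] / len(pool), 1)
        if pred is not None and pred[2] > 0:
            pred_items, pred_ops, n_alive = pred
            for pid, count in pred_items.items():
                if pid < 1:
                    continue
                it = B(pid)
                counts = pred_ops[pid]
                for o in np.nonzero(counts)[0]:
                    add(it, post[PROGRAM_CORRECT] * counts[o] / n_alive, int(o) + 1)

    probs = probs / probs.sum() if probs.sum() > 0 else np.full(len(items), 1.0 / len(items))
    probs = _smooth(probs, eps)
    mixture = {}
    for it in items:
        total = sum(ops_acc[it].values())
        if total > 0:
            mixture[it] = {o: w / total for o, w in ops_acc[it].items()}
        else:
            mixture[it] = {1: 1.0}
    return ResponseDistribution(items=items, probs=probs, ops_mixture=mixture)


# -- exact oracle (n <= 2): full enumeration over latent outcomes ------------


def _enum_store_states(a_order: list[int], p_mem: float) -> dict[tuple, float]:
    """Exact distribution over buffer contents after storing ``a_order``."""
    states: dict[tuple, float] = {(): 1.0}
    for pid in a_order:
        new: dict[tuple, float] = {}

        def acc(buf: tuple, w: float) -> None:
            if w > 0:
                new[buf] = new.get(buf, 0.0) + w

        for buf, w in states.items():
            grown = buf + (pid,)
            acc(grown, w * (1.0 - p_mem))
            if p_mem > 0:
                swapped = grown if len(grown) < 2 else grown[:-2] + (grown[-1], grown[-2])
                acc(swapped, w * p_mem / 2.0)
                for i in range(len(grown)):
                    acc(grown[:i] + grown[i + 1 :], w * p_mem / (2.0 * len(grown)))
        states = new
    return states


def _enum_retrievals(
    buf: tuple, grammar: GrammarSpec, architecture: str
) -> list[tuple[float, tuple, tuple]]:
    """All (weight, emitted items, op counts) outcomes of the second half."""
    n = grammar.n_pairs
    outcomes: list[tuple[float, tuple, tuple]] = []

    def recurse(buf: tuple, emitted: tuple, ops: tuple, w: float, reversed_cs: bool) -> None:
        step = len(emitted) + 1
        if step > n:
            outcomes.append((w, emitted, ops))
            return
        if not buf:
            untouched = [i for i in range(1, n + 1) if i not in emitted]
            for pid in untouched:
                recurse(buf, emitted + (pid,), ops + (1,), w / len(untouched), reversed_cs)
            return
        if architecture == QUEUE and grammar.condition == CENTER_EMBEDDED:
            recurse(buf[:-1], emitted + (buf[-1],), ops + (len(buf),), w, reversed_cs)
        elif architecture == QUEUE and grammar.condition == CROSS_SERIAL:
            recurse(buf[1:], emitted + (buf[0],), ops + (1,), w, reversed_cs)
        elif architecture == STACK and grammar.condition == CENTER_EMBEDDED:
            recurse(buf[:-1], emitted + (buf[-1],), ops + (1,), w, reversed_cs)
        else:  # stack + cross-serial
            if not reversed_cs:
                rev = buf[::-1]
                recurse(rev[:-1], emitted + (rev[-1],), ops + (len(buf) + 1,), w, True)
            else:
                recurse(buf[:-1], emitted + (buf[-1],), ops + (1,), w, True)

    recurse(buf, (), (), 1.0, False)
    return outcomes


def _enum_program_sequences(
    program: str, grammar: GrammarSpec, architecture: str, p_mem: float
) -> list[tuple[float, tuple, tuple]]:
    """All (weight, touches, ops) complete sequences under one program."""
    import itertools

    n = grammar.n_pairs
    items = grammar.items
    out: list[tuple[float, tuple, tuple]] = []
    if program == PROGRAM_LAPSE:
        w = (1.0 / (2 * n)) ** (2 * n)
        for seq in itertools.product(items, repeat=2 * n):
            out.append((w, tuple(seq), (1,) * (2 * n)))
        return out
    perm_w = 1.0 / math.factorial(n)
    for a_order in itertools.permutations(range(1, n + 1)):
        a_touches = tuple(ItemToken(i, "A") for i in a_order)
        if program == PROGRAM_BLUE_THEN_RED:
            for b_order in itertools.permutations(range(1, n + 1)):
                touches = a_touches + tuple(B(i) for i in b_order)
                out.append((perm_w * perm_w, touches, (1,) * (2 * n)))
        else:
            for buf, w_buf in _enum_store_states(list(a_order), p_mem).items():
                for w_ret, emitted, ops in _enum_retrievals(buf, grammar, architecture):
                    touches = a_touches + tuple(B(i) for i in emitted)
                    out.append((perm_w * w_buf * w_ret, touches, (1,) * n + ops))
    return out


def exact_response_distribution(
    trial_prefix: list[ItemToken],
    params: ModelParams,
    architecture: str,
    grammar: GrammarSpec,
    trial_index: float,
) -> ResponseDistribution:
    """Brute-force next-touch distribution by summing over all latent outcomes.

    Supported for n_pairs <= 2 only; serves as the independent oracle for the
    Monte Carlo estimator.
    """
    n = grammar.n_pairs
    if n > 2:
        raise ValueError("exact enumeration supported for n_pairs <= 2 only")
    prefix = tuple(trial_prefix)
    if len(prefix) >= 2 * n:
        raise ValueError("prefix is already a complete trial")
    items = grammar.items
    prior = program_weights(trial_index, params)
    probs = np.zeros(len(items))
    ops_acc: dict[ItemToken, dict[int, float]] = {it: {} for it in items}
    pos = len(prefix)
    for program, w_prog in prior.items():
        if w_prog <= 0:
            continue
        for w, touches, ops in _enum_program_sequences(program, grammar, architecture, params.p_mem):
            if touches[:pos] != prefix:
                continue
            mass = w_prog * w
            it = touches[pos]
            probs[items.index(it)] += mass
            ops_acc[it][ops[pos]] = ops_acc[it].get(ops[pos], 0.0) + mass
    z = probs.sum()
    if z <= 0:
        raise ValueError("prefix has zero probability under these parameters")
    probs = probs / z
    mixture = {}
    for it in items:
        total = sum(ops_acc[it].values())
        mixture[it] = (
            {o: v / total for o, v in ops_acc[it].items()} if total > 0 else {1: 1.0}
        )
    return ResponseDistribution(items=items, probs=probs, ops_mixture=mixture)


# ---------------------------------------------------------------------------
# error-source decomposition
# ---------------------------------------------------------------------------

ERROR_SOURCES = ("wrong_program", "memory", "lapse")


def _source_params(params: ModelParams, source: str) -> ModelParams:
    """Parameters with only one error source enabled."""
    if source == "wrong_program":
        return params.with_(p_mem=0.0, p_lapse=0.0)
    if source == "memory":
        return params.with_(p_lapse=0.0, gompertz_a=1.0, gompertz_b=0.0)
    if source == "lapse":
        return params.with_(p_mem=0.0, gompertz_a=1.0, gompertz_b=0.0)
    raise ValueError(f"unknown error source {source!r}")


def decompose_errors(
    fit: FitResult,
    design,
    M: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-trial error rates attributable to each source, by array length.

    For each source, the fitted generative model is re-simulated over the
    design's training schedule with the other two sources switched off; the
    per-trial error rate is the fraction of simulated training trials ending
    in an error.  Returns one row per length with columns
    rate_wrong_program, rate_memory, rate_lapse.
    """
    params = fit.params_hat
    rows = []
    for source in ERROR_SOURCES:
        sp = _source_params(params, source)
        t_clock = 0
        for n in design.lengths:
            grammar = GrammarSpec(design.condition, n)
            n_train = design.training_trials_per_length[n]
            reps = max(1, M // n_train)
            errors = 0
            total = 0
            for i in range(n_train):
                for _ in range(reps):
                    tr = simulate_trial(
                        grammar, fit.architecture, sp, t_clock + i, feedback=True, rng=rng
                    )
                    errors += tr.first_error_index is not None
                    total += 1
            t_clock += n_train
            rows.append(
                {
                    "condition": design.condition,
                    "n_pairs": n,
                    "source": source,
                    "rate": errors / total,
                }
            )
    wide = (
        pd.DataFrame(rows)
        .pivot(index=["condition", "n_pairs"], columns="source", values="rate")
        .reset_index()
    )
    wide.columns.name = None
    return wide.rename(
        columns={
            "wrong_program": "rate_wrong_program",
            "memory": "rate_memory",
            "lapse": "rate_lapse",
        }
    )
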