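# Methods

## The task and the two memory architectures

The modeled task is production of indexed AⁿBⁿ sequences: an array shows n
paired items, n "blue" A items and n "red" B items, one pair per shape.  A
correct sequence touches all A items first (in any order) and then the B
items in an order fixed by the grammar — reversed A order in the
center-embedded (CE) condition (A₁A₂A₃B₃B₂B₁, nested like brackets), repeated
A order in the cross-serial (CS) condition (A₁A₂A₃B₁B₂B₃).  Either grammar
licenses exactly n! complete sequences, which gives the analytic baselines:
random responding succeeds with probability n!/(2n)! (8.3% at 4 items, 0.8%
at 6), and the partial "blue then red" strategy with probability 1/n! (50%,
17%, 4% at 4/6/8 items).

Producing a sequence requires holding the chosen A order in working memory.
Two buffer architectures are compared, distinguished by their per-touch
operation counts:

| architecture × grammar | second-half op counts (n pairs) |
| --- | --- |
| stack + CE | 1, 1, …, 1 (pop each item off the top) |
| stack + CS | n+1, 1, …, 1 (reverse onto a second stack once, then pop) |
| queue + CE | n, n−1, …, 1 (iterative search from the front) |
| queue + CS | 1, 1, …, 1 (read off the front) |

Every architecture stores each A touch with a single operation.  The
decreasing queue/CE schedule is the discriminating signature: response times
that scale with op count fall linearly over the second half of CE sequences
if and only if the producer is traversing a queue.

## The generative trial model

Each trial runs one of three latent programs:

* **correct** (probability g(t) after lapse exclusion): draws a uniformly
  random A order, stores it in the buffer, and retrieves the B half through
  the architecture;
* **blue-then-red** (probability 1−g(t)): uniformly random orders within each
  half, no pair matching, no buffer engagement (one op per touch);
* **lapse** (probability p_lapse, drawn first): every touch uniform over all
  2n displayed items, repeats allowed (items remain selectable).

g(t) = A·exp(−B·exp(−C·t)) is a Gompertz learning curve in t, the cumulative
count of feedback training trials across array sizes.  A single curve per
participant (rather than one per length) keeps the per-participant parameter
count at eight; per-length displays are produced by slicing the curve over
each length's training window.

Memory noise: each store corrupts the buffer with probability p_mem, the
corruption being equiprobably a **swap** (transpose the just-stored item with
its immediate predecessor — the local-transposition convention of
serial-recall modeling; a no-op on a singleton buffer) or a **deletion** (one
uniformly chosen stored item is removed).  A buffer exhausted by deletions
yields a uniform guess among untouched items at one op, so deletions produce
omission-like errors rather than dead ends.  Corruption strikes at storage
only, not at retrieval.  One consequence worth noting: because store counts
are equal across grammars, queue-based CE and CS production err at similar
rates, and the deletion-recovery asymmetry of the fallback (a deleted
first-stored item is harmless for CE, a deleted last-stored item for CS) can
even make CS slightly more error-prone at equal p_mem.  Condition differences
in overall accuracy are carried chiefly by the learning curve, not the noise
mechanism.

Response times are lognormal with median linear in op count:
rt = (t_base + t_op·ops)·exp(ε), ε ~ N(0, σ_rt²).  This form has positive
support, right skew, and two interpretable location parameters; t_base
absorbs perceptual/motor time, t_op is the per-operation latency that turns
op schedules into RT profiles.  The interval between the last A and the
first B is generated like any other touch; the behavioral RT-profile
analysis excludes it downstream (it can reflect a half-switch cost), and the
likelihood retains it.

Feedback (training) trials end at the first ungrammatical touch; test trials
always run to completion.

### Parameters

| name | meaning | units | default / recovery range |
| --- | --- | --- | --- |
| p_mem | corruption probability per store | — | U(0.02, 0.15) |
| p_lapse | probability a trial is random responding | — | U(0, 0.1) |
| gompertz A | asymptotic P(correct program) | — | U(0.6, 1) |
| gompertz B | learning-curve displacement | — | U(0.5, 5) |
| gompertz C | learning rate | 1/trial | U(0.05, 0.5) |
| t_base | base latency per touch | ms | U(200, 600) |
| t_op | latency per memory operation | ms | U(50, 300) |
| σ_rt | log-space RT noise sd | — | U(0.1, 0.4) |

The recovery ranges are generator settings chosen to yield accuracy and RT
magnitudes in the realistic regime of adult touchscreen performance (median
inter-touch RTs roughly 0.3–1.5 s, training error rates roughly 10–50%);
both models have the same eight free parameters, so AIC differences reduce
to likelihood differences.

## Synthetic cohorts

The generator emulates the further-training phase: for each array size in
(4, 6, 8 items), five unreinforced test trials then 20/40/40 error-corrected
training trials, 20 participants per cohort in the recovery studies (the
emulated study assigned 50 per condition; 20 keeps the fitting studies
desk-sized while leaving binomial error well below the effects tested).
Ground-truth parameters and latent program labels are recorded per
participant.  Not emulated: the initial criterion-training and
novel-combination phases (the model is fit only to further-training trials),
spatial array geometry and the initial array-scan latency (observed in the
motivating data but predicted by neither architecture), the 2-s error
timeout, and any participant-level drift in parameters across the session.
Passing tests therefore certify the inference machinery on data generated by
the model's own assumptions — they do not certify those assumptions against
real behavior.

## Likelihood, fitting, model comparison

The likelihood of a training trial is a three-program mixture; each program
term is a product over touches of P(item | prefix, program) ×
f(rt | item, program).  Lapse and blue-then-red terms are analytic.  For the
correct program, the observed A touches pin down the stores, so corruption
history is marginalized by forward-simulating M particle buffers (default
M = 5,000; 100,000 available via configuration) and filtering on the
observed B touches; item probabilities are surviving-particle fractions with
additive smoothing ε = 1/(M+2n) (preventing −∞ log-likelihoods), and RT
densities are lognormal mixtures over the op counts the surviving particles
incurred.  A brute-force enumeration over all latent outcomes (programs ×
corruption events × fallback draws), feasible at n ≤ 2, provides the
independent oracle against which the Monte Carlo estimator is tested.

Fitting maximizes the summed trial log-likelihood per participant.  Since
only p_mem affects the particle simulation, it is profiled over a fixed grid
(0 to 0.24 in steps of 0.02); at each grid value the remaining seven
parameters are maximized by bounded Nelder–Mead, with five Latin-hypercube
starts at the first grid value and warm starts plus one fresh start
thereafter.  The particle generator is reseeded identically at every p_mem
value (common random numbers), making the likelihood surface — and hence the
whole fit — a deterministic function of data and configuration.  The profile
grid quantizes fitted p_mem to ±0.01, well inside the recovery tolerance.
AIC = 2·8 − 2·logL; ΔAIC = AIC(queue) − AIC(stack), negative favoring the
queue.

Error decomposition re-simulates the training schedule at the fitted
parameters with one error source enabled at a time (the other two switched
off: p_mem = 0, p_lapse = 0, or g ≡ 1 as appropriate), reporting per-trial
error rates per array size.  This generative source-switching matches how
the three error modes are defined; it is not an additive decomposition of
the observed error rate (sources interact mildly when combined).

## Numerical choices and degenerate inputs

* Smoothing ε = 1/(M+2n) floors every item probability; exact enumeration is
  left unsmoothed (the difference is ≪ the MC tolerance at M ≥ 10⁴).
* Inner-optimization bounds: p_lapse ∈ [10⁻⁴, 0.5], A ∈ [0.05, 1],
  B ∈ [0, 8], C ∈ [0.005, 1], t_base ∈ [50, 1500] ms, t_op ∈ [0, 600] ms,
  σ_rt ∈ [0.02, 1.5].
* A prefix impossible under every program (possible only at degenerate
  parameter settings) makes the MC response distribution fall back to
  uniform over programs rather than raising mid-optimization.
* Ties across multi-starts resolve to the first start evaluated; the p_mem
  grid is scanned in increasing order.
* Pair relabeling leaves the likelihood estimand invariant; the MC estimate
  matches across relabelings only up to the sampling error of the
  exhausted-buffer fallback draws.

## Known limitations

* The RT likelihood treats op-count mixtures per touch independently given
  the item prefix; within-trial correlation of corruption histories across
  touches is captured for item choices but not propagated into joint RT
  dependence.
* The stack/CS reversal is costed once (one op per transferred item plus the
  pop) at the first B touch; re-reversal accounting would change the CS
  first-touch prediction.
* Whole-list / content-addressable architectures, which also predict flat CE
  profiles, are outside the model space; the comparison is strictly stack vs
  queue.
* Fitted group-level ΔAIC magnitudes and error rates depend on the data they
  are fit to; on synthetic cohorts only the qualitative contrasts (sign of
  ΔAIC, growth of memory errors with array size, slope orderings) are
  meaningful.
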