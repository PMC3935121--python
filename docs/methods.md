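# Methods

This note records the modelling and numerical choices behind the package:
the learner, the evaluation protocol, the synthetic data generator, and the
problem sizes used by the test suite and `scripts/acceptance.py`.

## The learner

**Incremental ridge regression.** The state consists of the inverse
regularized covariance `A⁻¹` (D×D), the output accumulator `β = ZᵀY` (D×p)
and the weights `w = A⁻¹β`. Initialization is `A⁻¹ = λ⁻¹I`, `β = w = 0`,
which makes the fresh model predict zero. Each sample performs the
Sherman–Morrison rank-1 update

```
A⁻¹ ← A⁻¹ − (A⁻¹ z zᵀ A⁻¹) / (1 + zᵀ A⁻¹ z)
```

followed by `β ← β + z yᵀ` and a recomputation of `w`. After m updates the
state equals the closed-form batch solution `(λI + ZᵀZ)⁻¹ZᵀY` on the same
samples, in any order; the test suite asserts this to 1e-8 relative after
every prefix of a 200-sample stream. Assumptions: squared-error loss, no
forgetting (all updates accumulate forever — there is no decay factor), and
homogeneous features (no intercept inside the learner; the evaluation
harness centres training outputs instead).

Two numerical choices are ours, as the update recursion itself does not
prescribe them:

* **Re-symmetrization.** Floating-point drift can make `A⁻¹` slightly
  asymmetric over long streams; every 1000 rank-1 updates the state is
  projected back with `(A⁻¹ + A⁻ᵀ)/2`. Measured asymmetry stays below
  1e-8 after 10⁴ updates.
* **Weight recomputation.** `update()` recomputes `w = A⁻¹β` after every
  sample (O(D²p)), the literal per-sample recursion; a `weight_mode="lazy"`
  option defers the product until the next prediction, which is
  mathematically identical and cheaper on long update streams. A block
  variant `update_many()` applies the Woodbury identity (the k-sample
  generalization of Sherman–Morrison) and is what the evaluation harness
  uses; equivalence with the sequential form is tested to 1e-8.

**Random Fourier features.** `z(x) = √(2/D)·cos(Ωx + b)` with
`Ω ~ N(0, 2γ)` per entry and `b ~ U[0, 2π)`. The √(2/D) factor is applied
once outside the cosine; this is algebraically identical to scaling each
feature by √2 and averaging D of them, and the inner product `z(x)ᵀz(y)`
is an unbiased estimate of `exp(−γ‖x−y‖²)` (tested by Monte-Carlo with
3-standard-error bands). Maps are frozen at construction and bit-reproducible
from `(n, D, γ, seed)`.

**Baselines.** Exact linear ridge (capacity baseline) and exact RBF kernel
ridge regression in dual form, `(K + λI)C = Y` via Cholesky (accuracy
oracle). KRR deliberately refuses incremental updates: its per-update cost
grows with the training set, which is the problem the random-feature
approximation removes.

**Hyper-parameters.** λ > 0 trades data fit against shrinkage; γ > 0 is the
RBF bandwidth (large γ = short length scale). The grid search is
leave-one-trial-out over the training trials on a 2-power grid
(λ ∈ 2⁻¹²…2⁵, γ ∈ 2⁻⁸…2⁷, 288 pairs), with windows subsampled by 4 during
the search only; ties break toward larger λ, then smaller γ (prefer the
smoother model), deterministically. D needs no tuning — accuracy increases
monotonically with D — so it is set by the compute budget (1000 for
offline evaluation, 300 for the low-latency preset, which also uses fixed
λ = 1.0, γ = 2.47 and no windowing). The evaluation runs in the tests and
the acceptance script use the fixed preset values λ = 1.0, γ = 2.47, which
sit in the optimal region for the synthetic data's feature scale; running
the full 288-pair search inside every replicate would dominate the run
time without changing the qualitative comparisons, and the grid machinery
is exercised separately against a brute-force oracle.

## Evaluation protocol

Trials are strictly chronological; the harness asserts that every scored
trial comes after all trials its model was trained on. Settings:

* **batch**: train on session 1 trials 1–3; optionally retrain from
  scratch on trials 1–3 of each session (12 training trials).
* **incremental**: initial batch as above, then one `update_many` on the
  first and tenth trial of every session (3 + 1 + 3·2 = 10 training
  trials, 62 scored).
* **realistic 1/2**: the incremental schedule with training targets taken
  from the stimulus (graded) or from the stimulus thresholded at 50% MVC
  to {0, plateau}; scoring always uses measured force.

The intercept (training-output mean) is estimated once from the initial
three trials and held fixed across incremental updates — re-centring
mid-stream would retroactively change the meaning of earlier updates.
Hyper-parameters are likewise never re-tuned at update trials. nMSE is
normalized by the per-subject, per-DOF force variance over *all* trials
(population variance, ddof = 0), so the constant-mean predictor scores
exactly 1.0. If a scored trial yields a constant prediction its Pearson
correlation is undefined; it is recorded as missing and excluded from
averages. Multi-run aggregates vary only the feature-map seed on fixed
data, mirroring how randomized initializations are averaged in practice;
the acceptance checks additionally vary the synthetic subject per
replicate.

## Synthetic data generator

The generator emulates the structure of the multi-day recording protocol,
not the physiology of EMG. Per trial, the five fingers are activated in
sequence (thumb first): a sin²-shaped ("square-sinusoidal") onset ramp to
an 80% MVC plateau held for 1.5/3/4.5 s (chosen per activation), a
symmetric offset ramp, and a rest between activations. At most one finger
is non-zero at any sample, which is what makes a single force sensor
sufficient in the real protocol. Defaults: 10 channels, 5 DOFs, 4 sessions
× 18 trials (90 activations/session), 100 Hz, day boundary after session
2. MVC is fixed at 1.0 per finger, so forces and stimuli are fractions of
MVC and the 50%-MVC threshold and 80% plateau are exact.

**Force.** Subjects track the stimulus open-loop (their own force is not
displayed), so each activation's realized plateau amplitude differs from
the 0.8 target: it is drawn from a normal distribution centred on the
middle of the configured inconsistency band (default 0.4–1.0 MVC) with SD
one fifth of the band, clipped to the band — typical activations land
mid-band, occasional ones reach the extremes, covering the stated
~40–100% MVC spread over a session. A smooth tracking error (Gaussian
white noise smoothed with σ = 250 ms, scaled by the activation envelope,
SD 0.03 MVC) and small sensor noise (SD 0.005) are added; force is zero at
rest up to noise. We initially drew amplitudes uniformly over the full
band; that extreme reading makes the graded stimulus as poor a magnitude
surrogate as the binary one and suppresses the expected separation between
the two realistic settings, so the clipped-normal draw is the package's
default.

**EMG.** `emg = g(t) ⊙ [M_day · h(f)] + noise`, where

* `h(f) = (1+k)·f^0.6/(f^0.6 + k)` (k = 0.3) is a monotone saturating
  force→activation map; it breaks the linear RMS–force relationship so the
  linear baseline is structurally mis-specified (any monotone saturating
  map would do; this one is smooth, concave, and pins h(0)=0, h(1)=1);
* `M` (channels × DOFs, non-negative) maps finger activations to
  electrodes as Gaussian bumps over the array plus a uniform cross-talk
  floor (0.08), so every finger drives ≥ 2 channels and every channel
  hears ≥ 1 finger; `M_day` multiplies each entry by
  `exp(σ_shift·N(0,1))` once per day from day 2 on (σ_shift = 0.35),
  modelling electrode repositioning;
* `g(t) = 1 + a_c·exp(−t/τ)` is a per-channel warm-up gain with τ = 300 s
  and `a_c ~ U(−0.3, 0.3)`, active in the first session of each day
  (electrode–skin temperature adaptation);
* noise is multiplicative log-normal (σ = 0.1) where the signal is active
  plus a folded-normal floor (σ = 0.01), keeping the envelope non-negative
  without clipping artifacts.

No measured drift magnitudes exist for this protocol; σ_shift, the drift
amplitude and τ are set to reproduce the *qualitative* degradation
patterns (frozen model decays across sessions, worst after the day
boundary; updates recover it; linear trails non-linear) and are plainly
configurable. What the generator does **not** emulate: motor-unit action
potentials or raw (unrectified) EMG, reaction-time lag between stimulus
and force, fatigue accumulation across a session, inter-subject anatomy
differences. Passing tests therefore demonstrate correctness of the
algorithms and protocols and qualitative robustness to the modelled
nonstationarities — not performance figures transferable to human
recordings, whose absolute errors are substantially larger.

Randomness: one master seed fans out through `numpy.random.SeedSequence`
spawning to per-trial data streams, the per-day mixing perturbation and
per-session drift amplitudes; datasets are bit-identical under the same
seed. In the evaluation harness a run seed fans out to one feature-map
seed per run the same way.

## Problem sizes in tests and the acceptance script

Full-resolution evaluation (window increment 1) produces ~4 000 windows
per trial; the qualitative comparisons are unchanged at increment 4, which
the end-to-end tests and the acceptance script use, together with D = 1000
features and the standard 4 × 18 layout. Distributional claims
("in ≥ 20 of 25 replicates", medians) use 25 seeded synthetic subjects in
the test suite; the acceptance script reports means over 5 subjects and
median KRR-gap over 25 feature maps. The convergence check trains on
three trials (increment 8) of a single session so exact KRR stays cheap.

## Degenerate inputs and edge cases

D = 1 and p = 1 work (used in hand-computed tests); a fresh model predicts
zeros rather than erroring; recordings shorter than one window raise a
specific error; a DOF with zero force variance raises rather than
silently producing infinite nMSE; non-finite update samples are rejected.
Sessions need at least 4 trials to split into training and test. Model
archives and HDF5 datasets carry a format-version field and round-trip
bit-exactly; CSV interchange is validated column-by-column with named
errors and round-trips to ~6 significant digits.

## Known limitations

* No forgetting: after a large distribution shift the accumulated old
  covariance slows (but does not prevent) adaptation; a decay factor is
  deliberately out of scope.
* The per-sample `update()` with literal weight recomputation costs
  O(D²p) per sample; use `update_many`/lazy weights for long streams.
* Exact KRR is O(m³) in training samples and is intended as an oracle on
  modest m, not as a practical learner here.
* Synthetic-data absolute performance is optimistic relative to human
  recordings (see above); only qualitative orderings should be read from
  it.
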