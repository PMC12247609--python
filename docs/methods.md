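# Methods

## The question being simulated

Small-sample face-recognition experiments report the rate at which
structural MRI scans can be matched to subjects' photographs when the
candidate set is the study sample itself (N = 157): roughly 10% for
defaced scans and 38% for "refaced" scans whose facial structure was
imputed from a population-average template. The threat model of
interest here is the harder *sample-to-population* attack: the
adversary holds reference photographs for everyone in the surrounding
population who matches the demographics released with the data (age
band, gender, race/ethnicity) and must pick the right person out of
that pool. The alternative scenario — the attacker already suspects a
specific individual and only needs to confirm membership — is a
different and easier problem whose effective pool is the dataset size;
it is documented here as out of the simulation's scope.

`reidsim` asks how the published small-sample match rates extrapolate
to candidate pools of realistic, census-derived size.

## Generative model

* Each enrolled individual is a vector of `d = 1000` iid standard-normal
  features. No claim is made that real face-embedding coordinates are
  Gaussian or independent; the model captures the one mechanism that
  drives the pool-size effect — a fixed per-probe signal-to-noise ratio
  confronted with an increasing number of independent distractors.
* The attacker's probe for individual `i` is `p_i = x_i + σ z`, with
  `z` iid standard normal. The source experiments say only that test
  data were perturbed with random noise; iid additive Gaussian with a
  single scalar σ is the minimal model consistent with a Gaussian
  feature space and a scalar calibration target.
* Feature location and scale are fixed at 0 and 1. This loses no
  generality: identification decisions are invariant to scaling
  features and noise together (asserted in the test suite), so only
  σ relative to unit feature variance matters.
* Identification is exact 1-nearest-neighbour under squared Euclidean
  distance — monotone-equivalent to Euclidean — with ties broken to the
  lowest gallery index. Rank-1 accuracy is the fraction of probes whose
  nearest row is their source.

## Random-number discipline

Every gallery row and every probe's noise vector has its own
counter-based (Philox) stream keyed by `(seed, stream tag, row)`.
Consequences, all tested:

* identical configs give bit-identical galleries;
* generating rows in any chunking is bit-identical to one-shot
  generation, so galleries of 865,000 x 1,000 can be streamed and
  regenerated on demand rather than stored;
* probe noise is independent of gallery draws even under the same user
  seed;
* galleries at different pool sizes are fresh draws by default (the
  sweep derives a per-size seed); a `nested=True` flag instead reuses
  one stream so that smaller pools are strict prefixes of larger ones.
  Fresh-vs-nested is statistically exchangeable here; fresh is the
  default because it makes rows independent across sizes.

## Matcher numerics

The gallery is scanned in row chunks (default 16,384 rows) against
probe blocks, accumulating each probe's two best candidates by the
surrogate score `||g||² − 2·p·g` (the probe's own norm is constant per
probe and dropped). For problems above 5×10⁷ probe-gallery pairs the
scan runs in float32, which is severalfold faster than float64 for
single-threaded GEMM; the winner between each probe's two retained
candidates is then always re-decided with exact float64 distances,
which also applies the lowest-index tie rule deterministically. The
residual failure mode — the true argmin ranked below second by
float32 rounding — requires score margins at the float32 precision
floor, orders of magnitude below the margins that occur with
continuous Gaussian data; the test suite forces the float32 path on
small instances and checks exact agreement with a naive double-loop
brute-force matcher, which exists solely as an independent oracle.

Accuracy estimates carry 95% Wilson score intervals
(statsmodels' implementation, cross-checked against the closed form in
the tests), and zero-success rows also report the rule-of-three bound
3/n.

## Calibration

`calibrate_noise` bisects σ. All evaluations share one reference
gallery (157 x 1000) and one pre-drawn noise bank scaled by σ (common
random numbers), which makes empirical accuracy an exactly
non-increasing step function of σ — bisection therefore converges
without stochastic flutter. The noise bank probes every reference
individual in whole replicates, sized so the binomial standard error
is below half the accuracy tolerance (default tolerance 0.005,
i.e. ~38,000 probes for the 0.38 anchor). The bracket is verified
first and the upper bound expanded geometrically if needed;
convergence requires both a narrow σ interval (10⁻⁴ relative) and an
evaluated accuracy within tolerance. The reported `achieved` accuracy
is re-measured with an independent noise bank, so it is an honest
estimate rather than the optimisation's own objective.

The calibrated σ is a property of the run's reference gallery: at
P = 157 the gallery-to-gallery spread of accuracy at fixed σ is of
order one percentage point, the same order as the difference between
the published anchor (38%) and the published measured value (37.6%).
The sweep results inherit this spread; the acceptance comparisons use
sampling-error tolerances accordingly.

## Probe budgets

The number of evaluated probes per pool size is a reporting decision,
not part of the model. Defaults: pools up to 10,000 probe every
individual, in whole replicates until at least 10,000 probes are spent
(a single pass over 157 individuals would leave ~4-point noise);
larger pools use a seeded subsample without replacement, sized to
target ≥ 20 expected successes. The pilot accuracy for that sizing
comes from the semi-analytic oracle below, which costs nothing; a
policy variant (`empirical-pilot`) runs a small pilot match instead.
Budgets are recorded in every output row. The desk-scale runs in
`analysis/` and `scripts/acceptance.py` use explicit overrides
(6,000–20,000 probes at the census-scale pools) chosen to keep a full
two-condition study around ten minutes on one CPU core; the low-SNR
condition at 423,000 and 865,000 (published ≈ 0.05% and 0.03%) would
need several hundred thousand probes for a useful direct estimate and
is instead covered by the oracle, which matches those
one-significant-figure values within their rounding.

## Semi-analytic expected accuracy

For a probe `p = x + σz`, writing `u = ||z||²` (χ²_d) and
`c = x + σz`, `m = ||c||²`:

* self-distance `s0 = σ²u`;
* given `c`, each distractor's squared distance is noncentral
  χ²_d with noncentrality `m`, and distractors are conditionally
  independent given `c`;
* given `u`, `m` is noncentral χ²_d with noncentrality `σ²u`,
  approximated by a normal with its exact first two moments (the only
  approximation; it needs d ≳ 50, enforced as a floor).

Expected accuracy is `E[ P(distractor farther | c)^(P−1) ]`, integrated
over a 200-point equal-probability χ² grid in `u` and 40 Gauss–Hermite
nodes in `m`. For very large noncentrality the exact ncx2 CDF is
replaced by its CLT normal limit (scipy's series are impractically
slow there; the relative error is negligible). Validation, run in the
test suite before the oracle is trusted anywhere: agreement with
brute-force Monte Carlo within two standard errors over
P ∈ {10, 100, 1000} × σ ∈ {13.5, 25.1} with the Monte-Carlo error
budget including gallery-to-gallery variance; measured bias is ~0.003
absolute at worst. Limits checked exactly: accuracy → 1 as σ → 0 or
P → 1, and → 1/P as σ → ∞.

## Scaling fit

`fit_loglog` is ordinary least squares of log accuracy on log pool
size over rows with at least one success (zero-success rows carry no
usable log value and are excluded). The published claim is only
qualitative — approximately linear in log-log coordinates — so the
acceptance property is a negative slope with R² ≥ 0.95. On simulated
sweeps the local slope steepens slowly with pool size (from ≈ −0.40
between 157 and 6,500 toward ≈ −0.57 at the census scale in the
high-SNR condition), so the power law is an excellent summary but not
an exact law; R² typically exceeds 0.99.

## Pool calculator

Candidate pools are `base population × stratum fraction`, with an
explicit rounding rule (`nearest-1000`, `nearest-5000`, or none)
recorded alongside the exact product, because published figures mix
granularities. Fractions are inputs from a CSV; the packaged example
table carries the Pittsburgh-area values (base 2,349,172; 36.8% adults
20–49 → 865,000 at nearest-5,000; 18% female 20–49 → 423,000 at
nearest-1,000). One published inconsistency is preserved rather than
resolved: the "female 25–29" stratum is printed as 3.2% *and* as a
pool of roughly 70,000, but 0.032 × 2,349,172 = 75,174. The sweep
ladder uses the published 70,000 as a direct input (like 6,500, which
has no printed fraction at all), and `analysis/01_pool_sizes.py`
records both numbers.

## What the synthetic data does and does not show

The generator emulates the *structure* the simulation needs — a
homogeneous population in a high-dimensional feature space with
calibrated probe noise — and its accuracy-vs-pool-size curve is exact
for that model. Real face-recognition scores are not iid Gaussian:
embeddings are anisotropic and clustered (demographic structure,
family resemblance), match quality varies across subjects
(image quality, acquisition), and an attacker's reference set has
coverage gaps. Passing tests therefore validate the computational
pipeline and the model's internal predictions — most importantly the
robust qualitative finding that rank-1 accuracy falls roughly as a
power of the pool size — not the exact real-world match rates at any
given pool size. Heterogeneous per-subject identifiability would
fatten the high-accuracy tail and slow the decay; that regime is
outside this model.

## Known limitations

* Top-1 accuracy only; rank-k match rates are not part of the core
  surface.
* No approximate nearest-neighbour indexing; exactness is part of the
  contract, so very large galleries pay a full linear scan.
* The calibrated σ inherits the reference gallery's realisation
  (~1-point spread at P = 157), which propagates as a few-percent
  relative uncertainty at census-scale pools.
* The membership-confirmation threat model and real-embedding
  calibration are documented but not simulated.
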