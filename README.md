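# reidsim

How quickly does the risk of reidentifying a participant from shared,
"deidentified" neuroimaging data fall as the pool of potential matches
grows from a study sample to a realistic population?

Published face-recognition experiments show that structural MRI can be
matched to a subject's photograph at worrying rates when the candidate
set is a study sample of 157 people — about 10% for defaced images and
38% for refaced images (defaced scans whose facial structure was
imputed from a population-average template). But a real attacker who
does not already know who is in the study must search everyone in the
surrounding population who fits the demographics shared with the data.
`reidsim` simulates that regime: it models identification as
nearest-neighbour matching in a high-dimensional Gaussian feature
space, calibrates the noise level to the published small-sample match
rates, and measures how rank-1 accuracy decays as the gallery grows to
census-derived candidate pools of up to 865,000 people.

This is a simulation study, aimed at researchers and data stewards
reasoning about privacy risk of openly shared imaging data — not a
face-recognition system.

## Model

* **Population.** Each of `P` individuals is a feature vector
  `x_i ~ N(0, I_d)` with `d = 1000`.
* **Probe.** The attacker's query for individual `i` is
  `p_i = x_i + σ z`, `z ~ N(0, I_d)`. Only the noise-to-signal ratio
  matters, so the feature scale is fixed and `σ` carries the condition.
* **Matching.** A probe is identified when its nearest gallery row
  (squared Euclidean distance, exact argmin, ties to the lowest index)
  is its source: rank-1 identification accuracy.
* **Calibration.** `σ` is bisected (common random numbers, monotone
  accuracy) until accuracy at the reference pool size `P = 157` equals
  the published anchor: 0.38 (high SNR, "refaced") or 0.10 (low SNR,
  "defaced").
* **Pool sizes.** Candidate pools come from census strata:
  `pool = base population × stratum fraction`, e.g.
  2,349,172 × 18% ≈ 423,000 (females aged 20–49, Pittsburgh
  metropolitan area).
* **Scaling law.** Accuracy vs `P` is summarised by an OLS fit of
  `log(accuracy)` on `log(P)`; a semi-analytic oracle computes expected
  accuracy by low-dimensional numerical integration without simulation.

## Worked example

```python
import reidsim as rs

# calibrate the high-SNR ("refaced") condition to its 38% anchor at P=157
cal = rs.calibrate_noise(rs.CalibrationSpec(target_accuracy=0.38, seed=11))
print(f"sigma* = {cal.sigma_star:.3f}, achieved = {100*cal.achieved.accuracy:.1f}%")

# sweep accuracy over the candidate-pool ladder
spec = rs.SweepSpec(
    population_sizes=(157, 6500, 70_000),
    sigma=cal.sigma_star, seed=11, label="high-SNR",
)
result = rs.run_sweep(spec)
for row in result.rows:
    print(f"P={row.gallery_size:>6,}: {100*row.accuracy:5.2f}% "
          f"(95% CI {100*row.ci_low:.2f}-{100*row.ci_high:.2f})")

fit = rs.fit_loglog(result)
print(f"accuracy ~ P^{fit.slope:.2f}, R^2 = {fit.r_squared:.3f}")
```

prints

```
sigma* = 13.576, achieved = 38.0%
P=   157: 37.89% (95% CI 36.94-38.84)
P= 6,500:  8.56% (95% CI 8.09-9.05)
P=70,000:  3.05% (95% CI 2.38-3.90)
accuracy ~ P^-0.41, R^2 = 0.999
```

— with one in 157 candidates the attacker succeeds for roughly two in
five probes, but against the 70,000-strong demographic stratum only
about three in a hundred probes are matched, and the decay continues
as a near power law toward census-scale pools.

The same pipeline is available from the shell (`reidsim calibrate`,
`reidsim sweep`, `reidsim pool`), and the `analysis/` scripts run the
full study: `01_pool_sizes.py` (census arithmetic), `02_calibrate_noise.py`
(both anchors), `03_accuracy_sweep.py` (the accuracy ladder),
`04_scaling_fit.py` (power-law fit and the semi-analytic tail), writing
tables under `results/`.

## Layout

* `src/reidsim/population.py` — keyed-stream Gaussian gallery and probe generator
* `src/reidsim/matching.py` — chunked exact 1-NN matcher, brute-force oracle, Wilson accuracy estimates
* `src/reidsim/calibration.py` — stochastic bisection of σ against an anchor
* `src/reidsim/scaling.py` — sweeps, log-log fit, semi-analytic oracle, probe-budget policy
* `src/reidsim/pools.py` — census-stratum pool calculator (packaged example table)
* `docs/methods.md` — model details, assumptions, numerics, limitations
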