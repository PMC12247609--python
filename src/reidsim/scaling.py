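"""Accuracy-vs-population-size sweeps, the log-log scaling fit, and a
semi-analytic expected-accuracy oracle.

The central empirical claim being simulated is that rank-1
identification accuracy decays with the size of the candidate pool —
from the study-sample scale (157) up to census-derived pools (865,000)
— roughly as a power law, i.e. approximately linearly in log-log
coordinates.

The semi-analytic oracle computes the same expected accuracy without
simulation.  Under the Gaussian population/noise model a probe is
``p = x + sigma z`` with ``x, z ~ N(0, I_d)``.  Writing ``u = ||z||^2``
(chi-square, d dof):

* the probe's distance to its own gallery row is ``s0 = sigma^2 u``;
* given the probe location ``c = x + sigma z`` with ``m = ||c||^2``,
  each distractor's distance is noncentral chi-square ``chi'^2_d(m)``;
* given ``u``, ``m`` is itself noncentral chi-square with noncentrality
  ``sigma^2 u``, approximated by a normal matched to its exact first
  two moments.

Expected accuracy is then ``E[ P(distractor farther | c)^(P-1) ]``,
integrated numerically over ``u`` (equal-probability chi-square grid)
and ``m`` (Gauss-Hermite).  Distractors are treated as conditionally
independent given the probe location, which is exact; the only
approximation is the normal on ``m``.  The oracle is validated against
brute-force Monte Carlo in the test suite before being relied on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import INDEX_STREAM, derive_seed
from .matching import AccuracyEstimate, estimate_accuracy, nearest_neighbor_identify
from .population import NoiseModel, PopulationConfig, generate_probes

__all__ = [
    "ProbeBudgetPolicy",
    "SweepSpec",
    "SweepResult",
    "PowerLawFit",
    "run_sweep",
    "fit_loglog",
    "expected_accuracy_semianalytic",
]

_MIN_FEATURES_FOR_ORACLE = 50


@dataclass(frozen=True)
class ProbeBudgetPolicy:
    """How many probes to evaluate at each population size.

    For pools up to ``small_pool_limit`` every individual is probed, in
    whole replicates until at least ``min_probes`` probes are spent (a
    single pass over 157 individuals would leave ~4-point binomial
    noise, far coarser than the quantities of interest).  For larger
    pools the budget targets ``target_successes`` expected correct
    matches, using the semi-analytic oracle as the pilot accuracy
    estimate ("oracle-pilot", default) or a small empirical pilot match
    run ("empirical-pilot").  Explicit per-size overrides win.
    """

    name: str = "oracle-pilot"
    small_pool_limit: int = 10_000
    min_probes: int = 10_000
    target_successes: int = 20
    min_probes_large: int = 2_000
    max_probes_large: int = 50_000
    pilot_probes: int = 2_000
    overrides: tuple[tuple[int, int], ...] = ()

    def budget(self, pool_size: int, n_features: int, sigma: float) -> int:
        for size, n in self.overrides:
            if size == pool_size:
                return n
        if pool_size <= self.small_pool_limit:
            reps = max(1, int(np.ceil(self.min_probes / pool_size)))
            return reps * pool_size
        if self.name == "empirical-pilot":
            return -1  # sentinel: caller runs a pilot
        p_hat = max(
            expected_accuracy_semianalytic(pool_size, n_features, sigma), 1e-9
        )
        n = int(np.ceil(self.target_successes / p_hat))
        return int(np.clip(n, self.min_probes_large, self.max_probes_large))


@dataclass(frozen=True)
class SweepSpec:
    """One accuracy-vs-pool-size experiment at a fixed noise level."""

    population_sizes: tuple[int, ...]
    sigma: float
    n_features: int = 1000
    probe_budget: ProbeBudgetPolicy = field(default_factory=ProbeBudgetPolicy)
    seed: int = 0
    label: str = ""
    nested: bool = False

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.population_sizes)
        object.__setattr__(self, "population_sizes", sizes)
        if any(s < 1 for s in sizes):
            raise ValueError("population sizes must be >= 1")
        if any(b >= a for a, b in zip(sizes[1:], sizes[:-1])):
            raise ValueError("population_sizes must be strictly increasing")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SweepResult:
    """Accuracy estimates, one per requested population size."""

    rows: list[AccuracyEstimate]
    spec: SweepSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PowerLawFit:
    """OLS fit of log(accuracy) on log(pool size)."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, pool_size: float) -> float:
        return float(np.exp(self.intercept + self.slope * np.log(pool_size)))


def _probe_indices(pool_size: int, n_probes: int, seed: int) -> np.ndarray:
    """Which individuals to probe: whole replicates of everyone when the
    budget allows, otherwise a seeded subsample without replacement."""
    if n_probes >= pool_size:
        reps = n_probes // pool_size
        idx = np.tile(np.arange(pool_size), reps)
        rem = n_probes - reps * pool_size
        if rem:
            rng = np.random.default_rng(derive_seed(seed, INDEX_STREAM, pool_size))
            idx = np.concatenate([idx, rng.choice(pool_size, rem, replace=False)])
        return idx
    rng = np.random.default_rng(derive_seed(seed, INDEX_STREAM, pool_size))
    return rng.choice(pool_size, n_probes, replace=False)


def run_sweep(spec: SweepSpec, *, chunk_rows: int = 16384) -> SweepResult:
    """Measure rank-1 accuracy at every population size in the spec.

    Galleries are drawn fresh per size by default (``nested=True``
    reuses one stream so that smaller pools are prefixes of larger
    ones).  Large galleries are never materialised; the matcher streams
    them chunk by chunk.
    """
    rows: list[AccuracyEstimate] = []
    noise = NoiseModel(sigma=spec.sigma)
    for size in spec.population_sizes:
        gallery_seed = (
            derive_seed(spec.seed, 0) if spec.nested else derive_seed(spec.seed, 0, size)
        )
        config = PopulationConfig(
            n_individuals=size, n_features=spec.n_features, seed=gallery_seed
        )
        try:
            n_probes = spec.probe_budget.budget(size, spec.n_features, spec.sigma)
            probe_seed = derive_seed(spec.seed, 1, size)
            if n_probes < 0:  # empirical pilot
                pilot_idx = _probe_indices(size, spec.probe_budget.pilot_probes, probe_seed)
                pilot = generate_probes(config, noise, pilot_idx, derive_seed(probe_seed, 99))
                pilot_acc = max(
                    nearest_neighbor_identify(pilot, config, chunk_rows=chunk_rows)
                    .correct_flags.mean(),
                    1.0 / spec.probe_budget.pilot_probes,
                )
                n_probes = int(
                    np.clip(
                        np.ceil(spec.probe_budget.target_successes / pilot_acc),
                        spec.probe_budget.min_probes_large,
                        spec.probe_budget.max_probes_large,
                    )
                )
            idx = _probe_indices(size, n_probes, probe_seed)
            probes = generate_probes(config, noise, idx, probe_seed)
            result = nearest_neighbor_identify(probes, config, chunk_rows=chunk_rows)
            rows.append(
                estimate_accuracy(
                    result, label=spec.label, sigma=spec.sigma, seed=spec.seed
                )
            )
        except Exception as err:
            raise RuntimeError(f"sweep failed at population size {size}") from err
    return SweepResult(rows=rows, spec=spec)


def fit_loglog(result: SweepResult) -> PowerLawFit:
    """Least-squares line through (log pool size, log accuracy).

    Zero-success rows carry no usable log-accuracy and are excluded; at
    least two usable rows are required.
    """
    usable = [r for r in result.rows if r.n_correct >= 1]
    if len(usable) < 2:
        raise ValueError("need at least 2 rows with nonzero successes for a log-log fit")
    x = np.log([r.gallery_size for r in usable])
    y = np.log([r.accuracy for r in usable])
    fit = stats.linregress(x, y)
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def expected_accuracy_semianalytic(
    gallery_size: int,
    n_features: int,
    sigma: float,
    *,
    n_grid: int = 200,
    n_hermite: int = 40,
) -> float:
    """Expected rank-1 accuracy under the Gaussian model, no simulation.

    See the module docstring for the derivation.  Requires
    ``n_features >= 50`` (the moment-matched normal on the probe-location
    norm is a large-d approximation).
    """
    if gallery_size < 1:
        raise ValueError("gallery_size must be >= 1")
    if n_features < _MIN_FEATURES_FOR_ORACLE:
        raise ValueError(f"semi-analytic oracle requires n_features >= {_MIN_FEATURES_FOR_ORACLE}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if gallery_size == 1 or sigma == 0.0:
        return 1.0
    d = n_features
    # equal-probability grid over u = ||z||^2 ~ chi2_d
    qs = (np.arange(n_grid) + 0.5) / n_grid
    u = stats.chi2.ppf(qs, d)
    s0 = sigma**2 * u
    # m | u ~ ncx2(d, sigma^2 u): normal with the exact first two moments
    m_mean = d + sigma**2 * u
    m_sd = np.sqrt(2 * d + 4 * sigma**2 * u)
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_hermite)
    gh_w = gh_w / np.sqrt(2 * np.pi)
    m = np.maximum(m_mean[:, None] + m_sd[:, None] * gh_x[None, :], 1e-12)
    # P(distractor closer) = P(chi'^2_d(m) < s0); for very large
    # noncentrality the exact ncx2 evaluation is replaced by its CLT
    # normal limit (relative error is negligible there and scipy's
    # series become extremely slow)
    s0_b = np.broadcast_to(s0[:, None], m.shape)
    big = m > 1e7
    cdf = np.empty_like(m)
    if np.any(~big):
        cdf[~big] = stats.ncx2.cdf(s0_b[~big], d, m[~big])
    if np.any(big):
        mb = m[big]
        cdf[big] = stats.norm.cdf((s0_b[big] - (d + mb)) / np.sqrt(2 * d + 4 * mb))
    log_further = np.log1p(-np.clip(cdf, 0.0, 1.0 - 1e-16))
    inner = np.exp(np.clip((gallery_size - 1) * log_further, -745.0, 0.0)) @ gh_w
    return float(np.clip(inner.mean(), 0.0, 1.0))
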