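"""Noise-scale calibration against an anchor match rate.

The simulation's only free parameter is the probe-noise standard
deviation ``sigma``.  It is chosen so that rank-1 accuracy at the
reference gallery size (157 individuals, 1,000 features in the
reference setup) reproduces a published anchor match rate: 0.38 for the
"refaced" (high-SNR) condition, 0.10 for the "defaced" (low-SNR)
condition.

Search: stochastic bisection with common random numbers.  A single
reference gallery and a single bank of standard-normal noise draws are
fixed up front; accuracy at any sigma is evaluated by scaling the same
noise bank, which makes accuracy an exactly non-increasing step
function of sigma and lets bisection converge cleanly.  Each
evaluation probes every reference individual, replicated until the
binomial standard error is below half the accuracy tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from ._rng import PROBE_NOISE_STREAM, derive_seed, row_block_normal
from .matching import AccuracyEstimate
from .population import PopulationConfig, generate_gallery

__all__ = ["CalibrationSpec", "CalibrationResult", "calibrate_noise"]

_GALLERY_TAG = 11
_CRN_TAG = 12
_ACHIEVED_TAG = 13
_SIGMA_CAP = 1e6


@dataclass(frozen=True)
class CalibrationSpec:
    """Target and search settings for noise calibration.

    ``n_probes_per_eval`` defaults to the smallest whole-replicate count
    whose binomial standard error at the target is below tolerance/2.
    """

    target_accuracy: float
    reference_size: int = 157
    n_features: int = 1000
    tolerance: float = 0.005
    sigma_bounds: tuple[float, float] = (0.0, 64.0)
    n_probes_per_eval: int | None = None
    max_iterations: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_accuracy <= 1):
            raise ValueError("target_accuracy must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.sigma_bounds[0] < 0 or self.sigma_bounds[1] <= self.sigma_bounds[0]:
            raise ValueError("sigma_bounds must satisfy 0 <= lower < upper")

    def resolved_probes_per_eval(self) -> int:
        if self.n_probes_per_eval is not None:
            return self.n_probes_per_eval
        p = self.target_accuracy
        se_target = self.tolerance / 2.0
        n = int(np.ceil(p * (1 - p) / se_target**2))
        reps = max(1, int(np.ceil(n / self.reference_size)))
        return reps * self.reference_size


@dataclass
class CalibrationResult:
    """Calibrated sigma with the accuracy it achieves at the reference size."""

    sigma_star: float
    achieved: AccuracyEstimate
    n_iterations: int
    converged: bool
    spec: CalibrationSpec = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "sigma_star": self.sigma_star,
            "achieved": self.achieved.to_dict(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "target_accuracy": self.spec.target_accuracy if self.spec else None,
        }


def _make_evaluator(spec: CalibrationSpec) -> tuple[Callable[[float], float], np.ndarray, np.ndarray]:
    """Common-random-numbers accuracy evaluator at the reference size.

    Returns (accuracy_fn, gallery values, true indices of the probe bank).
    """
    p_count = spec.resolved_probes_per_eval()
    d = spec.n_features
    config = PopulationConfig(
        n_individuals=spec.reference_size,
        n_features=d,
        seed=derive_seed(spec.seed, _GALLERY_TAG),
    )
    gallery = generate_gallery(config).values
    true_idx = np.tile(np.arange(spec.reference_size), p_count // spec.reference_size + 1)[:p_count]
    noise_bank = row_block_normal(derive_seed(spec.seed, _CRN_TAG), PROBE_NOISE_STREAM, 0, p_count, d)
    base = gallery[true_idx]
    g_norm = np.einsum("ij,ij->i", gallery, gallery)

    def accuracy(sigma: float) -> float:
        correct = 0
        block = 4096
        for s in range(0, p_count, block):
            e = min(s + block, p_count)
            probes = base[s:e] + sigma * noise_bank[s:e]
            scores = g_norm[None, :] - 2.0 * probes @ gallery.T
            correct += int((scores.argmin(axis=1) == true_idx[s:e]).sum())
        return correct / p_count

    return accuracy, gallery, true_idx


def calibrate_noise(spec: CalibrationSpec) -> CalibrationResult:
    """Bisection for the sigma that meets ``spec.target_accuracy``.

    The bracket is checked first (accuracy at the lower sigma bound must
    be at or above the target); the upper bound is expanded
    geometrically until accuracy falls below the target, up to a cap.
    Convergence requires both a narrow sigma interval and an accuracy
    within tolerance of the target.
    """
    accuracy, _, _ = _make_evaluator(spec)
    lo, hi = spec.sigma_bounds

    acc_lo = accuracy(lo)
    if acc_lo < spec.target_accuracy - spec.tolerance:
        raise ValueError(
            f"target {spec.target_accuracy} not bracketed: accuracy at "
            f"sigma={lo} is only {acc_lo:.4f}; feasible targets are <= {acc_lo:.4f}"
        )
    if abs(acc_lo - spec.target_accuracy) <= spec.tolerance:
        # the lower sigma bound already meets the target (e.g. target 1.0
        # with distinct gallery rows at sigma 0): nothing to search for
        achieved = _evaluate_achieved(spec, lo)
        return CalibrationResult(
            sigma_star=float(lo),
            achieved=achieved,
            n_iterations=0,
            converged=abs(achieved.accuracy - spec.target_accuracy)
            <= spec.tolerance + achieved.half_width,
            spec=spec,
        )
    n_iter = 0
    acc_hi = accuracy(hi)
    while acc_hi > spec.target_accuracy and hi < _SIGMA_CAP:
        lo, acc_lo = hi, acc_hi
        hi *= 2.0
        acc_hi = accuracy(hi)
        n_iter += 1

    mid, acc_mid = lo, acc_lo
    for _ in range(spec.max_iterations - n_iter):
        mid = 0.5 * (lo + hi)
        acc_mid = accuracy(mid)
        n_iter += 1
        if acc_mid >= spec.target_accuracy:
            lo, acc_lo = mid, acc_mid
        else:
            hi, acc_hi = mid, acc_mid
        interval_ok = (hi - lo) <= max(1e-6, 1e-4 * mid)
        accuracy_ok = abs(acc_mid - spec.target_accuracy) <= spec.tolerance
        if interval_ok and accuracy_ok:
            break

    # choose the bracket end closest to the target
    sigma_star = lo if abs(acc_lo - spec.target_accuracy) <= abs(acc_hi - spec.target_accuracy) else hi
    achieved = _evaluate_achieved(spec, sigma_star)
    converged = (
        abs(achieved.accuracy - spec.target_accuracy)
        <= spec.tolerance + achieved.half_width
    )
    return CalibrationResult(
        sigma_star=float(sigma_star),
        achieved=achieved,
        n_iterations=n_iter,
        converged=converged,
        spec=spec,
    )


def _evaluate_achieved(spec: CalibrationSpec, sigma: float) -> AccuracyEstimate:
    """Accuracy at sigma with fresh probe noise (independent of the CRN bank)."""
    p_count = spec.resolved_probes_per_eval()
    d = spec.n_features
    config = PopulationConfig(
        n_individuals=spec.reference_size,
        n_features=d,
        seed=derive_seed(spec.seed, _GALLERY_TAG),
    )
    gallery = generate_gallery(config).values
    true_idx = np.tile(np.arange(spec.reference_size), p_count // spec.reference_size + 1)[:p_count]
    noise = row_block_normal(derive_seed(spec.seed, _ACHIEVED_TAG), PROBE_NOISE_STREAM, 0, p_count, d)
    g_norm = np.einsum("ij,ij->i", gallery, gallery)
    correct = 0
    block = 4096
    for s in range(0, p_count, block):
        e = min(s + block, p_count)
        probes = gallery[true_idx[s:e]] + sigma * noise[s:e]
        scores = g_norm[None, :] - 2.0 * probes @ gallery.T
        correct += int((scores.argmin(axis=1) == true_idx[s:e]).sum())
    lo_ci, hi_ci = proportion_confint(correct, p_count, alpha=0.05, method="wilson")
    return AccuracyEstimate(
        n_probes=p_count,
        n_correct=correct,
        accuracy=correct / p_count,
        ci_low=float(lo_ci),
        ci_high=float(hi_ci),
        label=f"calibration target={spec.target_accuracy}",
        gallery_size=spec.reference_size,
        sigma=sigma,
        seed=spec.seed,
    )
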