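#!/usr/bin/env python
"""Fit the power-law decay of accuracy with pool size and tabulate the
semi-analytic expectations, including the overnight-scale low-SNR tail.

Requires the sweep CSVs from 03_accuracy_sweep.py.
Writes results/loglog_fit.json, results/loglog_points_<cond>.csv and,
if matplotlib is available, results/scaling.png.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import reidsim as rs

RESULTS = Path(__file__).resolve().parents[1] / "results"
LADDER = (157, 6500, 70_000, 423_000, 865_000)


def load_sweep(label: str) -> rs.SweepResult:
    df = pd.read_csv(RESULTS / f"sweep_{label}.csv")
    rows = [
        rs.AccuracyEstimate(
            n_probes=int(r.n_probes), n_correct=int(r.n_correct),
            accuracy=float(r.accuracy), ci_low=float(r.ci_low),
            ci_high=float(r.ci_high), label=str(r.label),
            gallery_size=int(r.gallery_size), sigma=float(r.sigma),
        )
        for r in df.itertuples()
    ]
    spec = rs.SweepSpec(
        population_sizes=tuple(df["gallery_size"]), sigma=float(df["sigma"].iloc[0])
    )
    return rs.SweepResult(rows=rows, spec=spec)


def main() -> None:
    fits = {}
    for label in ("high", "low"):
        sweep = load_sweep(label)
        fit = rs.fit_loglog(sweep)
        fits[label] = {"slope": fit.slope, "intercept": fit.intercept, "r_squared": fit.r_squared}
        print(
            f"{label}-SNR: accuracy ~ P^{fit.slope:.3f} "
            f"(R^2 = {fit.r_squared:.4f}) over {len(sweep.rows)} pool sizes"
        )
        usable = [r for r in sweep.rows if r.n_correct >= 1]
        pd.DataFrame(
            {
                "log10_population": [np.log10(r.gallery_size) for r in usable],
                "log10_accuracy": [np.log10(r.accuracy) for r in usable],
            }
        ).to_csv(RESULTS / f"loglog_points_{label}.csv", index=False)

        sigma = sweep.spec.sigma
        oracle = {P: rs.expected_accuracy_semianalytic(P, 1000, sigma) for P in LADDER}
        fits[label]["semianalytic_percent"] = {str(P): 100 * v for P, v in oracle.items()}
        tail = ", ".join(f"P={P:,}: {100 * v:.4f}%" for P, v in oracle.items())
        print(f"  semi-analytic expectation: {tail}")

    (RESULTS / "loglog_fit.json").write_text(json.dumps(fits, indent=2))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, marker in (("high", "o"), ("low", "s")):
        sweep = load_sweep(label)
        P = [r.gallery_size for r in sweep.rows if r.n_correct]
        acc = [100 * r.accuracy for r in sweep.rows if r.n_correct]
        ax.loglog(P, acc, marker, label=f"{label}-SNR (measured)")
        grid = np.logspace(np.log10(157), np.log10(865_000), 40)
        ax.loglog(
            grid,
            [100 * rs.expected_accuracy_semianalytic(int(p), 1000, sweep.spec.sigma) for p in grid],
            "--", alpha=0.6,
        )
    ax.set_xlabel("candidate pool size")
    ax.set_ylabel("rank-1 identification accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "scaling.png", dpi=150)
    print(f"wrote {RESULTS / 'scaling.png'}")


if __name__ == "__main__":
    main()
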