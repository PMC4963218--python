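#!/usr/bin/env python
"""Bayesian two-state probability profiles for arginine methylation.

Pools the Δ samples as in the condensed-curve view (mono-Nε with mono-Nη;
symmetric with asymmetric di-methyl), fits the two-state model for
mono-vs-unmodified and di-vs-unmodified, and reports where the mean profile
puts ≥ 80% probability on the methylated state.  The arginine surrogate
calibration is illustrative (its Δ distributions exist only as figures in
the source study), so the printed thresholds characterize the surrogate, not
experiment.  Writes results/profiles_arg_*.csv and a figure.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ptmdelta.bayes import (build_model_spec, fit_state_model,
                            probability_profile, threshold_query)
from ptmdelta.delta import kde_density
from ptmdelta.reference import compute_reference_stats, synthetic_shift_table

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results"

POOLS = {
    "monomethyl": ["ARG_monomethyl-NE", "ARG_monomethyl-NH"],
    "dimethyl": ["ARG_dimethyl-sym", "ARG_dimethyl-asym"],
}


def main():
    delta_dir = OUT / "deltas"
    if not delta_dir.exists():
        raise SystemExit("run analysis/04_delta_distributions.py first")
    ref = compute_reference_stats(synthetic_shift_table(seed=SEED + 900_001),
                                  "ARG", "CZ")
    # the unmodified Δ samples are the charged twins of the mono-NE ensemble
    unmod = pd.read_csv(OUT / "shifts" / "ARG_monomethyl-NE_unmod.csv")
    d_unmod = unmod["value"] - unmod["value"].mean()

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, (label, tags) in zip(axes, POOLS.items()):
        samples = np.concatenate([
            pd.read_csv(delta_dir / f"{t}.csv")["delta"].to_numpy()
            for t in tags
        ])
        dist_mod = kde_density(samples, residue="ARG", state=label, nucleus="CZ")
        dist_unmod = kde_density(d_unmod, residue="ARG", state="charged",
                                 nucleus="CZ")
        spec = build_model_spec(dist_mod, dist_unmod, ref, seed=SEED + 5)
        draws = fit_state_model(spec, dist_mod.samples, dist_unmod.samples)
        grid = np.linspace(min(samples.min(), d_unmod.min()) - 2,
                           max(samples.max(), d_unmod.max()) + 2, 400)
        prof = probability_profile(draws, grid, state_a=label, state_b="charged")
        regions = threshold_query(prof, 0.8, "A")
        pd.DataFrame({"delta": grid, "p_mean": prof.mean_curve,
                      "p_low": prof.band_low, "p_high": prof.band_high}
                     ).to_csv(OUT / f"profiles_arg_{label}.csv", index=False)
        rtxt = ", ".join(f"[{a:.1f}, {b:.1f}]" for a, b in regions) or "none"
        print(f"ARG {label:<11} pooled n={dist_mod.n:>4}  mean Δ "
              f"{dist_mod.mean:+5.2f} ppm  P≥80% on {rtxt}  "
              f"(max R̂ {draws.diagnostics['max_rhat']:.3f})")
        step = max(1, len(prof.curves) // 60)
        for curve in prof.curves[::step]:
            ax.plot(grid, curve, color="C0", alpha=0.08, lw=0.7)
        ax.plot(grid, prof.mean_curve, color="C3", lw=1.8)
        ax.set_title(f"{label} vs charged Arg")
        ax.set_xlabel("Δ (ppm), ¹³Cζ")
    axes[0].set_ylabel("P(methylated | Δ)")
    fig.tight_layout()
    fig.savefig(OUT / "fig_profiles_arg.png", dpi=150)
    print(f"\nwrote profile curves and {OUT / 'fig_profiles_arg.png'}")


if __name__ == "__main__":
    main()
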