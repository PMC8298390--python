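#!/usr/bin/env python
"""Compare the three mixing regimes of the drop-on-drop collision.

Runs the stochastic engine on the calcium-dye validation recipe (4 nL
drop with 1 mM of each indicator; 3 x 60 pL drops of 100 mM CaCl2) in
the diffusion-only, cone-jet and mass-flow regimes and tabulates the
90%-of-asymptote equilibration times of the bound dyes. Writes
results/regime_comparison.json plus one resampled trajectory CSV per
regime.

The diffusive regimes run on a coarse 20 µm lattice with 1e4 particles
for the most abundant moiety so the comparison completes in minutes;
means are unbiased under the particle scaling.
"""

import argparse
from pathlib import Path

from dropmix.mixing_pipeline import MixingConfig, compare_regimes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--h-um", type=float, default=20.0)
    ap.add_argument("--particles", type=float, default=1e4)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    configs = [
        MixingConfig(regime="mass_flow", seed=args.seed),
        MixingConfig(regime="cone_jet", h_um=args.h_um,
                     target_particles=args.particles, seed=args.seed),
        MixingConfig(regime="diffusion_only", h_um=args.h_um,
                     target_particles=args.particles, seed=args.seed),
    ]
    report = compare_regimes(configs)
    report.to_json(args.out / "regime_comparison.json")
    for regime, df in report.trajectories.items():
        df.to_csv(args.out / f"trajectory_{regime}.csv", index=False)

    tbl = report.table[report.table.species == "bound_total"]
    print(tbl[["regime", "equilibration_time_s", "reached"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    t = dict(zip(tbl.regime, tbl.equilibration_time_s))
    print(f"\nmass-flow equilibration: {t['mass_flow']*1e3:.3g} ms "
          f"(<1 ms: inertial mixing is not the bottleneck)")
    print(f"diffusion-only equilibration: {t['diffusion_only']:.3g} s "
          f"(comparable to or slower than a 1-2 s enzymatic turnover)")
    print(f"separation: {t['diffusion_only']/t['mass_flow']:.3g}x")


if __name__ == "__main__":
    main()
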