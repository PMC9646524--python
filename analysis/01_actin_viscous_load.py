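"""Ensemble response of the lamellipodial actin network to viscous loading.

Runs 20-replicate stochastic simulations at 0.8 and 8 cP (plus the 2 and
5 cP intermediates) with the viscous dashpot switched on at t = 6 s, and
summarizes: the post-load network density, the steady edge velocity, and the
transient excess of pointed-end over capped-barbed-end creation at load
onset. Writes results/actin_ensemble.csv and results/actin_summary.csv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from viscocell import actin

VISCOSITIES_CP = (0.8, 2.0, 5.0, 8.0)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--n-rep", type=int, default=20)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    t_load = actin.ActinSimParams().t_load
    frames, summary = [], []
    for cp in VISCOSITIES_CP:
        params = actin.ActinSimParams.from_cp(cp)
        ens = actin.ensemble_density(params, n_rep=args.n_rep, base_seed=args.seed)
        frames.append(
            pd.DataFrame(
                {
                    "viscosity_cp": cp,
                    "time_s": ens.times,
                    "mean_density": ens.mean_density,
                    "sd_density": ens.sd_density,
                    "mean_edge_vel_um_s": ens.mean_edge_vel,
                    "mean_pointed_minus_capped": ens.mean_pointed_minus_capped,
                }
            )
        )
        after = (ens.times >= t_load) & (ens.times < t_load + 1.5)
        before = (ens.times >= t_load - 1.5) & (ens.times < t_load)
        summary.append(
            {
                "viscosity_cp": cp,
                "preload_density": ens.mean_density[ens.times < t_load].mean(),
                "postload_density": ens.mean_density[ens.times >= t_load].mean(),
                "late_edge_vel_um_s": ens.mean_edge_vel[ens.times >= 10.0].mean(),
                "pointed_minus_capped_jump": ens.mean_pointed_minus_capped[after].mean()
                - ens.mean_pointed_minus_capped[before].mean(),
            }
        )
    pd.concat(frames).to_csv(args.out / "actin_ensemble.csv", index=False)
    table = pd.DataFrame(summary)
    table.to_csv(args.out / "actin_summary.csv", index=False)

    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    lo, hi = table.iloc[0], table.iloc[-1]
    print(
        f"\nViscous load applied at t = {t_load:.0f} s. At 8 cP the post-load "
        f"network is {hi.postload_density / lo.postload_density:.2f}x denser than "
        f"at 0.8 cP, the steady edge is {hi.late_edge_vel_um_s / lo.late_edge_vel_um_s:.2f}x "
        "as fast (slower under load), and pointed-end creation transiently "
        f"outpaces capping by {hi.pointed_minus_capped_jump:+.2f} events/step at onset."
    )


if __name__ == "__main__":
    main()
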