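#!/usr/bin/env python
"""Ratiometric signal R = I488/I435 versus temperature per medium, its OLS
sensitivity, and the cross-media correlation of sensitivity with the
van't Hoff enthalpy.

Reads the emission pairs of 01_simulate_spectra.py and the enthalpies of
03_thermodynamics.py; writes results/ratiometric.csv and
results/sensitivity_vs_enthalpy.csv.
"""

import argparse
import re
from pathlib import Path

import pandas as pd

import protoshift as ps

LAMP_RATIO = 1.3  # must match the simulation driver


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--spectra", type=Path, default=Path("results/spectra"))
    parser.add_argument("--thermo", type=Path, default=Path("results/thermodynamics.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    ratio_rows, fit_rows = [], []
    for medium_dir in sorted(p for p in args.spectra.iterdir() if p.is_dir()):
        points = []
        for p488 in sorted(medium_dir.glob("em488_T*.csv")):
            t_c = float(re.search(r"T(\d+)", p488.stem).group(1))
            em488 = ps.read_spectrum(p488)
            em435 = ps.read_spectrum(medium_dir / f"em435_T{t_c:.0f}.csv")
            em435 = ps.lamp_correct(em435, LAMP_RATIO)
            point = ps.ratiometric_signal(em488, em435, medium=medium_dir.name)
            points.append(point)
            ratio_rows.append({"medium": medium_dir.name, "temperature_c": t_c,
                               "I488": point.I488, "I435": point.I435, "R": point.R})
        fit = ps.sensitivity_fit(points, "temperature")
        fit_rows.append({"medium": medium_dir.name,
                         "sensitivity_per_C": fit.slope,
                         "sensitivity_1e-2_per_C": fit.slope * 100.0,
                         "r_squared": fit.r_squared})
        print(f"{medium_dir.name}: dR/dT = {fit.slope * 100:.3f} x 1e-2/degC "
              f"(r^2 {fit.r_squared:.4f})")

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ratio_rows).to_csv(args.out / "ratiometric.csv", index=False)
    fits = pd.DataFrame(fit_rows)

    thermo = pd.read_csv(args.thermo)
    merged = fits.merge(thermo[["medium", "dH_kJ_per_mol"]], on="medium")
    corr = ps.sensitivity_vs_enthalpy(
        list(zip(merged.dH_kJ_per_mol, merged["sensitivity_1e-2_per_C"]))
    )
    merged.to_csv(args.out / "sensitivity_vs_enthalpy.csv", index=False)
    print(f"sensitivity vs enthalpy across media: slope = {corr.slope:.4f} "
          f"per kJ/mol, r^2 = {corr.r_squared:.4f}")


if __name__ == "__main__":
    main()
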