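#!/usr/bin/env python
"""Decompose the simulated absorption spectra into monoanion/dianion
concentrations and compute apparent equilibrium constants.

Reads the files written by 01_simulate_spectra.py, so the full file I/O
path is exercised; writes results/equilibrium.csv with one row per spectrum
(medium, T, pH, c_M, c_D, R^2, pKa_app).
"""

import argparse
import re
from pathlib import Path

import pandas as pd

import protoshift as ps
from protoshift.spectra import read_species_reference


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--spectra", type=Path, default=Path("results/spectra"))
    parser.add_argument("--out", type=Path, default=Path("results/equilibrium.csv"))
    args = parser.parse_args()

    rows = []
    for medium_dir in sorted(p for p in args.spectra.iterdir() if p.is_dir()):
        refs = {
            float(re.search(r"refs_T(\d+)", p.stem).group(1)): read_species_reference(p)
            for p in medium_dir.glob("refs_T*.csv")
        }
        for path in sorted(medium_dir.glob("abs_*.csv")):
            spec = ps.read_spectrum(path)
            ref = refs[round(spec.meta.temperature_c)]
            dec = ps.decompose(spec, ref, fit_range_nm=(400.0, 540.0))
            point = ps.compute_Ka(dec, spec.meta.ph, spec.meta.temperature_k)
            rows.append({
                "medium": medium_dir.name,
                "temperature_c": spec.meta.temperature_c,
                "ph": spec.meta.ph,
                "c_M": dec.c_M,
                "c_D": dec.c_D,
                "r_squared": dec.r_squared,
                "Ka_app": point.Ka_app,
                "pKa_app": point.pKa_app,
            })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"decomposed {len(df)} spectra -> {args.out}")
    print(f"worst fit quality R^2 = {df.r_squared.min():.5f}")
    at25 = df[(df.temperature_c == 25.0)]
    for medium, grp in at25.groupby("medium"):
        print(f"{medium}: median pKa_app(25 degC, pH series) = "
              f"{grp.pKa_app.median():.3f}")


if __name__ == "__main__":
    main()
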