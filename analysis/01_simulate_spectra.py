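#!/usr/bin/env python
"""Synthesize the spectral data set: absorption series over temperature and
pH, and dual-excitation emission pairs, for the three characterized media
(buffer, 30% sucrose, 40% glycerol).

Writes commented-CSV spectra under results/spectra/<medium>/ plus the
noise-free species reference curves each medium's decomposition will use.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import protoshift as ps
from protoshift.spectra import write_species_reference

MEDIA = [
    {"name": "buffer", "cosolvent": "none", "w": 0.0, "dH": 7400.0, "pKa": 6.45},
    {"name": "sucrose30", "cosolvent": "sucrose", "w": 30.0, "dH": 4600.0, "pKa": 6.55},
    {"name": "glycerol40", "cosolvent": "glycerol", "w": 40.0, "dH": 3700.0, "pKa": 6.43},
]
TEMPS_C = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0]
PH_SERIES = [5.5, 5.75, 6.0, 6.25, 6.5, 6.75, 7.0, 7.25, 7.5]
LAMP_RATIO = 1.3  # deliberate excitation asymmetry, undone downstream


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/spectra"))
    args = parser.parse_args()

    for i, medium in enumerate(MEDIA):
        out = args.out / medium["name"]
        out.mkdir(parents=True, exist_ok=True)
        gt = ps.load_default_ground_truth(dH_true=medium["dH"], pKa_at_25C=medium["pKa"])
        gt = replace(gt, seed=args.seed * 1000 + i)
        deltaf = ps.media_polarity(medium["cosolvent"], medium["w"]).deltaf

        # temperature series at the working pH 6.5
        temps_k = [t + 273.15 for t in TEMPS_C]
        for spec, t_c in zip(
            ps.generate_absorption_series(gt, [6.5], temps_k, deltaf,
                                          medium["cosolvent"], medium["w"]),
            TEMPS_C,
        ):
            ps.write_spectrum(spec, out / f"abs_T{t_c:.0f}.csv")

        # pH titration at 25 degC
        for spec in ps.generate_absorption_series(gt, PH_SERIES, [298.15], deltaf,
                                                  medium["cosolvent"], medium["w"]):
            ps.write_spectrum(spec, out / f"abs_pH{spec.meta.ph:.2f}.csv")

        # dual-excitation emission pairs over temperature
        for t_c in TEMPS_C:
            em488, em435 = ps.generate_emission_pair(
                gt, 6.5, t_c + 273.15, LAMP_RATIO, deltaf,
                medium["cosolvent"], medium["w"],
            )
            ps.write_spectrum(em488, out / f"em488_T{t_c:.0f}.csv")
            ps.write_spectrum(em435, out / f"em435_T{t_c:.0f}.csv")

        # noise-free references per temperature (the decomposition basis)
        for t_c in TEMPS_C + [25.0]:
            ref = ps.generate_species_references(
                replace(gt, noise_rel=0.0), t_c + 273.15, deltaf
            )
            write_species_reference(ref, out / f"refs_T{t_c:.0f}.csv")

        print(f"{medium['name']}: wrote {len(list(out.glob('*.csv')))} files "
              f"(deltaf={deltaf:.4f}, ground truth dH={medium['dH']} J/mol, "
              f"pKa25={medium['pKa']})")
    print(f"lamp ratio used for emission pairs: {LAMP_RATIO}")


if __name__ == "__main__":
    main()
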