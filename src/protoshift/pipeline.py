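"""End-to-end runs from a single YAML config.

A run synthesizes its inputs (spectra series and/or solvent boxes), pushes
them through decomposition, equilibrium thermodynamics, the ratiometric
channel and the solvation statistics, and writes per-stage CSV tables plus
a JSON report whose per-medium rows carry the standard characterization of
such a probe: ratiometric temperature sensitivity, pKa_app at 25 degC, the
pKa temperature shift, the van't Hoff enthalpy, and the excited-state pKa
shift.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .boxes import BoxGroundTruth, generate_solvation_box
from .constants import T_REF_K
from .decomposition import compute_Ka, decompose, pKa_from_series, absorption_maximum
from .ratiometric import lamp_correct, ratiometric_signal, sensitivity_fit
from .solvation import detect_hbonds, mddf, occupancy, preferential_interaction
from .synthetic import (
    generate_absorption_series,
    generate_emission_pair,
    generate_pure_species_spectra,
    generate_species_references,
    load_default_ground_truth,
)
from .thermo import (
    PhotoState,
    forster_weller,
    media_polarity,
    vant_hoff,
    zero_zero_wavenumber,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run"]

_DEFAULT_MEDIA = [
    {"name": "buffer", "cosolvent": "none", "mass_fraction_percent": 0.0,
     "dH_true": 7400.0, "pKa_at_25C": 6.45},
    {"name": "sucrose30", "cosolvent": "sucrose", "mass_fraction_percent": 30.0,
     "dH_true": 4600.0, "pKa_at_25C": 6.55},
    {"name": "glycerol40", "cosolvent": "glycerol", "mass_fraction_percent": 40.0,
     "dH_true": 3700.0, "pKa_at_25C": 6.43},
]

_DEFAULTS = {
    "mode": "spectra",
    "seed": 0,
    "spectral": {"noise_rel": 0.005},
    "media": _DEFAULT_MEDIA,
    "box": {
        "box_edge": 4.0, "n_water": 200, "n_cosolvent": 20, "cosolvent": "GLY",
        "enrichment": 1.0, "shell_radius": 1.0, "hbond_fraction": 0.0, "n_frames": 20,
    },
    "analysis": {
        "fit_range_nm": [400.0, 540.0],
        "integration_range_nm": [500.0, 650.0],
        "d_max_nm": 0.35,
        "a_max_deg": 30.0,
        "r_cut_nm": 0.8,
        "lamp_ratio": 1.0,
        "ph": 6.5,
        "temperatures_c": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0],
        "ph_series": [5.5, 5.75, 6.0, 6.25, 6.5, 6.75, 7.0, 7.25, 7.5],
        "mddf_bin_nm": 0.02,
    },
}

_MODES = ("spectra", "solvation", "full")

# keys of the spectral block that may be overridden from a config file
_SPECTRAL_KEYS = {
    "pKa_at_25C", "dH_true", "noise_rel", "total_dye_M", "path_cm",
    "phi_ratio_D_over_M", "shift_dnu_dT", "shift_dnu_ddeltaf",
}
_MEDIA_KEYS = {"name", "cosolvent", "mass_fraction_percent", "dH_true", "pKa_at_25C"}
_BOX_KEYS = set(_DEFAULTS["box"])
_ANALYSIS_KEYS = set(_DEFAULTS["analysis"])


@dataclass
class RunConfig:
    mode: str
    seed: int
    spectral: dict
    media: list
    box: dict
    analysis: dict

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:16]


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    for key in block:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f"; did you mean '{hint[0]}'?" if hint else ""
            raise ValueError(f"unknown key '{key}' in {where}{suffix}")


def validate_config(source) -> RunConfig:
    """Resolve a YAML file/dict into a fully materialized RunConfig.

    Unknown keys are rejected (with a spelling suggestion); every tunable
    lands at an explicit value so the resolved config written to the run
    directory is self-contained.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = copy.deepcopy(source) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _reject_unknown(raw, {"mode", "seed", "spectral", "media", "box", "analysis"}, "config")
    mode = raw.get("mode", _DEFAULTS["mode"])
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    seed = raw.get("seed", _DEFAULTS["seed"])
    if not isinstance(seed, int) or seed < 0:
        raise ValueError("seed must be a non-negative integer")

    spectral = dict(_DEFAULTS["spectral"])
    spectral.update(raw.get("spectral") or {})
    _reject_unknown(spectral, _SPECTRAL_KEYS, "spectral block")

    media = copy.deepcopy(raw.get("media") or _DEFAULTS["media"])
    for i, medium in enumerate(media):
        _reject_unknown(medium, _MEDIA_KEYS, f"media[{i}]")
        for key in _MEDIA_KEYS:
            if key not in medium:
                raise ValueError(f"media[{i}]: missing required key '{key}'")

    box = dict(_DEFAULTS["box"])
    box.update(raw.get("box") or {})
    _reject_unknown(box, _BOX_KEYS, "box block")

    analysis = dict(_DEFAULTS["analysis"])
    analysis.update(raw.get("analysis") or {})
    _reject_unknown(analysis, _ANALYSIS_KEYS, "analysis block")

    return RunConfig(
        mode=mode, seed=seed, spectral=spectral, media=media, box=box, analysis=analysis
    )


def _prepare_out_dir(out_dir) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        out = out.with_name(out.name + "-" + time.strftime("%Y%m%d-%H%M%S"))
    out.mkdir(parents=True, exist_ok=True)
    return out


def _spectra_stage(cfg: RunConfig, out: Path) -> dict:
    ana = cfg.analysis
    report_rows = {}
    eq_rows, ratio_rows = [], []
    for i_medium, medium in enumerate(cfg.media):
        overrides = {k: v for k, v in cfg.spectral.items()}
        overrides["dH_true"] = medium["dH_true"]
        overrides["pKa_at_25C"] = medium["pKa_at_25C"]
        gt = load_default_ground_truth(**overrides)
        gt = replace(gt, seed=cfg.seed * 1000 + i_medium)
        deltaf = media_polarity(medium["cosolvent"], medium["mass_fraction_percent"]).deltaf

        # Ka(T) from decomposition at the working pH across temperatures
        T_list = [t + 273.15 for t in ana["temperatures_c"]]
        spectra = generate_absorption_series(
            gt, [ana["ph"]], T_list, deltaf,
            medium["cosolvent"], medium["mass_fraction_percent"],
        )
        points = []
        for spec, T_k in zip(spectra, T_list):
            ref = generate_species_references(gt, T_k, deltaf)
            dec = decompose(spec, ref, ana["fit_range_nm"])
            pt = compute_Ka(dec, ana["ph"], T_k)
            points.append(pt)
            eq_rows.append({
                "medium": medium["name"], "temperature_c": T_k - 273.15,
                "ph": ana["ph"], "c_M": dec.c_M, "c_D": dec.c_D,
                "r_squared": dec.r_squared, "pKa_app": pt.pKa_app,
            })
        vh = vant_hoff(points)
        pka_slope = float(
            stats.linregress([p.temperature - 273.15 for p in points],
                             [p.pKa_app for p in points]).slope
        )

        # pKa at 25 degC from a pH titration series
        series = generate_absorption_series(gt, ana["ph_series"], [T_REF_K], deltaf)
        ref25 = generate_species_references(gt, T_REF_K, deltaf)
        pka25 = pKa_from_series([
            compute_Ka(decompose(s, ref25, ana["fit_range_nm"]), s.meta.ph, T_REF_K)
            for s in series
        ])

        # ratiometric temperature sensitivity
        ratio_points = []
        for T_k in T_list:
            em488, em435 = generate_emission_pair(
                gt, ana["ph"], T_k, ana["lamp_ratio"], deltaf,
                medium["cosolvent"], medium["mass_fraction_percent"],
            )
            em435 = lamp_correct(em435, ana["lamp_ratio"])
            pt = ratiometric_signal(em488, em435, ana["integration_range_nm"],
                                    medium=medium["name"])
            ratio_points.append(pt)
            ratio_rows.append({
                "medium": medium["name"], "temperature_c": T_k - 273.15,
                "I488": pt.I488, "I435": pt.I435, "R": pt.R,
            })
        sens = sensitivity_fit(ratio_points, "temperature")

        # excited-state shift from 0-0 origins of the pure forms at 25 degC
        nu00 = {}
        for species in ("M", "D"):
            absorption, emission = generate_pure_species_spectra(gt, species, T_REF_K, deltaf)
            nu00[species] = zero_zero_wavenumber(
                absorption_maximum(absorption), absorption_maximum(emission)
            )
        dpka_star = forster_weller(
            PhotoState(nu00_D=nu00["D"], nu00_M=nu00["M"], temperature_k=T_REF_K)
        )

        report_rows[medium["name"]] = {
            "cosolvent": medium["cosolvent"],
            "mass_fraction_percent": medium["mass_fraction_percent"],
            "deltaf": deltaf,
            "ratiometric_T_sensitivity_per_C": sens.slope,
            "ratiometric_T_sensitivity_1e-2_per_C": sens.slope * 100.0,
            "ratiometric_fit_r_squared": sens.r_squared,
            "pKa_app_25C": pka25,
            "pKa_T_shift_per_C": pka_slope,
            "dH_J_per_mol": vh.dH,
            "dH_r_squared": vh.r_squared,
            "dpKa_excited_state": dpka_star,
            "ground_truth": {"dH_true": gt.dH_true, "pKa_at_25C": gt.pKa_at_25C,
                             "noise_rel": gt.noise_rel, "seed": gt.seed},
        }
    pd.DataFrame(eq_rows).to_csv(out / "equilibrium.csv", index=False)
    pd.DataFrame(ratio_rows).to_csv(out / "ratiometric.csv", index=False)
    return report_rows


def _solvation_stage(cfg: RunConfig, out: Path) -> dict:
    box_kwargs = dict(cfg.box)
    gt = BoxGroundTruth(seed=cfg.seed * 1000 + 777, **box_kwargs)
    frames = generate_solvation_box(gt)
    ana = cfg.analysis
    bonds = [detect_hbonds(fr, ana["d_max_nm"], ana["a_max_deg"]) for fr in frames]
    occ = occupancy(bonds, len(frames))
    occ_rows = [
        {"acceptor": acc, "state": state, "fraction": frac}
        for acc, states in occ.fractions.items()
        for state, frac in states.items()
    ]
    pd.DataFrame(occ_rows).to_csv(out / "occupancy.csv", index=False)

    m = mddf(frames, bin_width_nm=ana["mddf_bin_nm"], seed=cfg.seed * 1000 + 778)
    mddf_rows = []
    for sp, values in m.mddf.items():
        for r, g, n_cum in zip(m.r, values, m.n_cumulative[sp]):
            mddf_rows.append({"r_nm": r, "species": sp, "mddf": g, "n_cumulative": n_cum})
    pd.DataFrame(mddf_rows).to_csv(out / "mddf.csv", index=False)

    gamma_cos = preferential_interaction(m, ana["r_cut_nm"])
    gamma_wat = preferential_interaction(m, ana["r_cut_nm"], species="WAT")
    return {
        "box_ground_truth": {k: getattr(gt, k) for k in (
            "box_edge", "n_water", "n_cosolvent", "cosolvent", "enrichment",
            "shell_radius", "hbond_fraction", "n_frames", "seed")},
        "occupancy": occ.fractions,
        "gamma": {
            gamma_cos.species: gamma_cos.gamma,
            "WAT": gamma_wat.gamma,
        },
        "r_cut_nm": ana["r_cut_nm"],
    }


def run(config, out_dir) -> dict:
    """Execute the configured pipeline; returns the report dictionary.

    Writes resolved-config.yaml, per-stage CSV tables and report.json into
    the run directory (suffixed if the target already holds output).
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out = _prepare_out_dir(out_dir)
    (out / "resolved-config.yaml").write_text(cfg.resolved_yaml())
    report = {
        "provenance": {
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "package_version": __version__,
        },
        "mode": cfg.mode,
    }
    try:
        if cfg.mode in ("spectra", "full"):
            log.info("stage: spectra")
            report["media"] = _spectra_stage(cfg, out)
        if cfg.mode in ("solvation", "full"):
            log.info("stage: solvation")
            report["solvation"] = _solvation_stage(cfg, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline stage failed in mode {cfg.mode}: {exc}") from exc
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
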