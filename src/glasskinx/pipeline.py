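"""End-to-end simulate → analyze → report runs driven by one YAML config.

A run produces, per named annealing condition, the four report tables of a
cold-crystallization stability study:

* ``features.csv`` — heating-rate dependence of onset temperature, cold
  crystallization enthalpy, total fusion enthalpy and the form II / form I
  enthalpy ratio (one row per condition × heating rate);
* ``avrami.csv`` — t10 and Avrami exponent from the quasi-isothermal traces;
* ``kas.csv`` — isoconversional activation energies, intercepts, apparent
  frequency factors and ANCOVA p-values;
* ``pxrd_areas.csv`` — normalized split pseudo-Voigt peak areas;
* ``dissolution.csv`` — first-point-corrected concentration traces;

plus a ``manifest.json`` recording the seed, package version, per-file
SHA-256 hashes and a combined content hash. Reruns with the same config are
bit-identical (timings are recorded outside the hashed content).

Every random draw flows from the config seed through a stable per-stage
substream (SHA-256 of ``"<seed>:<stream name>"``), so adding a stage never
reshuffles another stage's noise.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .avrami import fit_trace
from .kas import kas_summary
from .profiles import SplitPVPeak
from .pxrd import fit_profile, normalized_area
from .synthetic import (
    simulate_dissolution,
    simulate_isothermal_trace,
    simulate_nonisothermal_thermogram,
    simulate_pxrd,
)
from .thermo import correct_concentration
from .thermogram import conversion_curve, deconvolve_melting, integrate_peak, \
    onset_temperature
from .types import (
    ArrheniusAvramiKinetics,
    NoiseSpec,
    Segment,
    TemperatureProgram,
    ThermoParams,
)
from . import io as gio

__all__ = ["PipelineError", "default_config", "run_pipeline", "derive_seed"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(base_seed: int, stream: str) -> int:
    """Stable substream seed below 2^31 from a base seed and a name."""
    digest = hashlib.sha256(f"{base_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def default_config() -> dict:
    """Demo configuration: two annealing conditions, three heating rates."""
    return {
        "seed": 1,
        "alphas": [0.05, 0.10],
        "edge_count": 100,
        "rates_K_min": [0.5, 1.0, 2.0],
        "exo_window_C": [82.0, 140.0],
        "melt_window_C": [140.5, 157.0],
        "conditions": [
            {
                "name": "annealed_-20C_40d",
                "kinetics": {"Ea_kJ_mol": 134.0, "lnA": 39.4102, "n": 4.7,
                             "alpha0": 1.0e-4},
                "ratio_II_I": 7.4,
                "avrami": {"t10_min": 13.6, "n": 4.7},
                "pxrd_areas": {6.8: 43, 16.1: 1000, 16.6: 267, 19.0: 437,
                               19.7: 64},
            },
            {
                "name": "annealed_25C_40d",
                "kinetics": {"Ea_kJ_mol": 115.0, "lnA": 32.6858, "n": 4.1,
                             "alpha0": 1.0e-5},
                "ratio_II_I": 5.4,
                "avrami": {"t10_min": 18.3, "n": 4.1},
                "pxrd_areas": {6.8: 53, 16.1: 1000, 16.6: 287, 19.0: 396,
                               19.7: 156},
            },
        ],
        "isothermal": {"hold_temp_C": 100.0, "duration_min": 120.0,
                       "dt_min": 0.01, "cp_amorphous": 2.1, "cp_crystal": 1.5},
        "noise": {"dsc_mW_mg": 0.0005, "mdsc_J_gK": 0.002,
                  "pxrd_counts": 2.0, "dissolution_ug_mL": 0.2},
        "pxrd": {
            "grid": [2.5, 40.0, 0.01],
            "fwhm_deg": 0.14,
            "background": [60.0, -0.8],
            "form_labels": {6.8: "form I", 16.1: "form II", 16.6: "form I",
                            19.0: "form II", 19.7: "form I"},
        },
        "dissolution": {"peak_time_h": 24.0, "c_max": 55.0, "c_final": 18.0,
                        "first_point_bias": 0.9, "duration_h": 48.0,
                        "dt_min": 10.0, "nominal_ug_mL": 40.0},
    }


def _kin(spec: dict) -> ArrheniusAvramiKinetics:
    return ArrheniusAvramiKinetics(
        Ea_J_mol=spec["Ea_kJ_mol"] * 1e3, lnA=spec["lnA"], n=spec["n"],
        alpha0=spec.get("alpha0", 0.0),
    )


def _kas_program(rate: float) -> TemperatureProgram:
    """Fast ramp to 80 °C, a 1-min hold, then the slow analysis ramp."""
    return TemperatureProgram((
        Segment("ramp", 25.0, 80.0, rate_C_min=10.0),
        Segment("isothermal", 80.0, 80.0, duration_min=1.0),
        Segment("ramp", 80.0, 160.0, rate_C_min=rate),
    ))


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full simulate → analyze → report pipeline.

    ``config`` is a dict or path to a YAML file (see ``default_config``).
    Returns the manifest dict; all tables are written under ``outdir``.
    """
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "traces").mkdir(exist_ok=True)

    seed = int(config["seed"])
    noise_cfg = config.get("noise", {})
    timings: dict[str, float] = {}
    files: list[Path] = []
    thermo = ThermoParams()

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise PipelineError(name, exc) from exc
        return _Ctx()

    thermograms: dict[str, dict[float, object]] = {}
    with _stage("simulate_dsc"):
        for cond in config["conditions"]:
            thermograms[cond["name"]] = {}
            for rate in config["rates_K_min"]:
                tg = simulate_nonisothermal_thermogram(
                    kin=_kin(cond["kinetics"]),
                    program=_kas_program(rate),
                    thermo=thermo,
                    ratio_II_I=cond.get("ratio_II_I", 7.4),
                    noise=NoiseSpec(
                        sd=noise_cfg.get("dsc_mW_mg", 0.0),
                        seed=derive_seed(seed, f"dsc:{cond['name']}:{rate}"),
                    ),
                    max_dT_C=0.05,
                )
                thermograms[cond["name"]][rate] = tg
                f = gio.write_thermogram(
                    tg, outdir / "traces" /
                    f"dsc_{cond['name']}_{rate:g}Kmin.csv")
                files += [f, f.with_suffix(".meta.yaml")]

    with _stage("features"):
        exo_w = tuple(config["exo_window_C"])
        melt_w = tuple(config["melt_window_C"])
        rows = []
        for cond in config["conditions"]:
            for rate in config["rates_K_min"]:
                tg = thermograms[cond["name"]][rate]
                onset = onset_temperature(tg, exo_w, kind="exo")
                if tg.incomplete_crystallization:
                    dHc = float("nan")
                else:
                    dHc = integrate_peak(tg, exo_w).enthalpy_J_g
                melt = deconvolve_melting(tg, melt_w)
                rows.append({
                    "condition": cond["name"], "rate_K_min": rate,
                    "T_onset_C": onset.T_onset_C if onset.found else float("nan"),
                    "dHc_J_g": dHc,
                    "dHf_J_g": melt.dHf_I_J_g + melt.dHf_II_J_g,
                    "ratio_II_I": melt.ratio_II_I,
                    "incomplete": tg.incomplete_crystallization,
                })
        feats = pd.DataFrame(rows)
        feats.to_csv(outdir / "features.csv", index=False)
        files.append(outdir / "features.csv")

    with _stage("avrami"):
        iso = config["isothermal"]
        rows = []
        avrami_n: dict[str, float] = {}
        for cond in config["conditions"]:
            trace = simulate_isothermal_trace(
                t10=cond["avrami"]["t10_min"], n=cond["avrami"]["n"],
                cp_amorphous=iso["cp_amorphous"], cp_crystal=iso["cp_crystal"],
                duration=iso["duration_min"], dt=iso["dt_min"],
                hold_temp_C=iso["hold_temp_C"],
                noise=NoiseSpec(sd=noise_cfg.get("mdsc_J_gK", 0.0),
                                seed=derive_seed(seed, f"mdsc:{cond['name']}")),
            )
            f = gio.write_modulated(
                trace, outdir / "traces" / f"mdsc_{cond['name']}.csv")
            files += [f, f.with_suffix(".meta.yaml")]
            fit = fit_trace(trace, edge_count=int(config.get("edge_count", 100)))
            avrami_n[cond["name"]] = fit.n
            rows.append({
                "condition": cond["name"],
                "hold_temp_C": iso["hold_temp_C"],
                "t10_min": fit.t10_min, "avrami_exponent": fit.n,
                "rss": fit.rss, "converged": fit.converged,
            })
        pd.DataFrame(rows).to_csv(outdir / "avrami.csv", index=False)
        files.append(outdir / "avrami.csv")

    with _stage("kas"):
        exo_w = tuple(config["exo_window_C"])
        curves = {
            cond["name"]: [
                conversion_curve(thermograms[cond["name"]][rate], exo_w)
                for rate in config["rates_K_min"]
            ]
            for cond in config["conditions"]
        }
        kas_df = kas_summary(curves, config["alphas"], avrami_n)
        kas_df.to_csv(outdir / "kas.csv", index=False)
        files.append(outdir / "kas.csv")

    with _stage("pxrd"):
        px = config["pxrd"]
        rows = []
        for cond in config["conditions"]:
            ref_amp = 2000.0
            peaks = []
            areas = cond["pxrd_areas"]
            ref = areas[16.1]
            for center, norm in areas.items():
                shape = SplitPVPeak(center, 1.0, px["fwhm_deg"],
                                    px["fwhm_deg"] * 1.3, 0.4, 0.4)
                amp = ref_amp * (norm / ref) / shape.area
                peaks.append(SplitPVPeak(center, amp, px["fwhm_deg"],
                                         px["fwhm_deg"] * 1.3, 0.4, 0.4))
            pattern = simulate_pxrd(
                peaks, background=px["background"], grid=tuple(px["grid"]),
                noise=NoiseSpec(sd=noise_cfg.get("pxrd_counts", 0.0),
                                seed=derive_seed(seed, f"pxrd:{cond['name']}")),
            )
            f = gio.write_pattern(
                pattern, outdir / "traces" / f"pxrd_{cond['name']}.xy")
            files.append(f)
            init = [
                SplitPVPeak(c, a.amplitude * 0.8, px["fwhm_deg"],
                            px["fwhm_deg"], 0.5, 0.5)
                for c, a in zip(areas, peaks)
            ]
            model = fit_profile(pattern, init, background_degree=1)
            table = normalized_area(
                model.peaks_,
                labels={float(k): v for k, v in px["form_labels"].items()},
            )
            table.insert(0, "condition", cond["name"])
            rows.append(table)
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "pxrd_areas.csv", index=False)
        files.append(outdir / "pxrd_areas.csv")

    with _stage("dissolution"):
        d = config["dissolution"]
        rows = []
        for cond in config["conditions"]:
            trace = simulate_dissolution(
                peak_time=d["peak_time_h"], c_max=d["c_max"],
                c_final=d["c_final"],
                first_point_bias=d["first_point_bias"],
                duration=d["duration_h"], dt=d["dt_min"],
                nominal=d["nominal_ug_mL"],
                noise=NoiseSpec(sd=noise_cfg.get("dissolution_ug_mL", 0.0),
                                seed=derive_seed(seed, f"diss:{cond['name']}")),
            )
            corrected = correct_concentration(trace)
            rows.append(pd.DataFrame({
                "condition": cond["name"],
                "time_h": corrected.time_h,
                "conc_corrected_ug_mL": corrected.conc_ug_mL,
            }))
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "dissolution.csv", index=False)
        files.append(outdir / "dissolution.csv")

    with _stage("manifest"):
        hashes = {
            str(f.relative_to(outdir)):
                hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(set(files))
        }
        content_hash = hashlib.sha256(
            json.dumps(hashes, sort_keys=True).encode()
        ).hexdigest()
        manifest = {
            "seed": seed,
            "version": __version__,
            "files": hashes,
            "content_hash": content_hash,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
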