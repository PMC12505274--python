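"""Plain-text I/O: CSV thermal traces with YAML sidecars, XY powder patterns.

Thermal traces are written as CSV with unit-bearing headers
(``time_min, temp_C, heat_flow_mW_per_mg`` or ``time_min, cp_J_per_gK``)
plus a ``<stem>.meta.yaml`` sidecar holding the mass, program and metadata.
Powder patterns are two-column whitespace-delimited XY files
(two_theta_deg, intensity_counts).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    DissolutionTrace,
    ModulatedTrace,
    PXRDPattern,
    Segment,
    TemperatureProgram,
    Thermogram,
)

__all__ = [
    "write_thermogram", "read_thermogram",
    "write_modulated", "read_modulated",
    "write_pattern", "read_pattern",
    "write_dissolution", "read_dissolution",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def _program_to_dict(program: TemperatureProgram | None) -> list | None:
    if program is None:
        return None
    return [
        {"kind": s.kind, "start_T": s.T_start_C, "end_T": s.T_end_C,
         "rate": s.rate_C_min, "duration": s.duration_min}
        for s in program.segments
    ]


def _program_from_dict(spec: list | None) -> TemperatureProgram | None:
    if spec is None:
        return None
    return TemperatureProgram(tuple(
        Segment(d["kind"], d["start_T"], d["end_T"],
                rate_C_min=d.get("rate", 0.0),
                duration_min=d.get("duration", 0.0))
        for d in spec
    ))


def write_thermogram(tg: Thermogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_min": tg.time_min,
        "temp_C": tg.temp_C,
        "heat_flow_mW_per_mg": tg.heat_flow,
    }).to_csv(path, index=False)
    meta = {
        "signal": "heat_flow_mW_per_mg",
        "sign_convention": "endothermic up",
        "mass_mg": tg.mass_mg,
        "incomplete_crystallization": bool(tg.incomplete_crystallization),
        "program": _program_to_dict(tg.program),
        "meta": _plain(tg.meta),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_thermogram(path: str | Path) -> Thermogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    return Thermogram(
        time_min=df["time_min"].to_numpy(),
        temp_C=df["temp_C"].to_numpy(),
        heat_flow=df["heat_flow_mW_per_mg"].to_numpy(),
        mass_mg=float(meta.get("mass_mg", 1.0)),
        program=_program_from_dict(meta.get("program")),
        incomplete_crystallization=bool(
            meta.get("incomplete_crystallization", False)
        ),
        meta=meta.get("meta", {}),
    )


def write_modulated(trace: ModulatedTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_min": trace.time_min,
        "cp_J_per_gK": trace.cp_J_gK,
    }).to_csv(path, index=False)
    meta = {
        "signal": "cp_J_per_gK",
        "hold_temp_C": trace.hold_temp_C,
        "meta": _plain(trace.meta),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_modulated(path: str | Path) -> ModulatedTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    return ModulatedTrace(
        time_min=df["time_min"].to_numpy(),
        cp_J_gK=df["cp_J_per_gK"].to_numpy(),
        hold_temp_C=float(meta.get("hold_temp_C", float("nan"))),
        meta=meta.get("meta", {}),
    )


def write_pattern(pattern: PXRDPattern, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([pattern.two_theta_deg, pattern.intensity]),
        fmt="%.6g",
        header="two_theta_deg intensity_counts",
    )
    return path


def read_pattern(path: str | Path) -> PXRDPattern:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pattern file not found: {path}")
    data = np.loadtxt(path)
    return PXRDPattern(data[:, 0], data[:, 1])


def write_dissolution(trace: DissolutionTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_h": trace.time_h,
        "conc_ug_mL": trace.conc_ug_mL,
    }).to_csv(path, index=False)
    meta = {"nominal_ug_mL": trace.nominal_ug_mL, "meta": _plain(trace.meta)}
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_dissolution(path: str | Path, nominal_ug_mL: float | None = None
                     ) -> DissolutionTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    if nominal_ug_mL is None:
        nominal_ug_mL = float(meta.get("nominal_ug_mL", 40.0))
    return DissolutionTrace(
        time_h=df["time_h"].to_numpy(),
        conc_ug_mL=df["conc_ug_mL"].to_numpy(),
        nominal_ug_mL=nominal_ug_mL,
        meta=meta.get("meta", {}),
    )


def _plain(obj):
    """Recursively convert numpy scalars so YAML stays readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
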