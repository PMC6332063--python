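"""Plain-text I/O for titration data.

Two small CSV dialects, both with ``# key: value`` metadata header lines:

NMR titration::

    # temperature_K: 298.0
    # owners: NH=host,CH3=guest
    H0_M,G0_M,NH,CH3
    1.6e-3,0.0,7.400,

ITC thermogram::

    # cell_conc_M: 0.0002
    # syringe_conc_M: 0.0014
    # cell_volume_mL: 1.4
    # temperature_K: 298.0
    injection_volume_uL,heat_ucal
    3.0,-21.05

Heats are stored in µcal and volumes in µL on disk (instrument units)
and converted to kcal / L in memory.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .equilibrium import ITCExperiment, TitrationPoint, TitrationSeries

__all__ = [
    "read_nmr_csv",
    "write_nmr_csv",
    "read_itc_csv",
    "write_itc_csv",
]

KCAL_PER_UCAL = 1e-9
L_PER_UL = 1e-6


def _read_metadata(path: Union[str, Path]) -> tuple[dict, str]:
    meta: dict[str, str] = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def write_nmr_csv(series: TitrationSeries, path: Union[str, Path]) -> None:
    owners = ",".join(f"{sid}={series.owners[sid]}" for sid in series.signals)
    lines = [
        f"# temperature_K: {series.temperature}",
        f"# owners: {owners}",
        "H0_M,G0_M," + ",".join(series.signals),
    ]
    for i, p in enumerate(series.points):
        shifts = []
        for sid in series.signals:
            v = series.signals[sid][i]
            shifts.append("" if np.isnan(v) else f"{v:.6f}")
        lines.append(f"{p.H0:.10g},{p.G0:.10g}," + ",".join(shifts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_nmr_csv(path: Union[str, Path]) -> TitrationSeries:
    meta, body = _read_metadata(path)
    df = pd.read_csv(_io.StringIO(body))
    if "H0_M" not in df or "G0_M" not in df:
        raise ValueError(f"{path}: missing H0_M/G0_M columns")
    owners = {}
    for item in meta.get("owners", "").split(","):
        if "=" in item:
            sid, _, owner = item.partition("=")
            owners[sid.strip()] = owner.strip()
    points = [
        TitrationPoint(float(h), float(g)) for h, g in zip(df["H0_M"], df["G0_M"])
    ]
    signal_cols = [c for c in df.columns if c not in ("H0_M", "G0_M")]
    signals = {c: df[c].to_numpy(dtype=float) for c in signal_cols}
    missing = [c for c in signal_cols if c not in owners]
    if missing:
        raise ValueError(f"{path}: no owner metadata for signal(s) {missing}")
    return TitrationSeries(
        points=points,
        signals=signals,
        owners={c: owners[c] for c in signal_cols},
        temperature=float(meta.get("temperature_K", 298.0)),
    )


def write_itc_csv(exp: ITCExperiment, path: Union[str, Path]) -> None:
    if exp.heats is None:
        raise ValueError("experiment has no heats to write")
    lines = [
        f"# cell_conc_M: {exp.cell_conc:.10g}",
        f"# syringe_conc_M: {exp.syringe_conc:.10g}",
        f"# cell_volume_mL: {exp.cell_volume * 1e3:.10g}",
        f"# temperature_K: {exp.temperature}",
        "injection_volume_uL,heat_ucal",
    ]
    for v, q in zip(exp.injection_volumes, exp.heats):
        lines.append(f"{v / L_PER_UL:.6g},{q / KCAL_PER_UCAL:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_itc_csv(path: Union[str, Path]) -> ITCExperiment:
    meta, body = _read_metadata(path)
    df = pd.read_csv(_io.StringIO(body))
    required = {"cell_conc_M", "syringe_conc_M", "cell_volume_mL"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"{path}: missing metadata {sorted(missing)}")
    return ITCExperiment(
        cell_conc=float(meta["cell_conc_M"]),
        syringe_conc=float(meta["syringe_conc_M"]),
        cell_volume=float(meta["cell_volume_mL"]) * 1e-3,
        injection_volumes=df["injection_volume_uL"].to_numpy(dtype=float) * L_PER_UL,
        heats=df["heat_ucal"].to_numpy(dtype=float) * KCAL_PER_UCAL,
        temperature=float(meta.get("temperature_K", 298.0)),
    )
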