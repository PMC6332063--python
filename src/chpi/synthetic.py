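"""Synthetic titration data and geometry fixtures.

Generators for every input the pipeline consumes, built on the exact
forward models of :mod:`chpi.equilibrium` plus i.i.d. Gaussian
measurement noise.  Defaults emulate the study conditions: ~1.6 mM host
solutions titrated past 10 guest equivalents under fast exchange, NH
signals moving ~+2 ppm downfield and bound guest methyls ~−0.5 ppm
upfield, and calorimetric runs injecting 3 µL aliquots of a syringe
solution seven times the 0.2 mM cell concentration.  Default noise
levels (0.005 ppm on shifts, 0.1 µcal on heats) are typical instrument
precision for a 400 MHz spectrometer and a VP-ITC cell.

Every generator is a pure function of (scenario, seed): one fresh
seeded ``numpy`` generator per call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decomposition import HostRecord
from .equilibrium import (
    ITCExperiment,
    ITCModelParams,
    TitrationPoint,
    TitrationSeries,
    predict_itc_heats,
    predict_shift,
)
from .geometry import RingDefinition, StructureCoordinates

__all__ = [
    "SignalSpec",
    "NMRScenario",
    "ITCScenario",
    "PaperScenario",
    "GeometryFixture",
    "generate_nmr_titration",
    "generate_itc",
    "generate_complex_geometry",
    "paper_scenarios",
]

#: Default per-shift noise, ppm.
DEFAULT_NMR_NOISE_PPM = 0.005
#: Default per-injection heat noise, kcal (0.1 µcal; 1 µcal = 1e-9 kcal).
DEFAULT_ITC_NOISE_KCAL = 1e-10


@dataclass(frozen=True)
class SignalSpec:
    """Limiting shifts of one observed signal: owner, δ_free, δ_bound (ppm)."""

    owner: str  # "host" | "guest"
    delta_free: float
    delta_bound: float


def _default_signals() -> Dict[str, SignalSpec]:
    # NH moves downfield by ~2 ppm on binding; guest methyls ~0.5 ppm upfield.
    return {"NH": SignalSpec("host", 7.4, 9.4)}


@dataclass(frozen=True)
class NMRScenario:
    """Design of one synthetic NMR titration."""

    K_true: float
    H0: float = 1.6e-3
    equivalents: Tuple[float, ...] = tuple(np.linspace(0.0, 12.0, 14))
    signals: Dict[str, SignalSpec] = field(default_factory=_default_signals)
    noise_sd: float = DEFAULT_NMR_NOISE_PPM
    dilution: bool = False
    titrant_stock_factor: float = 100.0  # guest stock conc. as multiple of H0
    temperature: float = 298.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true <= 0 or self.H0 <= 0:
            raise ValueError("K_true and H0 must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(np.diff(self.equivalents) < 0):
            raise ValueError("equivalents must be non-decreasing")


@dataclass(frozen=True)
class ITCScenario:
    """Design of one synthetic calorimetric titration."""

    K_true: float
    dH_true: float = -5.0  # kcal/mol
    n_true: float = 1.0
    cell_conc: float = 2e-4  # M
    syringe_factor: float = 7.0  # syringe conc. as multiple of cell conc.
    cell_volume: float = 1.4e-3  # L
    injection_volume: float = 3e-6  # L
    n_injections: int = 25
    noise_sd: float = DEFAULT_ITC_NOISE_KCAL  # kcal
    temperature: float = 298.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true <= 0 or self.syringe_factor <= 0:
            raise ValueError("K_true and syringe_factor must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_nmr_titration(scenario: NMRScenario) -> TitrationSeries:
    """Simulate a fast-exchange titration; shifts = forward model + N(0, σ²).

    Without dilution the host concentration is constant and only G0
    grows.  With ``dilution`` the guest comes from a stock at
    ``titrant_stock_factor × H0`` and both totals follow the volume
    bookkeeping of adding that stock to the initial host solution.
    Guest-owned signals are NaN at G0 = 0 (no guest to observe).
    """
    rng = np.random.default_rng(scenario.seed)
    points = []
    for eq in scenario.equivalents:
        if not scenario.dilution:
            points.append(TitrationPoint(H0=scenario.H0, G0=eq * scenario.H0))
        else:
            # v/V0 to reach `eq` equivalents from a stock c_g = f * H0:
            # eq = c_g v / (H0 V0)  =>  v/V0 = eq / f
            ratio = eq / scenario.titrant_stock_factor
            dil = 1.0 / (1.0 + ratio)
            points.append(
                TitrationPoint(
                    H0=scenario.H0 * dil,
                    G0=scenario.titrant_stock_factor * scenario.H0 * ratio * dil,
                )
            )
    signals: Dict[str, np.ndarray] = {}
    owners: Dict[str, str] = {}
    for sid, spec in scenario.signals.items():
        obs = np.empty(len(points))
        for i, p in enumerate(points):
            if spec.owner == "guest" and p.G0 == 0.0:
                obs[i] = np.nan
                continue
            obs[i] = predict_shift(
                p, scenario.K_true, spec.delta_free, spec.delta_bound, spec.owner
            )
        noise = rng.normal(0.0, scenario.noise_sd, size=obs.size)
        signals[sid] = np.where(np.isnan(obs), np.nan, obs + noise)
        owners[sid] = spec.owner
    return TitrationSeries(
        points=points, signals=signals, owners=owners,
        temperature=scenario.temperature,
    )


def generate_itc(scenario: ITCScenario) -> ITCExperiment:
    """Simulate a thermogram; heats = perfusion forward model + N(0, σ²)."""
    rng = np.random.default_rng(scenario.seed)
    exp = ITCExperiment(
        cell_conc=scenario.cell_conc,
        syringe_conc=scenario.syringe_factor * scenario.cell_conc,
        cell_volume=scenario.cell_volume,
        injection_volumes=np.full(scenario.n_injections, scenario.injection_volume),
        temperature=scenario.temperature,
    )
    params = ITCModelParams(
        n=scenario.n_true, K=scenario.K_true, dH=scenario.dH_true
    )
    heats = predict_itc_heats(exp, params)
    exp.heats = heats + rng.normal(0.0, scenario.noise_sd, size=heats.size)
    return exp


# ---------------------------------------------------------------------------
# bundled study scenarios


@dataclass(frozen=True)
class PaperScenario:
    """One host × guest system: tabulated K, ESP, walls and the method used."""

    host_id: str
    guest_id: str
    n_walls: int
    substituent: str
    esp: Optional[float]
    method: str  # "NMR" | "ITC"
    K: float
    K_sigma: float

    @property
    def host(self) -> HostRecord:
        return HostRecord(
            host_id=self.host_id,
            n_walls=self.n_walls,
            esp=self.esp,
            substituent=self.substituent,
        )

    def nmr_scenario(self, seed: int = 0, noise_sd: float = DEFAULT_NMR_NOISE_PPM
                     ) -> NMRScenario:
        return NMRScenario(K_true=self.K, seed=seed, noise_sd=noise_sd)

    def itc_scenario(self, seed: int = 0, noise_sd: float = DEFAULT_ITC_NOISE_KCAL
                     ) -> ITCScenario:
        return ITCScenario(K_true=self.K, seed=seed, noise_sd=noise_sd)


def paper_scenarios(path: Optional[str] = None) -> List[PaperScenario]:
    """The 12 bundled host × guest systems with their tabulated constants.

    NMR is the recommended protocol for K < 10⁴ M⁻¹ (fast exchange,
    measurable shift curvature); above that the complexes are in slow
    exchange and the constants come from ITC.
    """
    if path is None:
        src = resources.files("chpi.data") / "table1_scenarios.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        esp = None if pd.isna(row.esp_kcal_mol) else float(row.esp_kcal_mol)
        sub = "" if pd.isna(row.substituent) else str(row.substituent)
        out.append(
            PaperScenario(
                host_id=str(row.host_id),
                guest_id=str(row.guest_id),
                n_walls=int(row.n_walls),
                substituent=sub,
                esp=esp,
                method=str(row.method),
                K=float(row.K_M),
                K_sigma=float(row.K_sigma_M),
            )
        )
    return out


# ---------------------------------------------------------------------------
# geometry fixtures


@dataclass(frozen=True)
class GeometryFixture:
    """A constructed inclusion-complex geometry plus its atom selections."""

    structure: StructureCoordinates
    rings: Tuple[RingDefinition, ...]
    methyl_carbons: Tuple[str, ...]
    nh_o_pairs: Tuple[Tuple[str, str], ...]


def generate_complex_geometry(
    n_walls: int,
    d_contact: float = 3.5,
    perturbation: float = 0.0,
    seed: int = 0,
    nh_o_distance: float = 2.095,
) -> GeometryFixture:
    """Construct an idealised walled inclusion complex.

    A central guest (N with an apical O and ``n_walls`` methyl carbons)
    is surrounded by ``n_walls`` regular hexagonal rings (C–C 1.39 Å),
    each placed with its centroid exactly ``d_contact`` Å from one
    methyl carbon along the ring normal.  Four NH hydrogens sit
    ``nh_o_distance`` Å from the oxygen.  Optional Gaussian jitter of
    standard deviation ``perturbation`` (Å) is added to every
    coordinate.  Purely synthetic — a fixture with known ground truth,
    not an experimental structure.
    """
    if n_walls not in (2, 4):
        raise ValueError(f"n_walls must be 2 or 4, got {n_walls}")
    rng = np.random.default_rng(seed)

    ids: List[str] = []
    elements: List[str] = []
    coords: List[np.ndarray] = []

    def add(el: str, xyz) -> str:
        aid = f"{el}{len(ids) + 1}"
        ids.append(aid)
        elements.append(el)
        coords.append(np.asarray(xyz, dtype=float))
        return aid

    add("N", [0.0, 0.0, 0.0])
    o_id = add("O", [0.0, 0.0, 1.36])

    # four pyrrole NH hydrogens around the oxygen at the requested distance
    nh_pairs = []
    for k in range(4):
        ang = 2.0 * np.pi * k / 4.0
        tilt = np.array([np.cos(ang), np.sin(ang), 0.55])
        tilt /= np.linalg.norm(tilt)
        h_id = add("H", np.array([0.0, 0.0, 1.36]) + nh_o_distance * tilt)
        nh_pairs.append((h_id, o_id))

    angles = np.arange(n_walls) * (2.0 * np.pi / n_walls)
    rings: List[RingDefinition] = []
    methyls: List[str] = []
    for ang in angles:
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        methyl = add("C", 1.47 * u)
        methyls.append(methyl)
        centroid = 1.47 * u + d_contact * u
        v1 = np.array([0.0, 0.0, 1.0])
        v2 = np.cross(u, v1)
        ring_ids = []
        for t in np.arange(6) * (np.pi / 3.0):
            ring_ids.append(
                add("C", centroid + 1.39 * (np.cos(t) * v1 + np.sin(t) * v2))
            )
        rings.append(RingDefinition(tuple(ring_ids)))

    xyz = np.vstack(coords)
    if perturbation > 0:
        xyz = xyz + rng.normal(0.0, perturbation, size=xyz.shape)
    structure = StructureCoordinates(ids, elements, xyz, source="xyz")
    return GeometryFixture(
        structure=structure,
        rings=tuple(rings),
        methyl_carbons=tuple(methyls),
        nh_o_pairs=tuple(nh_pairs),
    )
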