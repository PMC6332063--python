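"""Forward models for 1:1 host–guest equilibria.

Three layers, each exact given the one above:

* :func:`solve_1to1` — speciation of the binding equilibrium
  H + G ⇌ HG from total concentrations and K, via the numerically
  stable root of the mass-balance quadratic;
* :func:`predict_shift` — fast-exchange NMR observed chemical shift as
  the population-weighted average of free and bound environments;
* :func:`predict_itc_heats` — heat evolved per injection in an
  overfilled-cell (perfusion) isothermal titration calorimetry run,
  the standard 1:1 Wiseman-type isotherm.

Concentrations are molar, volumes litres, energies kcal throughout;
conversion to instrument units (µcal, µL) happens only at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "SpeciesConcentrations",
    "ITCExperiment",
    "ITCModelParams",
    "solve_1to1",
    "predict_shift",
    "predict_itc_heats",
]


@dataclass(frozen=True)
class TitrationPoint:
    """Total (analytical) host and guest concentrations at one titration point."""

    H0: float  # total host, M
    G0: float  # total guest, M

    def __post_init__(self) -> None:
        if self.H0 <= 0:
            raise ValueError(f"total host concentration must be > 0, got {self.H0}")
        if self.G0 < 0:
            raise ValueError(f"total guest concentration must be >= 0, got {self.G0}")


@dataclass
class TitrationSeries:
    """An NMR titration: points plus observed shifts for one or more signals.

    ``signals`` maps a signal id to the per-point observed shift (ppm);
    ``owners`` says whether each signal belongs to a host or a guest
    nucleus, which decides the bound-fraction normalisation.  Guest-owned
    signals are undefined where G0 = 0 and may hold NaN there.
    """

    points: List[TitrationPoint]
    signals: Dict[str, np.ndarray]
    owners: Dict[str, str]
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a titration series needs at least 2 points")
        n = len(self.points)
        for sid, values in self.signals.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != (n,):
                raise ValueError(
                    f"signal {sid!r} has {arr.size} values for {n} points"
                )
            self.signals[sid] = arr
            owner = self.owners.get(sid)
            if owner not in ("host", "guest"):
                raise ValueError(f"signal {sid!r} owner must be 'host' or 'guest'")

    @property
    def H0(self) -> np.ndarray:
        return np.array([p.H0 for p in self.points])

    @property
    def G0(self) -> np.ndarray:
        return np.array([p.G0 for p in self.points])


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Equilibrium concentrations of free host, free guest and complex (M)."""

    free_host: float
    free_guest: float
    complex: float


@dataclass
class ITCExperiment:
    """One calorimetric titration: schedule, heats and cell metadata.

    ``heats`` are the measured (or simulated) heats per injection in kcal,
    reference/dilution heats already subtracted; ``None`` for a schedule
    that has not been measured yet.
    """

    cell_conc: float  # initial host concentration in the cell, M
    syringe_conc: float  # guest concentration in the syringe, M
    cell_volume: float  # active cell volume, L
    injection_volumes: np.ndarray  # per-injection volume, L
    heats: Optional[np.ndarray] = None  # kcal per injection
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be > 0")
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("cell and syringe concentrations must be > 0")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be > 0")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise ValueError("heats and injection_volumes differ in length")

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes.size)


@dataclass(frozen=True)
class ITCModelParams:
    """1:1 isotherm parameters: stoichiometry n, K (M^-1), ΔH (kcal/mol)."""

    n: float
    K: float
    dH: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")


def solve_1to1(H0: float, G0: float, K: float) -> SpeciesConcentrations:
    """Exact speciation of H + G ⇌ HG for totals ``H0``, ``G0`` and constant ``K``.

    The complex concentration is the physical root of
    ``K (H0 − x)(G0 − x) = x``.  It is evaluated as
    ``x = 2 H0 G0 / (b + sqrt(b² − 4 H0 G0))`` with ``b = H0 + G0 + 1/K``,
    which avoids the subtractive cancellation of the textbook quadratic
    formula for any K.  A bisection refinement kicks in if floating-point
    error ever leaves the mass-balance residual above 1e-10 relative.
    """
    if H0 <= 0:
        raise ValueError(f"H0 must be > 0, got {H0}")
    if G0 < 0:
        raise ValueError(f"G0 must be >= 0, got {G0}")
    if K <= 0:
        raise ValueError(f"K must be > 0, got {K}")
    if G0 == 0.0:
        return SpeciesConcentrations(free_host=H0, free_guest=0.0, complex=0.0)

    b = H0 + G0 + 1.0 / K
    disc = b * b - 4.0 * H0 * G0
    if disc < 0.0:  # only reachable through rounding; clamp
        disc = 0.0
    x = 2.0 * H0 * G0 / (b + np.sqrt(disc))
    x = min(x, H0, G0)

    # Residual check in units of the dominant term; refine by bisection if needed.
    scale = max(K * H0 * G0, x)
    resid = abs(K * (H0 - x) * (G0 - x) - x)
    if resid > 1e-10 * scale:
        lo, hi = 0.0, min(H0, G0)
        f = lambda t: K * (H0 - t) * (G0 - t) - t  # noqa: E731
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0.0:
                lo = mid
            else:
                hi = mid
        x = 0.5 * (lo + hi)

    return SpeciesConcentrations(
        free_host=max(H0 - x, 0.0), free_guest=max(G0 - x, 0.0), complex=x
    )


def predict_shift(
    point: TitrationPoint,
    K: float,
    delta_free: float,
    delta_bound: float,
    owner: str = "host",
) -> float:
    """Fast-exchange observed shift (ppm) at one titration point.

    δ_obs = δ_free + f_bound (δ_bound − δ_free), where the bound fraction
    normalises by total host for host-owned signals and by total guest
    for guest-owned ones.
    """
    if owner not in ("host", "guest"):
        raise ValueError(f"owner must be 'host' or 'guest', got {owner!r}")
    species = solve_1to1(point.H0, point.G0, K)
    if owner == "host":
        f_bound = species.complex / point.H0
    else:
        if point.G0 == 0.0:
            raise ValueError(
                "guest-owned signal is undefined at zero total guest concentration"
            )
        f_bound = species.complex / point.G0
    return delta_free + f_bound * (delta_bound - delta_free)


def predict_itc_heats(exp: ITCExperiment, params: ITCModelParams) -> np.ndarray:
    """Heat per injection (kcal) for a 1:1 isotherm in a perfusion cell.

    The cell holds a fixed active volume V0; each injection of volume v_i
    displaces an equal volume of pre-injection cell contents, so existing
    concentrations are scaled by (1 − v_i/V0) before the fresh titrant
    (syringe_conc · v_i/V0) is added.  With [HG]_i the complex
    concentration after equilibration of injection i (site concentration
    n·[H]_total in the 1:1 solver),

        q_i = ΔH · V0 · ([HG]_i − [HG]_{i−1} · (1 − v_i/V0)).

    The subtracted term removes complex carried over from the previous
    equilibrium (less the displaced share), so q_i is the heat of newly
    formed complex only.
    """
    V0 = exp.cell_volume
    H_tot = exp.cell_conc
    G_tot = 0.0
    bound_prev = 0.0
    heats = np.empty(exp.n_injections)
    for i, v in enumerate(exp.injection_volumes):
        dil = 1.0 - v / V0
        H_tot *= dil
        G_tot = G_tot * dil + exp.syringe_conc * v / V0
        bound = solve_1to1(params.n * H_tot, G_tot, params.K).complex
        heats[i] = params.dH * V0 * (bound - bound_prev * dil)
        bound_prev = bound
    return heats
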