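"""CH-π free-energy decomposition and the pseudo-Hammett regression.

The CH-π contribution to a walled host–guest complex is isolated by a
reference-state subtraction: the octamethyl host binds the same guest
through the identical four-fold NH···O hydrogen-bond array but offers no
aromatic walls, so

    ΔΔG = ΔG(walled complex) − ΔG(reference complex)

attributes the extra stabilisation to the wall–guest (CH-π) contacts.
Dividing by the number of methyl-to-ring contacts gives a per-contact
energy.  Regressing ΔΔG against the electrostatic surface potential
(ESP) at the ring centroids — a pseudo-Hammett linear free-energy
relationship — tests whether the interaction is electrostatically
driven: a slope indistinguishable from zero points to dispersion.

Sign convention: ΔG and ΔΔG are negative for favourable binding
internally; report tables print −ΔG / −ΔΔG (positive numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import BindingResult

__all__ = [
    "HostRecord",
    "DecompositionResult",
    "LFERResult",
    "MissingReferenceError",
    "delta_delta_G",
    "per_contact_energy",
    "lfer_regression",
    "build_table1",
]


class MissingReferenceError(ValueError):
    """No reference (zero-wall) binding result available for a guest."""


@dataclass(frozen=True)
class HostRecord:
    """A receptor: wall count, ring ESP and the para substituent tuning it."""

    host_id: str
    n_walls: int
    esp: Optional[float] = None  # kcal/mol at the ring centroid; None if no walls
    substituent: str = ""

    def __post_init__(self) -> None:
        if self.n_walls not in (0, 2, 4):
            raise ValueError(f"n_walls must be 0, 2 or 4, got {self.n_walls}")
        if self.n_walls > 0 and self.esp is None:
            raise ValueError(f"host {self.host_id!r} has walls but no ESP value")
        if self.n_walls == 0 and self.esp is not None:
            raise ValueError(f"host {self.host_id!r} has no walls; ESP meaningless")

    @property
    def default_contacts(self) -> int:
        """One methyl-to-ring contact per wall (0 for the reference host)."""
        return self.n_walls


@dataclass(frozen=True)
class DecompositionResult:
    """ΔΔG of one complex against its reference, optionally per contact."""

    host_id: str
    guest_id: str
    ddG: float
    ddG_sigma: float
    n_contacts: Optional[int] = None
    per_contact: Optional[float] = None

    def with_contacts(self, n_contacts: int) -> "DecompositionResult":
        return DecompositionResult(
            host_id=self.host_id,
            guest_id=self.guest_id,
            ddG=self.ddG,
            ddG_sigma=self.ddG_sigma,
            n_contacts=n_contacts,
            per_contact=per_contact_energy(self.ddG, n_contacts),
        )


@dataclass(frozen=True)
class LFERResult:
    """Slope/intercept of ΔΔG vs ESP with standard errors and slope t-test."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_slope: float
    n_points: int


def delta_delta_G(
    target: BindingResult, reference: BindingResult
) -> DecompositionResult:
    """ΔΔG = ΔG(target) − ΔG(reference), errors combined in quadrature.

    Both results must refer to the same guest and the same reporting
    temperature, otherwise the subtraction does not isolate the wall
    contribution.
    """
    if target.guest_id != reference.guest_id:
        raise ValueError(
            f"guest mismatch: {target.guest_id!r} vs {reference.guest_id!r}"
        )
    if not math.isclose(target.temperature, reference.temperature):
        raise ValueError(
            f"temperature mismatch: {target.temperature} vs {reference.temperature}"
        )
    return DecompositionResult(
        host_id=target.host_id,
        guest_id=target.guest_id,
        ddG=target.dG - reference.dG,
        ddG_sigma=math.hypot(target.dG_sigma, reference.dG_sigma),
    )


def per_contact_energy(ddG: float, n_contacts: int) -> float:
    """Evenly partitioned CH-π energy per methyl-to-ring contact."""
    if n_contacts < 1:
        raise ValueError(f"n_contacts must be >= 1, got {n_contacts}")
    return ddG / n_contacts


def lfer_regression(
    points: Sequence[Tuple[float, ...]],
    weighted: bool = False,
) -> LFERResult:
    """Linear free-energy relationship: regress ΔΔG on ring-centroid ESP.

    ``points`` are ``(esp, ddG)`` or ``(esp, ddG, ddG_sigma)`` tuples.
    Ordinary least squares by default; with ``weighted`` the fit is
    inverse-variance weighted (σ treated as known, covariance unscaled).
    The slope's two-sided p-value tests H0: slope = 0 on n − 2 degrees
    of freedom.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("all ESP values identical; regression is rank-deficient")
    n = x.size

    if not weighted:
        fit = stats.linregress(x, y)
        slope, intercept = fit.slope, fit.intercept
        slope_se, intercept_se = fit.stderr, fit.intercept_stderr
        if n > 2:
            p_slope = fit.pvalue
        else:
            p_slope = float("nan")  # zero residual dof: exact interpolation
    else:
        sigma = np.array(
            [p[2] if len(p) > 2 else 1.0 for p in points], dtype=float
        )
        if np.any(sigma <= 0):
            raise ValueError("weights require positive ddG_sigma values")
        w = 1.0 / sigma**2
        W = np.sum(w)
        xbar = np.sum(w * x) / W
        Sxx = np.sum(w * (x - xbar) ** 2)
        slope = np.sum(w * (x - xbar) * y) / Sxx
        intercept = (np.sum(w * y) - slope * np.sum(w * x)) / W
        # known-variance (unscaled) covariance
        slope_se = math.sqrt(1.0 / Sxx)
        intercept_se = math.sqrt(1.0 / W + xbar**2 / Sxx)
        if n > 2:
            t = slope / slope_se
            p_slope = 2.0 * stats.t.sf(abs(t), df=n - 2)
        else:
            p_slope = float("nan")

    return LFERResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        p_slope=float(p_slope),
        n_points=n,
    )


def build_table1(
    results: Iterable[BindingResult],
    hosts: Iterable[HostRecord],
    reference_id: str = "1a",
) -> pd.DataFrame:
    """Assemble the summary table: ESP, K ± σ, −ΔG and −ΔΔG per host × guest.

    One row per binding result, ordered by (guest, host) regardless of
    input order.  −ΔΔG is left empty for the reference host itself.
    Raises :class:`MissingReferenceError` (naming the guest) when a guest
    lacks a ``reference_id`` measurement.
    """
    host_map = {h.host_id: h for h in hosts}
    results = list(results)
    by_guest: dict[str, dict[str, BindingResult]] = {}
    for r in results:
        by_guest.setdefault(r.guest_id, {})[r.host_id] = r

    rows = []
    for guest_id in sorted(by_guest):
        group = by_guest[guest_id]
        if reference_id not in group:
            raise MissingReferenceError(
                f"no reference ({reference_id!r}) result for guest {guest_id!r}"
            )
        ref = group[reference_id]
        for host_id in sorted(group):
            r = group[host_id]
            host = host_map.get(host_id)
            row = {
                "host_id": host_id,
                "guest_id": guest_id,
                "n_walls": host.n_walls if host else None,
                "esp": host.esp if host else None,
                "K": r.K,
                "K_sigma": r.K_sigma,
                "minus_dG": -r.dG,
                "method": r.method,
            }
            if host_id == reference_id:
                row.update(
                    minus_ddG=np.nan, ddG_sigma=np.nan, n_contacts=np.nan,
                    per_contact=np.nan,
                )
            else:
                dec = delta_delta_G(r, ref)
                n_c = host.default_contacts if host and host.n_walls else None
                if n_c:
                    dec = dec.with_contacts(n_c)
                row.update(
                    minus_ddG=-dec.ddG,
                    ddG_sigma=dec.ddG_sigma,
                    n_contacts=dec.n_contacts if n_c else np.nan,
                    per_contact=-dec.per_contact if n_c else np.nan,
                )
            rows.append(row)
    return pd.DataFrame(rows)
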