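"""Hydrogen-bond free-energy prediction and K ↔ ΔG thermodynamics.

The strength of a single hydrogen bond between a donor and an acceptor
dissolved in a competing solvent is estimated with Hunter's empirical
descriptor model,

    dG_HB = [-(alpha - alpha_s) * (beta - beta_s) + 6] / 4.18   (kcal/mol)

where ``alpha``/``beta`` are dimensionless hydrogen-bond donor and
acceptor strengths of the two partners and ``alpha_s``/``beta_s`` those
of the solvent.  The offset ``6`` (kJ/mol) and the kJ→kcal factor
``4.18`` are part of the calibrated model, not tunable parameters.  The
model applies to a *single* point-to-point hydrogen bond; it is not
valid for cooperative hydrogen-bonding arrays.

The module also provides the exact thermodynamic conversions
ΔG = −RT·ln K and K = exp(−ΔG/RT), which every downstream stage uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "HBDescriptor",
    "SolventDescriptor",
    "ThermoConstants",
    "DescriptorTable",
    "DescriptorLookupError",
    "predict_hb_free_energy",
    "free_energy_to_K",
    "K_to_free_energy",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Reporting temperature (K) for binding free energies.
DEFAULT_TEMPERATURE_K = 298.0

# Calibrated constants of the descriptor model: offset in kJ/mol and the
# kJ -> kcal conversion used at calibration time.
_HB_OFFSET_KJ = 6.0
_KJ_PER_KCAL = 4.18


class DescriptorLookupError(KeyError):
    """Raised when a species or solvent id is absent from a descriptor table."""


@dataclass(frozen=True)
class HBDescriptor:
    """Hydrogen-bond donor/acceptor strengths of one species.

    ``alpha`` quantifies donor strength, ``beta`` acceptor strength; both
    are dimensionless and non-negative.  ``beta`` may be NaN when a species
    is only ever used as a donor (e.g. pyrrole here).
    """

    species_id: str
    alpha: float
    beta: float = float("nan")

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not math.isnan(self.beta) and self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class SolventDescriptor:
    """Donor/acceptor strengths of the solvent competing for both partners."""

    solvent_id: str
    alpha_s: float
    beta_s: float

    def __post_init__(self) -> None:
        if self.alpha_s < 0 or self.beta_s < 0:
            raise ValueError("solvent descriptors must be >= 0")


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and absolute temperature used in K ↔ ΔG conversions."""

    R: float = GAS_CONSTANT_KCAL
    T: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class DescriptorTable:
    """Lookup table of species and solvent hydrogen-bond descriptors.

    The built-in table ships the acetonitrile study system: pyrrole as
    donor (α = 3.0), trimethylamine N-oxide ``2a`` (β = 12.2) and
    trimethylphosphine P-oxide ``2b`` (β = 10.7) as acceptors, with
    CH3CN α_s = 1.7, β_s = 5.1.  User tables are plain CSV with columns
    ``species_id, alpha, beta`` (species) and ``solvent_id, alpha_s,
    beta_s`` (solvents).
    """

    species: dict[str, HBDescriptor] = field(default_factory=dict)
    solvents: dict[str, SolventDescriptor] = field(default_factory=dict)

    @classmethod
    def builtin(cls) -> "DescriptorTable":
        pkg = resources.files("chpi.data")
        with resources.as_file(pkg / "hb_descriptors.csv") as p:
            table = cls.from_csv(p)
        with resources.as_file(pkg / "solvents.csv") as p:
            table.add_solvents_csv(p)
        return table

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DescriptorTable":
        df = pd.read_csv(path)
        table = cls()
        for row in df.itertuples(index=False):
            sid = str(row.species_id)
            if sid in table.species:
                raise ValueError(f"duplicate species_id {sid!r}")
            beta = float(row.beta) if pd.notna(row.beta) else float("nan")
            table.species[sid] = HBDescriptor(sid, float(row.alpha), beta)
        return table

    def add_solvents_csv(self, path: Union[str, Path]) -> None:
        df = pd.read_csv(path)
        for row in df.itertuples(index=False):
            sid = str(row.solvent_id)
            self.solvents[sid] = SolventDescriptor(
                sid, float(row.alpha_s), float(row.beta_s)
            )

    def get_species(self, species_id: str) -> HBDescriptor:
        try:
            return self.species[species_id]
        except KeyError:
            raise DescriptorLookupError(
                f"no descriptor entry for species {species_id!r}"
            ) from None

    def get_solvent(self, solvent_id: str) -> SolventDescriptor:
        try:
            return self.solvents[solvent_id]
        except KeyError:
            raise DescriptorLookupError(
                f"no descriptor entry for solvent {solvent_id!r}"
            ) from None


def predict_hb_free_energy(
    donor: HBDescriptor,
    acceptor: HBDescriptor,
    solvent: SolventDescriptor,
) -> float:
    """Predict the free energy (kcal/mol) of one hydrogen bond in solution.

    Returns ``[-(α_donor − α_s)(β_acceptor − β_s) + 6] / 4.18``.  Negative
    values mean the donor–acceptor bond out-competes solvation of both
    partners; when the donor is no better than the solvent (α = α_s) the
    interaction term vanishes and only the unfavourable +6 kJ/mol offset
    remains.
    """
    if math.isnan(acceptor.beta):
        raise ValueError(
            f"species {acceptor.species_id!r} has no acceptor strength (beta)"
        )
    interaction_kj = -(donor.alpha - solvent.alpha_s) * (acceptor.beta - solvent.beta_s)
    return (interaction_kj + _HB_OFFSET_KJ) / _KJ_PER_KCAL


def free_energy_to_K(dG: float, const: ThermoConstants = ThermoConstants()) -> float:
    """Association constant K (M^-1) for a binding free energy (kcal/mol)."""
    return math.exp(-dG / const.RT)


def K_to_free_energy(K: float, const: ThermoConstants = ThermoConstants()) -> float:
    """Binding free energy ΔG = −RT ln K (kcal/mol); requires K > 0."""
    if K <= 0:
        raise ValueError(f"association constant must be > 0, got {K}")
    return -const.RT * math.log(K)
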