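"""Geometric characterisation of CH-π contacts and hydrogen bonds.

Given 3D coordinates (XYZ or PDB), computes aromatic ring centroids and
least-squares plane normals, and the three parameters conventionally
used to describe a C–H···π contact:

* ``d``      — distance from the donor hydrogen (or its carbon in
  heavy-atom mode) to the ring centroid, Å;
* ``theta``  — the C–H···centroid angle at the hydrogen, degrees
  (180° for a linear approach);
* ``phi``    — angular displacement of the donor from the ring normal
  through the centroid, degrees (0° directly above the ring face).

Contacts are counted from the methyl-carbon-to-centroid distance with a
configurable cutoff (default 4.0 Å, heavy-atom criterion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "StructureCoordinates",
    "RingDefinition",
    "RingFrame",
    "CHPiGeometry",
    "read_xyz",
    "read_pdb",
    "write_xyz",
    "ring_centroid_normal",
    "chpi_parameters",
    "count_contacts",
    "hydrogen_bond_distances",
]


@dataclass
class StructureCoordinates:
    """Atom ids, elements and Cartesian coordinates (Å) of one structure."""

    atom_ids: List[str]
    elements: List[str]
    coords: np.ndarray  # (N, 3)
    source: str = "xyz"
    _index: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_ids), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(set(self.atom_ids)) != len(self.atom_ids):
            raise ValueError("atom ids are not unique")
        self._index = {aid: i for i, aid in enumerate(self.atom_ids)}

    def position(self, atom_id: str) -> np.ndarray:
        try:
            return self.coords[self._index[atom_id]]
        except KeyError:
            raise KeyError(f"no atom with id {atom_id!r}") from None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureCoordinates":
        """Copy with coordinates rigidly rotated then translated."""
        return StructureCoordinates(
            atom_ids=list(self.atom_ids),
            elements=list(self.elements),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            source=self.source,
        )


@dataclass(frozen=True)
class RingDefinition:
    """Ordered atom ids of one aromatic ring (5–6 members)."""

    atom_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not 3 <= len(self.atom_ids) <= 6:
            raise ValueError("a ring needs 3-6 atoms")


@dataclass(frozen=True)
class RingFrame:
    """Centroid, unit normal and planarity of a fitted ring plane."""

    centroid: np.ndarray
    normal: np.ndarray
    max_out_of_plane: float  # Å, largest deviation of a ring atom from the plane


@dataclass(frozen=True)
class CHPiGeometry:
    """(d, theta, phi) of one CH-π contact; theta is NaN in heavy-atom mode."""

    d: float
    theta: float
    phi: float
    mode: str = "H"  # "H": d from the hydrogen; "C": heavy-atom fallback
    flags: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# readers / writer


def read_xyz(path: Union[str, Path]) -> StructureCoordinates:
    """Read the plain 2-header-line XYZ dialect; ids are element + 1-based index."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated XYZ file")
    natoms = int(lines[0].split()[0])
    rows = [ln.split() for ln in lines[2 : 2 + natoms]]
    if len(rows) < natoms:
        raise ValueError(f"{path}: expected {natoms} atom lines")
    elements = [r[0] for r in rows]
    coords = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    ids = [f"{el}{i + 1}" for i, el in enumerate(elements)]
    return StructureCoordinates(ids, elements, coords, source="xyz")


def write_xyz(
    structure: StructureCoordinates, path: Union[str, Path], comment: str = ""
) -> None:
    lines = [str(len(structure.atom_ids)), comment]
    for el, xyz in zip(structure.elements, structure.coords):
        lines.append(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: Union[str, Path]) -> StructureCoordinates:
    """Read ATOM/HETATM records (first model, first altloc) via gemmi."""
    import gemmi

    st = gemmi.read_pdb(str(path))
    st.remove_alternative_conformations()
    model = st[0]
    ids, elements, coords = [], [], []
    for chain in model:
        for residue in chain:
            for atom in residue:
                ids.append(f"{chain.name}.{residue.seqid.num}.{atom.name}")
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return StructureCoordinates(ids, elements, np.array(coords), source="pdb")


# ---------------------------------------------------------------------------
# ring frame


def ring_centroid_normal(
    structure: StructureCoordinates,
    ring: RingDefinition,
    toward: Optional[str] = None,
) -> RingFrame:
    """Centroid and least-squares plane normal of a ring.

    The normal is the singular vector of the centred ring coordinates
    with the smallest singular value (total-least-squares plane).  Its
    sign is arbitrary unless ``toward`` names an atom, in which case the
    normal points into that atom's half-space.
    """
    pts = np.array([structure.position(a) for a in ring.atom_ids])
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    # s[0] >= s[1] >= s[2]; a plane needs two well-spread in-plane directions
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate ring plane (atoms collinear)")
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    if toward is not None:
        q = structure.position(toward) - centroid
        if float(q @ normal) < 0:
            normal = -normal
    max_dev = float(np.max(np.abs(centred @ normal)))
    return RingFrame(centroid=centroid, normal=normal, max_out_of_plane=max_dev)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


# ---------------------------------------------------------------------------
# CH-pi parameters


def chpi_parameters(
    structure: StructureCoordinates,
    C_id: str,
    H_id: Optional[str],
    ring: RingDefinition,
    degenerate_tol: float = 1e-6,
) -> CHPiGeometry:
    """The (d, theta, phi) parameters of one C–H···ring contact.

    With a hydrogen given, ``d`` runs from H to the centroid and
    ``theta`` is the C–H···centroid angle; the C–H pair must be bonded
    (< 1.3 Å).  Without a hydrogen (heavy-atom mode) ``d`` runs from the
    carbon, ``theta`` is NaN and the result is flagged.  ``phi`` is
    measured between the centroid→donor vector and the ring normal
    (signed toward the donor), hence lies in [0°, 90°].
    """
    c_pos = structure.position(C_id)
    flags: List[str] = []
    if H_id is None:
        donor = c_pos
        mode = "C"
        flags.append("heavy_atom_mode")
    else:
        donor = structure.position(H_id)
        mode = "H"
        if np.linalg.norm(donor - c_pos) >= 1.3:
            raise ValueError(
                f"atoms {C_id!r} and {H_id!r} are not bonded (C-H >= 1.3 Å)"
            )
    frame = ring_centroid_normal(structure, ring, toward=None)
    v = donor - frame.centroid
    d = float(np.linalg.norm(v))
    if d < degenerate_tol:
        return CHPiGeometry(
            d=d, theta=float("nan"), phi=float("nan"), mode=mode,
            flags=tuple(flags) + ("degenerate_on_centroid",),
        )
    normal = frame.normal if float(v @ frame.normal) >= 0 else -frame.normal
    phi = _angle_deg(v, normal)
    if mode == "H":
        theta = _angle_deg(c_pos - donor, frame.centroid - donor)
    else:
        theta = float("nan")
    return CHPiGeometry(d=d, theta=theta, phi=phi, mode=mode, flags=tuple(flags))


def count_contacts(
    structure: StructureCoordinates,
    methyl_carbons: Sequence[str],
    rings: Sequence[RingDefinition],
    cutoff: float = 4.0,
    mode: str = "C",
) -> Tuple[int, List[Tuple[str, RingDefinition, CHPiGeometry]]]:
    """Count CH-π contacts: (donor, ring) pairs with d(centroid) ≤ cutoff.

    ``mode="C"`` (default) measures from the listed carbon atoms
    (heavy-atom criterion); ``mode="H"`` treats the listed atoms as
    hydrogens in heavy-atom geometry terms.  Returns the count and the
    per-contact geometries sorted by distance (ties broken by atom id)
    for a deterministic ordering.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not rings:
        raise ValueError("ring list is empty")
    if mode not in ("C", "H"):
        raise ValueError(f"mode must be 'C' or 'H', got {mode!r}")
    contacts = []
    for atom_id in methyl_carbons:
        pos = structure.position(atom_id)
        for ring in rings:
            frame = ring_centroid_normal(structure, ring)
            d = float(np.linalg.norm(pos - frame.centroid))
            if d <= cutoff:
                geom = chpi_parameters(structure, atom_id, None, ring)
                contacts.append((atom_id, ring, geom))
    contacts.sort(key=lambda c: (c[2].d, c[0]))
    return len(contacts), contacts


def hydrogen_bond_distances(
    structure: StructureCoordinates,
    pairs: Sequence[Tuple[str, str]],
) -> np.ndarray:
    """Euclidean donor→acceptor distances (Å) for a batch of atom-id pairs."""
    return np.array(
        [
            float(np.linalg.norm(structure.position(a) - structure.position(b)))
            for a, b in pairs
        ]
    )
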