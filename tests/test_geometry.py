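"""Ring frames, CH-π contact parameters and contact counting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chpi.geometry import (
    RingDefinition,
    StructureCoordinates,
    chpi_parameters,
    count_contacts,
    hydrogen_bond_distances,
    read_pdb,
    read_xyz,
    ring_centroid_normal,
    write_xyz,
)
from conftest import hexagon


def structure_from(coords, elements=None):
    coords = np.asarray(coords, float)
    if elements is None:
        elements = ["C"] * len(coords)
    ids = [f"{el}{i+1}" for i, el in enumerate(elements)]
    return StructureCoordinates(ids, list(elements), coords, source="xyz")


def hexagon_structure(extra=(), z=0.0, center=(0, 0, 0)):
    pts = hexagon(z=z, center=center)
    coords = np.vstack([pts] + [np.asarray(e, float)[None, :] for e in extra])
    elements = ["C"] * 6 + ["X"] * len(extra)
    return structure_from(coords, elements), RingDefinition(tuple(f"C{i+1}" for i in range(6)))


def random_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    Rm = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(0, 10.0, 3)
    return Rm, t


# ---------------------------------------------------------------------------
# ring centroid / normal


def test_hexagon_centroid_and_normal():
    st, ring = hexagon_structure()
    frame = ring_centroid_normal(st, ring)
    assert np.allclose(frame.centroid, 0.0, atol=1e-12)
    assert np.allclose(np.abs(frame.normal), [0, 0, 1], atol=1e-12)
    assert frame.max_out_of_plane == pytest.approx(0.0, abs=1e-12)


def test_normal_sign_points_toward_query_atom():
    st, ring = hexagon_structure(extra=[(0.0, 0.0, -2.5)])
    frame = ring_centroid_normal(st, ring, toward="X7")
    assert frame.normal[2] < 0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ring_frame_equivariant_under_rigid_motion(seed):
    st, ring = hexagon_structure()
    Rm, t = random_rigid_motion(seed)
    moved = st.transformed(Rm, t)
    f0 = ring_centroid_normal(st, ring)
    f1 = ring_centroid_normal(moved, ring)
    assert np.allclose(f1.centroid, Rm @ f0.centroid + t, atol=1e-9)
    assert min(
        np.linalg.norm(f1.normal - Rm @ f0.normal),
        np.linalg.norm(f1.normal + Rm @ f0.normal),
    ) < 1e-9


def test_puckered_ring_normal_close_to_axis():
    rng = np.random.default_rng(42)
    pts = hexagon()
    pts[:, 2] += rng.uniform(-0.05, 0.05, 6)
    st = structure_from(pts)
    frame = ring_centroid_normal(st, RingDefinition(tuple(st.atom_ids)))
    tilt = np.degrees(np.arccos(abs(frame.normal[2])))
    assert tilt < 3.0
    assert frame.max_out_of_plane < 0.1


def test_collinear_ring_rejected():
    pts = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
    st = structure_from(pts)
    with pytest.raises(ValueError, match="collinear"):
        ring_centroid_normal(st, RingDefinition(tuple(st.atom_ids)))


# ---------------------------------------------------------------------------
# CH-pi parameters


def test_axial_geometry():
    st, ring = hexagon_structure(extra=[(0, 0, 3.59), (0, 0, 2.5)])
    st.elements[-2:] = ["C", "H"]
    geom = chpi_parameters(st, "X7", "X8", ring)
    assert geom.d == pytest.approx(2.5)
    assert geom.theta == pytest.approx(180.0)
    assert geom.phi == pytest.approx(0.0, abs=1e-9)


def test_lateral_displacement_phi():
    # right-triangle oracle: phi = atan2(lateral, height)
    st, ring = hexagon_structure(extra=[(1.0, 0, 3.59), (1.0, 0, 2.5)])
    geom = chpi_parameters(st, "X7", "X8", ring)
    assert geom.phi == pytest.approx(np.degrees(np.arctan2(1.0, 2.5)), abs=1e-9)
    assert geom.d == pytest.approx(np.hypot(1.0, 2.5))


def test_heavy_atom_mode():
    st, ring = hexagon_structure(extra=[(0, 0, 3.5)])
    geom = chpi_parameters(st, "X7", None, ring)
    assert geom.d == pytest.approx(3.5)
    assert geom.mode == "C"
    assert "heavy_atom_mode" in geom.flags
    assert np.isnan(geom.theta)


def test_unbonded_ch_pair_rejected():
    st, ring = hexagon_structure(extra=[(0, 0, 5.0), (0, 0, 2.5)])
    with pytest.raises(ValueError, match="bonded"):
        chpi_parameters(st, "X7", "X8", ring)


def test_donor_on_centroid_flagged_degenerate():
    st, ring = hexagon_structure(extra=[(0, 0, 0)])
    geom = chpi_parameters(st, "X7", None, ring)
    assert "degenerate_on_centroid" in geom.flags


def test_phi_complements_in_plane_angle():
    st, ring = hexagon_structure(extra=[(1.3, 0.4, 3.6), (1.3, 0.4, 2.6)])
    geom = chpi_parameters(st, "X7", "X8", ring)
    v = st.position("X8")  # centroid at origin, normal along z
    in_plane = np.degrees(np.arcsin(abs(v[2]) / np.linalg.norm(v)))
    assert geom.phi + in_plane == pytest.approx(90.0, abs=1e-7)


@pytest.mark.parametrize("seed", [3, 4])
def test_chpi_parameters_invariant_under_rigid_motion(seed):
    st, ring = hexagon_structure(extra=[(1.0, 0.3, 3.5), (0.8, 0.2, 2.6)])
    g0 = chpi_parameters(st, "X7", "X8", ring)
    Rm, t = random_rigid_motion(seed)
    g1 = chpi_parameters(st.transformed(Rm, t), "X7", "X8", ring)
    assert g1.d == pytest.approx(g0.d, abs=1e-9)
    assert g1.theta == pytest.approx(g0.theta, abs=1e-7)
    assert g1.phi == pytest.approx(g0.phi, abs=1e-7)


# ---------------------------------------------------------------------------
# contact counting


def brute_force_contacts(structure, methyls, rings, cutoff):
    found = set()
    for m in methyls:
        for i, ring in enumerate(rings):
            centroid = np.mean([structure.position(a) for a in ring.atom_ids], axis=0)
            if np.linalg.norm(structure.position(m) - centroid) <= cutoff:
                found.add((m, i))
    return found


def test_counts_match_brute_force_on_random_fixtures():
    rng = np.random.default_rng(9)
    for _ in range(5):
        coords, elements, rings, methyls = [], [], [], []
        for r in range(3):
            center = rng.normal(0, 4.0, 3)
            pts = hexagon(center=center)
            start = len(coords)
            coords.extend(pts)
            elements.extend("C" * 6)
            rings.append(
                RingDefinition(tuple(f"C{start + i + 1}" for i in range(6)))
            )
        st_ids = [f"C{i+1}" for i in range(len(coords))]
        for m in range(4):
            coords.append(rng.normal(0, 4.0, 3))
            elements.append("C")
            st_ids.append(f"C{len(coords)}")
            methyls.append(st_ids[-1])
        st = StructureCoordinates(st_ids, elements, np.array(coords))
        n, contacts = count_contacts(st, methyls, rings, cutoff=4.0)
        expected = brute_force_contacts(st, methyls, rings, 4.0)
        assert n == len(expected)
        assert {(c[0], rings.index(c[1])) for c in contacts} == expected
        dists = [c[2].d for c in contacts]
        assert dists == sorted(dists)


def test_cutoff_below_all_distances_gives_zero():
    st, ring = hexagon_structure(extra=[(0, 0, 3.5)])
    n, contacts = count_contacts(st, ["X7"], [ring], cutoff=2.0)
    assert n == 0 and contacts == []


def test_empty_ring_list_rejected():
    st, _ = hexagon_structure(extra=[(0, 0, 3.5)])
    with pytest.raises(ValueError, match="empty"):
        count_contacts(st, ["X7"], [], cutoff=4.0)


# ---------------------------------------------------------------------------
# hydrogen-bond distances


def test_axial_pair_distance():
    st = structure_from([(0, 0, 0), (0, 0, 2.095)], ["N", "O"])
    assert hydrogen_bond_distances(st, [("N1", "O2")])[0] == pytest.approx(2.095)


def test_coincident_atoms_and_batch():
    rng = np.random.default_rng(1)
    coords = rng.normal(0, 3.0, (6, 3))
    coords[1] = coords[0]
    st = structure_from(coords, ["H", "O", "H", "O", "H", "O"])
    pairs = [("H1", "O2"), ("H3", "O4"), ("H5", "O6")]
    d = hydrogen_bond_distances(st, pairs)
    assert d[0] == 0.0
    for k, (a, b) in enumerate(pairs):
        assert d[k] == pytest.approx(
            np.linalg.norm(st.position(a) - st.position(b))
        )


def test_missing_atom_lookup_error():
    st = structure_from([(0, 0, 0)], ["N"])
    with pytest.raises(KeyError, match="O9"):
        hydrogen_bond_distances(st, [("N1", "O9")])


# ---------------------------------------------------------------------------
# file formats


def test_xyz_round_trip(tmp_path):
    st, _ = hexagon_structure(extra=[(0.1, -0.2, 3.5)])
    p = tmp_path / "complex.xyz"
    write_xyz(st, p, comment="fixture")
    back = read_xyz(p)
    assert back.elements == st.elements
    assert np.allclose(back.coords, st.coords, atol=1e-6)


def test_pdb_reader_first_altloc(tmp_path):
    pdb = "\n".join(
        [
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C",
            "ATOM      3  CA BALA A   1       1.600   0.100   0.000  0.40  0.00           C",
            "HETATM    4  O   HOH A   2       0.000   0.000   2.095  1.00  0.00           O",
            "END",
        ]
    )
    p = tmp_path / "s.pdb"
    p.write_text(pdb + "\n")
    st = read_pdb(p)
    assert len(st.atom_ids) == 3  # altloc B dropped
    d = hydrogen_bond_distances(st, [("A.1.N", "A.2.O")])
    assert d[0] == pytest.approx(2.095)
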