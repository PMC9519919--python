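"""Superposition, plane-fit, distance and segment-displacement geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from p450fx.geometry import (
    GeometryError,
    elevation_angle,
    fit_plane,
    kabsch_superpose,
    min_heavy_distance,
    pair_residues,
    rmsd_ca,
    rotation_angle_deg,
    segment_displacement,
)
from p450fx.structio import Atom, Chain, Model, Residue, Structure, copy_model


def rot_z(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

def test_kabsch_identical_sets_give_zero_rmsd(rng):
    pts = rng.normal(size=(10, 3))
    res = kabsch_superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_kabsch_recovers_exact_rigid_motion(rng):
    a = rng.normal(size=(15, 3))
    b = a @ rot_z(25.0).T + np.array([1.0, -2.0, 3.0])
    res = kabsch_superpose(a, b)
    assert res.rmsd == pytest.approx(0.0, abs=1e-8)
    assert rotation_angle_deg(res.rotation) == pytest.approx(25.0, abs=1e-6)
    assert np.allclose(res.apply(b), a, atol=1e-8)


def test_kabsch_beats_random_rotation_brute_force(rng):
    """Kabsch RMSD is a lower bound over 10,000 random rigid motions."""
    a = rng.normal(size=(12, 3))
    b = a + rng.normal(scale=0.4, size=a.shape)
    best = kabsch_superpose(a, b).rmsd
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    b0 = b - cb
    for _ in range(10_000):
        r = random_rotation(rng)
        # optimal translation for a fixed rotation aligns centroids
        trial = np.sqrt((((b0 @ r.T) + ca - a) ** 2).sum(axis=1).mean())
        assert best <= trial + 1e-12


def test_kabsch_rejects_degenerate_input(rng):
    with pytest.raises(GeometryError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
    with pytest.raises(GeometryError):
        kabsch_superpose(line, line)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st_.integers(0, 10_000))
def test_kabsch_rmsd_invariant_under_common_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(8, 3))
    b = a + rng.normal(scale=0.3, size=a.shape)
    base = kabsch_superpose(a, b).rmsd
    r = random_rotation(rng)
    t = rng.normal(size=3) * 10
    moved = kabsch_superpose(a @ r.T + t, b @ r.T + t).rmsd
    assert moved == pytest.approx(base, abs=1e-6)


# ---------------------------------------------------------------------------
# Residue pairing and RMSD
# ---------------------------------------------------------------------------

def _protein(seqs, chain="A", jitter=None, seed=0):
    """Structure with one chain of CA-only residues named by one-letter codes."""
    codes = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "G": "GLY"}
    rng = np.random.default_rng(seed)
    residues = []
    for i, letter in enumerate(seqs):
        pos = np.array([3.8 * i, np.sin(i), np.cos(i)])
        if jitter:
            pos = pos + rng.normal(scale=jitter, size=3)
        residues.append(
            Residue(name=codes[letter], seqid=i + 1,
                    atoms=[Atom(name="CA", element="C", position=pos)])
        )
    return Structure(models=[Model(chains=[Chain(chain, residues)])], source_id=seqs)


def test_pair_residues_same_numbering_self_pairs_everything():
    a = _protein("ACDEG")
    pairing = pair_residues(a, a, mode="same_numbering")
    assert len(pairing) == 5
    assert rmsd_ca(a, a, pairing) == pytest.approx(0.0, abs=1e-12)


def test_pair_residues_sequence_alignment_matches_brute_force():
    """ACDE vs ACE: best global alignment (match +1, gap -1) keeps 3 columns."""
    a = _protein("ACDE")
    b = _protein("ACE")
    pairing = pair_residues(a, b, mode="sequence_alignment")
    assert len(pairing) == 3
    paired_a = [p[0][1] for p in pairing.pairs]
    paired_b = [p[1][1] for p in pairing.pairs]
    assert paired_a == [1, 2, 4] and paired_b == [1, 2, 3]


def test_pair_residues_disjoint_numbering_errors():
    a = _protein("ACDE")
    b = _protein("ACDE")
    for c in b.models[0].chains:
        for r in c.residues:
            r.seqid += 1000
    with pytest.raises(GeometryError):
        pair_residues(a, b, mode="same_numbering")


def test_rmsd_ca_symmetric_under_pair_swap():
    a = _protein("ACDEGACDEG")
    b = _protein("ACDEGACDEG", jitter=0.8, seed=5)
    pairing = pair_residues(a, b, mode="same_numbering")
    swapped = type(pairing)(pairs=[(q, p) for p, q in pairing.pairs], mode=pairing.mode)
    assert rmsd_ca(a, b, pairing) == pytest.approx(rmsd_ca(b, a, swapped), abs=1e-9)


# ---------------------------------------------------------------------------
# Plane fitting and elevation
# ---------------------------------------------------------------------------

def test_fit_plane_exact_for_coplanar_points():
    pts = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float)
    plane = fit_plane(pts)
    assert plane.rms_residual == pytest.approx(0.0, abs=1e-12)
    assert abs(plane.normal[2]) == pytest.approx(1.0)
    with pytest.raises(GeometryError):
        fit_plane(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float))


def test_toy_heme_plane_is_exactly_planar(toy):
    st, cof = toy
    plane = fit_plane(st.coords(cof.heme_plane_atoms))
    assert plane.rms_residual == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "point,expected",
    [
        ((0.0, 0.0, 5.0), 90.0),
        ((5.0, 0.0, 0.0), 0.0),
        ((5.0, 0.0, 5.0), 45.0),
        ((0.0, 0.0, -5.0), -90.0),
        ((5.0, 0.0, -5.0), -45.0),
    ],
)
def test_elevation_angle_closed_forms(point, expected):
    pts = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float)
    plane = fit_plane(pts, orient_toward=np.array([0.0, 0.0, 1.0]))
    assert elevation_angle(plane, np.array(point)) == pytest.approx(expected, abs=1e-9)


def test_elevation_antisymmetric_under_reflection(rng):
    pts = rng.normal(size=(6, 2))
    pts = np.column_stack([pts, np.zeros(6)])
    plane = fit_plane(pts, orient_toward=np.array([0.0, 0.0, 1.0]))
    p = rng.normal(size=3)
    mirrored = p.copy()
    mirrored[2] = -mirrored[2]
    assert elevation_angle(plane, p) == pytest.approx(-elevation_angle(plane, mirrored), abs=1e-9)


def test_elevation_undefined_at_centroid(toy):
    st, cof = toy
    plane = fit_plane(st.coords(cof.heme_plane_atoms))
    fe = st.atom(cof.heme_iron).position  # Fe sits exactly at the plane centroid
    with pytest.raises(GeometryError):
        elevation_angle(plane, fe)


# ---------------------------------------------------------------------------
# Minimum heavy-atom distance
# ---------------------------------------------------------------------------

def _atoms(positions, element="C"):
    return [Atom(name=f"X{i}", element=element, position=np.asarray(p, dtype=float))
            for i, p in enumerate(positions)]


def test_min_distance_trivial_and_shared_atom():
    d, pair = min_heavy_distance(_atoms([(0, 0, 0)]), _atoms([(3, 0, 0)]))
    assert d == pytest.approx(3.0)
    shared = _atoms([(1, 1, 1), (5, 5, 5)])
    d, _ = min_heavy_distance(shared, shared)
    assert d == 0.0


def test_min_distance_equals_exhaustive_double_loop(rng):
    a = _atoms(rng.uniform(0, 20, size=(50, 3)))
    b = _atoms(rng.uniform(0, 20, size=(50, 3)))
    d, (pa, pb) = min_heavy_distance(a, b)
    brute = min(
        float(np.linalg.norm(x.position - y.position)) for x in a for y in b
    )
    assert d == pytest.approx(brute, abs=1e-12)
    assert float(np.linalg.norm(pa.position - pb.position)) == pytest.approx(d)


def test_min_distance_excludes_hydrogens_by_default():
    a = _atoms([(0, 0, 0)])
    b = _atoms([(1, 0, 0)], element="H") + _atoms([(4, 0, 0)])
    d, _ = min_heavy_distance(a, b)
    assert d == pytest.approx(4.0)
    with pytest.raises(GeometryError):
        min_heavy_distance(a, _atoms([(1, 0, 0)], element="H"))


# ---------------------------------------------------------------------------
# Segment displacement
# ---------------------------------------------------------------------------

def test_segment_displacement_zero_for_identical_structures():
    a = _protein("ACDEGACDEGAC")
    pairing = pair_residues(a, a, mode="same_numbering")
    disp = segment_displacement(a, a, pairing, segment=(4, 8))
    assert disp.mean_shift == pytest.approx(0.0, abs=1e-9)
    assert disp.max_shift == pytest.approx(0.0, abs=1e-9)
    assert disp.rotation_deg == pytest.approx(0.0, abs=1e-6)


def test_segment_displacement_recovers_constructed_rotation():
    """Rotate residues 5-9 by 25 deg about an axis through their centroid."""
    a = _protein("ACDEGACDEGACDE")
    b = Structure(models=[copy_model(a.models[0])], source_id="rot")
    seg = [r for r in b.models[0].chains[0].residues if 5 <= r.seqid <= 9]
    centroid = np.mean([r.atoms[0].position for r in seg], axis=0)
    for r in seg:
        r.atoms[0].position = rot_z(25.0) @ (r.atoms[0].position - centroid) + centroid
    pairing = pair_residues(a, b, mode="same_numbering")
    disp = segment_displacement(a, b, pairing, segment=(5, 9))
    assert disp.rotation_deg == pytest.approx(25.0, abs=1e-6)
    assert disp.n_residues == 5
    # untouched core superposes exactly, so core shift is zero
    core = pairing.excluding((5, 9))
    assert rmsd_ca(a, b, core) == pytest.approx(0.0, abs=1e-9)


def test_segment_too_short_is_an_error():
    a = _protein("ACDEGACDEG")
    pairing = pair_residues(a, a, mode="same_numbering")
    with pytest.raises(GeometryError):
        segment_displacement(a, a, pairing, segment=(4, 5))
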