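"""Superposition, RMSD, plane fitting, distances and angles.

The measurement layer behind every structural comparison in the package:
Kabsch rigid superposition of paired C-alpha sets, total-least-squares plane
fits of the porphyrin core, signed elevation angles of a point above that
plane, exact minimum heavy-atom cross distances, and rigid-segment
displacement/rotation between two conformations of the same protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.SeqUtils import seq1
from scipy.spatial import cKDTree

from .structio import Atom, Chain, Model, Residue, Structure

__all__ = [
    "GeometryError",
    "SuperpositionResult",
    "PlaneFit",
    "ResiduePairing",
    "SegmentDisplacement",
    "kabsch_superpose",
    "pair_residues",
    "rmsd_ca",
    "fit_plane",
    "elevation_angle",
    "min_heavy_distance",
    "segment_displacement",
    "rotation_angle_deg",
]

logger = logging.getLogger(__name__)

# Degeneracy threshold for superposition/plane fits: second singular value
# of the centered coordinates below this (in A) means effectively collinear.
_DEGENERATE_SV = 1e-8


class GeometryError(Exception):
    """Invalid geometric input (too few points, degenerate configuration)."""


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Proper rigid motion x -> R x + t mapping set B onto set A."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A (Kabsch, via SVD).

    Returns the proper rotation/translation minimising the RMSD of the
    transformed B against A over all rigid motions with det(R) = +1.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError(f"point sets must both be (n, 3); got {a.shape} and {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 point pairs, got {n}")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    if s[1] < _DEGENERATE_SV:
        raise GeometryError("degenerate (collinear) point set; rotation is not determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    diff = (b0 @ rot.T) - a0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Rotation angle of a 3x3 proper rotation: arccos((trace - 1)/2)."""
    c = (float(np.trace(rotation)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Residue pairing
# ---------------------------------------------------------------------------

@dataclass
class ResiduePairing:
    """One-to-one residue correspondence between two structures."""

    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]]
    mode: str

    def __len__(self) -> int:
        return len(self.pairs)

    def excluding(self, seq_range: tuple[int, int], which: str = "a") -> "ResiduePairing":
        lo, hi = seq_range
        idx = 0 if which == "a" else 1
        kept = [p for p in self.pairs if not (lo <= p[idx][1] <= hi)]
        return ResiduePairing(pairs=kept, mode=self.mode)

    def restricted_to(self, seq_range: tuple[int, int], which: str = "a") -> "ResiduePairing":
        lo, hi = seq_range
        idx = 0 if which == "a" else 1
        kept = [p for p in self.pairs if lo <= p[idx][1] <= hi]
        return ResiduePairing(pairs=kept, mode=self.mode)


def _ca_residues(model: Model, chain: Optional[str]) -> list[tuple[Chain, Residue]]:
    out = []
    for c, r in model.iter_residues():
        if chain is not None and c.cid != chain:
            continue
        if r.atom("CA") is not None:
            out.append((c, r))
    return out


def pair_residues(
    a: Structure,
    b: Structure,
    mode: str = "same_numbering",
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
    offset: int = 0,
) -> ResiduePairing:
    """Pair residues of two structures for RMSD computations.

    ``same_numbering`` matches residue numbers (b's numbers shifted by
    ``offset``); ``sequence_alignment`` globally aligns the one-letter
    sequences (match +1, mismatch 0, gap -1) and keeps non-gap columns.
    """
    ra = _ca_residues(a.models[0], chain_a)
    rb = _ca_residues(b.models[0], chain_b)
    if not ra or not rb:
        raise GeometryError("both structures need C-alpha atoms for pairing")

    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = []
    if mode == "same_numbering":
        index_b = {(r.seqid + offset, r.icode): (c, r) for c, r in rb}
        for c, r in ra:
            hit = index_b.get((r.seqid, r.icode))
            if hit is not None:
                cb, rbres = hit
                pairs.append(((c.cid, r.seqid, r.icode), (cb.cid, rbres.seqid, rbres.icode)))
    elif mode == "sequence_alignment":
        seq_a = "".join(seq1(r.name, undef_code="X") for _, r in ra)
        seq_b = "".join(seq1(r.name, undef_code="X") for _, r in rb)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        aln = aligner.align(seq_a, seq_b)[0]
        for (sa, ea), (sb, eb) in zip(*aln.aligned):
            for i, j in zip(range(sa, ea), range(sb, eb)):
                c, r = ra[i]
                cb, rbres = rb[j]
                pairs.append(((c.cid, r.seqid, r.icode), (cb.cid, rbres.seqid, rbres.icode)))
    else:
        raise GeometryError(f"unknown pairing mode {mode!r}")

    if not pairs:
        raise GeometryError("pairing produced zero residue pairs")
    return ResiduePairing(pairs=pairs, mode=mode)


def _paired_ca_coords(
    a: Structure, b: Structure, pairing: ResiduePairing
) -> tuple[np.ndarray, np.ndarray, list]:
    ma, mb = a.models[0], b.models[0]
    xa, xb, skipped = [], [], []
    for (ca_key, cb_key) in pairing.pairs:
        cid_a, num_a, ic_a = ca_key
        cid_b, num_b, ic_b = cb_key
        ch_a, ch_b = ma.chain(cid_a), mb.chain(cid_b)
        res_a = ch_a.residue(num_a, ic_a) if ch_a else None
        res_b = ch_b.residue(num_b, ic_b) if ch_b else None
        at_a = res_a.atom("CA") if res_a else None
        at_b = res_b.atom("CA") if res_b else None
        if at_a is None or at_b is None:
            skipped.append((ca_key, cb_key))
            continue
        xa.append(at_a.position)
        xb.append(at_b.position)
    if not xa:
        raise GeometryError("no paired residues carry C-alpha atoms")
    if skipped:
        logger.warning("rmsd pairing: %d pairs skipped (missing C-alpha)", len(skipped))
    return np.array(xa), np.array(xb), skipped


def rmsd_ca(
    a: Structure,
    b: Structure,
    pairing: ResiduePairing,
    superpose: bool = True,
) -> float:
    """C-alpha RMSD over a residue pairing, after optimal superposition."""
    xa, xb, _ = _paired_ca_coords(a, b, pairing)
    if superpose:
        return kabsch_superpose(xa, xb).rmsd
    return float(np.sqrt(((xa - xb) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Plane fitting and elevation angles
# ---------------------------------------------------------------------------

@dataclass
class PlaneFit:
    centroid: np.ndarray
    normal: np.ndarray
    rms_residual: float


def fit_plane(points: np.ndarray, orient_toward: Optional[np.ndarray] = None) -> PlaneFit:
    """Total-least-squares plane through >= 3 non-collinear points.

    The normal is the singular vector of the smallest singular value. Its
    sign points toward ``orient_toward`` when given (e.g. the proximal side
    of a heme); otherwise the first nonzero component is made positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("plane fit needs an (n >= 3, 3) point array")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < _DEGENERATE_SV:
        raise GeometryError("collinear points do not define a plane")
    normal = vt[2]
    if orient_toward is not None:
        ref = np.asarray(orient_toward, dtype=float) - centroid
        if float(normal @ ref) < 0:
            normal = -normal
    else:
        for comp in normal:
            if abs(comp) > 1e-12:
                if comp < 0:
                    normal = -normal
                break
    rms = float(np.sqrt(((centered @ normal) ** 2).mean()))
    return PlaneFit(centroid=centroid, normal=normal / np.linalg.norm(normal), rms_residual=rms)


def elevation_angle(plane: PlaneFit, point: np.ndarray) -> float:
    """Signed angle (degrees, [-90, +90]) of centroid->point above the plane.

    Positive on the side the plane normal points to; 0 for a point in the
    plane, +90 on the normal ray.
    """
    v = np.asarray(point, dtype=float) - plane.centroid
    norm = float(np.linalg.norm(v))
    if norm < 1e-9:
        raise GeometryError("point coincides with the plane centroid; angle undefined")
    s = float(np.clip(v @ plane.normal / norm, -1.0, 1.0))
    return float(np.degrees(np.arcsin(s)))


# ---------------------------------------------------------------------------
# Minimum heavy-atom distance
# ---------------------------------------------------------------------------

def min_heavy_distance(
    sel_a: Sequence[Atom],
    sel_b: Sequence[Atom],
    include_hydrogens: bool = False,
) -> tuple[float, tuple[Atom, Atom]]:
    """Exact minimum cross-pair distance between two atom selections."""
    aa = list(sel_a) if include_hydrogens else [a for a in sel_a if a.is_heavy]
    bb = list(sel_b) if include_hydrogens else [a for a in sel_b if a.is_heavy]
    if not aa or not bb:
        raise GeometryError("min_heavy_distance: empty selection")
    pa = np.array([a.position for a in aa])
    pb = np.array([a.position for a in bb])
    # Grid-accelerated nearest neighbour; exact because the KD-tree query
    # is exact.
    tree = cKDTree(pb)
    dists, idx = tree.query(pa, k=1)
    i = int(np.argmin(dists))
    return float(dists[i]), (aa[i], bb[int(idx[i])])


# ---------------------------------------------------------------------------
# Segment displacement
# ---------------------------------------------------------------------------

@dataclass
class SegmentDisplacement:
    mean_shift: float
    max_shift: float
    rotation_deg: float
    n_residues: int


def segment_displacement(
    a: Structure,
    b: Structure,
    core_pairing: ResiduePairing,
    segment: tuple[int, int],
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
    offset: int = 0,
) -> SegmentDisplacement:
    """Displacement and rotation of a residue segment between conformations.

    b is superposed onto a using the core pairing (which must exclude the
    segment); the segment's per-residue C-alpha shifts are then measured
    directly, and its rotation is the angle of the Kabsch rotation between
    the two segment C-alpha sets after the core superposition.
    """
    lo, hi = segment
    if any(lo <= p[0][1] <= hi for p in core_pairing.pairs):
        core_pairing = core_pairing.excluding(segment, which="a")
    if not core_pairing.pairs:
        raise GeometryError("core pairing is empty after excluding the segment")

    xa, xb, _ = _paired_ca_coords(a, b, core_pairing)
    core = kabsch_superpose(xa, xb)

    seg_a, seg_b = [], []
    ma = a.models[0]
    mb = b.models[0]
    for c, r in ma.iter_residues():
        if chain_a is not None and c.cid != chain_a:
            continue
        if not (lo <= r.seqid <= hi):
            continue
        ca = r.atom("CA")
        if ca is None:
            continue
        cb_chain = mb.chain(chain_b) if chain_b is not None else None
        if cb_chain is not None:
            res_b = cb_chain.residue(r.seqid + offset, r.icode)
        else:
            res_b = None
            for c2 in mb.chains:
                cand = c2.residue(r.seqid + offset, r.icode)
                if cand is not None and cand.atom("CA") is not None:
                    res_b = cand
                    break
        if res_b is None:
            continue
        cb_atom = res_b.atom("CA")
        if cb_atom is None:
            continue
        seg_a.append(ca.position)
        seg_b.append(cb_atom.position)

    if len(seg_a) < 3:
        raise GeometryError(f"segment {segment} has fewer than 3 paired C-alpha residues")

    seg_a = np.array(seg_a)
    seg_b_t = core.apply(np.array(seg_b))
    shifts = np.linalg.norm(seg_b_t - seg_a, axis=1)
    seg_rot = kabsch_superpose(seg_a, seg_b_t)
    return SegmentDisplacement(
        mean_shift=float(shifts.mean()),
        max_shift=float(shifts.max()),
        rotation_deg=rotation_angle_deg(seg_rot.rotation),
        n_residues=len(shifts),
    )
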