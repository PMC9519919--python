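"""Active-site characterization: lining residues and grid cavity volume.

``lining_residues`` enumerates the protein residues within contact range of
a probe selection (the bound sterol, or the cavity itself), the measurement
behind active-site census tables. ``cavity_volume`` estimates an enclosed
cavity volume by flood-filling a cubic grid from a seed point over grid
nodes farther than a probe radius from every heavy atom — a deliberately
simple probe-excluded-volume estimator, convergent under grid refinement,
not a probe-rolled molecular-surface volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structio import Model, Selection, SelectionError, Structure, parse_selection

__all__ = [
    "LiningReport",
    "CavityEstimate",
    "SeedError",
    "lining_residues",
    "cavity_volume",
]

DEFAULT_LINING_CUTOFF = 4.5      # A, heavy-atom van der Waals contact range
DEFAULT_GRID_SPACING = 0.5       # A
DEFAULT_PROBE_RADIUS = 1.4       # A, water-sized probe

# Residues excluded from cavity walls / lining reports by default: the
# cavity is measured in the protein, with cofactor, bound ligand and
# solvent removed so the space they occupy counts as cavity.
DEFAULT_EXCLUDED_RESIDUES = frozenset(
    {"HOH", "WAT", "HEM", "HEB", "HEC", "LAN", "ERG", "CLR", "OBT", "LNL"}
)


class SeedError(ValueError):
    """Cavity seed point is buried inside an atom's probe-inflated sphere."""


@dataclass
class LiningReport:
    """Residues lining a probe selection, nearest first."""

    residues: list[tuple[str, float]]       # ("A:TYR186", min distance A)
    cutoff: float
    probe: str

    def __len__(self) -> int:
        return len(self.residues)

    def residue_ids(self) -> list[str]:
        return [rid for rid, _ in self.residues]


def lining_residues(
    structure: Structure,
    probe_selection: str | Selection,
    cutoff: float = DEFAULT_LINING_CUTOFF,
    exclude: Optional[str | Selection] = None,
    model_index: int = 0,
    excluded_residue_names: frozenset[str] = DEFAULT_EXCLUDED_RESIDUES,
) -> LiningReport:
    """Protein residues with any heavy atom within ``cutoff`` of the probe.

    The probe's own residues, waters and heme are never listed; an extra
    ``exclude`` selection removes anything else. Sorted by min distance.
    """
    sel = parse_selection(probe_selection) if isinstance(probe_selection, str) else probe_selection
    model = structure.models[model_index]
    probe_atoms = sel.resolve(model)
    probe_keys = {(c.cid, r.seqid, r.icode) for c, r, _ in probe_atoms}
    probe_pos = np.array([a.position for _, _, a in probe_atoms])
    tree = cKDTree(probe_pos)

    excl = None
    if exclude is not None:
        excl = parse_selection(exclude) if isinstance(exclude, str) else exclude

    rows: list[tuple[str, float]] = []
    for c, r in model.iter_residues():
        if (c.cid, r.seqid, r.icode) in probe_keys:
            continue
        if r.name.upper() in excluded_residue_names:
            continue
        if excl is not None and excl.matches_residue(c, r):
            continue
        heavy = r.heavy_atoms()
        if not heavy:
            continue
        d = float(tree.query(np.array([a.position for a in heavy]), k=1)[0].min())
        if d <= cutoff:
            rows.append((f"{c.cid}:{r.name}{r.seqid}{r.icode}", d))
    rows.sort(key=lambda t: (t[1], t[0]))
    return LiningReport(residues=rows, cutoff=cutoff, probe=getattr(sel, "text", str(sel)))


@dataclass
class CavityEstimate:
    volume: float                 # A^3
    grid_spacing: float
    probe_radius: float
    n_grid_points: int
    seed_point: np.ndarray
    open_cavity: bool = False     # fill reached the bounding box edge
    lining_cutoff: Optional[float] = None


def _wall_atoms(model: Model,
                excluded_residue_names: frozenset[str],
                extra_exclude: Optional[Selection]) -> np.ndarray:
    pos = []
    for c, r in model.iter_residues():
        if r.name.upper() in excluded_residue_names:
            continue
        if extra_exclude is not None and extra_exclude.matches_residue(c, r):
            continue
        pos.extend(a.position for a in r.heavy_atoms())
    if not pos:
        raise SelectionError("no wall atoms left after exclusions")
    return np.array(pos)


def cavity_volume(
    structure: Structure,
    seed_point: Sequence[float],
    grid_spacing: float = DEFAULT_GRID_SPACING,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    bounding_selection: Optional[str | Selection] = None,
    exclude: Optional[str | Selection] = None,
    model_index: int = 0,
    excluded_residue_names: frozenset[str] = DEFAULT_EXCLUDED_RESIDUES,
) -> CavityEstimate:
    """Flood-fill cavity volume from a seed point.

    Grid nodes farther than ``probe_radius`` from every wall heavy atom are
    open; the connected open component containing the seed (6-connectivity)
    is the cavity, volume = n_nodes * spacing^3. Ligand/heme/water are
    treated as solvent (excluded from the walls) by default, so the space
    they occupy counts as cavity. If the fill touches the bounding box the
    cavity is open to bulk; the enclosed component volume is still reported
    with ``open_cavity`` set.
    """
    model = structure.models[model_index]
    excl = parse_selection(exclude) if isinstance(exclude, str) else exclude
    walls = _wall_atoms(model, excluded_residue_names, excl)

    if bounding_selection is not None:
        bsel = parse_selection(bounding_selection) if isinstance(bounding_selection, str) else bounding_selection
        bpos = np.array([a.position for _, _, a in bsel.resolve(model)])
    else:
        bpos = walls
    lo = bpos.min(axis=0) - probe_radius
    hi = bpos.max(axis=0) + probe_radius

    seed = np.asarray(seed_point, dtype=float)
    if np.any(seed < lo) or np.any(seed > hi):
        raise SeedError(f"seed {seed} lies outside the bounding box [{lo}, {hi}]")

    nx, ny, nz = (np.ceil((hi - lo) / grid_spacing).astype(int) + 1)
    axes = [lo[i] + grid_spacing * np.arange(n) for i, n in enumerate((nx, ny, nz))]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(walls)
    dmin = tree.query(pts, k=1)[0].reshape(nx, ny, nz)
    open_mask = dmin > probe_radius

    seed_idx = tuple(np.clip(np.round((seed - lo) / grid_spacing).astype(int),
                             0, [nx - 1, ny - 1, nz - 1]))
    if not open_mask[seed_idx]:
        raise SeedError(
            f"seed {seed} is within {probe_radius} A of a wall atom; "
            "choose a point inside the cavity"
        )

    labels, _ = ndimage.label(open_mask)  # default structure = 6-connectivity
    cavity = labels == labels[seed_idx]
    n = int(cavity.sum())

    touches_edge = bool(
        cavity[0, :, :].any() or cavity[-1, :, :].any()
        or cavity[:, 0, :].any() or cavity[:, -1, :].any()
        or cavity[:, :, 0].any() or cavity[:, :, -1].any()
    )
    return CavityEstimate(
        volume=n * grid_spacing ** 3,
        grid_spacing=grid_spacing,
        probe_radius=probe_radius,
        n_grid_points=n,
        seed_point=seed,
        open_cavity=touches_edge,
    )
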