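"""Pose-ensemble ranking/filtering and snapshot-ensemble statistics.

Two ensemble flavours share the multi-model Structure container:

* docking *pose* ensembles — rigid placements of a [2Fe-2S] ferredoxin
  around a heme-bearing P450, each carrying an interface-energy score
  (lower is better). The post-processing mirrors the standard decoy
  pipeline: rank by score, keep the top fraction, then discard poses whose
  heme-iron-to-cluster average distance is not electron-transfer competent.
* MD *snapshot* ensembles — frames of a trajectory, interrogated for
  per-frame donor-acceptor geometry (distance and heme-plane elevation
  series) and for interaction occupancies (fraction of frames in which an
  H-bond/salt-bridge/contact criterion holds), with a block-averaged
  standard error to acknowledge frame-to-frame correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryError, elevation_angle, fit_plane, min_heavy_distance
from .structio import (
    CofactorMap,
    Selection,
    SelectionError,
    Structure,
    parse_selection,
)

__all__ = [
    "Pose",
    "PoseEnsemble",
    "InteractionCriterion",
    "OccupancyResult",
    "GeometrySeries",
    "EnsembleError",
    "measure_poses",
    "rank_top_fraction",
    "filter_by_mean_fe_distance",
    "geometry_series",
    "occupancy",
]

# Field-standard interaction cutoffs (A / degrees); all overridable per
# criterion. The H-bond angle test only applies when hydrogens exist.
HBOND_DISTANCE_CUTOFF = 3.5
SALTBRIDGE_DISTANCE_CUTOFF = 4.0
HBOND_ANGLE_CUTOFF = 120.0
N_BLOCKS_DEFAULT = 5


class EnsembleError(Exception):
    """Invalid ensemble input (missing scores, empty model list...)."""


# ---------------------------------------------------------------------------
# Poses
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    """Geometric metrics (and optional score) of one rigid ligand placement."""

    model_index: int
    fe_fe_min: float
    fe_fe_mean: float
    elevation: float
    score: Optional[float] = None
    error: Optional[str] = None


@dataclass
class PoseEnsemble:
    poses: list[Pose]
    receptor_cofactors: CofactorMap
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.poses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model_index": p.model_index,
                    "score": p.score,
                    "fe_fe_min": p.fe_fe_min,
                    "fe_fe_mean": p.fe_fe_mean,
                    "elevation": p.elevation,
                    "error": p.error,
                }
                for p in self.poses
            ]
        )


def measure_poses(
    models: Structure,
    receptor_cofactors: CofactorMap,
    ligand_fes_selector: str | Selection = "*:FES:FE1,FE2",
    scores: Optional[pd.DataFrame] = None,
) -> PoseEnsemble:
    """Measure heme-Fe -> [2Fe-2S] geometry for every pose model.

    Per pose: the minimum and mean of the heme-iron distances to the two
    cluster irons, and the heme-plane elevation angle of the nearer iron
    (Fe1). The receptor heme is taken as fixed across models; the plane is
    refit per model so rigidly transformed ensembles stay consistent. A
    score table (columns model_index, score) attaches scores by model
    index. A model lacking the cluster is recorded as an errored pose and
    the run continues.
    """
    sel = parse_selection(ligand_fes_selector) if isinstance(ligand_fes_selector, str) else ligand_fes_selector
    score_by_index: dict[int, float] = {}
    if scores is not None:
        if not {"model_index", "score"} <= set(scores.columns):
            raise EnsembleError("score table needs columns model_index, score")
        score_by_index = dict(
            zip(scores["model_index"].astype(int), scores["score"].astype(float))
        )

    poses: list[Pose] = []
    for imodel, model in enumerate(models.models):
        try:
            heme_fe = models.atom(receptor_cofactors.heme_iron, imodel).position
            plane_pts = models.coords(receptor_cofactors.heme_plane_atoms, imodel)
            irons = sel.resolve_atoms(model)
            if len(irons) != 2:
                raise SelectionError(
                    f"expected 2 cluster irons, selector matched {len(irons)}"
                )
            d = sorted(float(np.linalg.norm(a.position - heme_fe)) for a in irons)
            fe1 = min(irons, key=lambda a: float(np.linalg.norm(a.position - heme_fe)))
            plane = fit_plane(plane_pts, orient_toward=fe1.position)
            elev = elevation_angle(plane, fe1.position)
            poses.append(
                Pose(
                    model_index=imodel,
                    fe_fe_min=d[0],
                    fe_fe_mean=(d[0] + d[1]) / 2.0,
                    elevation=elev,
                    score=score_by_index.get(imodel),
                )
            )
        except (SelectionError, GeometryError) as exc:
            poses.append(
                Pose(
                    model_index=imodel,
                    fe_fe_min=math.nan,
                    fe_fe_mean=math.nan,
                    elevation=math.nan,
                    score=score_by_index.get(imodel),
                    error=str(exc),
                )
            )
    return PoseEnsemble(poses=poses, receptor_cofactors=receptor_cofactors,
                        provenance=models.source_id)


def rank_top_fraction(ensemble: PoseEnsemble, fraction: float) -> PoseEnsemble:
    """Keep the best ceil(fraction * n) poses by ascending score.

    Stable: equal scores keep their original relative (model-index) order.
    """
    if not 0 < fraction <= 1:
        raise EnsembleError(f"fraction must be in (0, 1], got {fraction}")
    valid = [p for p in ensemble.poses if p.error is None]
    if any(p.score is None for p in valid):
        missing = [p.model_index for p in valid if p.score is None]
        raise EnsembleError(f"poses without scores cannot be ranked: models {missing[:5]}...")
    n_keep = math.ceil(fraction * len(valid))
    ranked = sorted(valid, key=lambda p: p.score)  # sorted() is stable
    return PoseEnsemble(
        poses=ranked[:n_keep],
        receptor_cofactors=ensemble.receptor_cofactors,
        provenance=ensemble.provenance,
    )


def filter_by_mean_fe_distance(ensemble: PoseEnsemble, cutoff: float) -> PoseEnsemble:
    """Keep poses whose heme-Fe to cluster *mean* distance is strictly < cutoff."""
    kept = [
        p for p in ensemble.poses
        if p.error is None and math.isfinite(p.fe_fe_mean) and p.fe_fe_mean < cutoff
    ]
    return PoseEnsemble(
        poses=kept,
        receptor_cofactors=ensemble.receptor_cofactors,
        provenance=ensemble.provenance,
    )


# ---------------------------------------------------------------------------
# Snapshot geometry series
# ---------------------------------------------------------------------------

@dataclass
class GeometrySeries:
    """Per-frame donor-acceptor geometry of a snapshot ensemble."""

    frame: pd.DataFrame = field(repr=False)
    converged: bool = False
    convergence_threshold: float = 0.5

    def summary(self) -> dict:
        num = self.frame.select_dtypes("number").drop(columns=["frame"])
        return {
            "n_frames": int(len(self.frame)),
            "converged": bool(self.converged),
            "min": {k: float(v) for k, v in num.min().items()},
            "max": {k: float(v) for k, v in num.max().items()},
            "mean": {k: float(v) for k, v in num.mean().items()},
        }


def geometry_series(
    models: Structure,
    cofactors: CofactorMap,
    reference_atom: Optional[str | Selection] = None,
    fes_selector: str | Selection = "*:FES:FE1,FE2",
    convergence_threshold: float = 0.5,
) -> GeometrySeries:
    """Heme-Fe/heme-plane geometry of the cluster iron per snapshot frame.

    Per frame: distance heme Fe -> nearer cluster iron (Fe1), heme-plane
    elevation of Fe1, and the same pair of measures for an optional
    reference atom (e.g. a ferredoxin surface residue's side-chain atom).
    Fe1 identity is fixed from the first frame so the series tracks one
    atom. The series is called converged when the standard deviation of the
    Fe1 distance over the last quartile of frames falls below
    ``convergence_threshold`` (A).
    """
    fes_sel = parse_selection(fes_selector) if isinstance(fes_selector, str) else fes_selector
    ref_sel = None
    if reference_atom is not None:
        ref_sel = parse_selection(reference_atom) if isinstance(reference_atom, str) else reference_atom

    fe1_name: Optional[str] = None
    records = []
    for iframe, model in enumerate(models.models):
        try:
            heme_fe = models.atom(cofactors.heme_iron, iframe).position
            plane_pts = models.coords(cofactors.heme_plane_atoms, iframe)
            irons = fes_sel.resolve_atoms(model)
        except SelectionError as exc:
            raise SelectionError(f"frame {iframe}: {exc}") from exc
        if len(irons) != 2:
            raise SelectionError(f"frame {iframe}: expected 2 cluster irons, got {len(irons)}")
        if fe1_name is None:
            fe1 = min(irons, key=lambda a: float(np.linalg.norm(a.position - heme_fe)))
            fe1_name = fe1.name
        else:
            by_name = {a.name: a for a in irons}
            if fe1_name not in by_name:
                raise SelectionError(f"frame {iframe}: cluster iron {fe1_name!r} missing")
            fe1 = by_name[fe1_name]
        plane = fit_plane(plane_pts, orient_toward=fe1.position)
        rec = {
            "frame": iframe,
            "fe_fe": float(np.linalg.norm(fe1.position - heme_fe)),
            "fe1_elevation": elevation_angle(plane, fe1.position),
            "plane_residual": plane.rms_residual,
        }
        if ref_sel is not None:
            try:
                refs = ref_sel.resolve_atoms(model)
            except SelectionError as exc:
                raise SelectionError(f"frame {iframe}: {exc}") from exc
            d, (_, ref) = min_heavy_distance(
                [models.atom(cofactors.heme_iron, iframe)], refs
            )
            rec["ref_distance"] = d
            rec["ref_elevation"] = elevation_angle(plane, ref.position)
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    tail = df["fe_fe"].iloc[-max(1, len(df) // 4):]
    converged = bool(float(tail.std(ddof=0)) < convergence_threshold)
    return GeometrySeries(frame=df, converged=converged,
                          convergence_threshold=convergence_threshold)


# ---------------------------------------------------------------------------
# Interaction occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionCriterion:
    """A geometric interaction test evaluated per frame.

    kinds: 'hbond' (donor-acceptor heavy distance <= cutoff, plus a
    D-H...A angle test when hydrogens are present and angle_cutoff is
    set), 'saltbridge' (charged-group heavy distance <= cutoff) and
    'contact' (any heavy-atom pair <= cutoff). ``negate`` inverts the
    test, turning a salt-bridge criterion into an "open" criterion.
    """

    kind: str
    selection_a: str
    selection_b: str
    distance_cutoff: float = 0.0
    angle_cutoff: Optional[float] = None
    negate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "saltbridge", "contact"):
            raise EnsembleError(f"unknown criterion kind {self.kind!r}")
        cutoff = self.distance_cutoff or {
            "hbond": HBOND_DISTANCE_CUTOFF,
            "saltbridge": SALTBRIDGE_DISTANCE_CUTOFF,
            "contact": 4.5,
        }[self.kind]
        if cutoff <= 0:
            raise EnsembleError("distance cutoff must be > 0")
        object.__setattr__(self, "distance_cutoff", cutoff)
        if self.kind == "hbond" and self.angle_cutoff is None:
            object.__setattr__(self, "angle_cutoff", HBOND_ANGLE_CUTOFF)


@dataclass
class OccupancyResult:
    fraction: float
    n_frames: int
    block_se: float
    criterion: InteractionCriterion
    satisfied: np.ndarray = field(repr=False, default=None)


def _hbond_angle_ok(donors, acceptors, angle_cutoff: float) -> bool:
    """D-H...A angle >= cutoff for the best H; True when no H present."""
    hydrogens = [a for a in donors if not a.is_heavy]
    if not hydrogens:
        return True
    heavy_acc = [a for a in acceptors if a.is_heavy]
    heavy_don = [a for a in donors if a.is_heavy]
    best = 0.0
    for h in hydrogens:
        dists = [float(np.linalg.norm(h.position - d.position)) for d in heavy_don]
        d_atom = heavy_don[int(np.argmin(dists))]
        for acc in heavy_acc:
            v1 = d_atom.position - h.position
            v2 = acc.position - h.position
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            best = max(best, ang)
    return best >= angle_cutoff


def occupancy(
    models: Structure,
    criterion: InteractionCriterion,
    n_blocks: int = N_BLOCKS_DEFAULT,
) -> OccupancyResult:
    """Fraction of frames satisfying an interaction criterion.

    Boundary semantics are inclusive: a distance exactly at the cutoff
    counts as satisfied. The standard error comes from block averaging
    over ``n_blocks`` contiguous blocks, the simplest estimator that does
    not assume independent frames.
    """
    if models.n_models < 1:
        raise EnsembleError("occupancy needs at least one frame")
    sel_a = parse_selection(criterion.selection_a)
    sel_b = parse_selection(criterion.selection_b)

    flags = np.zeros(models.n_models, dtype=bool)
    for iframe, model in enumerate(models.models):
        try:
            atoms_a = sel_a.resolve(model, heavy_only=False)
            atoms_b = sel_b.resolve(model, heavy_only=False)
        except SelectionError as exc:
            raise SelectionError(f"frame {iframe}: {exc}") from exc
        aa = [a for _, _, a in atoms_a]
        bb = [a for _, _, a in atoms_b]
        d, _ = min_heavy_distance(aa, bb)
        ok = d <= criterion.distance_cutoff
        if ok and criterion.kind == "hbond" and criterion.angle_cutoff is not None:
            ok = _hbond_angle_ok(aa, bb, criterion.angle_cutoff)
        flags[iframe] = not ok if criterion.negate else ok

    fraction = float(flags.mean())
    blocks = np.array_split(flags.astype(float), min(n_blocks, len(flags)))
    block_means = np.array([b.mean() for b in blocks])
    if len(block_means) > 1:
        block_se = float(block_means.std(ddof=1) / math.sqrt(len(block_means)))
    else:
        block_se = float("nan")
    return OccupancyResult(
        fraction=fraction,
        n_frames=models.n_models,
        block_se=block_se,
        criterion=criterion,
        satisfied=flags,
    )
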