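"""End-to-end analysis workflows with machine-readable reports.

Three workflows compose the lower-level operations:

* :func:`run_complex_report` — one redox complex (or snapshot ensemble):
  heme-Fe to [2Fe-2S] distances, Fe1 heme-plane elevation, the tunneling
  rate those distances imply, and optionally the contiguity of an
  electron-relay path across frames.
* :func:`run_decoy_workflow` — docking decoy post-processing: rank poses by
  interface score, keep the top fraction, drop poses whose mean
  heme-Fe-to-cluster distance is not ET-competent, and report the tunneling
  rate range of the survivors.
* :func:`run_switch_report` — substrate-induced conformational change
  between two structures: global C-alpha RMSD, per-segment
  displacement/rotation, and named contact distances reported per chain
  copy.

Every report is a plain JSON-serializable dict with a provenance block
(package version + the configuration that produced it); identical inputs
and configuration reproduce byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ensembles import (
    PoseEnsemble,
    filter_by_mean_fe_distance,
    measure_poses,
    rank_top_fraction,
)
from .etkinetics import RulerParameters, moser_dutton_rate, path_proximity
from .geometry import (
    elevation_angle,
    fit_plane,
    min_heavy_distance,
    pair_residues,
    rmsd_ca,
    segment_displacement,
)
from .structio import (
    CofactorMap,
    CofactorNaming,
    SelectionError,
    Structure,
    detect_cofactors,
    parse_selection,
)

__all__ = [
    "run_complex_report",
    "run_decoy_workflow",
    "run_switch_report",
    "write_report",
    "EXIT_OK",
    "EXIT_FAILURE",
    "EXIT_EMPTY",
]

logger = logging.getLogger(__name__)

# Pipelines distinguish "nothing passed the filters" from "broke".
EXIT_OK = 0
EXIT_FAILURE = 1
EXIT_EMPTY = 2


def _provenance(config: dict) -> dict:
    return {"package": "p450fx", "version": __version__, "config": config}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Write a report deterministically (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Complex report
# ---------------------------------------------------------------------------

def run_complex_report(
    structure: Structure,
    chain: Optional[str] = None,
    naming: CofactorNaming | dict | None = None,
    cofactors: Optional[CofactorMap] = None,
    ruler: Optional[RulerParameters] = None,
    waypoints: Optional[Sequence[str]] = None,
    hop_cutoff: float = 4.5,
) -> dict:
    """Donor-acceptor geometry and implied ET rate for one complex.

    For a single-model structure this reports the |Fe-Fe| metal-to-metal
    distances of a crystallographic complex; for a multi-model ensemble the
    per-model measurements and their range. Rates use the nearer cluster
    iron (Fe1) distance; the mean over both irons is reported alongside
    because decoy filtering conventionally averages the cluster.
    """
    ruler = ruler or RulerParameters()
    if cofactors is None:
        cofactors = detect_cofactors(structure, naming=naming, chain=chain)

    stage = "measure"
    try:
        per_model = []
        for imodel in range(structure.n_models):
            heme_fe = structure.atom(cofactors.heme_iron, imodel).position
            rec: dict = {"model": imodel}
            if cofactors.fes_irons:
                d = sorted(
                    float(np.linalg.norm(structure.atom(a, imodel).position - heme_fe))
                    for a in cofactors.fes_irons
                )
                fe1_addr = min(
                    cofactors.fes_irons,
                    key=lambda a: float(np.linalg.norm(structure.atom(a, imodel).position - heme_fe)),
                )
                plane = fit_plane(
                    structure.coords(cofactors.heme_plane_atoms, imodel),
                    orient_toward=structure.atom(fe1_addr, imodel).position,
                )
                rec.update(
                    fe_fe_min=d[0],
                    fe_fe_mean=(d[0] + d[1]) / 2.0,
                    fe1_elevation=elevation_angle(plane, structure.atom(fe1_addr, imodel).position),
                    log10_rate=moser_dutton_rate(d[0], ruler).log10_rate,
                    rate=moser_dutton_rate(d[0], ruler).rate,
                )
            per_model.append(rec)

        report: dict = {
            "provenance": _provenance({
                "chain": chain,
                "hop_cutoff": hop_cutoff,
                "ruler": dataclasses.asdict(ruler),
                "waypoints": list(waypoints) if waypoints else None,
            }),
            "source_id": structure.source_id,
            "n_models": structure.n_models,
            "heme_iron": str(cofactors.heme_iron),
            "fes_irons": [str(a) for a in cofactors.fes_irons],
            "per_model": per_model,
        }
        with_fes = [r for r in per_model if "fe_fe_min" in r]
        if with_fes:
            mins = [r["fe_fe_min"] for r in with_fes]
            report["fe_fe_min_range"] = [min(mins), max(mins)]
            report["rate_range"] = [
                moser_dutton_rate(max(mins), ruler).rate,
                moser_dutton_rate(min(mins), ruler).rate,
            ]
        if cofactors.substrate_c14_methyl is not None:
            heme_fe = structure.atom(cofactors.heme_iron, 0).position
            c14 = structure.atom(cofactors.substrate_c14_methyl, 0).position
            report["heme_fe_to_c14_methyl"] = float(np.linalg.norm(c14 - heme_fe))
            report["c14_methyl_atom"] = str(cofactors.substrate_c14_methyl)
        if waypoints:
            stage = "path_proximity"
            pp = path_proximity(structure, cofactors, waypoints, hop_cutoff=hop_cutoff)
            report["path"] = {
                "fraction_contiguous": pp.fraction_contiguous,
                "hop_cutoff": pp.hop_cutoff,
                "hops": pp.hop_labels,
            }
        return report
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


# ---------------------------------------------------------------------------
# Decoy workflow
# ---------------------------------------------------------------------------

def run_decoy_workflow(
    poses: Structure,
    scores: pd.DataFrame,
    cofactors: Optional[CofactorMap] = None,
    naming: CofactorNaming | dict | None = None,
    chain: Optional[str] = None,
    top_fraction: float = 0.007,
    distance_cutoff: float = 18.0,
    ruler: Optional[RulerParameters] = None,
    ligand_fes_selector: str = "*:FES:FE1,FE2",
) -> dict:
    """Rank -> distance-filter -> rate a docking decoy ensemble.

    Mirrors the standard decoy post-processing: sort by interface score,
    keep the best ``top_fraction``, then require the heme-iron to cluster
    *average* distance to be strictly below ``distance_cutoff``. The rate
    range endpoints are the ruler evaluated at the retained minimum and
    maximum Fe1 distances. ``status`` is 'empty' when nothing survives.
    """
    ruler = ruler or RulerParameters()
    if cofactors is None:
        cofactors = detect_cofactors(poses, naming=naming, chain=chain)

    ensemble = measure_poses(poses, cofactors, ligand_fes_selector, scores=scores)
    ranked = rank_top_fraction(ensemble, top_fraction)
    retained = filter_by_mean_fe_distance(ranked, distance_cutoff)

    report: dict = {
        "provenance": _provenance({
            "top_fraction": top_fraction,
            "distance_cutoff": distance_cutoff,
            "ruler": dataclasses.asdict(ruler),
            "ligand_fes_selector": ligand_fes_selector,
        }),
        "source_id": poses.source_id,
        "n_poses": len(ensemble),
        "n_errored": sum(1 for p in ensemble.poses if p.error is not None),
        "n_ranked": len(ranked),
        "n_retained": len(retained),
        "status": "ok" if len(retained) else "empty",
        "retained": [
            {
                "model_index": p.model_index,
                "score": p.score,
                "fe_fe_min": p.fe_fe_min,
                "fe_fe_mean": p.fe_fe_mean,
                "elevation": p.elevation,
            }
            for p in retained.poses
        ],
    }
    if retained.poses:
        dmin = min(p.fe_fe_min for p in retained.poses)
        dmax = max(p.fe_fe_min for p in retained.poses)
        report["fe_fe_min_range"] = [dmin, dmax]
        report["rate_range"] = [
            moser_dutton_rate(dmax, ruler).rate,
            moser_dutton_rate(dmin, ruler).rate,
        ]
        report["log10_rate_range"] = [
            moser_dutton_rate(dmax, ruler).log10_rate,
            moser_dutton_rate(dmin, ruler).log10_rate,
        ]
    else:
        logger.warning("decoy workflow: no ET-competent poses retained")
    return report


# ---------------------------------------------------------------------------
# Conformational-switch report
# ---------------------------------------------------------------------------

def run_switch_report(
    a: Structure,
    b: Structure,
    pairing_mode: str = "same_numbering",
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
    offset: int = 0,
    segments: Optional[dict[str, tuple[int, int]]] = None,
    contacts: Optional[Sequence[tuple[str, str]]] = None,
) -> dict:
    """Quantify a conformational change between two structures.

    Reports the global C-alpha RMSD under the requested pairing, the
    displacement and rotation of each named segment (measured after
    superposing on everything outside that segment), and minimum
    heavy-atom distances for named contact pairs. Contacts whose selections
    use the wildcard chain are evaluated once per chain of ``a`` (e.g. per
    crystallographic copy), so copy-to-copy variation is visible.
    """
    pairing = pair_residues(a, b, mode=pairing_mode, chain_a=chain_a,
                            chain_b=chain_b, offset=offset)
    report: dict = {
        "provenance": _provenance({
            "pairing_mode": pairing_mode,
            "chain_a": chain_a,
            "chain_b": chain_b,
            "offset": offset,
            "segments": {k: list(v) for k, v in (segments or {}).items()},
            "contacts": [list(c) for c in (contacts or [])],
        }),
        "source_a": a.source_id,
        "source_b": b.source_id,
        "n_pairs": len(pairing),
        "rmsd_ca": rmsd_ca(a, b, pairing),
    }

    seg_rows = {}
    for name, rng in (segments or {}).items():
        disp = segment_displacement(a, b, pairing, tuple(rng), chain_a=chain_a,
                                    chain_b=chain_b, offset=offset)
        seg_rows[name] = {
            "range": list(rng),
            "mean_shift": disp.mean_shift,
            "max_shift": disp.max_shift,
            "rotation_deg": disp.rotation_deg,
            "n_residues": disp.n_residues,
        }
    if seg_rows:
        report["segments"] = seg_rows

    contact_rows = []
    model = a.models[0]
    for sel_text_a, sel_text_b in contacts or []:
        s1, s2 = parse_selection(sel_text_a), parse_selection(sel_text_b)
        per_chain: dict[str, float] = {}
        chains = [c.cid for c in model.chains] if s1.chain == "*" else [s1.chain]
        for cid in chains:
            c1 = dataclasses.replace(s1, chain=cid)
            c2 = dataclasses.replace(s2, chain=cid) if s2.chain == "*" else s2
            try:
                d, _ = min_heavy_distance(c1.resolve_atoms(model), c2.resolve_atoms(model))
            except SelectionError:
                continue
            per_chain[cid] = d
        contact_rows.append({
            "selection_a": sel_text_a,
            "selection_b": sel_text_b,
            "distance_by_chain": per_chain,
            "min_distance": min(per_chain.values()) if per_chain else None,
        })
    if contact_rows:
        report["contacts"] = contact_rows
    return report
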