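"""Pose ranking/filtering and snapshot-ensemble statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from p450fx.ensembles import (
    EnsembleError,
    InteractionCriterion,
    filter_by_mean_fe_distance,
    geometry_series,
    measure_poses,
    occupancy,
    rank_top_fraction,
)
from p450fx.structio import SelectionError, Structure, copy_model
from p450fx.synthdata import (
    PoseGenConfig,
    TwoStateConfig,
    sample_pose_ensemble,
    simulate_two_state_series,
)

SALT_BRIDGE = dict(kind="saltbridge", selection_a="A:178:OE1,OE2",
                   selection_b="A:259:ND1,NE2")


# ---------------------------------------------------------------------------
# measure_poses
# ---------------------------------------------------------------------------

def test_zero_spread_ensemble_measures_exactly(toy):
    _, cof = toy
    poses, scores, _ = sample_pose_ensemble(
        PoseGenConfig(n_poses=5, fe_fe_mean=15.0, fe_fe_sd=0.0, score_noise_sd=0.0, seed=0)
    )
    ens = measure_poses(poses, cof, scores=scores)
    assert len(ens) == 5
    for p in ens.poses:
        assert p.fe_fe_min == pytest.approx(15.0, abs=1e-9)
        assert p.fe_fe_min <= p.fe_fe_mean


def test_measured_distances_match_generator_log(toy, small_pose_set):
    _, cof = toy
    poses, scores, truth = small_pose_set
    ens = measure_poses(poses, cof, scores=scores)
    df = ens.to_frame()
    assert np.allclose(df["fe_fe_min"], truth["distance"], atol=1e-9)
    assert df["fe_fe_min"].min() == pytest.approx(truth["distance"].min())
    assert df["fe_fe_min"].max() == pytest.approx(truth["distance"].max())
    assert np.allclose(df["score"], truth["score"])


def test_single_pose_ensemble(toy):
    _, cof = toy
    poses, scores, _ = sample_pose_ensemble(PoseGenConfig(n_poses=1, seed=4))
    ens = measure_poses(poses, cof, scores=scores)
    assert len(ens) == 1


def test_pose_missing_cluster_is_flagged_not_fatal(toy, small_pose_set):
    _, cof = toy
    poses, scores, _ = small_pose_set
    models = [copy_model(m) for m in poses.models[:4]]
    broken = models[2].chain("B")
    broken.residues = [r for r in broken.residues if r.name != "FES"]
    st = Structure(models=models, source_id="broken")
    ens = measure_poses(st, cof, scores=scores)
    assert len(ens) == 4
    assert ens.poses[2].error is not None
    assert math.isnan(ens.poses[2].fe_fe_min)
    assert all(p.error is None for i, p in enumerate(ens.poses) if i != 2)


# ---------------------------------------------------------------------------
# rank / filter
# ---------------------------------------------------------------------------

def _fake_ensemble(toy_cof, scored):
    from p450fx.ensembles import Pose, PoseEnsemble

    poses = [
        Pose(model_index=i, fe_fe_min=d, fe_fe_mean=dm, elevation=0.0, score=s)
        for i, (s, d, dm) in enumerate(scored)
    ]
    return PoseEnsemble(poses=poses, receptor_cofactors=toy_cof)


def test_rank_top_fraction_counts_and_stability(toy):
    _, cof = toy
    ens = _fake_ensemble(cof, [(float(i % 7), 15.0, 15.5) for i in range(3000)])
    top = rank_top_fraction(ens, 0.007)
    assert len(top) == 21  # ceil(0.007 * 3000)
    assert [p.score for p in top.poses] == sorted(p.score for p in top.poses)
    # stability: equal scores keep ascending model_index order
    zeros = [p.model_index for p in top.poses if p.score == 0.0]
    assert zeros == sorted(zeros)
    assert len(rank_top_fraction(ens, 1.0)) == 3000


def test_rank_requires_scores(toy):
    _, cof = toy
    ens = _fake_ensemble(cof, [(1.0, 15.0, 15.5)])
    ens.poses[0].score = None
    with pytest.raises(EnsembleError):
        rank_top_fraction(ens, 0.5)
    with pytest.raises(EnsembleError):
        rank_top_fraction(ens, 0.0)


def test_distance_filter_strict_boundary(toy):
    _, cof = toy
    ens = _fake_ensemble(
        cof, [(1.0, 17.0, 17.9), (2.0, 17.0, 18.0), (3.0, 17.0, 18.1)]
    )
    kept = filter_by_mean_fe_distance(ens, 18.0)
    assert [p.fe_fe_mean for p in kept.poses] == [17.9]
    assert len(filter_by_mean_fe_distance(ens, float("inf"))) == 3
    assert len(filter_by_mean_fe_distance(ens, 0.0)) == 0  # empty result is valid


def test_rank_then_filter_subset_and_predicates(toy, small_pose_set):
    _, cof = toy
    poses, scores, _ = small_pose_set
    ens = measure_poses(poses, cof, scores=scores)
    out = filter_by_mean_fe_distance(rank_top_fraction(ens, 0.2), 16.5)
    ids = {p.model_index for p in ens.poses}
    threshold = sorted(p.score for p in ens.poses)[math.ceil(0.2 * len(ens)) - 1]
    for p in out.poses:
        assert p.model_index in ids
        assert p.score <= threshold
        assert p.fe_fe_mean < 16.5
    # brute-force recount oracle
    brute = [
        p for p in sorted(ens.poses, key=lambda q: q.score)[: math.ceil(0.2 * len(ens))]
        if p.fe_fe_mean < 16.5
    ]
    assert [p.model_index for p in out.poses] == [p.model_index for p in brute]


# ---------------------------------------------------------------------------
# geometry series
# ---------------------------------------------------------------------------

def test_static_trajectory_zero_variance(toy):
    st, cof = toy
    static = Structure(models=[copy_model(st.models[0]) for _ in range(6)],
                       source_id="static")
    series = geometry_series(static, cof, reference_atom="B:63:CG")
    assert series.frame["fe_fe"].std() == pytest.approx(0.0, abs=1e-12)
    assert series.frame["ref_distance"].std() == pytest.approx(0.0, abs=1e-12)
    assert series.converged


def test_two_state_series_bimodal_at_programmed_means():
    cfg = TwoStateConfig(n_frames=400, p_open=0.5, persistence=0.5, seed=9)
    traj, truth = simulate_two_state_series(cfg)
    crit = InteractionCriterion(**SALT_BRIDGE)
    occ = occupancy(traj, crit)
    closed = truth["distance"][truth["state"] == "closed"]
    opened = truth["distance"][truth["state"] == "open"]
    assert closed.mean() == pytest.approx(cfg.closed_distance_mean, abs=0.1)
    assert opened.mean() == pytest.approx(cfg.open_distance_mean, abs=0.2)
    # emitted distances are what the structure encodes
    from p450fx.geometry import min_heavy_distance
    from p450fx.structio import parse_selection

    sel_a = parse_selection(SALT_BRIDGE["selection_a"])
    sel_b = parse_selection(SALT_BRIDGE["selection_b"])
    d0, _ = min_heavy_distance(sel_a.resolve_atoms(traj.models[0]),
                               sel_b.resolve_atoms(traj.models[0]))
    assert d0 == pytest.approx(truth["distance"].iloc[0], abs=1e-9)


def test_rigid_translation_changes_distances_not_plane_residual(toy):
    st, cof = toy
    models = []
    for i in range(4):
        m = copy_model(st.models[0])
        for c in m.chains:
            if c.cid == "B":
                for r in c.residues:
                    for a in r.atoms:
                        a.position = a.position + np.array([0.0, 0.0, -2.0 * i])
        models.append(m)
    traj = Structure(models=models, source_id="sliding")
    series = geometry_series(traj, cof)
    assert series.frame["fe_fe"].nunique() == 4
    assert np.allclose(series.frame["plane_residual"], 0.0, atol=1e-12)


def test_series_missing_iron_names_frame(toy):
    st, cof = toy
    models = [copy_model(st.models[0]) for _ in range(3)]
    fes = models[1].chain("B").residues
    models[1].chain("B").residues = [r for r in fes if r.name != "FES"]
    traj = Structure(models=models, source_id="gap")
    with pytest.raises(SelectionError, match="frame 1"):
        geometry_series(traj, cof)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def test_occupancy_all_closed_and_open_complement():
    traj, _ = simulate_two_state_series(TwoStateConfig(n_frames=50, p_open=0.0, seed=1))
    closed = occupancy(traj, InteractionCriterion(**SALT_BRIDGE))
    assert closed.fraction == 1.0
    opened = occupancy(traj, InteractionCriterion(**SALT_BRIDGE, negate=True))
    assert opened.fraction == 0.0


def test_occupancy_matches_generator_log_exactly():
    """Non-overlapping emission distributions let the logged states predict
    the per-frame criterion outcome exactly."""
    cfg = TwoStateConfig(n_frames=600, p_open=0.3, persistence=0.8, seed=21)
    traj, truth = simulate_two_state_series(cfg)
    res = occupancy(traj, InteractionCriterion(**SALT_BRIDGE, negate=True))
    # all emissions stay on their side of the 4.0 A cutoff for these params
    assert ((truth["distance"] > 4.0) == (truth["state"] == "open")).all()
    assert res.fraction == pytest.approx((truth["state"] == "open").mean(), abs=1e-12)
    assert np.array_equal(res.satisfied, (truth["state"] == "open").to_numpy())


def test_occupancy_recovers_programmed_open_probability():
    cfg = TwoStateConfig(n_frames=2000, p_open=0.30, persistence=0.9, seed=7)
    traj, _ = simulate_two_state_series(cfg)
    res = occupancy(traj, InteractionCriterion(**SALT_BRIDGE, negate=True))
    assert res.fraction == pytest.approx(0.30, abs=3 * max(res.block_se, 1e-3))


def test_occupancy_boundary_is_inclusive(toy):
    st, _ = toy
    # engineer a frame with the pair exactly at the cutoff
    m = copy_model(st.models[0])
    res259 = m.chain("A").residue(259)
    res178 = m.chain("A").residue(178)
    shift = np.array([0.0, 0.0, -(4.0 - 2.8)])
    for a in res259.atoms:
        a.position = a.position + shift
    d = np.linalg.norm(res178.atom("OE1").position - res259.atom("NE2").position)
    assert d == pytest.approx(4.0)
    traj = Structure(models=[m], source_id="boundary")
    res = occupancy(traj, InteractionCriterion(**SALT_BRIDGE))
    assert res.fraction == 1.0


def test_occupancy_rejects_bad_inputs():
    with pytest.raises(EnsembleError):
        InteractionCriterion(kind="magic", selection_a="A:1", selection_b="A:2")
    with pytest.raises(EnsembleError):
        InteractionCriterion(kind="contact", selection_a="A:1", selection_b="A:2",
                             distance_cutoff=-1.0)
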