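"""Synthetic inputs with logged ground truth.

Three generators stand in for data classes that published studies of
P450-ferredoxin fusions produce but rarely deposit: rigid-body docking
decoys, MD snapshot trajectories, and the redox complex itself.

* :func:`make_toy_complex` — a minimal two-chain redox complex: an exactly
  planar 8-atom porphyrin core with its iron at the centroid, an axial
  cysteine, a heme-bulge lysine, a bound sterol stand-in, a salt-bridge
  donor/acceptor pair (Glu178/His259), and a [2Fe-2S] ligand chain whose
  proximal iron (FE1) sits exactly 15.0 A from the heme iron, with a
  cluster-ligating glutamate and a surface proline. Every cofactor resolves
  with the default naming config.
* :func:`sample_pose_ensemble` — rigid ligand placements at
  normally-distributed Fe1 distances in uniformly random orientations, with
  a distance-correlated score; emulates a docking decoy set.
* :func:`simulate_two_state_series` — a hidden two-state (closed/open)
  Markov chain emitting donor-acceptor distances, the acceptor residue
  moved accordingly; emulates a salt-bridge opening/closing trajectory.

Every generator takes one integer seed, is bit-deterministic for that seed,
and returns its ground truth (sampled distances, scores, state sequence)
alongside the structures; downstream estimators are tested against these
logs, never against published values, for anything stochastic.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .structio import (
    Atom,
    Chain,
    CofactorMap,
    Model,
    Residue,
    Structure,
    copy_model,
    detect_cofactors,
    write_multimodel,
)

__all__ = [
    "PoseGenConfig",
    "TwoStateConfig",
    "ConfigError",
    "make_toy_complex",
    "sample_pose_ensemble",
    "simulate_two_state_series",
]

#: Ruler van der Waals contact distance; sampled Fe-Fe distances are
#: truncated to stay above it.
CONTACT_DISTANCE = 3.6

LIGAND_CHAIN = "B"
RECEPTOR_CHAIN = "A"
TOY_FE_FE = 15.0


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------

def _res(name: str, seqid: int, atoms: list[tuple[str, str, tuple[float, float, float]]],
         het: bool = False) -> Residue:
    return Residue(
        name=name,
        seqid=seqid,
        het=het,
        atoms=[Atom(name=n, element=e, position=np.array(p)) for n, e, p in atoms],
    )


def make_toy_complex() -> tuple[Structure, CofactorMap]:
    """Build the toy redox complex (see module docstring).

    Layout (A): the heme plane is z = 0 with Fe at the origin; the ligand
    chain sits on the proximal (-z) side with FE1 at (0, 0, -15); the
    sterol stand-in sits on the distal side with its nearest carbon 4.1 A
    above the iron; Glu178 OE1 and His259 NE2 are 2.8 A apart. The
    electron-relay waypoints FE1 -> Glu19 -> Lys393 -> Cys394 -> heme Fe
    are each within 4.5 A of their neighbours.
    """
    heme_core = []
    for name, radius, angles in (
        (("NA", "NB", "NC", "ND"), 2.0, (45, 135, 225, 315)),
        (("CHA", "CHB", "CHC", "CHD"), 3.4, (0, 90, 180, 270)),
    ):
        for n, ang in zip(name, angles):
            t = math.radians(ang)
            el = "N" if n.startswith("N") else "C"
            heme_core.append((n, el, (radius * math.cos(t), radius * math.sin(t), 0.0)))
    heme = _res("HEM", 500, [("FE", "FE", (0.0, 0.0, 0.0))] + heme_core, het=True)

    receptor = Chain(RECEPTOR_CHAIN)
    # Pseudo-protein scaffold: a dozen glycines on an irregular ring, giving
    # the chain C-alpha atoms for pairing/superposition work.
    for i in range(12):
        t = 2 * math.pi * i / 12
        r = 11.0 + (i % 3)
        ca = (r * math.cos(t), r * math.sin(t), 2.0 * math.sin(3 * t))
        n = (ca[0] - 0.8, ca[1] + 0.9, ca[2] + 0.4)
        o = (ca[0] + 0.7, ca[1] - 0.6, ca[2] - 0.9)
        receptor.residues.append(
            _res("GLY", i + 1, [("N", "N", n), ("CA", "C", ca), ("O", "O", o)])
        )
    receptor.residues.append(
        _res("GLU", 178, [
            ("CA", "C", (8.0, 0.0, 4.9)),
            ("CD", "C", (8.0, 0.0, 3.5)),
            ("OE1", "O", (8.0, 0.0, 2.8)),
            ("OE2", "O", (8.8, 0.8, 3.8)),
        ])
    )
    receptor.residues.append(
        _res("HIS", 259, [
            ("CA", "C", (8.0, 0.0, -2.2)),
            ("CG", "C", (8.0, 0.0, -0.9)),
            ("ND1", "N", (8.0, 0.9, -0.1)),
            ("NE2", "N", (8.0, 0.0, 0.0)),
        ])
    )
    receptor.residues.append(
        _res("LYS", 393, [
            ("CA", "C", (1.5, 0.3, -7.5)),
            ("CB", "C", (0.8, 0.2, -6.5)),
            ("NZ", "N", (0.0, 0.0, -9.0)),
        ])
    )
    receptor.residues.append(
        _res("CYS", 394, [
            ("CA", "C", (1.2, -0.4, -4.0)),
            ("CB", "C", (0.5, 0.0, -3.5)),
            ("SG", "S", (0.0, 0.0, -2.3)),
        ])
    )
    receptor.residues.append(heme)
    receptor.residues.append(
        _res("LAN", 600, [
            ("C30", "C", (0.0, 0.0, 4.1)),
            ("C14", "C", (0.8, 0.1, 5.3)),
            ("C13", "C", (1.8, 0.6, 6.0)),
            ("C3", "C", (3.5, 1.0, 7.4)),
            ("O3", "O", (4.2, 0.4, 8.2)),
        ], het=True)
    )

    ligand = Chain(LIGAND_CHAIN)
    ligand.residues.append(
        _res("GLU", 19, [
            ("CA", "C", (2.2, 0.0, -13.3)),
            ("CD", "C", (0.9, 0.0, -13.0)),
            ("OE1", "O", (0.0, 0.0, -13.0)),
            ("OE2", "O", (0.9, 0.9, -12.3)),
        ])
    )
    for i, seqid in enumerate((40, 41, 42, 43)):
        t = 2 * math.pi * i / 4
        ca = (3.5 * math.cos(t), 3.5 * math.sin(t), -16.0 - 0.8 * i)
        ligand.residues.append(_res("GLY", seqid, [("CA", "C", ca)]))
    ligand.residues.append(
        _res("PRO", 63, [
            ("CA", "C", (4.6, 0.4, -18.6)),
            ("CB", "C", (4.4, 0.1, -17.6)),
            ("CG", "C", (4.0, 0.0, -18.0)),
        ])
    )
    ligand.residues.append(
        _res("FES", 700, [
            ("FE1", "FE", (0.0, 0.0, -TOY_FE_FE)),
            ("FE2", "FE", (0.0, 0.0, -TOY_FE_FE - 2.7)),
            ("S1", "S", (1.1, 0.0, -TOY_FE_FE - 1.35)),
            ("S2", "S", (-1.1, 0.0, -TOY_FE_FE - 1.35)),
        ], het=True)
    )

    structure = Structure(models=[Model(chains=[receptor, ligand])], source_id="toy_complex")
    return structure, detect_cofactors(structure)


# ---------------------------------------------------------------------------
# Pose ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseGenConfig:
    """Rigid-pose generator settings.

    Defaults emulate a docking decoy set of the size and geometric spread
    reported for P450-ferredoxin interface searches: 3000 decoys with
    cluster distances centred a little above the ET-competent range, and an
    interface score correlated with distance (nearer poses scoring better)
    plus noise.
    """

    n_poses: int = 3000
    fe_fe_mean: float = 16.0      # A
    fe_fe_sd: float = 1.5         # A
    score_slope: float = 5.0      # score units per A
    score_noise_sd: float = 4.0   # score units
    score_offset: float = -210.0  # score units; puts scores in an
                                  # interface-energy-like negative range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ConfigError("n_poses must be >= 1")
        if self.fe_fe_sd < 0 or self.score_noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.fe_fe_mean <= CONTACT_DISTANCE:
            raise ConfigError(f"fe_fe_mean must exceed contact distance {CONTACT_DISTANCE} A")


def _uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized 4-normal quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _transform_chain(chain: Chain, rot: np.ndarray, pivot: np.ndarray,
                     dest: np.ndarray) -> None:
    for r in chain.residues:
        for a in r.atoms:
            a.position = rot @ (a.position - pivot) + dest


def sample_pose_ensemble(
    config: PoseGenConfig,
    out_dir: Optional[str | Path] = None,
) -> tuple[Structure, pd.DataFrame, pd.DataFrame]:
    """Sample a rigid-pose ensemble around the toy receptor.

    Each pose rotates the ligand chain uniformly at random about its
    proximal iron (FE1), then places FE1 at a N(fe_fe_mean, fe_fe_sd)
    distance (truncated above van der Waals contact) from the heme iron
    along a uniformly random direction. Orientations that would bring the
    second iron nearer the heme than FE1 are rejected and resampled, so
    FE1 is by construction the proximal iron of every pose and the logged
    distance is exact. Score = offset + slope * distance + noise.

    Returns (poses, score table, ground-truth log); with ``out_dir`` also
    writes poses.pdb, scores.csv, truth.csv and config.json.
    """
    base, cof = make_toy_complex()
    rng = np.random.default_rng(config.seed)
    heme_fe = base.atom(cof.heme_iron).position
    base_model = base.models[0]
    fe1_home = base.atom(cof.fes_irons[0]).position

    models: list[Model] = []
    truth_rows = []
    for i in range(config.n_poses):
        d = -1.0
        while d <= CONTACT_DISTANCE:
            d = rng.normal(config.fe_fe_mean, config.fe_fe_sd) if config.fe_fe_sd > 0 else config.fe_fe_mean
        # uniform direction on the sphere
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        dest = heme_fe + d * u
        model = copy_model(base_model)
        ligand = model.chain(LIGAND_CHAIN)
        fe2_home = base_model.chain(LIGAND_CHAIN).residue(700).atom("FE2").position
        while True:
            rot = _uniform_rotation(rng)
            fe2_new = rot @ (fe2_home - fe1_home) + dest
            if np.linalg.norm(fe2_new - heme_fe) > d:
                break
        _transform_chain(ligand, rot, fe1_home, dest)
        score = config.score_offset + config.score_slope * d
        if config.score_noise_sd > 0:
            score += rng.normal(0.0, config.score_noise_sd)
        truth_rows.append({"model_index": i, "distance": d, "score": score})
        models.append(model)

    poses = Structure(models=models, source_id=f"synthetic_poses_seed{config.seed}")
    truth = pd.DataFrame(truth_rows)
    scores = truth[["model_index", "score"]].copy()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_multimodel(poses, out / "poses.pdb")
        scores.to_csv(out / "scores.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
        (out / "config.json").write_text(json.dumps(
            {**asdict(config), "rng": "numpy PCG64 default_rng",
             "rotation_scheme": "normalized 4-normal quaternion"},
            indent=2, sort_keys=True) + "\n")
    return poses, scores, truth


# ---------------------------------------------------------------------------
# Two-state trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateConfig:
    """Two-state (closed/open) salt-bridge trajectory settings.

    The hidden chain is a stationary two-state Markov process with open
    fraction ``p_open`` and a persistence knob (the frame-weighted mean
    probability of remaining in the current state). Emitted donor-acceptor
    distances are state-conditional normals whose defaults (2.8 A closed /
    6.0 A open) straddle the 4.0 A salt-bridge cutoff with negligible
    overlap, so occupancy estimates can be checked against the logged
    states exactly.
    """

    n_frames: int = 2000
    p_open: float = 0.45
    closed_distance_mean: float = 2.8
    closed_distance_sd: float = 0.2
    open_distance_mean: float = 6.0
    open_distance_sd: float = 0.5
    persistence: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if not 0 <= self.p_open <= 1:
            raise ConfigError("p_open must be in [0, 1]")
        if not 0 <= self.persistence < 1:
            raise ConfigError("persistence must be in [0, 1)")
        if self.open_distance_mean <= self.closed_distance_mean:
            raise ConfigError("open state must be more distant than closed state")


def _transition_rates(p_open: float, persistence: float) -> tuple[float, float]:
    """(alpha, beta) = P(open->closed), P(closed->open).

    Chosen so the stationary open fraction is exactly p_open and the
    stationary frame-weighted stay probability is ``persistence``:
    with c = (1 - persistence) / (2 p (1-p)), alpha = c (1-p), beta = c p.
    """
    if p_open in (0.0, 1.0):
        return 0.0, 0.0
    c = (1.0 - persistence) / (2.0 * p_open * (1.0 - p_open))
    alpha, beta = c * (1.0 - p_open), c * p_open
    if alpha > 1.0 or beta > 1.0:
        raise ConfigError(
            f"persistence {persistence} too low for p_open {p_open}: "
            "transition probabilities exceed 1"
        )
    return alpha, beta


def simulate_two_state_series(
    config: TwoStateConfig,
    out_dir: Optional[str | Path] = None,
) -> tuple[Structure, pd.DataFrame]:
    """Simulate the two-state salt-bridge trajectory (see class docstring).

    Frames are copies of the toy complex with the His259 acceptor residue
    translated so its NE2 nitrogen sits the emitted distance from Glu178's
    OE1 oxygen (the closest donor-acceptor heavy pair). The initial state
    is drawn from the stationary distribution.

    Returns (trajectory, truth log) with per-frame state ('open'/'closed')
    and emitted distance; with ``out_dir`` also writes trajectory.pdb,
    truth.csv and config.json.
    """
    base, _ = make_toy_complex()
    base_model = base.models[0]
    alpha, beta = _transition_rates(config.p_open, config.persistence)
    rng = np.random.default_rng(config.seed)

    donor = base_model.chain(RECEPTOR_CHAIN).residue(178).atom("OE1").position
    acceptor_res = base_model.chain(RECEPTOR_CHAIN).residue(259)
    ne2 = acceptor_res.atom("NE2").position
    axis = (ne2 - donor) / np.linalg.norm(ne2 - donor)
    base_d = float(np.linalg.norm(ne2 - donor))

    open_state = bool(rng.random() < config.p_open)
    rows = []
    models: list[Model] = []
    for i in range(config.n_frames):
        if i > 0:
            flip_p = alpha if open_state else beta
            if rng.random() < flip_p:
                open_state = not open_state
        mean = config.open_distance_mean if open_state else config.closed_distance_mean
        sd = config.open_distance_sd if open_state else config.closed_distance_sd
        d = -1.0
        while d < 1.0:
            d = rng.normal(mean, sd) if sd > 0 else mean
        model = copy_model(base_model)
        res = model.chain(RECEPTOR_CHAIN).residue(259)
        shift = (d - base_d) * axis
        for a in res.atoms:
            a.position = a.position + shift
        models.append(model)
        rows.append({"frame": i, "state": "open" if open_state else "closed", "distance": d})

    traj = Structure(models=models, source_id=f"synthetic_twostate_seed{config.seed}")
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_multimodel(traj, out / "trajectory.pdb")
        truth.to_csv(out / "truth.csv", index=False)
        (out / "config.json").write_text(json.dumps(
            {**asdict(config), "rng": "numpy PCG64 default_rng"},
            indent=2, sort_keys=True) + "\n")
    return traj, truth
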