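import numpy as np
import pytest

from p450fx.structio import Atom, Chain, Model, Residue, Structure
from p450fx.synthdata import PoseGenConfig, make_toy_complex, sample_pose_ensemble


@pytest.fixture(scope="session")
def toy():
    """(Structure, CofactorMap) of the synthetic toy redox complex."""
    return make_toy_complex()


@pytest.fixture(scope="session")
def small_pose_set():
    """50 seeded synthetic poses: (Structure, scores, truth log)."""
    return sample_pose_ensemble(PoseGenConfig(n_poses=50, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def build_structure(atom_positions, resname="ALA", element="C", chain="A"):
    """One-residue structure from a list of xyz positions."""
    res = Residue(
        name=resname,
        seqid=1,
        atoms=[
            Atom(name=f"C{i}", element=element, position=np.asarray(p, dtype=float))
            for i, p in enumerate(atom_positions)
        ],
    )
    return Structure(models=[Model(chains=[Chain(chain, [res])])], source_id="test")


@pytest.fixture()
def make_shell():
    """Factory for a hollow spherical shell of wall atoms (cavity tests)."""

    def _make(r_cavity=5.0, probe=1.4, n=800):
        golden = np.pi * (3 - 5 ** 0.5)
        radius = r_cavity + probe
        pts = []
        for i in range(n):
            y = 1 - 2 * i / (n - 1)
            rad = np.sqrt(max(0.0, 1 - y * y))
            th = golden * i
            pts.append((radius * np.cos(th) * rad, radius * y, radius * np.sin(th) * rad))
        return build_structure(pts)

    return _make
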