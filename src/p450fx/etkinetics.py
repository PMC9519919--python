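"""Electron-transfer kinetics: the distance-to-rate ruler and affinity math.

The empirical Moser-Dutton ruler estimates the nonadiabatic electron
tunneling rate between a donor and acceptor buried in protein from their
edge-to-edge distance R (A) and the Marcus activation term:

    log10 k_et = C - beta_10 (R - R0) - gamma (dG + lambda)^2 / lambda

with C = 13 the log-rate at van der Waals contact (R0 = 3.6 A), beta_10 =
0.6 /A the exponential fall-off through the insulating protein medium,
gamma = 3.1 the room-temperature Franck-Condon coefficient, dG the driving
force and lambda the reorganization energy (both eV). For a thermoneutral
reaction (dG = 0, lambda = 1 eV) the activation term costs 3.1 log units.

Also here: the Kd <-> binding free energy conversion (dG = RT ln Kd for Kd
in mol/L, so negative dG means sub-molar Kd) and the path-contiguity test
used to ask whether an ordered relay of residues stays within hopping
distance across an ensemble of snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import min_heavy_distance
from .structio import CofactorMap, Selection, SelectionError, Structure, parse_selection

__all__ = [
    "RulerParameters",
    "ETRateResult",
    "AffinityConversion",
    "ParameterError",
    "moser_dutton_rate",
    "deltag_to_kd",
    "kd_to_deltag",
    "path_proximity",
    "PathProximityResult",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.98720425e-3


class ParameterError(ValueError):
    """A kinetic/thermodynamic parameter is out of its valid domain."""


@dataclass(frozen=True)
class RulerParameters:
    """Constants of the distance-to-rate ruler (see module docstring)."""

    contact_log_rate: float = 13.0
    decay_per_angstrom: float = 0.6
    contact_distance: float = 3.6
    franck_condon_coeff: float = 3.1
    delta_g: float = 0.0          # eV
    lambda_reorg: float = 1.0     # eV

    def __post_init__(self) -> None:
        if self.lambda_reorg <= 0:
            raise ParameterError("reorganization energy lambda must be > 0 eV")
        if self.contact_distance <= 0:
            raise ParameterError("contact distance must be > 0 A")


@dataclass(frozen=True)
class ETRateResult:
    distance: float
    log10_rate: float
    parameters: RulerParameters
    clamped_to_contact: bool = False

    @property
    def rate(self) -> float:
        """Rate in s^-1."""
        return 10.0 ** self.log10_rate


def moser_dutton_rate(distance: float, params: RulerParameters | None = None) -> ETRateResult:
    """Electron tunneling rate at a donor-acceptor distance (A).

    Distances below van der Waals contact are clamped to the contact rate
    and flagged: the ruler is an interpolation for R >= R0, not a model of
    orbital overlap at shorter range.
    """
    if params is None:
        params = RulerParameters()
    if not math.isfinite(distance):
        raise ParameterError("distance must be finite")
    clamped = distance < params.contact_distance
    r = params.contact_distance if clamped else distance
    log10_rate = (
        params.contact_log_rate
        - params.decay_per_angstrom * (r - params.contact_distance)
        - params.franck_condon_coeff
        * (params.delta_g + params.lambda_reorg) ** 2
        / params.lambda_reorg
    )
    return ETRateResult(distance=distance, log10_rate=log10_rate,
                        parameters=params, clamped_to_contact=clamped)


# ---------------------------------------------------------------------------
# Binding free energy <-> dissociation constant
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityConversion:
    delta_g: float            # kcal/mol
    kd: float                 # mol/L
    temperature: float = 298.15


def deltag_to_kd(delta_g: float, temperature: float = 298.15) -> AffinityConversion:
    """Binding free energy (kcal/mol) to dissociation constant (mol/L).

    Kd = exp(dG / RT): a favourable (negative) dG gives Kd < 1 M.
    """
    if not math.isfinite(delta_g):
        raise ParameterError("delta_g must be finite")
    if temperature <= 0:
        raise ParameterError("temperature must be > 0 K")
    kd = math.exp(delta_g / (GAS_CONSTANT_KCAL * temperature))
    return AffinityConversion(delta_g=delta_g, kd=kd, temperature=temperature)


def kd_to_deltag(kd: float, temperature: float = 298.15) -> AffinityConversion:
    """Dissociation constant (mol/L) to binding free energy (kcal/mol)."""
    if kd <= 0 or not math.isfinite(kd):
        raise ParameterError("kd must be a positive finite molar concentration")
    if temperature <= 0:
        raise ParameterError("temperature must be > 0 K")
    dg = GAS_CONSTANT_KCAL * temperature * math.log(kd)
    return AffinityConversion(delta_g=dg, kd=kd, temperature=temperature)


# ---------------------------------------------------------------------------
# Electron-transfer path contiguity
# ---------------------------------------------------------------------------

@dataclass
class PathProximityResult:
    """Per-frame contiguity of an ordered electron-relay path."""

    fraction_contiguous: float
    n_frames: int
    hop_cutoff: float
    hop_labels: list[str]
    distances: pd.DataFrame = field(repr=False)


def path_proximity(
    models: Structure,
    cofactors: Optional[CofactorMap],
    waypoints: Sequence[str | Selection],
    hop_cutoff: float = 4.5,
) -> PathProximityResult:
    """Fraction of frames in which every consecutive waypoint pair touches.

    Waypoints are selection strings ('chain:residues[:atoms]') naming the
    relay stations in order, e.g. the [2Fe-2S] Fe1, a cluster-ligating
    glutamate, the heme-bulge lysine, the axial cysteine and the heme iron.
    A frame is contiguous when every consecutive pair's minimum heavy-atom
    distance is <= hop_cutoff (default 4.5 A, van der Waals contact range).
    Returns the contiguous-frame fraction plus the full per-hop series.
    """
    sels = [parse_selection(w) if isinstance(w, str) else w for w in waypoints]
    if len(sels) < 2:
        raise SelectionError("a path needs at least two waypoints")

    labels = [f"{sels[i].text}->{sels[i + 1].text}" for i in range(len(sels) - 1)]
    records = []
    n_contig = 0
    for iframe, model in enumerate(models.models):
        atom_sets = []
        for s in sels:
            try:
                atom_sets.append(s.resolve_atoms(model))
            except SelectionError as exc:
                raise SelectionError(f"frame {iframe}: {exc}") from exc
        row: dict = {"frame": iframe}
        ok = True
        for label, aa, bb in zip(labels, atom_sets[:-1], atom_sets[1:]):
            d, _ = min_heavy_distance(aa, bb)
            row[label] = d
            if d > hop_cutoff:
                ok = False
        row["contiguous"] = ok
        n_contig += ok
        records.append(row)

    df = pd.DataFrame.from_records(records)
    return PathProximityResult(
        fraction_contiguous=n_contig / len(models.models),
        n_frames=len(models.models),
        hop_cutoff=hop_cutoff,
        hop_labels=labels,
        distances=df,
    )


def with_params(base: RulerParameters | None = None, **overrides) -> RulerParameters:
    """Convenience: derive a RulerParameters with selected fields replaced."""
    return replace(base or RulerParameters(), **overrides)
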