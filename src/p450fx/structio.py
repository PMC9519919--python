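"""Coordinate I/O and cofactor location.

Reads PDB/mmCIF files into a light hierarchical model (models -> chains ->
residues -> atoms), writes multi-model PDB (the snapshot/pose interchange
format used throughout the package), and resolves the redox cofactors every
downstream measurement needs: the heme iron, the porphyrin core defining the
heme plane, the two irons of a [2Fe-2S] cluster, and the sterol substrate.

File parsing and format detection are delegated to :mod:`gemmi`; the model
kept here is deliberately minimal so that synthetic structures can be built
atom by atom and round-tripped through PDB text exactly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Model",
    "Structure",
    "AtomAddress",
    "CofactorMap",
    "CofactorNaming",
    "Selection",
    "StructureError",
    "ParseError",
    "FormatError",
    "RosterError",
    "SelectionError",
    "MissingCofactorError",
    "AmbiguousCofactorError",
    "read_structure",
    "write_multimodel",
    "detect_cofactors",
    "parse_selection",
]

# Elements never counted as "heavy" in distance criteria.
_LIGHT_ELEMENTS = {"H", "D"}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class StructureError(Exception):
    """Base class for structure-model errors."""


class ParseError(StructureError):
    """A coordinate file could not be parsed."""


class FormatError(StructureError):
    """An unknown or unsupported coordinate format was requested."""


class RosterError(StructureError):
    """Models meant to share an atom roster do not."""


class SelectionError(StructureError):
    """A selection string did not resolve to any atoms."""


class MissingCofactorError(StructureError):
    """A required cofactor (heme) is absent."""


class AmbiguousCofactorError(StructureError):
    """More than one heme in scope; an explicit chain choice is required."""


# ---------------------------------------------------------------------------
# Hierarchical model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom record.

    position is in the orthogonal Angstrom frame of the source file;
    b_factor in A^2; occupancy a fraction.
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    serial: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _LIGHT_ELEMENTS


@dataclass
class Residue:
    name: str
    seqid: int
    icode: str = ""
    het: bool = False
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def key(self) -> tuple[int, str]:
        return (self.seqid, self.icode)


@dataclass
class Chain:
    cid: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqid: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seqid == seqid and r.icode == icode:
                return r
        return None


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)

    def chain(self, cid: str) -> Optional[Chain]:
        for c in self.chains:
            if c.cid == cid:
                return c
        return None

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c, r

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c, r in self.iter_residues():
            for a in r.atoms:
                yield c, r, a

    def atom_count(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def roster(self) -> list[tuple[str, int, str, str, str]]:
        """(chain, seqid, icode, resname, atomname) in file order."""
        return [(c.cid, r.seqid, r.icode, r.name, a.name) for c, r, a in self.iter_atoms()]


@dataclass
class Structure:
    models: list[Model] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise StructureError("a Structure needs at least one model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def atom(self, address: "AtomAddress", model_index: int = 0) -> Atom:
        model = self.models[model_index]
        chain = model.chain(address.chain)
        if chain is None:
            raise SelectionError(f"chain {address.chain!r} not in model {model_index}")
        res = chain.residue(address.seqid, address.icode)
        if res is None:
            raise SelectionError(
                f"residue {address.chain}:{address.seqid}{address.icode} not in model {model_index}"
            )
        a = res.atom(address.atom)
        if a is None:
            raise SelectionError(f"atom {address} not in model {model_index}")
        return a

    def coords(self, addresses: Sequence["AtomAddress"], model_index: int = 0) -> np.ndarray:
        return np.array([self.atom(ad, model_index).position for ad in addresses])


@dataclass(frozen=True)
class AtomAddress:
    """Stable (chain, residue number + insertion code, atom name) address."""

    chain: str
    seqid: int
    icode: str
    resname: str
    atom: str

    def __str__(self) -> str:
        return f"{self.chain}:{self.resname}{self.seqid}{self.icode}:{self.atom}"


# ---------------------------------------------------------------------------
# Cofactor naming and detection
# ---------------------------------------------------------------------------

# Porphyrin core: four pyrrole nitrogens, plus the four meso carbons when the
# deposition names them; the nitrogens alone still define the plane.
HEME_PLANE_NITROGENS = ("NA", "NB", "NC", "ND")
HEME_PLANE_MESO = ("CHA", "CHB", "CHC", "CHD")


@dataclass
class CofactorNaming:
    """Residue/atom naming conventions used to locate cofactors.

    Defaults cover b-type heme (HEM), plant-type/adrenodoxin [2Fe-2S]
    clusters (FES/FS2) and common sterol ligand codes.
    """

    heme_residues: frozenset[str] = frozenset({"HEM", "HEB", "HEC"})
    heme_iron_atom: str = "FE"
    fes_residues: frozenset[str] = frozenset({"FES", "FS2"})
    fes_iron_atoms: tuple[str, ...] = ("FE1", "FE2")
    substrate_residues: frozenset[str] = frozenset({"LAN", "ERG", "CLR", "OBT", "LNL"})
    substrate_c14_methyl_atom: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "CofactorNaming":
        kw = {}
        for key in ("heme_residues", "fes_residues", "substrate_residues"):
            if key in d:
                kw[key] = frozenset(str(x).upper() for x in d[key])
        if "heme_iron_atom" in d:
            kw["heme_iron_atom"] = str(d["heme_iron_atom"]).upper()
        if "fes_iron_atoms" in d:
            kw["fes_iron_atoms"] = tuple(str(x).upper() for x in d["fes_iron_atoms"])
        if "substrate_c14_methyl_atom" in d:
            v = d["substrate_c14_methyl_atom"]
            kw["substrate_c14_methyl_atom"] = None if v is None else str(v).upper()
        return cls(**kw)


DEFAULT_NAMING = CofactorNaming()


@dataclass
class CofactorMap:
    """Resolved cofactor addresses for one receptor/ligand complex."""

    heme_iron: AtomAddress
    heme_plane_atoms: list[AtomAddress]
    fes_irons: list[AtomAddress] = field(default_factory=list)
    substrate_atoms: list[AtomAddress] = field(default_factory=list)
    substrate_c14_methyl: Optional[AtomAddress] = None

    def __post_init__(self) -> None:
        if len(self.heme_plane_atoms) < 4:
            raise StructureError("heme plane needs at least 4 atoms")
        if len(self.fes_irons) not in (0, 2):
            raise StructureError("fes_irons must be empty or a [2Fe-2S] pair")


def _addr(chain: Chain, res: Residue, atom: Atom) -> AtomAddress:
    return AtomAddress(chain.cid, res.seqid, res.icode, res.name, atom.name)


def detect_cofactors(
    structure: Structure,
    naming: CofactorNaming | dict | None = None,
    chain: Optional[str] = None,
    model_index: int = 0,
) -> CofactorMap:
    """Locate heme, [2Fe-2S] irons and substrate in one model.

    When the model holds several hemes (e.g. four P450 copies in an
    asymmetric unit) a chain must be named explicitly; the FeS cluster and
    substrate associated with the chosen heme are the nearest ones by
    iron/centroid distance, wherever their chain. Absent cofactors yield
    empty fields, never errors — only a missing heme is fatal.
    """
    if naming is None:
        naming = DEFAULT_NAMING
    elif isinstance(naming, dict):
        naming = CofactorNaming.from_dict(naming)

    model = structure.models[model_index]

    hemes: list[tuple[Chain, Residue]] = []
    for c, r in model.iter_residues():
        if r.name.upper() in naming.heme_residues:
            if chain is None or c.cid == chain:
                hemes.append((c, r))
    if not hemes:
        scope = f"chain {chain}" if chain else "structure"
        raise MissingCofactorError(f"no heme residue ({sorted(naming.heme_residues)}) in {scope}")
    if len(hemes) > 1:
        where = ", ".join(f"{c.cid}:{r.name}{r.seqid}" for c, r in hemes)
        raise AmbiguousCofactorError(
            f"{len(hemes)} hemes in scope ({where}); pass an explicit chain"
        )
    heme_chain, heme = hemes[0]

    fe = heme.atom(naming.heme_iron_atom)
    if fe is None:
        raise MissingCofactorError(
            f"heme {heme_chain.cid}:{heme.seqid} lacks iron atom {naming.heme_iron_atom!r}"
        )
    heme_iron = _addr(heme_chain, heme, fe)

    plane = [heme.atom(n) for n in HEME_PLANE_NITROGENS]
    if any(a is None for a in plane):
        raise MissingCofactorError(
            f"heme {heme_chain.cid}:{heme.seqid} lacks pyrrole nitrogens "
            f"{HEME_PLANE_NITROGENS}"
        )
    meso = [heme.atom(n) for n in HEME_PLANE_MESO]
    if all(a is not None for a in meso):
        plane = plane + meso
    plane_addrs = [_addr(heme_chain, heme, a) for a in plane]  # type: ignore[arg-type]

    # Nearest [2Fe-2S] cluster (by closest iron) to the chosen heme iron.
    fes_irons: list[AtomAddress] = []
    best_d = math.inf
    for c, r in model.iter_residues():
        if r.name.upper() not in naming.fes_residues:
            continue
        irons = [r.atom(n) for n in naming.fes_iron_atoms]
        if any(a is None for a in irons):
            continue
        d = min(float(np.linalg.norm(a.position - fe.position)) for a in irons)  # type: ignore[union-attr]
        if d < best_d:
            best_d = d
            fes_irons = [_addr(c, r, a) for a in irons]  # type: ignore[arg-type]

    # Nearest substrate residue (by heavy-atom centroid) to the heme iron.
    substrate_atoms: list[AtomAddress] = []
    substrate_res: Optional[tuple[Chain, Residue]] = None
    best_d = math.inf
    for c, r in model.iter_residues():
        if r.name.upper() not in naming.substrate_residues:
            continue
        heavy = r.heavy_atoms()
        if not heavy:
            continue
        centroid = np.mean([a.position for a in heavy], axis=0)
        d = float(np.linalg.norm(centroid - fe.position))
        if d < best_d:
            best_d = d
            substrate_res = (c, r)
    if substrate_res is not None:
        c, r = substrate_res
        substrate_atoms = [_addr(c, r, a) for a in r.heavy_atoms()]

    c14 = None
    if substrate_res is not None:
        c, r = substrate_res
        if naming.substrate_c14_methyl_atom:
            a = r.atom(naming.substrate_c14_methyl_atom)
            if a is not None:
                c14 = _addr(c, r, a)
        if c14 is None:
            # Fallback: the substrate carbon nearest the heme iron. In a
            # catalytically posed sterol that is the 14alpha-methyl carbon.
            carbons = [a for a in r.heavy_atoms() if a.element.upper() == "C"]
            if carbons:
                a = min(carbons, key=lambda a: float(np.linalg.norm(a.position - fe.position)))
                c14 = _addr(c, r, a)

    return CofactorMap(
        heme_iron=heme_iron,
        heme_plane_atoms=plane_addrs,
        fes_irons=fes_irons,
        substrate_atoms=substrate_atoms,
        substrate_c14_methyl=c14,
    )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the hierarchical model.

    Alternate locations are collapsed to the highest-occupancy conformer per
    atom name. Multi-MODEL files yield one :class:`Model` per MODEL block.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise FormatError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        gst = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    models: list[Model] = []
    for gmodel in gst:
        model = Model()
        for gchain in gmodel:
            chain = Chain(cid=gchain.name)
            for gres in gchain:
                res = Residue(
                    name=gres.name,
                    seqid=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    het=gres.het_flag == "H",
                )
                best: dict[str, gemmi.Atom] = {}
                for ga in gres:
                    prev = best.get(ga.name)
                    if prev is None or ga.occ > prev.occ:
                        best[ga.name] = ga
                seen = set()
                for ga in gres:
                    if ga.name in seen or best[ga.name] is not ga:
                        continue
                    seen.add(ga.name)
                    res.atoms.append(
                        Atom(
                            name=ga.name,
                            element=ga.element.name or "X",
                            position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            occupancy=ga.occ,
                            b_factor=ga.b_iso,
                            serial=ga.serial,
                        )
                    )
                if res.atoms:
                    chain.residues.append(res)
            if chain.residues:
                model.chains.append(chain)
        models.append(model)
    if not models:
        raise ParseError(f"{path}: no models found")
    return Structure(models=models, source_id=gst.name or path.stem)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _pdb_atom_line(serial: int, atom: Atom, res: Residue, chain: Chain) -> str:
    record = "ATOM  " if res.name in _STANDARD_AA else "HETATM"
    name = atom.name
    # PDB column convention: atom names of <4 chars start in column 14
    # unless the element symbol is two letters.
    if len(name) < 4 and len(atom.element) < 2:
        name = " " + name
    x, y, z = atom.position
    return (
        f"{record}{serial:5d} {name:<4s}{'':1s}{res.name:>3s} {chain.cid:1s}"
        f"{res.seqid:4d}{res.icode or '':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element.upper():>2s}"
    )


def write_multimodel(models: Iterable[Model] | Structure, path: str | Path) -> None:
    """Write models sharing one atom roster as a multi-MODEL PDB file."""
    if isinstance(models, Structure):
        models = models.models
    models = list(models)
    if not models:
        raise RosterError("no models to write")
    ref = models[0].roster()
    for i, m in enumerate(models[1:], start=2):
        roster = m.roster()
        if roster != ref:
            for j, (a, b) in enumerate(zip(ref, roster)):
                if a != b:
                    raise RosterError(
                        f"model {i} atom {j}: {b} does not match model 1 atom {a}"
                    )
            raise RosterError(
                f"model 1 has {len(ref)} atoms but model {i} has {len(roster)}"
            )

    lines: list[str] = []
    multi = len(models) > 1
    for imodel, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        serial = 0
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    lines.append(_pdb_atom_line(serial, atom, res, chain))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


@dataclass(frozen=True)
class Selection:
    """A 'chain:residues:atoms' selection.

    chain: a chain id or '*'; residues: number, number range 'n-m', residue
    name (e.g. 'HEM'), or '*'; atoms: comma-separated names or '*' (atoms
    part optional, defaults to all heavy atoms).
    """

    text: str
    chain: str
    res_numbers: Optional[tuple[tuple[int, int], ...]]
    res_name: Optional[str]
    atom_names: Optional[tuple[str, ...]]

    def matches_residue(self, chain: Chain, res: Residue) -> bool:
        if self.chain != "*" and chain.cid != self.chain:
            return False
        if self.res_name is not None and res.name.upper() != self.res_name:
            return False
        if self.res_numbers is not None:
            if not any(lo <= res.seqid <= hi for lo, hi in self.res_numbers):
                return False
        return True

    def resolve(self, model: Model, heavy_only: bool = True) -> list[tuple[Chain, Residue, Atom]]:
        out = []
        for c, r in model.iter_residues():
            if not self.matches_residue(c, r):
                continue
            for a in r.atoms:
                if heavy_only and not a.is_heavy:
                    continue
                if self.atom_names is not None and a.name.upper() not in self.atom_names:
                    continue
                out.append((c, r, a))
        if not out:
            raise SelectionError(f"selection {self.text!r} matched no atoms")
        return out

    def resolve_atoms(self, model: Model, heavy_only: bool = True) -> list[Atom]:
        return [a for _, _, a in self.resolve(model, heavy_only=heavy_only)]


def parse_selection(text: str) -> Selection:
    """Parse 'chain:residues[:atoms]' into a :class:`Selection`."""
    parts = text.split(":")
    if len(parts) == 2:
        chain, resspec = parts
        atomspec = "*"
    elif len(parts) == 3:
        chain, resspec, atomspec = parts
    else:
        raise SelectionError(f"bad selection {text!r}; expected chain:residues[:atoms]")
    chain = chain.strip() or "*"

    res_numbers: Optional[tuple[tuple[int, int], ...]] = None
    res_name: Optional[str] = None
    resspec = resspec.strip()
    if resspec in ("", "*"):
        pass
    else:
        ranges = []
        name = None
        for token in resspec.split(","):
            token = token.strip()
            m = _RANGE_RE.match(token)
            if m:
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                if hi < lo:
                    lo, hi = hi, lo
                ranges.append((lo, hi))
            else:
                name = token.upper()
        if ranges and name:
            raise SelectionError(f"selection {text!r} mixes residue numbers and a residue name")
        res_numbers = tuple(ranges) if ranges else None
        res_name = name

    atomspec = atomspec.strip()
    atom_names = None
    if atomspec not in ("", "*"):
        atom_names = tuple(t.strip().upper() for t in atomspec.split(",") if t.strip())

    return Selection(text=text, chain=chain, res_numbers=res_numbers,
                     res_name=res_name, atom_names=atom_names)


def copy_model(model: Model) -> Model:
    """Deep copy of a model (atoms included)."""
    new = Model()
    for chain in model.chains:
        nc = Chain(cid=chain.cid)
        for res in chain.residues:
            nr = Residue(name=res.name, seqid=res.seqid, icode=res.icode, het=res.het)
            nr.atoms = [
                Atom(name=a.name, element=a.element, position=a.position.copy(),
                     occupancy=a.occupancy, b_factor=a.b_factor, serial=a.serial)
                for a in res.atoms
            ]
            nc.residues.append(nr)
        new.chains.append(nc)
    return new
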