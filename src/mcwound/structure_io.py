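"""Coordinate I/O and complex representation.

A predicted enzyme–substrate complex is a single PDB file with two chains:
one type II metacaspase (the enzyme) and one propeptide candidate (the
substrate).  This module reads such files into a light-weight
:class:`StructureModel`, writes models back out as standard PDB, locates
the catalytic thiol sulfur (the "SG" atom of the active-site cysteine,
C139 in AtMC4), and excises inter-domain linker segments from sequences
before they are sent off for structure prediction.

Parsing and serialisation are delegated to :mod:`gemmi`; this module adds
the role tagging (enzyme vs substrate chain), water removal, altloc policy
and validation the screening pipeline relies on.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "RadiiTable",
    "LinkerSpec",
    "CatalyticSiteSpec",
    "StructureError",
    "ChainAbsentError",
    "CatalyticAtomError",
    "read_structure",
    "write_structure",
    "excise_linker",
    "locate_atom",
    "load_radii_table",
]


class StructureError(ValueError):
    """Malformed or inconsistent structural input."""


class ChainAbsentError(StructureError):
    """A chain named in the configuration is missing from the file."""


class CatalyticAtomError(StructureError):
    """The catalytic-site spec resolves to zero or multiple atoms."""


@dataclass(frozen=True)
class Atom:
    """One atom record, in the source file's own numbering.

    ``coord`` is a length-3 tuple in Å.  ``element`` is the upper-case
    element symbol; when the file omits it, it is inferred from the atom
    name.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        if not self.element:
            raise StructureError(f"atom {self.serial}: empty element symbol")
        if not all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.serial}: non-finite coordinate")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class StructureModel:
    """One predicted complex with role-tagged chains."""

    atoms: list[Atom]
    enzyme_chain: str
    substrate_chain: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.enzyme_chain == self.substrate_chain:
            raise StructureError("enzyme and substrate chains must differ")
        chains = {a.chain_id for a in self.atoms}
        for role, cid in (("enzyme", self.enzyme_chain), ("substrate", self.substrate_chain)):
            if cid not in chains:
                raise ChainAbsentError(f"{role} chain {cid!r} has no atoms")

    def chain_atoms(self, chain_id: str, include_hydrogens: bool = True) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and (include_hydrogens or not a.is_hydrogen)
        ]

    @property
    def enzyme_atoms(self) -> list[Atom]:
        return self.chain_atoms(self.enzyme_chain)

    @property
    def substrate_atoms(self) -> list[Atom]:
        return self.chain_atoms(self.substrate_chain)

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        return np.array([a.coord for a in atoms], dtype=float).reshape(-1, 3)

    def translated(self, chain_id: str, offset: np.ndarray) -> "StructureModel":
        """Return a copy with one chain rigidly shifted by ``offset`` (Å)."""
        off = np.asarray(offset, dtype=float)
        moved = [
            Atom(
                a.serial,
                a.name,
                a.element,
                a.res_name,
                a.res_seq,
                a.chain_id,
                tuple(np.asarray(a.coord) + off),
                a.occupancy,
                a.bfactor,
            )
            if a.chain_id == chain_id
            else a
            for a in self.atoms
        ]
        return StructureModel(moved, self.enzyme_chain, self.substrate_chain, self.label)


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii by element, with a fallback for unknowns."""

    radii: dict[str, float]
    default: float = 1.70

    REQUIRED = ("C", "N", "O", "S", "P", "H")

    def __post_init__(self) -> None:
        missing = [e for e in self.REQUIRED if e not in self.radii]
        if missing:
            raise StructureError(f"radii table missing elements: {missing}")
        if self.default <= 0 or any(r <= 0 for r in self.radii.values()):
            raise StructureError("all radii must be positive")

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default)

    def for_atoms(self, atoms: Iterable[Atom]) -> np.ndarray:
        return np.array([self.radius(a.element) for a in atoms], dtype=float)


@dataclass(frozen=True)
class LinkerSpec:
    """Inclusive 1-based residue range of an inter-domain linker."""

    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_res <= self.end_res):
            raise StructureError(
                f"invalid linker range {self.start_res}..{self.end_res}"
            )


@dataclass(frozen=True)
class CatalyticSiteSpec:
    """Designation of the catalytic atom, e.g. SG of Cys139 on the enzyme chain."""

    chain_id: str
    res_seq: int
    atom_name: str = "SG"


def load_radii_table(path: str | Path | None = None) -> RadiiTable:
    """Load element radii from a two-column text file.

    ``None`` loads the packaged Bondi-style defaults (C 1.70, N 1.55,
    O 1.52, S 1.80, P 1.80, H 1.20; unknown elements fall back to 1.70 Å).
    """
    if path is None:
        ref = importlib.resources.files("mcwound.data").joinpath("vdw_radii.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    radii: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise StructureError(f"radii file line {lineno}: expected 'element radius'")
        try:
            radii[parts[0].upper()] = float(parts[1])
        except ValueError as exc:
            raise StructureError(f"radii file line {lineno}: bad radius {parts[1]!r}") from exc
    return RadiiTable(radii)


def _element_from_name(name: str) -> str:
    # Fallback only; gemmi normally supplies the element from columns 77-78.
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "MG", "ZN", "NA", "SE"):
        return stripped[:2].upper()
    return stripped[:1].upper()


def read_structure(
    path: str | Path, enzyme_chain: str, substrate_chain: str, label: str = ""
) -> StructureModel:
    """Read a PDB complex and tag the enzyme/substrate chains.

    Water (HOH) records are dropped; only altloc ``' '`` or ``'A'`` atoms
    are kept.  Raises :class:`ChainAbsentError` if either named chain is
    missing and :class:`StructureError` for unparseable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: cannot parse PDB: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models in file")
    atoms: list[Atom] = []
    for chain in st[0]:
        for residue in chain:
            if residue.name.strip() == "HOH":
                continue
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                element = atom.element.name.upper() if atom.element.name else ""
                if not element or element == "X":
                    element = _element_from_name(atom.name)
                atoms.append(
                    Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=element,
                        res_name=residue.name.strip(),
                        res_seq=residue.seqid.num,
                        chain_id=chain.name,
                        coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                        bfactor=atom.b_iso,
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: no atoms after filtering")
    return StructureModel(atoms, enzyme_chain, substrate_chain, label or path.stem)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB ATOM records with TER between chains and END.

    Serials above 99,999 restart at 1 with a warning (fixtures never get
    that large).
    """
    st = gemmi.Structure()
    st.name = model.label or "complex"
    gm = gemmi.Model("1")
    by_chain: dict[str, list[Atom]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain_id, []).append(a)
    serial = 0
    for chain_id, chain_atoms in by_chain.items():
        gchain = gemmi.Chain(chain_id)
        current_res: gemmi.Residue | None = None
        for a in chain_atoms:
            serial += 1
            if serial > 99999:
                warnings.warn("atom serial overflow; restarting serials at 1")
                serial = 1
            if (
                current_res is None
                or current_res.seqid.num != a.res_seq
                or current_res.name != a.res_name
            ):
                current_res = gemmi.Residue()
                current_res.name = a.res_name
                current_res.seqid = gemmi.SeqId(a.res_seq, " ")
                gchain.add_residue(current_res)
                current_res = gchain[-1]
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = a.occupancy
            ga.b_iso = a.bfactor
            ga.serial = serial
            current_res.add_atom(ga)
        gm.add_chain(gchain)
    st.add_model(gm)
    st.setup_entities()
    # Force polymer classification so TER records separate the chains even
    # for single-residue toy fixtures.
    for m in st:
        for chain in m:
            for residue in chain:
                residue.entity_type = gemmi.EntityType.Polymer
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


def excise_linker(sequence: str, spec: LinkerSpec) -> str:
    """Delete an inclusive 1-based residue range from a protein sequence.

    Used to remove the inter-domain linker of a type II metacaspase before
    structure prediction, so the catalytic site is not occluded by it.
    """
    n = len(sequence)
    if spec.end_res > n:
        raise StructureError(
            f"linker range {spec.start_res}..{spec.end_res} exceeds sequence length {n}"
        )
    result = sequence[: spec.start_res - 1] + sequence[spec.end_res :]
    if not result:
        raise StructureError("linker excision would remove the entire sequence")
    return result


def locate_atom(model: StructureModel, spec: CatalyticSiteSpec) -> Atom:
    """Resolve a catalytic-site spec to exactly one atom."""
    matches = [
        a
        for a in model.atoms
        if a.chain_id == spec.chain_id
        and a.res_seq == spec.res_seq
        and a.name.strip() == spec.atom_name
    ]
    if not matches:
        raise CatalyticAtomError(
            f"no atom {spec.atom_name!r} at {spec.chain_id}/{spec.res_seq}"
        )
    if len(matches) > 1:
        raise CatalyticAtomError(
            f"ambiguous: {len(matches)} atoms named {spec.atom_name!r} "
            f"at {spec.chain_id}/{spec.res_seq}"
        )
    return matches[0]
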