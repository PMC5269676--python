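"""Atomic models, PDB I/O and antibody numbering annotations.

The central container is :class:`Structure`: chains of residues of atoms,
with author numbering (for antibody chains this is assumed to be a scheme
numbering such as Chothia, as deposited by curated Fv libraries) and an
optional per-chain role tag (``heavy`` / ``light`` / ``antigen``).

PDB parsing and serialisation are delegated to :mod:`gemmi`; only the first
MODEL is read, alternate locations are resolved to the highest-occupancy
conformer, and hydrogens, waters and heteroatoms are dropped unless
requested.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: residue names treated as water on input
_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyModelError(ValueError):
    """Raised when a file yields no usable atoms."""


class GapError(ValueError):
    """Raised when a numbered range is requested but residues are missing."""

    def __init__(self, missing: Sequence[int], message: str | None = None):
        self.missing = list(missing)
        super().__init__(
            message or f"missing residue positions: {self.missing}"
        )


@dataclass(frozen=True, order=True)
class ResidueID:
    """Chain / author-number / insertion-code triple.

    Ordering is lexicographic on (chain, number, insertion); the blank
    insertion code sorts before ``'A'``, giving the conventional
    ... 100, 100A, 100B, 101 ... order.
    """

    chain: str
    number: int
    insertion: str = ""

    def __str__(self) -> str:  # e.g. H100A
        return f"{self.chain}{self.number}{self.insertion}"


@dataclass
class AtomRecord:
    """One heavy atom: name, element and position in Å."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_polar(self) -> bool:
        """Nitrogen/oxygen heavy atoms with hydrogen-bonding capacity."""
        return self.element in ("N", "O")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.coord.copy())


@dataclass
class Residue:
    rid: ResidueID
    name: str  # three-letter residue type
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.rid} has no atom {name!r}")

    def has_atoms(self, names: Iterable[str]) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    @property
    def backbone(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_backbone]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def copy(self) -> "Residue":
        return Residue(self.rid, self.name, [a.copy() for a in self.atoms])


class Structure:
    """Chains of residues of heavy atoms, with optional chain roles.

    Residues are kept in insertion-aware order per chain; the invariant of
    no duplicate (ResidueID, atom name) pairs is enforced on insertion.
    """

    def __init__(self, roles: Mapping[str, str] | None = None):
        self._chains: dict[str, list[Residue]] = {}
        self.roles: dict[str, str] = dict(roles or {})
        self.metadata: dict[str, str] = {}

    # -- construction -------------------------------------------------
    def add_residue(self, residue: Residue) -> Residue:
        chain = self._chains.setdefault(residue.rid.chain, [])
        for existing in chain:
            if existing.rid == residue.rid:
                raise ValueError(f"duplicate residue {residue.rid}")
        chain.append(residue)
        chain.sort(key=lambda r: (r.rid.number, r.rid.insertion))
        return residue

    def new_residue(
        self,
        chain: str,
        number: int,
        name: str,
        atoms: Iterable[tuple[str, str, Sequence[float]]] = (),
        insertion: str = "",
    ) -> Residue:
        res = Residue(ResidueID(chain, number, insertion), name)
        seen = set()
        for aname, elem, xyz in atoms:
            if aname in seen:
                raise ValueError(f"duplicate atom {aname} in {res.rid}")
            seen.add(aname)
            res.atoms.append(AtomRecord(aname, elem, np.asarray(xyz, float)))
        return self.add_residue(res)

    # -- access -------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self._chains)

    def chain(self, chain_id: str) -> list[Residue]:
        return self._chains[chain_id]

    def has_chain(self, chain_id: str) -> bool:
        return chain_id in self._chains

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        if chain_id is not None:
            yield from self._chains.get(chain_id, [])
        else:
            for chain in self._chains.values():
                yield from chain

    def get_residue(self, rid: ResidueID) -> Residue:
        for res in self._chains.get(rid.chain, []):
            if res.rid == rid:
                return res
        raise KeyError(f"no residue {rid}")

    def atoms(self, chain_id: str | None = None) -> Iterator[tuple[Residue, AtomRecord]]:
        for res in self.residues(chain_id):
            for atom in res.atoms:
                yield res, atom

    def coords(
        self,
        chain_id: str | None = None,
        backbone_only: bool = False,
        atom_names: Sequence[str] | None = None,
    ) -> np.ndarray:
        pts = [
            a.coord
            for _, a in self.atoms(chain_id)
            if (not backbone_only or a.is_backbone)
            and (atom_names is None or a.name in atom_names)
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def chains_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    # -- manipulation -------------------------------------------------
    def copy(self) -> "Structure":
        out = Structure(self.roles)
        out.metadata = dict(self.metadata)
        for res in self.residues():
            out.add_residue(res.copy())
        return out

    def subset(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = set(chain_ids)
        out = Structure({c: r for c, r in self.roles.items() if c in wanted})
        for res in self.residues():
            if res.rid.chain in wanted:
                out.add_residue(res.copy())
        return out

    def remove_residue(self, rid: ResidueID) -> None:
        chain = self._chains.get(rid.chain, [])
        self._chains[rid.chain] = [r for r in chain if r.rid != rid]

    def merged_with(self, other: "Structure") -> "Structure":
        """Union of two structures with disjoint chain ids."""
        overlap = set(self._chains) & set(other._chains)
        if overlap:
            raise ValueError(f"chain id collision on merge: {sorted(overlap)}")
        out = self.copy()
        out.roles.update(other.roles)
        for res in other.residues():
            out.add_residue(res.copy())
        return out

    def transform(self, rigid) -> "Structure":
        """Return a copy moved by a geometry.RigidTransform (roles untouched)."""
        out = self.copy()
        for _, atom in out.atoms():
            atom.coord = rigid.apply(atom.coord)
        return out


# ----------------------------------------------------------------------
# Antibody annotation

#: Default CDR boundaries (inclusive author-numbered ranges, Chothia-style
#: loops with the H3 span widened to the 93–103 anchor-to-anchor window).
DEFAULT_CDR_RANGES: dict[str, tuple[int, int]] = {
    "H1": (26, 32),
    "H2": (52, 56),
    "H3": (93, 103),
    "L1": (24, 34),
    "L2": (50, 56),
    "L3": (89, 97),
}


@dataclass
class FvAnnotation:
    """Heavy/light chain ids plus the CDR boundary table for one Fv."""

    heavy: str
    light: str | None = None
    scheme: str = "chothia"
    cdr_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CDR_RANGES)
    )

    def __post_init__(self):
        lo, hi = self.cdr_ranges.get("H3", (0, 0))
        if not (lo <= 93 and hi >= 103):
            raise ValueError("H3 range must contain positions 93-103")
        for cid in ("H", "L"):
            spans = sorted(
                rng for loop, rng in self.cdr_ranges.items() if loop.startswith(cid)
            )
            for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
                if b_lo <= a_hi:
                    raise ValueError(
                        f"overlapping CDR ranges on chain class {cid}"
                    )

    def loop_chain(self, loop: str) -> str:
        if loop.startswith("H"):
            return self.heavy
        if loop.startswith("L"):
            if self.light is None:
                raise ValueError("annotation has no light chain")
            return self.light
        raise ValueError(f"unknown loop id {loop!r}")

    def loop_range(self, loop: str) -> tuple[int, int]:
        try:
            return self.cdr_ranges[loop]
        except KeyError:
            raise ValueError(f"unknown loop id {loop!r}") from None

    def cdr_residues(self, structure: Structure) -> list[Residue]:
        """All residues of `structure` falling in any CDR range (in order)."""
        out: list[Residue] = []
        for loop in sorted(self.cdr_ranges):
            if loop.startswith("L") and self.light is None:
                continue
            chain_id = self.loop_chain(loop)
            if not structure.has_chain(chain_id):
                continue
            lo, hi = self.cdr_ranges[loop]
            for res in structure.residues(chain_id):
                if lo <= res.rid.number <= hi:
                    out.append(res)
        return out


def parse_role_map(spec: str) -> dict[str, str]:
    """Parse a ``H:L:antigen`` style chain-role string, e.g. ``"H:L:A"``.

    Fields are heavy-chain id, light-chain id ('' for none) and one or more
    antigen chain ids (comma-separated).
    """
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"role map must have 3 ':'-separated fields, got {spec!r}")
    roles: dict[str, str] = {}
    if parts[0]:
        roles[parts[0]] = "heavy"
    if parts[1]:
        roles[parts[1]] = "light"
    for c in parts[2].split(","):
        if c:
            roles[c] = "antigen"
    return roles


# ----------------------------------------------------------------------
# PDB I/O

def read_pdb(
    path: str | Path,
    roles: Mapping[str, str] | None = None,
    include_het: bool = False,
    include_waters: bool = False,
) -> Structure:
    """Read first-model heavy atoms from a fixed-column PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first encountered).  Hydrogens are always dropped;
    waters and heteroatom residues are dropped unless requested.
    """
    path = Path(path)
    try:
        doc = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(doc) == 0:
        raise EmptyModelError(f"{path}: no MODEL found")
    model = doc[0]

    out = Structure(roles)
    for chain in model:
        for gres in chain:
            if gres.name in _WATER_NAMES and not include_waters:
                continue
            if gres.het_flag == "H" and gres.name not in _WATER_NAMES and not include_het:
                continue
            rid = ResidueID(
                chain.name, gres.seqid.num, (gres.seqid.icode or " ").strip()
            )
            best: dict[str, gemmi.Atom] = {}
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            res = Residue(rid, gres.name)
            for atom in gres:  # preserve file order among winners
                winner = best.get(atom.name)
                if winner is atom:
                    res.atoms.append(
                        AtomRecord(
                            atom.name,
                            atom.element.name.upper(),
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        )
                    )
            try:
                out.add_residue(res)
            except ValueError as exc:
                raise PDBFormatError(f"{path}: {exc}") from exc

    if out.n_atoms() == 0:
        raise EmptyModelError(f"{path}: no heavy atoms after filtering")
    for remark in doc.raw_remarks:
        if remark.startswith("REMARK  99 PARAGRAFT "):
            key, _, value = remark[len("REMARK  99 PARAGRAFT "):].partition("=")
            out.metadata[key.strip()] = value.strip()
    return out


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column PDB records, preserving insertion codes."""
    if structure.n_atoms() == 0:
        raise EmptyModelError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = "paragraft"
    model = gemmi.Model("1")
    for chain_id in structure.chain_ids:
        if len(chain_id) != 1:
            raise ValueError(f"PDB chain id must be one character, got {chain_id!r}")
        chain = gemmi.Chain(chain_id)
        for res in structure.residues(chain_id):
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.rid.number, res.rid.insertion or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = 1.0
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.raw_remarks = [
        f"REMARK  99 PARAGRAFT {key}={value}"
        for key, value in structure.metadata.items()
    ]
    st.write_pdb(str(path))


def extract_region(
    structure: Structure,
    annotation: FvAnnotation,
    loop: str | tuple[str, int, int],
) -> Structure:
    """Extract one contiguous numbered range (a CDR loop by id, or an
    explicit ``(chain_id, start, end)`` span), insertion codes included.

    Raises :class:`GapError` naming absent integer positions in the range.
    """
    if isinstance(loop, str):
        chain_id = annotation.loop_chain(loop)
        lo, hi = annotation.loop_range(loop)
    else:
        chain_id, lo, hi = loop
    if not structure.has_chain(chain_id):
        raise ValueError(f"structure has no chain {chain_id!r}")

    picked = [
        res for res in structure.residues(chain_id) if lo <= res.rid.number <= hi
    ]
    present = {res.rid.number for res in picked}
    missing = [n for n in range(lo, hi + 1) if n not in present]
    if missing:
        raise GapError(missing, f"chain {chain_id} range {lo}-{hi} missing {missing}")

    role = structure.roles.get(chain_id)
    out = Structure({chain_id: role} if role else None)
    for res in picked:
        out.add_residue(res.copy())
    return out
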