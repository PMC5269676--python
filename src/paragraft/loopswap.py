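"""CDRH3 loop harvesting and transplantation by anchor superposition.

The CDRH3 root residues VH93 and VH103 have highly conserved backbone
geometry across Fab structures, so an exogenous loop spanning VH93–VH103
can be carried into a design by superposing only its terminal backbone
atoms onto the design's anchors, deleting the anchors, and ligating the
incoming loop to VH92/VH104 of the framework.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import RigidTransform, superpose
from .grafting import clash_check
from .structures import (
    FvAnnotation,
    GapError,
    Residue,
    ResidueID,
    Structure,
    extract_region,
)

logger = logging.getLogger(__name__)

#: terminal backbone atoms used for anchor superposition (8 points); the
#: carbonyl-free alternative is ("N", "CA", "C")
ANCHOR_ATOMS_NCACO = ("N", "CA", "C", "O")
ANCHOR_ATOMS_NCAC = ("N", "CA", "C")

LOOP_START = 93
LOOP_END = 103


@dataclass
class LoopRecord:
    """A harvested CDRH3 fragment: residues VH93–VH103 inclusive."""

    source_id: str
    residues: list[Residue]

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty loop")
        first, last = self.residues[0], self.residues[-1]
        if first.rid.number != LOOP_START or last.rid.number != LOOP_END:
            raise ValueError(
                f"loop must run {LOOP_START}..{LOOP_END}, got "
                f"{first.rid.number}..{last.rid.number}"
            )
        for res in (first, last):
            if not res.has_atoms(ANCHOR_ATOMS_NCACO):
                raise ValueError(
                    f"terminal residue {res.rid} lacks complete backbone"
                )

    @property
    def length(self) -> int:
        """Residues between and excluding positions 93 and 103."""
        return len(self.residues) - 2

    @property
    def sequence(self) -> str:
        return "-".join(r.name for r in self.residues)

    def terminal_coords(self, atom_set: Sequence[str] = ANCHOR_ATOMS_NCACO) -> np.ndarray:
        pts = [self.residues[0].atom(n).coord for n in atom_set]
        pts += [self.residues[-1].atom(n).coord for n in atom_set]
        return np.array(pts)

    def transformed(self, rigid: RigidTransform) -> "LoopRecord":
        moved = [r.copy() for r in self.residues]
        for res in moved:
            for atom in res.atoms:
                atom.coord = rigid.apply(atom.coord)
        return LoopRecord(self.source_id, moved)


@dataclass
class HarvestResult:
    records: list[LoopRecord]
    skipped: list[tuple[str, str]]  # (scaffold id, reason)


def harvest_cdrh3(
    library: Iterable[tuple[str, Structure, FvAnnotation]]
) -> HarvestResult:
    """Dissect the VH93–VH103 span from every scaffold whose span is
    gap-free with complete terminal backbones; others are skipped with a
    logged reason."""
    records: list[LoopRecord] = []
    skipped: list[tuple[str, str]] = []
    for scaffold_id, scaffold, annotation in library:
        try:
            region = extract_region(
                scaffold, annotation, (annotation.heavy, LOOP_START, LOOP_END)
            )
            record = LoopRecord(scaffold_id, [r.copy() for r in region.residues()])
        except (GapError, ValueError, KeyError) as exc:
            logger.info("skipping %s: %s", scaffold_id, exc)
            skipped.append((scaffold_id, str(exc)))
            continue
        records.append(record)
    return HarvestResult(records, skipped)


@dataclass
class SwapResult:
    loop_id: str
    chimera: Structure | None
    anchor_rmsd: float
    junction_bonds: tuple[float, float] | None
    clash_pairs: list
    rejected: bool
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return not self.rejected


def swap_cdrh3(
    design: Structure,
    annotation: FvAnnotation,
    loop: LoopRecord,
    clash_cutoff: float = 2.5,
    atom_set: Sequence[str] = ANCHOR_ATOMS_NCACO,
) -> SwapResult:
    """Transplant `loop` into `design` via VH93/VH103 anchor superposition.

    Procedure: remove design VH94–VH102; superpose the loop's terminal
    backbone atoms onto the anchors' same atoms; delete the anchors; splice
    the transformed loop so its own 93 and 103 bond to VH92 and VH104.
    The chimera is rejected (with the clash list) if any incoming-loop
    backbone atom clashes with the rest of the design or the antigen;
    atom pairs across the two covalent splice junctions are exempt.
    """
    heavy = annotation.heavy
    anchors: dict[int, Residue] = {}
    for num in (LOOP_START, LOOP_END):
        matches = [
            r
            for r in design.residues(heavy)
            if r.rid.number == num and not r.rid.insertion
        ]
        if not matches or not matches[0].has_atoms(atom_set):
            raise ValueError(f"design lacks anchor residue VH{num} with backbone")
        anchors[num] = matches[0]
    for num in (LOOP_START - 1, LOOP_END + 1):
        if not any(r.rid.number == num for r in design.residues(heavy)):
            raise ValueError(f"design lacks framework residue VH{num}")

    anchor_ref = np.array(
        [anchors[LOOP_START].atom(n).coord for n in atom_set]
        + [anchors[LOOP_END].atom(n).coord for n in atom_set]
    )
    transform, anchor_rmsd = superpose(loop.terminal_coords(atom_set), anchor_ref)
    placed = loop.transformed(transform)

    chimera = design.copy()
    # drop the old loop including the anchors (replaced by the donor's own
    # 93/103, side chains therefore from the donor)
    for res in list(chimera.residues(heavy)):
        if LOOP_START <= res.rid.number <= LOOP_END:
            chimera.remove_residue(res.rid)
    loop_rids = []
    for res in placed.residues:
        renamed = res.copy()
        renamed = Residue(
            ResidueID(heavy, res.rid.number, res.rid.insertion),
            res.name,
            renamed.atoms,
        )
        chimera.add_residue(renamed)
        loop_rids.append(renamed.rid)

    # clash filter: incoming-loop backbone vs all other heavy atoms,
    # excluding the covalently bonded junction residue pairs
    junction_exempt = {
        (ResidueID(heavy, LOOP_START), ResidueID(heavy, LOOP_START - 1)),
        (ResidueID(heavy, LOOP_END), ResidueID(heavy, LOOP_END + 1)),
    }
    loop_rid_set = set(loop_rids)
    loop_atoms = [
        (res.rid, a)
        for res in chimera.residues(heavy)
        if res.rid in loop_rid_set
        for a in res.atoms
        if a.is_backbone
    ]
    other_atoms = [
        (res.rid, a) for res, a in chimera.atoms() if res.rid not in loop_rid_set
    ]
    pairs = clash_check(
        np.array([a.coord for _, a in loop_atoms]).reshape(-1, 3),
        np.array([a.coord for _, a in other_atoms]).reshape(-1, 3),
        clash_cutoff,
    )
    clashes = [
        (loop_atoms[i][0], loop_atoms[i][1].name, other_atoms[j][0],
         other_atoms[j][1].name, d)
        for i, j, d in pairs
        if (loop_atoms[i][0], other_atoms[j][0]) not in junction_exempt
    ]

    bonds = _junction_bonds(chimera, heavy)
    if clashes:
        return SwapResult(
            loop.source_id, None, anchor_rmsd, bonds, clashes, True,
            f"{len(clashes)} backbone clash(es)",
        )
    return SwapResult(loop.source_id, chimera, anchor_rmsd, bonds, [], False)


def _junction_bonds(chimera: Structure, heavy: str) -> tuple[float, float]:
    def bond(num_c: int, icode_c: str, num_n: int) -> float:
        c_res = next(
            r for r in chimera.residues(heavy)
            if r.rid.number == num_c and r.rid.insertion == icode_c
        )
        n_res = next(
            r for r in chimera.residues(heavy) if r.rid.number == num_n
        )
        return float(np.linalg.norm(c_res.atom("C").coord - n_res.atom("N").coord))

    return (
        bond(LOOP_START - 1, "", LOOP_START),
        bond(LOOP_END, "", LOOP_END + 1),
    )


@dataclass
class JunctionReport:
    bond_n: float  # C(92)–N(93) Å
    bond_c: float  # C(103)–N(104) Å
    omega_n: float  # ω torsion at the 92–93 junction, degrees
    omega_c: float  # ω torsion at the 103–104 junction, degrees
    flagged: bool  # any bond outside [1.2, 1.5] Å

    BOND_RANGE = (1.2, 1.5)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w))))


def junction_geometry(chimera: Structure, annotation: FvAnnotation) -> JunctionReport:
    """C–N bond lengths and ω torsions at the two splice junctions."""
    heavy = annotation.heavy

    def res_at(num: int) -> Residue:
        for r in chimera.residues(heavy):
            if r.rid.number == num and not r.rid.insertion:
                return r
        raise ValueError(f"chimera lacks residue VH{num}")

    r92, r93 = res_at(LOOP_START - 1), res_at(LOOP_START)
    r103, r104 = res_at(LOOP_END), res_at(LOOP_END + 1)
    bond_n = float(np.linalg.norm(r92.atom("C").coord - r93.atom("N").coord))
    bond_c = float(np.linalg.norm(r103.atom("C").coord - r104.atom("N").coord))
    omega_n = _dihedral(
        r92.atom("CA").coord, r92.atom("C").coord,
        r93.atom("N").coord, r93.atom("CA").coord,
    )
    omega_c = _dihedral(
        r103.atom("CA").coord, r103.atom("C").coord,
        r104.atom("N").coord, r104.atom("CA").coord,
    )
    lo, hi = JunctionReport.BOND_RANGE
    flagged = not (lo <= bond_n <= hi and lo <= bond_c <= hi)
    return JunctionReport(bond_n, bond_c, omega_n, omega_c, flagged)
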