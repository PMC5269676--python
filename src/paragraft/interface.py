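"""Interface analysis and design triage.

Metrics mirror the standard repertoire for protein–protein interface
assessment: Shrake–Rupley solvent-accessible surface area, buried SASA,
geometric hydrogen-bond detection, the Lawrence–Colman shape
complementarity statistic Sc, and counts of buried unsatisfied polar
atoms.  A deterministic surrogate interface score (weighted sum of these
terms, lower is better) stands in for a physical binding free energy and
drives alanine scanning, point-mutation enumeration and stage triage
(designs with Sc < 0.5 are rejected after hotspot grafting, Sc < 0.6
after CDRH3 swapping; the top five mutations are kept for combination).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .grafting import clash_check
from .structures import AtomRecord, Residue, ResidueID, Structure

logger = logging.getLogger(__name__)

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
}
_DEFAULT_RADIUS = 1.70

#: hydroxyl oxygens act as hydrogen-bond donors as well as acceptors
_HYDROXYL_NAMES = {"OG", "OG1", "OH"}

AMINO_ACIDS_3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()
#: mutation target alphabet: all types except glycine, proline, cysteine
MUTATION_ALPHABET = tuple(
    a for a in AMINO_ACIDS_3 if a not in ("GLY", "PRO", "CYS")
)

SC_THRESHOLDS = {"graft": 0.5, "swap": 0.6}


class NoBuriedSurfaceError(ValueError):
    """Sc is undefined: the two partners bury no molecular surface."""


def _radii(structure: Structure) -> np.ndarray:
    return np.array(
        [VDW_RADII.get(a.element, _DEFAULT_RADIUS) for _, a in structure.atoms()]
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


# ----------------------------------------------------------------------
# SASA

def sasa(
    structure: Structure, probe: float = 1.4, sphere_points: int = 960
) -> np.ndarray:
    """Per-atom Shrake–Rupley solvent-accessible surface area (Å²).

    Atom order follows ``structure.atoms()``; the molecular total is the
    sum over atoms.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    coords = structure.coords()
    radii = _radii(structure) + probe
    n = coords.shape[0]
    unit = _fibonacci_sphere(sphere_points)
    tree = cKDTree(coords)
    areas = np.zeros(n)
    max_r = radii.max()
    neighbor_lists = tree.query_ball_point(coords, radii + max_r)
    for i in range(n):
        # exactly coincident equal-radius duplicates count their area once
        # (the lower-index copy keeps it)
        if any(
            j < i
            and radii[j] == radii[i]
            and np.linalg.norm(coords[j] - coords[i]) < 1e-6
            for j in neighbor_lists[i]
        ):
            continue
        pts = coords[i] + radii[i] * unit
        nb = [j for j in neighbor_lists[i] if j != i]
        frac = _accessible_fraction(pts, coords[nb], radii[np.asarray(nb, int)]) \
            if nb else 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return areas


def _accessible_fraction(pts: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> float:
    """Fraction of sphere dots outside every occluding sphere.

    Occluders are visited nearest-first so buried dots die early and most
    distance work is skipped."""
    center = pts.mean(axis=0)
    order = np.argsort(np.linalg.norm(centers - center, axis=1))
    alive = np.ones(len(pts), dtype=bool)
    idx = np.arange(len(pts))
    for j in order:
        live = idx[alive]
        if live.size == 0:
            break
        d2 = ((pts[live] - centers[j]) ** 2).sum(axis=1)
        alive[live[d2 < radii[j] ** 2 - 1e-9]] = False
    return float(alive.mean())


def buried_sasa(
    a: Structure, b: Structure, probe: float = 1.4, sphere_points: int = 960
) -> float:
    """Interface area buried on complexation: SASA(a) + SASA(b) − SASA(ab)."""
    merged = a.merged_with(b)
    return float(
        sasa(a, probe, sphere_points).sum()
        + sasa(b, probe, sphere_points).sum()
        - sasa(merged, probe, sphere_points).sum()
    )


# ----------------------------------------------------------------------
# Hydrogen bonds

@dataclass(frozen=True)
class HydrogenBond:
    donor: tuple[ResidueID, str]
    acceptor: tuple[ResidueID, str]
    distance: float
    angle: float  # antecedent–donor–acceptor, degrees (nan when no antecedent)


def _polar_inventory(structure: Structure):
    """(donors, acceptors): lists of (rid, atom, antecedent-coord-or-None)."""
    donors, acceptors = [], []
    for res, atom in structure.atoms():
        if not atom.is_polar:
            continue
        is_donor = atom.element == "N" or (
            atom.element == "O" and atom.name in _HYDROXYL_NAMES
        )
        is_acceptor = atom.element == "O"
        if not (is_donor or is_acceptor):
            continue
        antecedent = None
        best = np.inf
        for other in res.atoms:
            if other is atom or other.element == "H":
                continue
            d = np.linalg.norm(other.coord - atom.coord)
            if d < best and d <= 2.0:
                best, antecedent = d, other.coord
        if is_donor:
            donors.append((res.rid, atom, antecedent))
        if is_acceptor:
            acceptors.append((res.rid, atom, antecedent))
    return donors, acceptors


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _scan_hbonds(donors, acceptors, d_max, angle_min, exclude=None):
    out = []
    if not donors or not acceptors:
        return out
    acc_tree = cKDTree(np.array([a.coord for _, a, _ in acceptors]))
    for d_rid, d_atom, d_ante in donors:
        for j in acc_tree.query_ball_point(d_atom.coord, d_max):
            a_rid, a_atom, _ = acceptors[j]
            if a_rid == d_rid and a_atom.name == d_atom.name:
                continue
            if exclude is not None and exclude(d_rid, a_rid):
                continue
            dist = float(np.linalg.norm(d_atom.coord - a_atom.coord))
            if dist > d_max or dist < 2.0:  # sub-bonding distances are clashes
                continue
            if d_ante is not None:
                ang = _angle_deg(d_ante, d_atom.coord, a_atom.coord)
                if ang < angle_min:
                    continue
            else:
                ang = float("nan")
            out.append(
                HydrogenBond((d_rid, d_atom.name), (a_rid, a_atom.name), dist, ang)
            )
    return out


def hydrogen_bonds(
    a: Structure,
    b: Structure,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HydrogenBond]:
    """Heavy-atom donor–acceptor pairs across the interface.

    Criteria: donor–acceptor distance ≤ `d_max` and antecedent–donor–
    acceptor angle ≥ `angle_min` (skipped when the donor has no bonded
    heavy-atom antecedent, as for isolated pseudo-atoms).
    """
    donors_a, acceptors_a = _polar_inventory(a)
    donors_b, acceptors_b = _polar_inventory(b)
    return _scan_hbonds(donors_a, acceptors_b, d_max, angle_min) + _scan_hbonds(
        donors_b, acceptors_a, d_max, angle_min
    )


def _intra_hbond_satisfied(
    structure: Structure, d_max: float, angle_min: float
) -> set[tuple[ResidueID, str]]:
    """Atoms with >= 1 hydrogen-bond partner anywhere in the structure
    (sequence-adjacent residue pairs excluded as covalent neighbours)."""

    def adjacent(r1: ResidueID, r2: ResidueID) -> bool:
        return r1.chain == r2.chain and abs(r1.number - r2.number) <= 1

    donors, acceptors = _polar_inventory(structure)
    satisfied: set[tuple[ResidueID, str]] = set()
    for hb in _scan_hbonds(donors, acceptors, d_max, angle_min, exclude=adjacent):
        satisfied.add(hb.donor)
        satisfied.add(hb.acceptor)
    return satisfied


# ----------------------------------------------------------------------
# Shape complementarity

@dataclass
class ScParams:
    w: float = 0.5          # Å⁻², distance attenuation
    density: float = 15.0   # surface points per Å²
    trim: float = 1.5       # Å, peripheral band removed
    probe: float = 1.7      # Å, burial probe radius


def _dot_surface(structure: Structure, density: float = 15.0):
    """vdW dot surface: points and outward normals, self-occluded dots removed."""
    coords = structure.coords()
    radii = _radii(structure)
    tree = cKDTree(coords)
    max_r = radii.max()
    pts_out, nrm_out = [], []
    neighbor_lists = tree.query_ball_point(coords, radii + max_r)
    for i in range(coords.shape[0]):
        n_dots = max(12, int(round(4.0 * np.pi * radii[i] ** 2 * density)))
        unit = _fibonacci_sphere(n_dots)
        pts = coords[i] + radii[i] * unit
        nb = [j for j in neighbor_lists[i] if j != i]
        keep = np.ones(len(pts), dtype=bool)
        if nb:
            nb_arr = np.asarray(nb, int)
            order = nb_arr[np.argsort(np.linalg.norm(coords[nb_arr] - coords[i], axis=1))]
            idx = np.arange(len(pts))
            for j in order:
                live = idx[keep]
                if live.size == 0:
                    break
                d2 = ((pts[live] - coords[j]) ** 2).sum(axis=1)
                keep[live[d2 < radii[j] ** 2 - 1e-9]] = False
        pts_out.append(pts[keep])
        nrm_out.append(unit[keep])
    return np.concatenate(pts_out), np.concatenate(nrm_out)


def _buried_mask(points, normals, other: Structure, probe: float) -> np.ndarray:
    """A surface dot is buried if a probe resting on it clashes with the
    partner molecule (i.e. the dot is solvent-inaccessible in the complex)."""
    other_coords = other.coords()
    other_radii = _radii(other)
    probe_centers = points + probe * normals
    tree = cKDTree(other_coords)
    mask = np.zeros(len(points), dtype=bool)
    reach = other_radii.max() + probe
    for idx, hits in enumerate(tree.query_ball_point(probe_centers, reach)):
        for j in hits:
            if (
                np.linalg.norm(probe_centers[idx] - other_coords[j])
                < other_radii[j] + probe
            ):
                mask[idx] = True
                break
    return mask


def shape_complementarity(
    a: Structure, b: Structure, params: ScParams | None = None
) -> float:
    """Lawrence–Colman shape complementarity statistic Sc in [−1, 1].

    Buried interface dots on each vdW surface are paired with the nearest
    opposing dot; each pair scores (n̂_a · −n̂_b)·exp(−w·d²); Sc is the
    mean of the two per-surface medians after trimming the peripheral
    band of the buried patch.
    """
    params = params or ScParams()
    pa, na = _dot_surface(a, params.density)
    pb, nb = _dot_surface(b, params.density)
    mask_a = _buried_mask(pa, na, b, params.probe)
    mask_b = _buried_mask(pb, nb, a, params.probe)
    if not mask_a.any() or not mask_b.any():
        raise NoBuriedSurfaceError("partners bury no surface at this separation")

    def trimmed(points, mask):
        buried = points[mask]
        exposed = points[~mask]
        if len(exposed) == 0:
            return buried, np.ones(len(buried), dtype=bool)
        tree = cKDTree(exposed)
        dist, _ = tree.query(buried)
        keep = dist > params.trim
        return buried, keep

    pa_b, keep_a = trimmed(pa, mask_a)
    pb_b, keep_b = trimmed(pb, mask_b)
    na_b = na[mask_a]
    nb_b = nb[mask_b]
    if not keep_a.any() or not keep_b.any():
        raise NoBuriedSurfaceError("buried patch vanishes after peripheral trim")

    def half_statistic(p_from, n_from, keep_from, p_to, n_to):
        tree = cKDTree(p_to)
        dist, idx = tree.query(p_from[keep_from])
        dots = np.einsum("ij,ij->i", n_from[keep_from], -n_to[idx])
        return float(np.median(dots * np.exp(-params.w * dist**2)))

    s_ab = half_statistic(pa_b, na_b, keep_a, pb_b, nb_b)
    s_ba = half_statistic(pb_b, nb_b, keep_b, pa_b, na_b)
    return 0.5 * (s_ab + s_ba)


# ----------------------------------------------------------------------
# Interface residues, buried unsatisfied polars, surrogate score

def interface_residues(
    a: Structure, b: Structure, cutoff: float = 5.0
) -> tuple[list[ResidueID], list[ResidueID]]:
    """Residues with >= 1 heavy atom within `cutoff` of the partner."""
    coords_b = b.coords()
    coords_a = a.coords()
    if coords_a.size == 0 or coords_b.size == 0:
        return [], []
    tree_b = cKDTree(coords_b)
    tree_a = cKDTree(coords_a)
    side_a = [
        res.rid
        for res in a.residues()
        if any(tree_b.query_ball_point(at.coord, cutoff) for at in res.atoms)
    ]
    side_b = [
        res.rid
        for res in b.residues()
        if any(tree_a.query_ball_point(at.coord, cutoff) for at in res.atoms)
    ]
    return side_a, side_b


def buried_unsat_polars(
    a: Structure,
    b: Structure,
    sasa_cut: float = 0.1,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    probe: float = 1.4,
    sphere_points: int = 960,
    interface_cutoff: float = 5.0,
) -> int:
    """Polar heavy atoms of interface residues that are buried in the
    complex (SASA < `sasa_cut` Å²) yet have no hydrogen-bond partner."""
    merged = a.merged_with(b)
    side_a, side_b = interface_residues(a, b, interface_cutoff)
    iface = set(side_a) | set(side_b)
    if not iface:
        return 0
    areas = sasa(merged, probe, sphere_points)
    satisfied = _intra_hbond_satisfied(merged, d_max, angle_min)
    count = 0
    for (res, atom), area in zip(merged.atoms(), areas):
        if res.rid not in iface or not atom.is_polar:
            continue
        if area >= sasa_cut:
            continue
        if (res.rid, atom.name) not in satisfied:
            count += 1
    return count


@dataclass
class ScoreWeights:
    """Weights of the surrogate interface score (lower is better):
    −w_hb·n_hbonds − w_sasa·buried_sasa + w_clash·n_clashes + w_unsat·n_unsat."""

    w_hb: float = 1.0
    w_sasa: float = 0.01      # per Å²
    w_clash: float = 10.0
    w_unsat: float = 0.5
    clash_cutoff: float = 2.0  # Å, severe heavy-atom overlap
    hb_d_max: float = 3.5
    hb_angle_min: float = 120.0
    probe: float = 1.4
    sphere_points: int = 960


def surrogate_interface_score(
    a: Structure, b: Structure, weights: ScoreWeights | None = None
) -> float:
    """Deterministic geometric stand-in for a binding energy; rigid-motion
    invariant, zero for fully separated partners."""
    w = weights or ScoreWeights()
    bsasa = buried_sasa(a, b, w.probe, w.sphere_points)
    if bsasa < 1e-6:
        bsasa = 0.0
    hbonds = hydrogen_bonds(a, b, w.hb_d_max, w.hb_angle_min)
    clashes = clash_check(a.coords(), b.coords(), w.clash_cutoff)
    unsat = (
        buried_unsat_polars(
            a, b, d_max=w.hb_d_max, angle_min=w.hb_angle_min,
            probe=w.probe, sphere_points=w.sphere_points,
        )
        if bsasa > 0
        else 0
    )
    return (
        -w.w_hb * len(hbonds)
        - w.w_sasa * bsasa
        + w.w_clash * len(clashes)
        + w.w_unsat * unsat
    )


# ----------------------------------------------------------------------
# Reports and triage

@dataclass
class InterfaceReport:
    buried_sasa: float
    sc: float  # nan when undefined (no buried surface)
    hbonds: list[HydrogenBond]
    buried_unsat: int
    surrogate_score: float
    residues_a: list[ResidueID]
    residues_b: list[ResidueID]

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)


def analyze_interface(
    a: Structure,
    b: Structure,
    weights: ScoreWeights | None = None,
    sc_params: ScParams | None = None,
) -> InterfaceReport:
    """Compute the full triage metric set for one two-partner complex."""
    w = weights or ScoreWeights()
    bsasa = buried_sasa(a, b, w.probe, w.sphere_points)
    hbonds = hydrogen_bonds(a, b, w.hb_d_max, w.hb_angle_min)
    side_a, side_b = interface_residues(a, b)
    try:
        sc = shape_complementarity(a, b, sc_params)
    except NoBuriedSurfaceError:
        sc = float("nan")
    unsat = (
        buried_unsat_polars(
            a, b, d_max=w.hb_d_max, angle_min=w.hb_angle_min,
            probe=w.probe, sphere_points=w.sphere_points,
        )
        if bsasa > 1e-6
        else 0
    )
    clashes = clash_check(a.coords(), b.coords(), w.clash_cutoff)
    score = (
        -w.w_hb * len(hbonds)
        - w.w_sasa * max(bsasa, 0.0)
        + w.w_clash * len(clashes)
        + w.w_unsat * unsat
    )
    return InterfaceReport(bsasa, sc, hbonds, unsat, score, side_a, side_b)


@dataclass
class ScoredDesign:
    design_id: str
    payload: object
    report: InterfaceReport


def triage(
    candidates: Sequence, stage: str, top_k: int = 5
) -> list:
    """Stage filter: drop candidates whose Sc falls below the stage
    threshold (0.5 after grafting, 0.6 after loop swap), rank the rest by
    surrogate score ascending, keep `top_k`."""
    if stage not in SC_THRESHOLDS:
        raise ValueError(f"stage must be one of {sorted(SC_THRESHOLDS)}")
    thr = SC_THRESHOLDS[stage]
    kept = [
        c
        for c in candidates
        if not np.isnan(c.report.sc) and c.report.sc >= thr
    ]
    kept.sort(key=lambda c: c.report.surrogate_score)
    return kept[:top_k]


# ----------------------------------------------------------------------
# Alanine scanning and point mutations

@dataclass
class AlanineScanEntry:
    position: ResidueID
    residue_type: str
    dscore: float
    hotspot: bool


def _truncate_to_alanine(res: Residue) -> None:
    res.atoms = [a for a in res.atoms if a.is_backbone or a.name == "CB"]
    res.name = "ALA"


def alanine_scan(
    a: Structure,
    b: Structure,
    weights: ScoreWeights | None = None,
    hotspot_quantile: float = 0.75,
    interface_cutoff: float = 5.0,
) -> list[AlanineScanEntry]:
    """Computational alanine scan of side `a` against partner `b`.

    Each interface residue with a side chain beyond Cβ is truncated to
    alanine (no repacking) and the surrogate score recomputed; Δscore =
    mutant − wild-type, so large positive values mark energetically
    important residues.  Residues with Δscore at or above the configured
    quantile (and strictly positive) are flagged as hotspots; glycine and
    alanine are skipped.
    """
    w = weights or ScoreWeights()
    wt_score = surrogate_interface_score(a, b, w)
    side_a, _ = interface_residues(a, b, interface_cutoff)
    entries: list[AlanineScanEntry] = []
    for rid in side_a:
        res = a.get_residue(rid)
        if res.name in ("GLY", "ALA"):
            continue
        mutant = a.copy()
        _truncate_to_alanine(mutant.get_residue(rid))
        dscore = surrogate_interface_score(mutant, b, w) - wt_score
        entries.append(AlanineScanEntry(rid, res.name, dscore, False))
    if entries:
        thr = float(np.quantile([e.dscore for e in entries], hotspot_quantile))
        for e in entries:
            e.hotspot = e.dscore >= thr and e.dscore > 1e-9
    return entries


@dataclass
class MutationProposal:
    position: ResidueID
    from_type: str
    to_type: str
    dscore: float
    rank: int

    def __post_init__(self):
        if self.to_type in ("GLY", "PRO", "CYS"):
            raise ValueError("mutations to Gly/Pro/Cys are excluded")


_TEMPLATE_CACHE: dict[str, tuple[np.ndarray, list[tuple[str, str, np.ndarray]]]] = {}


def _sidechain_template(resname: str):
    """Idealised side-chain template from the chemical component dictionary:
    backbone N/CA/C reference frame plus heavy side-chain atoms."""
    if resname not in _TEMPLATE_CACHE:
        import biotite.structure.info as struc_info

        arr = struc_info.residue(resname)
        names = list(arr.atom_name)
        coords = np.asarray(arr.coord, dtype=float)
        elements = list(arr.element)
        frame = np.array([coords[names.index(n)] for n in ("N", "CA", "C")])
        side = [
            (n, e.upper(), coords[i])
            for i, (n, e) in enumerate(zip(names, elements))
            if n not in ("N", "CA", "C", "O", "OXT") and not e.upper().startswith("H")
        ]
        _TEMPLATE_CACHE[resname] = (frame, side)
    return _TEMPLATE_CACHE[resname]


def mutate_residue(structure: Structure, rid: ResidueID, to_type: str) -> Structure:
    """Return a copy with one residue mutated: backbone kept, side chain
    placed from the idealised template aligned on N/CA/C (no repacking)."""
    from .geometry import superpose

    out = structure.copy()
    res = out.get_residue(rid)
    if not res.has_atoms(("N", "CA", "C")):
        raise ValueError(f"residue {rid} lacks backbone for mutation")
    frame, side = _sidechain_template(to_type)
    target = np.array([res.atom(n).coord for n in ("N", "CA", "C")])
    transform, _ = superpose(frame, target)
    res.name = to_type
    res.atoms = [a for a in res.atoms if a.is_backbone]
    for name, element, coord in side:
        res.atoms.append(AtomRecord(name, element, transform.apply(coord)))
    return out


def enumerate_point_mutations(
    antibody: Structure,
    antigen: Structure,
    positions: Sequence[ResidueID] | None = None,
    weights: ScoreWeights | None = None,
    interface_cutoff: float = 5.0,
) -> list[MutationProposal]:
    """Single mutations of interfacial antibody positions to every allowed
    type (all amino acids except Gly/Pro/Cys and the wild type), scored by
    the surrogate ΔΔG analogue and ranked ascending (best first)."""
    w = weights or ScoreWeights()
    if positions is None:
        positions, _ = interface_residues(antibody, antigen, interface_cutoff)
    wt_score = surrogate_interface_score(antibody, antigen, w)
    proposals: list[MutationProposal] = []
    for rid in positions:
        wt = antibody.get_residue(rid).name
        for to_type in MUTATION_ALPHABET:
            if to_type == wt:
                continue
            mutant = mutate_residue(antibody, rid, to_type)
            dscore = surrogate_interface_score(mutant, antigen, w) - wt_score
            proposals.append(MutationProposal(rid, wt, to_type, dscore, rank=0))
    proposals.sort(key=lambda p: p.dscore)
    for i, p in enumerate(proposals):
        p.rank = i + 1
    return proposals
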