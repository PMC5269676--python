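"""Hotspot grafting by residue-triplet geometric hashing.

The donor interaction pattern (e.g. the Nrf2 ETGE hotspots Glu79/Thr80/Glu82
bound to the Keap1 Kelch domain) is summarised as a *triplet*: the three
virtual triangles through the Cα, N and C backbone atoms of three residues
(nine vertices).  Every three-residue combination drawn from a scaffold's
CDR loops is indexed by a rigid-invariant key built from quantized
inter-residue backbone distances; key matches are confirmed by nine-vertex
least-squares superposition, the whole scaffold is carried into the antigen
frame, the matched residues are replaced by the hotspot residues, and
candidates whose backbone clashes with the antigen are discarded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, superpose
from .structures import FvAnnotation, Residue, ResidueID, Structure

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Triplet geometry and keys

#: vertex layout: indices 0-2 the Cα triangle, 3-5 the N, 6-8 the C triangle
TripletVertices = np.ndarray  # shape (9, 3)

#: within each atom class, distances are taken between residue pairs
#: (0,1), (0,2), (1,2) in that order
_PAIR_INDEX = [(0, 1), (0, 2), (1, 2)]


@dataclass(frozen=True)
class TripletKey:
    """Quantized triplet geometry: 9 binned distances + an ordering token.

    ``token`` records how residue order was canonicalised: ``"seq"`` keeps
    the distances in residue order (donor and acceptor both in sequence
    order), ``"sorted"`` sorts each atom class's three distances so the key
    is permutation-invariant.
    """

    bins: tuple[int, ...]
    token: str = "seq"

    def __post_init__(self):
        if len(self.bins) != 9:
            raise ValueError("triplet key needs 9 binned distances")


def triplet_vertices(
    structure: Structure, residues: Sequence[ResidueID]
) -> TripletVertices:
    """Collect the 9 triangle vertices for three residues (Cα, N, C rows)."""
    if len(residues) != 3:
        raise ValueError("a triplet needs exactly 3 residues")
    resolved = [structure.get_residue(rid) for rid in residues]
    return residue_triplet_vertices(resolved)


def residue_triplet_vertices(residues: Sequence[Residue]) -> TripletVertices:
    if len(residues) != 3:
        raise ValueError("a triplet needs exactly 3 residues")
    rows = []
    for atom_name in ("CA", "N", "C"):
        for res in residues:
            try:
                rows.append(res.atom(atom_name).coord)
            except KeyError:
                raise ValueError(
                    f"residue {res.rid} is missing backbone atom {atom_name}"
                ) from None
    return np.array(rows, dtype=float)


def _triplet_distances(v: TripletVertices, sort_within_class: bool) -> np.ndarray:
    v = np.asarray(v, float)
    if v.shape != (9, 3):
        raise ValueError("triplet vertices must be a (9, 3) array")
    dists = []
    for cls in range(3):  # Cα, N, C triangles
        block = v[3 * cls : 3 * cls + 3]
        d = [float(np.linalg.norm(block[i] - block[j])) for i, j in _PAIR_INDEX]
        if sort_within_class:
            d = sorted(d)
        dists.extend(d)
    return np.array(dists)


def triplet_key(
    v: TripletVertices, bin_width: float = 1.0, token: str = "seq"
) -> TripletKey:
    """Rigid-invariant hash key from the 9 within-class pairwise distances."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = _triplet_distances(v, sort_within_class=(token == "sorted"))
    return TripletKey(tuple(int(x) for x in np.floor(d / bin_width)), token)


def neighbor_keys(key: TripletKey, spread: int = 1) -> Iterator[TripletKey]:
    """All keys within ±`spread` bins per distance (boundary-miss probing)."""
    ranges = [range(b - spread, b + spread + 1) for b in key.bins]
    for combo in itertools.product(*ranges):
        yield TripletKey(combo, key.token)


# ----------------------------------------------------------------------
# Hotspots and scaffolds

@dataclass
class HotspotSet:
    """Donor hotspot residues in the antigen-bound frame, plus the antigen
    the graft must keep clear of (and keep the hotspot contacts to)."""

    residues: list[Residue]
    antigen: Structure

    def __post_init__(self):
        if len(self.residues) < 3:
            raise ValueError("need at least 3 hotspot residues for a triplet")
        for res in self.residues:
            if not res.has_atoms(("N", "CA", "C")):
                raise ValueError(f"hotspot {res.rid} lacks a complete backbone")

    def triplets(self) -> Iterator[tuple[Residue, Residue, Residue]]:
        """All three-residue combinations, in residue order."""
        yield from itertools.combinations(self.residues, 3)


@dataclass
class GraftParams:
    bin_width: float = 1.0
    neighbor_spread: int = 1
    rmsd_threshold: float = 0.75
    clash_cutoff: float = 2.5
    #: "sequence": match donor/acceptor triplets in residue order;
    #: "permute": try all residue orderings of the scaffold triplet
    match_mode: str = "sequence"
    max_span: int | None = None
    #: clash scope: grafted-scaffold backbone vs all antigen heavy atoms
    clash_backbone_only: bool = True


@dataclass
class GraftCandidate:
    scaffold_id: str
    matched_residues: tuple[ResidueID, ResidueID, ResidueID]
    rmsd: float
    transform: RigidTransform
    clash_pairs: list[tuple[int, int, float]]
    grafted: Structure

    @property
    def clash_count(self) -> int:
        return len(self.clash_pairs)

    @property
    def accepted(self) -> bool:
        return self.clash_count == 0


def enumerate_cdr_triplets(
    scaffold: Structure,
    annotation: FvAnnotation,
    max_span: int | None = None,
    bin_width: float = 1.0,
    token: str = "seq",
) -> Iterator[tuple[tuple[ResidueID, ResidueID, ResidueID], TripletKey]]:
    """Emit every 3-combination of CDR residues (with complete N/CA/C
    backbones) exactly once, with its hash key.

    `max_span` limits the author-number span (last minus first) of a
    triplet; when set, cross-chain triplets are excluded since numbering is
    only comparable within a chain.
    """
    cdr = [
        r for r in annotation.cdr_residues(scaffold) if r.has_atoms(("N", "CA", "C"))
    ]
    for combo in itertools.combinations(cdr, 3):
        if max_span is not None:
            chains = {r.rid.chain for r in combo}
            if len(chains) > 1:
                continue
            span = combo[-1].rid.number - combo[0].rid.number
            if span > max_span:
                continue
        v = residue_triplet_vertices(combo)
        yield (
            tuple(r.rid for r in combo),
            triplet_key(v, bin_width, token),
        )


def clash_check(
    a: np.ndarray | Sequence[Sequence[float]],
    b: np.ndarray | Sequence[Sequence[float]],
    cutoff: float,
) -> list[tuple[int, int, float]]:
    """All cross-set heavy-atom pairs closer than `cutoff` (exact, via a
    spatial grid).  Returns (index in a, index in b, distance) tuples."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = np.asarray(a, float).reshape(-1, 3)
    B = np.asarray(b, float).reshape(-1, 3)
    if A.shape[0] == 0 or B.shape[0] == 0:
        return []
    tree = cKDTree(B)
    pairs: list[tuple[int, int, float]] = []
    for i, hits in enumerate(tree.query_ball_point(A, r=cutoff)):
        for j in hits:
            d = float(np.linalg.norm(A[i] - B[j]))
            if d < cutoff:
                pairs.append((i, j, d))
    return pairs


def graft_residues(
    scaffold: Structure,
    matched: Sequence[ResidueID],
    hotspots: Sequence[Residue],
) -> Structure:
    """Replace the matched scaffold residues' side chains and types with the
    hotspot residues; the scaffold backbone (N, CA, C, O) is kept, hotspot
    side-chain coordinates are carried over rigidly (already in the aligned
    frame)."""
    out = scaffold.copy()
    for rid, donor in zip(matched, hotspots):
        res = out.get_residue(rid)
        res.name = donor.name
        backbone = [a for a in res.atoms if a.is_backbone]
        side = [a.copy() for a in donor.atoms if not a.is_backbone]
        res.atoms = backbone + side
    return out


def match_and_graft(
    hotspots: HotspotSet,
    library: Iterable[tuple[str, Structure, FvAnnotation]],
    params: GraftParams | None = None,
) -> list[GraftCandidate]:
    """Search a scaffold library for CDR triplets geometrically matching a
    hotspot triplet, superpose, transplant and clash-filter.

    Candidates (clashing ones included, with their clash pairs) are
    returned sorted by nine-vertex RMSD, clash-free first among ties.
    """
    params = params or GraftParams()
    token = "sorted" if params.match_mode == "permute" else "seq"

    # precompute the probe key set for every hotspot triplet
    probes: list[tuple[tuple[Residue, ...], TripletVertices, set[TripletKey]]] = []
    for combo in hotspots.triplets():
        v = residue_triplet_vertices(combo)
        key = triplet_key(v, params.bin_width, token)
        probes.append((combo, v, set(neighbor_keys(key, params.neighbor_spread))))

    antigen_coords = hotspots.antigen.coords()
    candidates: list[GraftCandidate] = []
    for scaffold_id, scaffold, annotation in library:
        for rids, key in enumerate_cdr_triplets(
            scaffold, annotation, params.max_span, params.bin_width, token
        ):
            for donors, hv, probe_set in probes:
                if key not in probe_set:
                    continue
                sv = triplet_vertices(scaffold, rids)
                orders = (
                    [(0, 1, 2)]
                    if params.match_mode == "sequence"
                    else list(itertools.permutations(range(3)))
                )
                best: tuple[float, RigidTransform, tuple[int, ...]] | None = None
                for order in orders:
                    idx = np.array(
                        [order[0], order[1], order[2]] * 3
                    ) + np.repeat([0, 3, 6], 3)
                    try:
                        transform, fit = superpose(sv[idx], hv)
                    except ValueError:
                        continue
                    if best is None or fit < best[0]:
                        best = (fit, transform, order)
                if best is None or best[0] > params.rmsd_threshold:
                    continue
                fit, transform, order = best
                moved = scaffold.transform(transform)
                ordered_rids = tuple(rids[i] for i in order)
                grafted = graft_residues(moved, ordered_rids, donors)
                bb = grafted.coords(backbone_only=params.clash_backbone_only)
                pairs = clash_check(bb, antigen_coords, params.clash_cutoff)
                candidates.append(
                    GraftCandidate(
                        scaffold_id=scaffold_id,
                        matched_residues=ordered_rids,
                        rmsd=fit,
                        transform=transform,
                        clash_pairs=pairs,
                        grafted=grafted,
                    )
                )
    candidates.sort(key=lambda c: (c.rmsd, c.clash_count))
    return candidates


def brute_force_matches(
    hotspots: HotspotSet,
    library: Iterable[tuple[str, Structure, FvAnnotation]],
    params: GraftParams | None = None,
) -> list[tuple[str, tuple[ResidueID, ...], float]]:
    """Exhaustive all-triplet superposition search (no hashing); the
    completeness oracle for :func:`match_and_graft`."""
    params = params or GraftParams()
    hits: list[tuple[str, tuple[ResidueID, ...], float]] = []
    hv_list = [residue_triplet_vertices(c) for c in hotspots.triplets()]
    for scaffold_id, scaffold, annotation in library:
        cdr = [
            r
            for r in annotation.cdr_residues(scaffold)
            if r.has_atoms(("N", "CA", "C"))
        ]
        for combo in itertools.combinations(cdr, 3):
            if params.max_span is not None:
                if len({r.rid.chain for r in combo}) > 1:
                    continue
                if combo[-1].rid.number - combo[0].rid.number > params.max_span:
                    continue
            sv = residue_triplet_vertices(combo)
            for hv in hv_list:
                orders = (
                    [(0, 1, 2)]
                    if params.match_mode == "sequence"
                    else list(itertools.permutations(range(3)))
                )
                best = np.inf
                for order in orders:
                    idx = np.array(
                        [order[0], order[1], order[2]] * 3
                    ) + np.repeat([0, 3, 6], 3)
                    try:
                        _, fit = superpose(sv[idx], hv)
                    except ValueError:
                        continue
                    best = min(best, fit)
                if best <= params.rmsd_threshold:
                    hits.append((scaffold_id, tuple(r.rid for r in combo), best))
    return hits
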