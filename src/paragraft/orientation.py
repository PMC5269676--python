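"""VH/VL orientation descriptors and rigid-body deviation measures.

The six orientation descriptors follow the ABangle convention: a reference
frame plane is registered onto each variable domain by least-squares fit of
packaged consensus coreset Cα positions; the inter-domain vector **C**
joins the two frame origins, each plane carries two in-plane vectors
(H1/H2 on VH, L1/L2 on VL), and the descriptors are

* ``HL`` — torsion angle between H1 and L1 about **C** (signed,
  right-handed about **C** pointing from VH to VL),
* ``HC1``/``HC2``/``LC1``/``LC2`` — bend angles between each plane vector
  and **C**,
* ``dc`` — the length of **C** in Å.

The frame set shipped as the default is synthetic: it is generated from
the package's own template VH/VL domains, so descriptors are directly
comparable across structures built from those templates (or any structure
a user supplies frames for via :class:`FrameData`), with the same
mathematical structure as the published convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import RigidTransform, rotation_angle, center_of_mass, superpose
from .structures import FvAnnotation, ResidueID, Structure

logger = logging.getLogger(__name__)


@dataclass
class DomainFrame:
    """Consensus coreset (Cα positions in the frame's local coordinates)
    plus the local frame origin and two in-plane unit vectors."""

    coreset_positions: list[tuple[int, str]]  # (author number, insertion)
    coreset_coords: np.ndarray                # (n, 3) local Å
    origin: np.ndarray                        # (3,) local
    plane1: np.ndarray                        # (3,) local unit vector
    plane2: np.ndarray

    def __post_init__(self):
        self.coreset_coords = np.asarray(self.coreset_coords, float).reshape(-1, 3)
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.plane1 = _unit(np.asarray(self.plane1, float))
        self.plane2 = _unit(np.asarray(self.plane2, float))
        if len(self.coreset_positions) != self.coreset_coords.shape[0]:
            raise ValueError("coreset positions/coords length mismatch")


@dataclass
class FrameData:
    heavy: DomainFrame
    light: DomainFrame


@dataclass
class FvOrientation:
    hl_torsion: float   # degrees, (−180, 180]
    hc1_bend: float     # degrees, [0, 180]
    hc2_bend: float
    lc1_bend: float
    lc2_bend: float
    dc: float           # Å
    fit_rmsd_heavy: float
    fit_rmsd_light: float


@dataclass
class DeviationReport:
    com_distance: float
    rotation_angle: float
    rotation_axis: np.ndarray
    reference_selection: str
    target_selection: str


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def default_frames() -> FrameData:
    """Synthetic consensus frames matching the packaged template domains."""
    from .synthfix import template_frame_data

    return template_frame_data()


def _register_frame(
    structure: Structure,
    chain_id: str,
    frame: DomainFrame,
    max_missing_frac: float = 0.2,
    warn_rmsd: float = 1.0,
):
    present: dict[tuple[int, str], np.ndarray] = {}
    for res in structure.residues(chain_id):
        try:
            present[(res.rid.number, res.rid.insertion)] = res.atom("CA").coord
        except KeyError:
            continue
    local, observed = [], []
    for pos, xyz in zip(frame.coreset_positions, frame.coreset_coords):
        if pos in present:
            local.append(xyz)
            observed.append(present[pos])
    n_total = len(frame.coreset_positions)
    if n_total - len(local) > max_missing_frac * n_total:
        raise ValueError(
            f"chain {chain_id}: {n_total - len(local)}/{n_total} coreset "
            "positions missing (> 20%)"
        )
    transform, fit = superpose(np.array(local), np.array(observed))
    if fit > warn_rmsd:
        logger.warning(
            "chain %s: coreset fit rmsd %.2f Å exceeds %.2f Å — frame "
            "registration may be unreliable", chain_id, fit, warn_rmsd,
        )
    return transform, fit


def _signed_torsion(a: np.ndarray, axis: np.ndarray, b: np.ndarray) -> float:
    """Signed angle from a to b about `axis` (right-handed), degrees."""
    a_p = a - np.dot(a, axis) * axis
    b_p = b - np.dot(b, axis) * axis
    x = np.dot(a_p, b_p)
    y = np.dot(np.cross(axis, a_p), b_p)
    return float(np.degrees(np.arctan2(y, x)))


def _bend(v: np.ndarray, axis: np.ndarray) -> float:
    return float(
        np.degrees(np.arccos(np.clip(np.dot(_unit(v), axis), -1.0, 1.0)))
    )


def abangle_descriptors(
    fv: Structure,
    annotation: FvAnnotation,
    frames: FrameData | None = None,
) -> FvOrientation:
    """Compute the six VH/VL orientation descriptors for one Fv."""
    frames = frames or default_frames()
    t_h, fit_h = _register_frame(fv, annotation.heavy, frames.heavy)
    if annotation.light is None:
        raise ValueError("orientation analysis needs both domains")
    t_l, fit_l = _register_frame(fv, annotation.light, frames.light)

    o_h = t_h.apply(frames.heavy.origin)
    o_l = t_l.apply(frames.light.origin)
    h1 = t_h.rotation @ frames.heavy.plane1
    h2 = t_h.rotation @ frames.heavy.plane2
    l1 = t_l.rotation @ frames.light.plane1
    l2 = t_l.rotation @ frames.light.plane2

    c = o_l - o_h
    dc = float(np.linalg.norm(c))
    if dc < 1e-9:
        raise ValueError("degenerate Fv: coincident frame origins")
    c_hat = c / dc
    return FvOrientation(
        hl_torsion=_signed_torsion(h1, c_hat, l1),
        hc1_bend=_bend(h1, c_hat),
        hc2_bend=_bend(h2, c_hat),
        lc1_bend=_bend(l1, c_hat),
        lc2_bend=_bend(l2, c_hat),
        dc=dc,
        fit_rmsd_heavy=fit_h,
        fit_rmsd_light=fit_l,
    )


# ----------------------------------------------------------------------
# Rigid-body deviation (crystal vs model comparison)

def _selection_coords(
    structure: Structure,
    chains: Sequence[str],
    atom_names: Sequence[str] = ("CA",),
) -> dict[tuple[ResidueID, str], np.ndarray]:
    out = {}
    for cid in chains:
        for res in structure.residues(cid):
            for atom in res.atoms:
                if atom.name in atom_names:
                    out[(res.rid, atom.name)] = atom.coord
    return out


def rigid_body_deviation(
    model_a: Structure,
    model_b: Structure,
    reference_chains: Sequence[str],
    target_chains: Sequence[str],
    atom_names: Sequence[str] = ("CA",),
) -> DeviationReport:
    """Rigid-body drift of a target selection after superposing two models
    on a reference selection.

    `model_b` is fitted onto `model_a` using the matched reference atoms;
    the report gives the COM distance between the target selections and
    the angle/axis of the residual best-fit rotation between them — the
    COM-drift / rotation-angle characterisation of domain movement.
    """
    sel_a_ref = _selection_coords(model_a, reference_chains, atom_names)
    sel_b_ref = _selection_coords(model_b, reference_chains, atom_names)
    common_ref = sorted(
        set(sel_a_ref) & set(sel_b_ref), key=lambda k: (k[0], k[1])
    )
    only_a = set(sel_a_ref) - set(sel_b_ref)
    only_b = set(sel_b_ref) - set(sel_a_ref)
    if not common_ref:
        raise ValueError(
            f"no matched reference atoms; unmatched: {sorted(only_a | only_b)!r}"
        )
    if only_a or only_b:
        logger.warning("reference correspondence drops %d unmatched atoms",
                       len(only_a) + len(only_b))
    ref_a = np.array([sel_a_ref[k] for k in common_ref])
    ref_b = np.array([sel_b_ref[k] for k in common_ref])
    align, _ = superpose(ref_b, ref_a)

    sel_a_tgt = _selection_coords(model_a, target_chains, atom_names)
    sel_b_tgt = _selection_coords(model_b, target_chains, atom_names)
    common_tgt = sorted(
        set(sel_a_tgt) & set(sel_b_tgt), key=lambda k: (k[0], k[1])
    )
    missing = (set(sel_a_tgt) ^ set(sel_b_tgt))
    if len(common_tgt) < 3:
        raise ValueError(
            f"target correspondence too small; unmatched: {sorted(missing)!r}"
        )
    tgt_a = np.array([sel_a_tgt[k] for k in common_tgt])
    tgt_b = align.apply(np.array([sel_b_tgt[k] for k in common_tgt]))

    com_dist = float(
        np.linalg.norm(center_of_mass(tgt_a) - center_of_mass(tgt_b))
    )
    fit, _ = superpose(tgt_b, tgt_a)
    angle, axis = rotation_angle(fit)
    return DeviationReport(
        com_distance=com_dist,
        rotation_angle=angle,
        rotation_axis=axis,
        reference_selection="+".join(reference_chains),
        target_selection="+".join(target_chains),
    )
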