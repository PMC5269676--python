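"""Deterministic synthetic structures for exercising every pipeline stage.

The generators emulate the three input classes the pipeline consumes:
scaffolds with planted hotspot-compatible CDR triplets, idealized hairpin
CDRH3 loops sharing canonical anchor geometry, toy two-domain Fvs with a
known relative orientation, and complementary pseudo-atom slab interfaces
with tunable gap and roughness.  Everything is a poly-alanine / pseudo-atom
construction: the simplest geometry that exercises each code path, with a
few planted polar atoms where hydrogen-bond behaviour is needed.  Identical
seeds give identical structures (and byte-identical files when written).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .grafting import HotspotSet, TripletVertices, residue_triplet_vertices
from .loopswap import LoopRecord
from .structures import AtomRecord, FvAnnotation, Residue, ResidueID, Structure

logger = logging.getLogger(__name__)


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _rigid_from_rng(rng: np.random.Generator, max_shift: float = 20.0) -> RigidTransform:
    rotvec = rng.normal(size=3)
    rotvec = _unit(rotvec) * rng.uniform(0, np.pi)
    R = Rotation.from_rotvec(rotvec).as_matrix()
    t = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(R, t)


# ----------------------------------------------------------------------
# Canonical CDRH3 anchor geometry (shared by all generated loops/designs)

def _anchor_residue_93() -> dict[str, np.ndarray]:
    ca = np.zeros(3)
    n = ca + 1.46 * _unit((-0.75, 0.45, -0.65))
    c = ca + 1.52 * _unit((0.55, -0.25, 0.85))
    o = c + 1.23 * _unit(np.cross(c - ca, n - ca))
    cb = ca + 1.53 * _unit(np.cross(n - ca, c - ca) + np.array([0.0, -0.6, 0.0]))
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def _anchor_residue_103() -> dict[str, np.ndarray]:
    ca = np.array([5.4, 0.0, 0.0])
    n = ca + 1.46 * _unit((-0.55, -0.25, 0.85))
    c = ca + 1.52 * _unit((0.80, 0.45, -0.50))
    o = c + 1.23 * _unit(np.cross(c - ca, n - ca))
    cb = ca + 1.53 * _unit(np.cross(n - ca, c - ca) + np.array([0.0, 0.6, 0.0]))
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def _interior_numbering(length: int) -> list[tuple[int, str]]:
    """Author numbering for `length` residues between anchors: 94..102 then
    insertion codes at 100 for longer loops, 94.. upward for shorter."""
    if length <= 9:
        return [(94 + k, "") for k in range(length)]
    base = [(n, "") for n in range(94, 101)]  # 94..100
    inserts = [(100, chr(ord("A") + k)) for k in range(length - 9)]
    tail = [(101, ""), (102, "")]
    return base + inserts + tail


def make_hairpin_loop(length: int, seed: int = 0, chain: str = "H") -> LoopRecord:
    """Idealized β-hairpin CDRH3 fragment numbered 93..103.

    `length` counts the residues between and excluding the two anchor
    positions.  All loops share byte-identical canonical terminal-residue
    geometry, so anchor superposition across loops is exact by
    construction.  Backbone atoms are strung along a semi-elliptical arc
    with ideal bond lengths along the path (N–CA 1.46, CA–C 1.52,
    C–N 1.33 Å); a small seeded jitter (σ = 0.03 Å) decorrelates interior
    conformations between seeds.
    """
    if not 4 <= length <= 20:
        raise ValueError("loop length must be in [4, 20]")
    rng = np.random.default_rng(seed)
    a93 = _anchor_residue_93()
    a103 = _anchor_residue_103()

    start = a93["C"]
    end = a103["N"]
    chord = end - start
    c_len = float(np.linalg.norm(chord))
    u = chord / c_len
    up = _unit(np.array([0.0, 0.0, 1.0]) - np.array([0.0, 0.0, 1.0]).dot(u) * u)
    total = 1.33 + 4.31 * length  # path length C(93) -> N(103)
    mid = (start + end) / 2.0

    # stadium-shaped hairpin: two straight strands joined by a semicircular
    # cap; the cap radius (half the mouth width) keeps curvature gentle so
    # chord distances stay close to arc-length bond distances
    cap_r = c_len / 2.0
    strand = (total - np.pi * cap_r) / 2.0
    center = mid + strand * up

    def at(s: float) -> np.ndarray:
        if s <= strand:
            return start + s * up
        if s <= strand + np.pi * cap_r:
            phi = (s - strand) / cap_r
            return center - cap_r * np.cos(phi) * u + cap_r * np.sin(phi) * up
        return end + (total - s) * up

    def tangent(s: float) -> np.ndarray:
        eps = 0.05
        return _unit(at(min(s + eps, total)) - at(max(s - eps, 0.0)))

    residues: list[Residue] = []
    residues.append(_residue_from_coords(chain, 93, "", "ALA", a93))
    for k, (num, icode) in enumerate(_interior_numbering(length)):
        s_n = 1.33 + k * 4.31
        s_ca = s_n + 1.46
        s_c = s_ca + 1.52
        t = tangent(s_ca)
        w = at(s_ca) - mid
        normal = _unit(w - w.dot(t) * t)
        coords = {
            "N": at(s_n),
            "CA": at(s_ca),
            "C": at(s_c),
            "O": at(s_c) + 1.23 * normal,
            "CB": at(s_ca) + 1.53 * _unit(np.cross(t, normal)),
        }
        jitter = rng.normal(0.0, 0.03, size=(5, 3))
        for (name, xyz), dx in zip(list(coords.items()), jitter):
            coords[name] = xyz + dx
        residues.append(_residue_from_coords(chain, num, icode, "ALA", coords))
    residues.append(_residue_from_coords(chain, 103, "", "ALA", a103))
    return LoopRecord(f"hairpin-{length}-{seed}", residues)


def _residue_from_coords(
    chain: str, number: int, icode: str, name: str, coords: dict[str, np.ndarray]
) -> Residue:
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    res = Residue(ResidueID(chain, number, icode), name)
    for atom_name in ("N", "CA", "C", "O", "CB"):
        if atom_name in coords:
            res.atoms.append(
                AtomRecord(atom_name, elements[atom_name], np.asarray(coords[atom_name]))
            )
    return res


def loop_to_structure(record: LoopRecord) -> Structure:
    out = Structure({"H": "heavy"})
    out.metadata["source"] = record.source_id
    for res in record.residues:
        out.add_residue(res.copy())
    return out


# ----------------------------------------------------------------------
# Toy Fv design with a swappable CDRH3

def make_toy_design(
    seed: int = 0, loop_length: int = 13, with_antigen: bool = False
) -> tuple[Structure, FvAnnotation]:
    """A minimal heavy-chain design: framework residues 85–92 and 104–110
    flanking a generated hairpin CDRH3, with exact peptide bonds (C–N
    1.33 Å, ω = 180°) at the 92–93 and 103–104 junctions."""
    loop = make_hairpin_loop(loop_length, seed)
    st = Structure({"H": "heavy"})
    for res in loop.residues:
        st.add_residue(res.copy())

    a93 = _anchor_residue_93()
    a103 = _anchor_residue_103()
    down1 = _unit((-0.65, 0.25, -0.72))
    down2 = _unit((0.65, 0.25, -0.72))

    def bonded_neighbor(anchor: dict, direction: np.ndarray, before: bool):
        """Residue covalently preceding (before=True) or following an anchor
        with ideal bond geometry and trans ω."""
        if before:  # build residue 92: its C bonds the anchor N
            n_a, ca_a = anchor["N"], anchor["CA"]
            e1 = _unit(n_a - (n_a + 1.33 * _unit(n_a - ca_a)))  # placeholder
            c = n_a + 1.33 * _unit(direction + _unit(n_a - ca_a))
            # CA(92) in the C(92)/N(93)/CA(93) plane, trans across the bond
            e = _unit(n_a - c)
            w = ca_a - n_a
            w_perp = w - w.dot(e) * e
            ca = c + 1.52 * (np.cos(np.deg2rad(116)) * e
                             - np.sin(np.deg2rad(116)) * _unit(w_perp))
            o = c + 1.23 * _unit(np.cross(e, w_perp))
            n = ca + 1.46 * _unit(direction + 0.3 * _unit(np.cross(e, w_perp)))
            return {"N": n, "CA": ca, "C": c, "O": o}
        # build residue 104: its N bonds the anchor C
        c_a, ca_a, o_a = anchor["C"], anchor["CA"], anchor["O"]
        n = c_a + 1.33 * _unit(direction + _unit(c_a - ca_a))
        e = _unit(n - c_a)
        w = ca_a - c_a
        w_perp = w - w.dot(e) * e
        ca = n + 1.46 * (np.cos(np.deg2rad(121)) * (-e)
                         + np.sin(np.deg2rad(121)) * (-_unit(w_perp)))
        c = ca + 1.52 * _unit(direction)
        o = c + 1.23 * _unit(np.cross(direction, w_perp))
        return {"N": n, "CA": ca, "C": c, "O": o}

    r92 = bonded_neighbor(a93, down1, before=True)
    r104 = bonded_neighbor(a103, down2, before=False)
    st.add_residue(_residue_from_coords("H", 92, "", "ALA", r92))
    st.add_residue(_residue_from_coords("H", 104, "", "ALA", r104))

    # straight framework strands walking away from the loop mouth
    for start_num, step, origin_ca, direction in (
        (91, -1, r92["CA"], down1),
        (105, +1, r104["CA"], down2),
    ):
        num = start_num
        ca_prev = origin_ca
        while 85 <= num <= 110:
            ca = ca_prev + 3.8 * direction
            t = direction
            normal = _unit(np.cross(t, np.array([0.0, 1.0, 0.1])))
            coords = {
                "N": ca - 1.46 * t,
                "CA": ca,
                "C": ca + 1.52 * t,
                "O": ca + 1.52 * t + 1.23 * normal,
                "CB": ca + 1.53 * np.cross(t, normal),
            }
            st.add_residue(_residue_from_coords("H", num, "", "ALA", coords))
            ca_prev = ca
            num += step

    if with_antigen:
        # well below the framework strands, clear of any loop conformation
        ag = _slab_chain("A", n=8, spacing=2.0, z0=-28.0, element="C")
        st = st.merged_with(ag)
    annotation = FvAnnotation(heavy="H", light=None)
    return st, annotation


# ----------------------------------------------------------------------
# Hotspot complex and planted scaffolds

def _slab_chain(
    chain: str, n: int, spacing: float, z0: float, element: str = "C"
) -> Structure:
    st = Structure({chain: "antigen"})
    num = 1
    half = (n - 1) * spacing / 2.0
    for i in range(n):
        for j in range(n):
            st.new_residue(
                chain, num, "UNK",
                [("C1", element, (i * spacing - half, j * spacing - half, z0))],
            )
            num += 1
    return st


def _placed_template_residue(
    chain: str, number: int, name: str, ca: np.ndarray,
    side_dir: np.ndarray, seq_dir: np.ndarray,
) -> Residue:
    """Full-atom residue from the idealised template, rigidly placed so CA
    sits at `ca`, the CA→CB vector points along `side_dir` and the N→C
    axis along `seq_dir`."""
    from .interface import _sidechain_template
    import biotite.structure.info as struc_info

    arr = struc_info.residue(name)
    names = list(arr.atom_name)
    coords = np.asarray(arr.coord, float)
    elements = [e.upper() for e in arr.element]
    idx = {n: i for i, n in enumerate(names)}
    t_ca = coords[idx["CA"]]
    t_cb = coords[idx["CB"]]
    t_n = coords[idx["N"]]
    t_c = coords[idx["C"]]

    def frame(origin, v_side, v_seq):
        e1 = _unit(v_side)
        e2 = _unit(v_seq - v_seq.dot(e1) * e1)
        e3 = np.cross(e1, e2)
        return np.column_stack([e1, e2, e3])

    R = frame(ca, side_dir, seq_dir) @ frame(t_ca, t_cb - t_ca, t_c - t_n).T
    res = Residue(ResidueID(chain, number), name)
    for i, (aname, elem) in enumerate(zip(names, elements)):
        if elem.startswith("H") or aname == "OXT":
            continue
        res.atoms.append(AtomRecord(aname, elem, R @ (coords[i] - t_ca) + ca))
    return res


def make_hotspot_complex(seed: int = 0) -> tuple[HotspotSet, Structure]:
    """A toy donor complex: three full-atom hotspot residues (Glu, Thr,
    Glu — the ETGE-like pattern) perched above a pseudo-atom antigen slab,
    side chains pointing down at planted polar partner atoms."""
    antigen = _slab_chain("A", n=12, spacing=2.0, z0=-2.5)
    down = np.array([0.0, 0.0, -1.0])
    seq = np.array([1.0, 0.0, 0.0])
    placements = [
        (79, "GLU", np.array([0.0, 0.0, 4.6])),
        (80, "THR", np.array([3.8, 0.6, 5.0])),
        (82, "GLU", np.array([10.2, 0.0, 4.6])),
    ]
    hotspot_residues = [
        _placed_template_residue("P", num, name, ca, down, seq)
        for num, name, ca in placements
    ]
    # polar partner atoms 2.9 Å beneath each acidic/hydroxyl tip
    partner_num = 500
    tips = []
    for res in hotspot_residues:
        for atom in res.atoms:
            if atom.name in ("OE1", "OE2", "OG1"):
                tips.append(atom.coord)
    for tip in tips:
        antigen.new_residue(
            "A", partner_num, "UNK", [("N1", "N", tip + 2.9 * down)]
        )
        partner_num += 1

    complex_structure = antigen.copy()
    for res in hotspot_residues:
        complex_structure.add_residue(res.copy())
    complex_structure.roles["P"] = "antigen"  # donor peptide side
    return HotspotSet(hotspot_residues, antigen), complex_structure


def make_planted_scaffold(
    hotspot_triplet: TripletVertices,
    noise: float = 0.0,
    seed: int = 0,
    plant: bool = True,
    up=(0.0, 0.0, 1.0),
) -> tuple[Structure, FvAnnotation]:
    """A toy numbered Fv-like heavy chain whose CDR contains (when
    `plant`) three residues reproducing the donor triplet geometry up to a
    random rigid motion plus Gaussian jitter of σ = `noise` Å; the rest of
    the chain arcs away on the `up` side, clear of the antigen.

    The planted residue ids are recorded in the structure metadata (and as
    a REMARK when written to PDB)."""
    v = np.asarray(hotspot_triplet, float)
    if v.shape != (9, 3):
        raise ValueError("hotspot triplet must be a (9, 3) vertex array")
    rng = np.random.default_rng(seed)
    up = _unit(up)
    e1 = _unit(np.cross(up, [1.0, 0.3, 0.2]))
    e2 = np.cross(up, e1)
    tc = v[:3].mean(axis=0)  # Cα-triangle centroid

    st = Structure({"H": "heavy"})
    planted = {27: 0, 28: 1, 30: 2}
    for k, number in enumerate(range(20, 41)):
        if plant and number in planted:
            i = planted[number]
            coords = {
                "CA": v[i] + rng.normal(0, noise, 3),
                "N": v[3 + i] + rng.normal(0, noise, 3),
                "C": v[6 + i] + rng.normal(0, noise, 3),
            }
            ca, n, c = coords["CA"], coords["N"], coords["C"]
            coords["O"] = c + 1.23 * _unit(np.cross(c - ca, n - ca))
            coords["CB"] = ca + 1.53 * _unit(np.cross(n - ca, c - ca))
        else:
            ang = np.deg2rad(137.5) * k
            lateral = (number - 30) * 2.1
            height = 5.0 + 5.0 * np.sin(np.pi * (number - 20) / 20.0)
            ca = tc + height * up + lateral * e1 + 2.5 * np.cos(ang) * e2
            spin = Rotation.from_rotvec(ang * up).as_matrix()
            coords = {
                "CA": ca,
                "N": ca + spin @ np.array([-1.10, 0.55, -0.62]),
                "C": ca + spin @ np.array([1.25, 0.42, 0.60]),
            }
            coords["O"] = coords["C"] + 1.23 * up
            coords["CB"] = ca + 1.53 * up
        st.add_residue(_residue_from_coords("H", number, "", "ALA", coords))

    motion = _rigid_from_rng(rng)
    st = st.transform(motion)
    if plant:
        st.metadata["planted"] = ",".join(f"H{n}" for n in sorted(planted))
    return st, FvAnnotation(heavy="H", light=None)


def make_decoy_scaffold(seed: int = 0) -> tuple[Structure, FvAnnotation]:
    """A scaffold with no planted triplet (decoy library member)."""
    dummy = residue_triplet_vertices(
        make_hotspot_complex()[0].residues
    )
    return make_planted_scaffold(dummy, seed=seed, plant=False)


# ----------------------------------------------------------------------
# Toy two-domain Fv with known VH/VL orientation

_TEMPLATE_N_RES = 36
_PACK_DC = 16.0
_PACK_TWIST = -60.0  # degrees about the inter-domain axis
_PACK_TILT = 10.0    # degrees, keeps bend angles away from 90°


def _domain_template_cas(kind: str) -> np.ndarray:
    phase = 0.0 if kind == "H" else 1.1
    i = np.arange(_TEMPLATE_N_RES)
    theta = np.deg2rad(100.0) * i + phase
    radius = 6.0 + 0.8 * np.sin(3.0 * theta)
    cas = np.column_stack(
        (radius * np.cos(theta), radius * np.sin(theta), 1.35 * i)
    )
    return cas - cas.mean(axis=0)


def _pack_transform() -> RigidTransform:
    twist = RigidTransform.about_axis((0, 0, 1), _PACK_TWIST)
    tilt = RigidTransform.about_axis((1, 0, 0), _PACK_TILT)
    shift = RigidTransform.translation_by((0.0, 0.0, _PACK_DC))
    return shift.compose(tilt.compose(twist))


def template_frame_data():
    """Frame data matching the packaged synthetic template domains."""
    from .orientation import DomainFrame, FrameData

    def frame(kind):
        cas = _domain_template_cas(kind)
        return DomainFrame(
            coreset_positions=[(n, "") for n in range(2, _TEMPLATE_N_RES)],
            coreset_coords=cas[1:_TEMPLATE_N_RES - 1],
            origin=np.zeros(3),
            plane1=np.array([1.0, 0.0, 0.0]),
            plane2=np.array([0.0, 1.0, 0.0]),
        )

    return FrameData(heavy=frame("H"), light=frame("L"))


def make_toy_fv(
    domain_transform: RigidTransform | None = None, seed: int = 0
) -> tuple[Structure, FvAnnotation]:
    """Two Cα-trace template domains in a canonical packing; an optional
    extra rigid motion is applied to the VL domain on top of the packing
    (e.g. a rotation about the inter-domain axis to shift the HL torsion)."""
    st = Structure({"H": "heavy", "L": "light"})
    for num, ca in enumerate(_domain_template_cas("H"), start=1):
        st.new_residue("H", num, "GLY", [("CA", "C", ca)])
    pack = _pack_transform()
    extra = domain_transform or RigidTransform.identity()
    for num, ca in enumerate(_domain_template_cas("L"), start=1):
        st.new_residue("L", num, "GLY", [("CA", "C", extra.apply(pack.apply(ca)))])
    return st, FvAnnotation(heavy="H", light="L")


def c_axis() -> tuple[np.ndarray, np.ndarray]:
    """The canonical inter-domain (C) axis of the toy Fv: (point, direction)."""
    return np.zeros(3), np.array([0.0, 0.0, 1.0])


# ----------------------------------------------------------------------
# Complementary slab interfaces

def make_interface_pair(
    gap: float,
    bumpiness: float = 0.0,
    seed: int = 0,
    n: int = 16,
    spacing: float = 0.5,
) -> Structure:
    """Two pseudo-atom slabs (chains A and B) with complementary facing
    surfaces separated by `gap` Å; surface roughness of amplitude
    `bumpiness` is shared by both slabs so complementarity is preserved."""
    if gap < 0:
        raise ValueError("gap must be non-negative")
    rng = np.random.default_rng(seed)
    radius = 1.70  # carbon vdW
    half = (n - 1) * spacing / 2.0
    st = Structure({"A": "antigen", "B": "heavy"})
    num = 1
    for i in range(n):
        for j in range(n):
            x = i * spacing - half + rng.normal(0, 0.01)
            y = j * spacing - half + rng.normal(0, 0.01)
            h = bumpiness * np.sin(2 * np.pi * x / 4.0) * np.sin(2 * np.pi * y / 4.0)
            st.new_residue("A", num, "SLB", [("C1", "C", (x, y, -radius + h))])
            st.new_residue("B", num, "SLB", [("C1", "C", (x, y, radius + gap + h))])
            num += 1
    return st
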