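# Methods

This note documents the models, algorithms, parameters and numerical
choices behind `paragraft`, and what the synthetic test conditions do and
do not demonstrate about real antibody design.

## Structural model and conventions

Structures are heavy-atom atomic models grouped chain → residue → atom,
read from fixed-column PDB files (first MODEL only) via gemmi.  Alternate
locations resolve to the highest-occupancy conformer (ties keep the first
encountered); hydrogens are ignored on input, so every hydrogen-bond
criterion in the package is heavy-atom based.  Waters and heteroatom
residues are excluded unless requested.

Antibody chains are assumed to arrive **pre-numbered** in a scheme where
the CDRH3 anchor residues are VH93 and VH103 (the convention of curated
Fv libraries; Chothia-style numbering satisfies this).  No sequence-based
renumbering is performed — numbering is treated as a solved upstream
problem.  CDR boundaries ship as an editable table with defaults
H1 26–32, H2 52–56, H3 93–103, L1 24–34, L2 50–56, L3 89–97; the H3 range
is validated to contain the 93–103 anchor window.

## Rigid-body mathematics

Superposition is the Kabsch algorithm in SVD form with determinant sign
correction (proper rotations only), optionally weighted.  Degenerate
point sets (fewer than three points, or second singular value of the
cross-covariance below 1e-9 of the first, i.e. near-collinear) raise an
error rather than returning an arbitrary fit.  Rotation magnitude uses
the trace formula θ = arccos((tr R − 1)/2) with the argument clamped to
[−1, 1]; the axis comes from the rotation vector, with +z reported by
convention for near-identity rotations.  The test suite checks the
superposition RMSD against an independently implemented quaternion
eigendecomposition oracle to 1e-8 on random point sets.

## Hotspot grafting

A donor *triplet* is the ordered 9-vertex set (Cα triangle, N triangle,
C triangle) of three donor residues.  Scaffold CDR triplets are hashed by
the nine within-class pairwise distances, floor-quantized at
`bin_width = 1.0 Å`.  Distance quantization is rigid-invariant by
construction; boundary effects are absorbed by probing all ±1-bin
neighbour keys at lookup (3⁹ probes, done once per donor triplet).  A
Monte-Carlo estimate shows why probing matters: with σ = 0.05 Å
coordinate jitter, the *exact* key survives only ~60% of draws (each of
nine distances has a few-percent chance of straddling a bin edge), while
discoverability under ±1-bin probing is effectively 100%.

Key matches are verified by 9-vertex superposition; candidates are kept
when the fit RMSD is at most `rmsd_threshold = 0.75 Å` (a design choice:
tight enough that the grafted side chains preserve the donor's contact
geometry, and configurable).  The entire
scaffold is carried into the antigen frame by the fitted transform;
the three matched residues keep their scaffold backbone (N, CA, C, O) but
take the donor residues' types and side-chain coordinates rigidly — no χ
refitting, matching the design philosophy of preserving the donor's
interaction pattern exactly.  The clash filter rejects candidates with
any grafted-scaffold *backbone* atom within `clash_cutoff = 2.5 Å` of any
antigen heavy atom (backbone-vs-all-heavy; an all-atom scaffold mode is
available).  Donor/acceptor residue order is matched in sequence order by
default (the motivating hotspots are sequence-ordered); a
best-of-permutations mode sorts distances within class and tries all six
orderings.

Completeness of the hash search is not assumed: the test suite and the
acceptance script compare it against an exhaustive all-triplet
superposition search on toy libraries and require identical accepted
sets.

## CDRH3 loop swapping

Donor loops span VH93–VH103 inclusive (insertion codes allowed); loop
*length* counts the residues strictly between the roots.  Harvesting
skips any scaffold whose 93–103 span has missing integer positions or
incomplete terminal backbones, with the reason logged.

The swap: (1) delete design VH94–VH102; (2) superpose the donor loop's
terminal backbone atoms — N, CA, C, O of its own 93 and 103 (8 points;
a CA/N/C-only mode exists because the carbonyl choice is a genuine
convention ambiguity) — onto the design anchors; (3) delete the anchors;
(4) splice the transformed loop whole, so its 93/103 (donor side chains
included) bond to VH92/VH104.  No closure refinement is attempted — root
conservation is relied upon, and splice quality is *reported* instead:
C(92)–N(93) and C(103)–N(104) bond lengths (flagged outside 1.2–1.5 Å)
and the two ω torsions.

The clash filter checks incoming-loop backbone atoms against all other
heavy atoms of the chimera and antigen at the same 2.5 Å cutoff, with one
necessary carve-out: atom pairs across the two covalent splice junctions
(loop 93 ↔ design 92, loop 103 ↔ design 104) are exempt, since a correct
splice *requires* a 1.33 Å C–N bond and a ~2.2 Å O(92)–N(93) contact
there.  Without the exemption every swap, including re-inserting a
design's own loop, would be rejected.  Self-swap is verified to be a
backbone identity to < 1e-6 Å.

## Interface metrics

**SASA** is Shrake–Rupley with Fibonacci-lattice sphere points
(default 960; probe 1.4 Å) and vdW radii C 1.70 / N 1.55 / O 1.52 /
S 1.80 / P 1.80 Å (1.70 fallback).  Occluders are visited nearest-first
with early exit, which makes dense systems cheap.  Exactly coincident
equal-radius duplicates count their area once.  The implementation is
cross-checked in the tests against Biopython's independent Shrake–Rupley
and against the closed forms for one atom and a two-sphere contact.
Buried SASA is SASA(a) + SASA(b) − SASA(a∪b).

**Hydrogen bonds** are heavy-atom donor–acceptor pairs: donors are
nitrogens and hydroxyl oxygens (OG/OG1/OH), acceptors are oxygens;
criteria are distance in [2.0, 3.5] Å and antecedent–donor–acceptor angle
≥ 120° (the antecedent is the nearest bonded heavy atom in the donor's
residue; the angle test is skipped for isolated pseudo-atoms that have
none).  These thresholds are conventional defaults and configurable.

**Shape complementarity (Sc)** follows the Lawrence–Colman statistic:
dot surfaces (vdW spheres at ~15 points/Å², self-occluded dots removed)
are marked *buried* where a 1.7 Å probe resting on the dot would clash
with the partner; the buried patch is trimmed of a 1.5 Å peripheral band;
each buried dot is paired with the nearest opposing buried dot and scores
(n̂_a · −n̂_b)·exp(−w·d²) with w = 0.5 Å⁻²; Sc is the mean of the two
per-surface medians.  On ideal complementary flat slabs at contact the
implementation yields Sc ≈ 0.98, collapsing to ≈ 0.01 at a 3 Å gap; when
no surface is buried, Sc is undefined and a dedicated error is raised
(reported as NaN and auto-rejected in triage).

**Buried unsatisfied polar atoms**: polar heavy atoms of interface
residues (any residue with a heavy atom within 5.0 Å of the partner)
whose SASA in the complex is below 0.1 Å² and which lack any
hydrogen-bond partner in the whole complex under the criteria above
(sequence-adjacent residues excluded as covalent neighbours).

**Surrogate interface score.**  Physical energy functions are
deliberately out of scope; designs are ranked by the deterministic
geometric score

    score = − w_hb·n_hbonds − w_sasa·buried_SASA
            + w_clash·n_clashes + w_unsat·n_unsat

with defaults w_hb = 1.0, w_sasa = 0.01 Å⁻², w_clash = 10.0 (heavy-atom
overlaps below 2.0 Å), w_unsat = 0.5; lower is better, separated partners
score exactly 0, and the score is rigid-motion invariant.  The weights
set the intended trade-off scale (one hydrogen bond ≈ 100 Å² of buried
surface; any hard clash dominates) and are configurable.  The score
drives alanine scanning (side chains truncated to Cβ, no repacking;
Δscore = mutant − wild-type; hotspots flagged at or above the 0.75
quantile of positive shifts), point-mutation enumeration (all interface
positions × all types except Gly/Pro/Cys, mutant side chains placed from
idealized chemical-component templates aligned on N/CA/C, ranked by
Δscore), and triage (drop Sc < 0.5 at the graft stage, Sc < 0.6 at the
swap stage; keep the top 5 by score).

## VH/VL orientation

Each variable domain carries a reference frame defined by a consensus
coreset of Cα positions with a local origin and two in-plane unit
vectors; registration is by least-squares superposition of the packaged
coreset onto the observed Cα positions (error if > 20% of coreset
positions are missing; warning above 1.0 Å fit RMSD).  With **C** the
vector between the two frame origins: HL = signed torsion from H1 to L1
about **C** (right-handed, **C** pointing VH→VL), HC1/HC2/LC1/LC2 =
bend angles of each plane vector against **C**, dc = |**C**|.

The frame data shipped as the default is **synthetic**: it is generated
from the package's own template domains, so descriptors are exact and
self-consistent for structures built from those templates, and all
orientation behaviour (rigid invariance, pure-rotation HL shifts,
pure-translation dc shifts) is convention-independent and fully tested.
Published consensus coresets for real, scheme-numbered antibodies are not
bundled; users analysing real Fvs supply their own `FrameData` (JSON-easy
dataclass).  Rigid-body deviation between two models superposes them on a
reference selection (default Cα of chosen chains), then reports the COM
distance of the target selections and the angle/axis of the residual
best-fit rotation — the standard COM-drift/rotation characterisation of
domain movement, with the atom selection exposed because conventions for
it vary.

## Synthetic fixtures: what they do and do not show

The generators are deterministic (same seed ⇒ byte-identical files) and
intentionally minimal:

* **Hotspot complex** — full-atom Glu/Thr/Glu placed from idealized
  templates above a pseudo-atom slab, with planted polar partner atoms at
  2.9 Å from the acidic/hydroxyl tips.  Exercises matching, grafting,
  clash filtering and hydrogen-bond counting with known ground truth.
* **Planted scaffolds** — a 21-residue numbered chain whose CDR contains
  the donor triplet geometry up to a random rigid motion plus Gaussian
  jitter, the remainder arcing clear of the antigen.  σ = 0.2 Å is the
  planted-recovery study condition; recovery ≥ 95% over 50 seeds at the
  0.75 Å threshold.
* **Hairpin loops** — stadium-shaped backbones (straight strands joined
  by a semicircular cap, radius = half the anchor mouth) with atoms at
  ideal bond spacings along the path and byte-identical canonical anchor
  geometry across lengths 4–20.  The stadium shape keeps curvature gentle
  so C–N distances stay within ~0.1 Å of 1.33 Å.
* **Toy Fvs** — Cα-trace helix-like domains in a canonical packing
  (dc 16 Å, −60° twist, 10° tilt) with optional extra VL transforms.
* **Slab interfaces** — complementary pseudo-atom slabs (0.5 Å lateral
  spacing) sharing one roughness field, separated by a controlled gap.

Passing on these fixtures demonstrates the *geometric correctness* of
every pipeline stage — search completeness, superposition accuracy,
splice fidelity, metric limits and invariances — under exactly known
ground truth.  It does not demonstrate chemical realism: fixtures are
poly-alanine or pseudo-atom constructions with no rotamer diversity, no
real CDR conformational ensembles and no energetics, so performance on
real scaffold libraries (where triplet geometry is denser and clash
landscapes tighter) must be assessed on real data.

## Problem sizes and numerical notes

Default problem sizes — 10-scaffold libraries, 50-seed recovery sweeps,
16×16-atom slabs, 960 SASA sphere points — were chosen as the smallest
sets that make the statistical checks meaningful; all are parameters.
Ties in altloc occupancy keep the first conformer; residue ordering is
insertion-code aware (… 100, 100A, 100B, 101 …); triage treats undefined
Sc as failing the threshold; mutation enumeration is deterministic given
the input structure, as is every other stage — the only randomness in the
package lives in the fixture generators and is always seeded.
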