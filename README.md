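# paragraft

Computational machinery for epitope-specific antibody design by **hotspot
residue grafting** and **CDRH3 loop swapping**, with the interface triage
metrics and VH/VL orientation analyses used to vet and compare the
resulting models.

## Who this is for

Structural bioinformaticians designing antibodies that must bind a
*pre-selected* epitope — typically the binding site of a natural partner
protein (the motivating system is the Keap1 Kelch domain, whose Nrf2 ETGE
hairpin contributes three energetic hotspot residues, Glu79/Thr80/Glu82).
The idea: transplant those hotspot side chains onto geometrically
compatible positions in the CDR loops of existing antibody Fv scaffolds,
so the designed antibody occupies the partner's site and blocks the
interaction.

## What it does

1. **Hotspot grafting by triplet hashing** (`paragraft.grafting`).
   Three donor residues define a *triplet*: the three virtual triangles
   through their backbone Cα, N and C atoms (nine vertices).  Every
   3-combination of CDR residues in every library scaffold is indexed by a
   rigid-invariant key — the nine within-class pairwise distances
   (Cα–Cα ×3, N–N ×3, C–C ×3) quantized into 1.0 Å bins, with ±1-bin
   probing at lookup.  Key matches are confirmed by nine-vertex
   least-squares (Kabsch) superposition; candidates with fit RMSD ≤ 0.75 Å
   are carried into the antigen frame, the matched residues' side chains
   are replaced by the hotspot residues, and any design whose backbone
   comes within 2.5 Å of the antigen is discarded.

2. **CDRH3 loop swapping** (`paragraft.loopswap`).  The loop root
   residues VH93/VH103 have conserved backbone geometry across Fabs, so a
   donor loop (VH93–VH103, harvested from any numbered scaffold library)
   can be spliced into a design by superposing only its terminal backbone
   atoms (N, CA, C, O of both roots) on the design anchors, deleting the
   anchors and ligating to VH92/VH104.  Splice quality is reported as
   junction C–N bond lengths and ω torsions.

3. **Interface triage** (`paragraft.interface`).  Shrake–Rupley SASA and
   buried SASA, geometric hydrogen bonds, Lawrence–Colman shape
   complementarity Sc, buried unsatisfied polar atoms, and a deterministic
   surrogate interface score (lower = better) that stands in for a
   physical binding energy.  Stage filters reject Sc < 0.5 after grafting
   and Sc < 0.6 after loop swap; the top five point mutations per design
   are kept for combination.  Alanine scanning and exhaustive single-point
   mutation enumeration (all types except Gly/Pro/Cys) rank positions by
   the surrogate ΔΔG analogue.

4. **Fv orientation analysis** (`paragraft.orientation`).  The six
   ABangle-style VH/VL descriptors — HL torsion, HC1/HC2/LC1/LC2 bends
   and the inter-domain distance dc — from consensus-frame registration,
   plus rigid-body deviation reports (COM drift + rotation angle/axis)
   for crystal-vs-model comparison.

5. **Synthetic fixtures** (`paragraft.synthfix`).  Deterministic toy
   structures exercising every stage with no downloads: scaffolds with
   planted hotspot-compatible triplets, idealized hairpin CDRH3 loops with
   shared canonical anchors, two-domain Fvs with known orientation, and
   complementary slab interfaces with tunable gap.

## Worked example

```bash
paragraft fixtures fx --seed 1            # write a synthetic fixture set
paragraft graft fx/hotspot_complex.pdb fx/scaffolds.tsv --outdir graft_out
cat graft_out/graft_report.tsv
```

```
scaffold     matched_residues  rmsd    clashes  accepted  sc     buried_sasa  n_hbonds  n_unsat  surrogate_score  triaged
scaffold000  H27+H28+H30       0.2552  0        True      0.779  291.2        5         0        -7.912           True
```

One scaffold in the ten-member library carries a planted copy of the
donor triplet (jittered by σ = 0.2 Å); the search finds exactly that
triplet at residues H27/H28/H30 with a nine-vertex fit of 0.26 Å, grafts
the Glu/Thr/Glu side chains without antigen clashes, and the design
passes triage: Sc 0.78 (above the 0.5 graft-stage floor), 291 Å² buried,
five hydrogen bonds to the planted partner atoms, no buried unsatisfied
polars, surrogate score −7.9.

```bash
paragraft swap fx/design.pdb fx/loops.tsv --outdir swap_out --roles "H::"
paragraft orient fx/toy_fv.pdb --roles "H:L:"
```

The swap report lists one row per donor loop with anchor-fit RMSD,
junction bond lengths (1.33 Å for the idealized fixtures) and the clash
verdict; the orientation report gives the six descriptor columns.

## Limitations

The surrogate score is a geometric stand-in, not an energy function; no
side-chain repacking or backbone refinement is performed anywhere.  The
default orientation frames are synthetic (matched to the packaged
template domains); analysing real Fvs requires supplying a `FrameData`
for the numbering scheme in use.  See `docs/methods.md` for the full
model description, parameter table and design rationale.
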