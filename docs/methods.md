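# Methods

This note documents the models, parameter choices, and numerical
conventions behind `ensdock`, and what the synthetic fixtures do and do not
establish.

## Elastic network models

GNM and ANM are built at Cα resolution from a `CAModel`. Cutoffs default to
10 Å (GNM) and 15 Å (ANM) with spring constant γ = 1 — the conventional
choices for Cα elastic networks; both are configurable. Eigenvalues below
`1e-8 · λ_max` are treated as rigid-body modes and removed; the relative
tolerance keeps the criterion scale-free. Fluctuation profiles
(`rmsf`) are reported in arbitrary units of kT/γ, as is standard for ENMs;
only ratios and shapes are meaningful.

The covariance overlap of two mode sets follows the Hess measure

    Ω = 1 − √[(Σσ_A + Σσ_B − 2 Σ_{ij} √(σ_{Ai} σ_{Bj}) (u_{Ai}·u_{Bj})²) / (Σσ_A + Σσ_B)]

with σ = 1/λ, and the dynamics distance is arccos(Ω) ∈ [0, π/2]. Because
arccos(1 − ε) ≈ √(2ε), machine-precision noise in Ω near 1 appears as
distances of order 1e-4; exact-zero assertions on dynamics distances are
therefore made at 1e-3 absolute.

## Implicit membrane scaling

The membrane slab is a half-width `z0` (default 15.35 Å, an OPM-style
boundary for an MFS fold) around z = 0; orientation of the input structure
along the membrane normal is the caller's contract. For every spring whose
endpoints both lie in the slab, the 3×3 inter-node block is rebuilt as
−(γ/r²)(Dd)(Dd)ᵀ with D = diag(√s, √s, 1) and s = 16 by default: in-plane
force components are stiffened 16-fold, the normal component is untouched,
each block stays symmetric positive semidefinite, and diagonal blocks are
rebuilt as negative row sums so translational invariance (three zero modes)
is preserved exactly. An alternative — node-wise diagonal restraints — was
rejected because it destroys the row-sum structure of the Hessian. The two
readings differ in spectra but both suppress radial motion; the per-contact
choice is verified by the strict decrease of the mean in-plane/normal RMSF
ratio on the helical-bundle fixture.

## Secondary structure and rigid blocks

Hydrogen bonds use the Kabsch–Sander electrostatic energy
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the −0.5
kcal/mol threshold. Amide hydrogens, when absent from the input, are placed
1.0 Å from N along the bisector of the C(i−1)→N and CA→N directions. Two
consecutive i→i+4 turns define a minimal helix (residues i..i+3 marked H);
Kabsch–Sander parallel/antiparallel bridge patterns mark strands; helix
wins on overlap; everything else is coil. A classic DSSP output file can be
supplied instead, in which case classes are copied verbatim (G/H/I → H,
E/B → E, else C).

Rigid blocks are one block per maximal contiguous helix or strand element
and one single-residue block per coil residue. This is one deterministic
reading of an SSE-based decomposition; published block counts for real
structures (e.g. 135 blocks for a fucose-transporter template) depend on
unstated merge details (3₁₀/π treatment, short strands) and are not
guaranteed to be reproduced exactly. The RTB basis per block is the
rank-revealed QR orthonormalization of 3 translations and 3 rotations about
the block centroid, so degenerate blocks (1 residue → 3 dof, 2 collinear
residues → 5 dof) are handled without special cases.

## Conformer sampling and selection

Coefficients (a₁, a₂) for the two softest modes are drawn uniformly on a
disc whose radius is calibrated so the maximum displacement RMSD equals
`max_rmsd` (for orthonormal per-coordinate modes, RMSD = |a|/√n). The
uniform disc is a choice: the protocol statement fixes only "along the two
lowest-frequency modes", and the disc gives an isotropic, bounded, seeded
exploration. A zero amplitude is allowed and reproduces the reference
exactly (the error contract rejects only negative amplitudes).

Diversity selection is a deterministic reading of "keep conformations at a
cutoff distance of 3 Å from the average": conformers are visited in order
of |RMSD-to-average − 3 Å|, skipping any within 0.5 Å pairwise RMSD of an
already-selected conformer, stopping at the target count (default 20).
Selection is idempotent as a set; the internal ordering may change on
reapplication because the ensemble average is recomputed.

Model quality uses the clashscore component only: significant non-bonded
vdW overlaps (> 0.4 Å, strict) per 1000 atoms, excluding 1-2/1-3 bonded
pairs (bond graph inferred from covalent radii + 0.45 Å) and plausible
N/O/F/S donor–acceptor pairs at 2.4–3.5 Å. Full MolProbity scoring
(rotamers, Ramachandran) needs all-atom chemistry outside this package's
scope; the ranking contract (ascending score, lexicographic tie-break,
top-3 per conformer) is unchanged. Energy minimization is a process hook
(`{input}`/`{output}` command template) that passes coordinates through
unchanged when no backend is configured.

## Enrichment screening

Activity classes: active ≤ active-threshold (1 μM default; 5 μM profile for
data-poor targets), inactive > 10 μM, in-between excluded from scoring.
Decoy augmentation targets a 1:36 active:nonactive ratio:
n_decoys = max(0, 36·n_actives − n_inactives), sampled without replacement.
(Published library sizes for one OATP target — 57 actives, 917 inactives,
1223 decoys — exceed this formula's 1135, plausibly from protomer
multiplicity; the formula is the contract here.)

AUC is the rank-based estimator with midrank ties, equal to the
win-plus-half-tie pair probability; orientation defaults to
lower-score-is-better (docking convention). EF at fraction f uses
⌈f·N⌉ top compounds with deterministic tie resolution by input order.
Model ranking is AUC-descending with near-ties (ΔAUC < 0.01) broken by
EF1%, then model id.

The mock docking backend scores
`‖centroid − site‖ + dist(centroid, box) + N(0, 0.25²)`, where the
compound's latent pharmacophore centroid is planted by the library
generator (actives at the binding site, σ = 0.5 Å; others scattered in a
±20 Å cube) and the noise is keyed deterministically on (seed, model,
compound). A model without a coherent site ("scrambled") returns pure
seeded noise — its AUC is individually a draw around 0.5 with binomial
spread (≈ 0.085 std for a 12-active/432-nonactive library), so chance-level
behavior is asserted on the scrambled-group mean (±0.1), not per model.
The round-two box (1 Å voxelization of active poses dilated by vdW + 2 Å
padding) contains the planted site, leaves active scores unchanged, and can
only penalize scattered nonactives; restriction therefore never lowers a
planted-site model's AUC.

The external-engine adapter (`VinaCommandBackend`) carries the screening
configuration — exhaustiveness 10 for library screening, 20 with 10 binding
modes for focused steroid docking — and parses the engine's score table; no
test requires it.

## Pose analysis

Cores are mapped with the sterane-type tetracyclic SMARTS (ring bonds
flexible, C18 angular methyl included). Note that Murcko reduction strips
that exocyclic methyl, so the core pattern is matched on the parent
molecule (the scaffold operation remains available separately). Cluster
distance is RMSD over mapped core atoms **without** re-superposition: poses
share the receptor frame and the binding-site location is exactly the
signal the clustering must resolve. Average linkage with a 2 Å flat cut;
cluster order is deterministic (by first pose id).

PLIF criteria are geometric stand-ins for a proprietary energy-based
scheme: H-bond ≤ 3.5 Å donor–acceptor with D–H···A ≥ 120° whenever the
donor hydrogen position is known (distance-only otherwise — relevant for
hydrogen-free receptor models); ionic ≤ 4.0 Å between opposite formal
charges (receptor charges from Asp/Glu/Lys/Arg side-chain templates);
arene ≤ 4.5 Å between aromatic ring centroids; metal ≤ 2.8 Å. Bits are
named from the residue's perspective. Interaction frequencies over a pose
set flag "key residues" at ≥ 10%.

Halogen-bond geometry is plausible at 2.5–6.0 Å and 120–180° (C–X···A
angle). Pocket volume counts 1 Å grid points inside the site sphere,
outside all vdW spheres, and contiguous with the site center (seeded flood
fill, POVME-style); seeding at the center rather than at bulk solvent is
deliberate so enclosed cavities — the interesting case for an occluded
transporter pocket — are measured rather than reported as zero.

## Synthetic fixtures: what a green test establishes

The helical bundle is an ideal-geometry backbone (φ = −57°, ψ = −47°, NeRF
construction, 0.05 Å seeded jitter) of 12 antiparallel helices on an 18 Å
ring — the topology, size, and membrane span of an MFS fold, but with
poly-alanine chemistry, no loops, no side chains, and no pore asymmetry.
Green ENM/membrane tests therefore establish correctness of the operators,
not biological realism of the motions. The compound library enumerates
steroid-template SMILES with A-ring/2,4-halogen/D-ring variants (protomer
siblings share a parent id) plus simple aromatic/aliphatic decoys;
activities are drawn inside the class bands, so classifier self-consistency
is by construction. The mock screen validates the *bookkeeping and
statistics* of enrichment docking — not any real scoring function. The pose
field plants one rigid core orientation per site with Gaussian jitter;
recovery at the 2 Å cutoff checks the clustering contract, not docking
accuracy.

## Known limitations

- No mmCIF input; membrane orientation is the caller's responsibility
  (no OPM-style prediction).
- Secondary-structure assignment implements the hydrogen-bond core of DSSP
  (H/E/C); 3₁₀/π helices fold into H, bends/turns into C.
- Clashscore approximates MolProbity's steric component on heavy atoms;
  absolute values on hydrogen-free ideal backbones are inflated by 1-4
  backbone contacts and are meaningful for ranking, not comparison with
  published clashscores.
- The mock backend's AUC values are not comparable to enrichment numbers
  obtained with a physical docking engine on curated libraries.
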