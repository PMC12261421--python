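# Methods

## Problem and approach

Predicting the folding free-energy change upon a point mutation,
ΔΔG = ΔG(mutant) − ΔG(wild type) in kcal/mol (positive = destabilizing), from
a wild-type structure and a pre-modeled mutant structure. The predictor is a
3D convolutional network over voxelized atomic neighborhoods of the mutation
site. Plain 3D CNNs are not SE(3)-invariant — rotating the input protein
changes the prediction, sometimes even its sign — so the pipeline first
transforms every structure into a canonical frame anchored on the mutated
residue's backbone. After that transform, any rigid motion of the input
yields bit-identical voxel grids, and therefore identical predictions.

## Orientation standardization

For mutated residue k with sequential predecessor k−1 in the same chain:

* **x** = unit vector from C(k−1) to N(k);
* **y** = the component of N(k)→Cα(k) orthogonal to **x** (so Cα(k) ends up in
  the half-plane y > 0, z ≈ 0);
* **z** = **x** × **y** (right-handed, so chirality is preserved — a mirror
  image does *not* standardize to the same coordinates);
* origin = N(k).

N(k) is the only point shared by all three defining elements, which is why it
serves as the translation origin; the voxel grid is separately centered at
the Cβ atom, so this choice only fixes a convention, not grid content. A
chain-start mutation has no frame; such records are recorded as
featurization failures and excluded. Near-degenerate geometry (N→Cα within
1e-6 rad of the x axis) errors out rather than picking an arbitrary y.

## Voxel featurization

Both structures are standardized with the **wild-type** frame and both grids
are centered at the **wild-type** Cβ (a virtual Cβ, built tetrahedrally at
1.521 Å from Cα with L-chirality, for glycine), so WT and MT grids are
spatially aligned voxel-for-voxel. Grids are 16×16×16 voxels at 1.0 Å
spacing (a 16 Å cube) with seven channels: hydrophobicity, H-bond acceptor,
H-bond donor, aromaticity, positive ionizability, negative ionizability, and
occupancy. A voxel's channel value is the maximum over that channel's atoms
of a smooth van-der-Waals occupancy

    n(d) = 1 − exp(−(r_vdw / d)^12),  n(0) := 1,

with per-element radii C 1.70, N 1.55, O 1.52, S 1.80 Å. Atom typing is a
frozen explicit rule table over the 20 standard residues (no run-time bond
perception): hydrophobic = carbons not bonded to N/O; aromatic = ring atoms
of PHE/TYR/TRP/HIS; positive ionizable = LYS NZ, ARG NE/NH1/NH2/CZ, HIS ring
N; negative ionizable = ASP/GLU carboxylate O; donors/acceptors by standard
protonation. Heavy atoms only contribute; hydrogen's donor information is
already encoded in the table. The WT/MT pair is stacked channel-wise as
[WT, MT], [WT, WT−MT] (the default) or [WT−MT]; difference blocks are raw
subtractions in [−1, 1] with no rescaling.

## Architectures

Two regression networks take the (16, 16, 16, C) tensor (channel-first
internally):

* **orgnet** (2 871 457 parameters at C=14): conv 16ch (k=3, p=1) → ReLU →
  maxpool (k=3, p=1, s=2); conv 80ch and conv 400ch blocks, same pattern;
  conv 512ch (k=2, valid) → ReLU; dense 512 → GELU → dense 128 → GELU →
  scalar. The convolutions carry **no bias terms**: with conv biases the same
  stack would have 2 872 465 parameters; dropping the 16+80+400+512 = 1008
  biases gives exactly the stated count. Spatial trace 16³→8³→4³→2³→1³.
* **thermonet_like** (133 273 parameters): three valid convolutions
  (16, 24, 32 ch, k=3, biased) with ReLU, one maxpool (k=2, s=2), dense 24 →
  ReLU → scalar. Spatial trace 16→14→12→10→5.

No dropout or normalization layers. Initialization is a fan-in uniform
scheme, U(±1/√fan_in), with a recorded seed. In classification mode
(stabilizing, ΔΔG < 0, is the positive class) the scalar passes through a
logistic; ΔΔG = 0 records are excluded from classification training.

The layers are implemented directly in numpy: convolution as an im2col
matrix product, the input gradient of a stride-1 convolution as a full-padded
flipped-kernel convolution, max-pool backward by scatter-add over argmax
indices, exact erf-based GELU, and Adam with the standard (0.9, 0.999)
moments. Backward passes are verified against central finite differences in
the test suite. Everything is deterministic given the seeds, so training is
bit-reproducible single-threaded.

## Training protocol

Adam at lr 0.001, batch size 8, up to 100 epochs, MSE loss (binary
cross-entropy for classification). Reduce-on-plateau: ×0.5 after 10 epochs
without validation improvement ("improvement" = any decrease), cooldown 5
epochs (bad epochs during cooldown do not count), floor 1e-6; the variant
schedule (×0.9, patience 5, no cooldown) is available through the same
config. Early stopping with patience 15; the best-validation-loss weights
are restored. Cross-validation is homology-aware: proteins with pairwise
identity above 25% (strict) are merged by connected components and clusters
are assigned whole to folds (seeded shuffle, round-robin). The ensemble is
one best model per fold with averaged predictions. Reverse augmentation adds,
for each A→B record with label ΔΔG, the formal B→A record with swapped grid
roles and label −ΔΔG; direct/reverse pairs always share a fold.

## Orientation-bias diagnostic

The bias scan rotates the WT/MT pair rigidly (same matrix, about the WT
centroid) into 120 fixed orientations — 10 icosahedron-vertex axes × 12
angles in π/6 steps — runs the full pipeline on each, and reports the
prediction spread and sign consistency (zero counts as positive). An
icosahedron has 12 vertices in 6 antipodal pairs, so "10 axes" cannot be 10
independent vertex directions; this package takes the 10 non-polar vertices
(the two pentagonal rings) of an icosahedron with a vertex at each pole.
Those 10 vertices themselves form 5 antipodal pairs, so with the full angle
set some of the 120 orientations coincide pairwise; the count and the
diagnostic are unaffected. With standardization enabled the spread is bounded
by numerical noise (< 1e-4 kcal/mol for *any* fixed model — the invariance
is a property of the featurization, not the weights); with the ablation flag
(`orient=False`) it is strictly positive.

For augmentation, axes come from a deterministic Fibonacci sphere lattice
(default grid of 100 axes) crossed with 72 angles {0, π/36, …, 2π − π/36};
(axis, angle) pairs are drawn uniformly with a seed, 10 per structure, and
applied about the all-atom centroid.

## Evaluation statistics

Pearson r, RMSE, MAE, MSE (r reported as NaN with a flag when either vector
is constant). The paired predictor comparison assigns "head" when
|y − a| < |y − b| strictly, discards exact ties, and tests the head count
against Bin(n, ½) with an exact two-sided p-value (double the smaller tail,
capped at 1; empty effective set gives p = 1). The test is verified against
exhaustive fair-coin enumeration for all n ≤ 12. Classification reports
confusion counts, precision/recall/F1 and accuracy at a threshold, with a
sweep helper.

## Synthetic data

Real benchmark corpora require externally modeled mutant structures, so the
test bed is generated: ideal-geometry peptides (N–Cα 1.458, Cα–C 1.525,
C–N 1.329, C=O 1.231 Å; trans peptide bonds; φ/ψ from helix/sheet/polyproline
baskets with ±8° jitter) built by internal-coordinate chaining, with Cβ
placed at the symmetric 110.5° geometry (improper N–C–Cα–Cβ = +123.1°,
matching CCD ideal L-residues) and one representative property-bearing stub
atom per residue type beyond Cβ — enough to exercise every channel without a
rotamer library. Default datasets are 50 mutations on 7-residue peptides,
mutation mid-chain so every record is featurizable.

Labels are coupled to structure by construction: label = w·s + ε with s the
signed sum of the WT−MT difference grid, w = 0.04 (putting labels at a
realistic ΔΔG spread of sd ≈ 1.6 kcal/mol), and ε ~ N(0, 0.1 kcal/mol)
seeded. The synthetic identity matrix groups peptides into clusters of ~3
with within-cluster identities 30–60% over a 5–15% background.

What passing on this bed shows: the geometry, invariance, bookkeeping and
optimization machinery are correct, and the network can extract a signal
that is a known function of its input. What it does not show: predictive
accuracy on real mutations — synthetic labels are far easier than
thermodynamic measurements, peptide stubs are not packed side chains, and
mutant structures here are idealized rather than physically relaxed.

## Problem sizes and numerical choices

The shipped learnability runs train the compact 133k-parameter architecture
on the 50-record (100 items after reverse augmentation) synthetic set for 30
epochs, which reaches a training MSE two orders of magnitude below the label
variance; the deep architecture trains with the identical code path.
Invariance checks use 100 random rigid transforms (rotations uniform on
SO(3), translations ~N(0, 10 Å)). Tolerances: orthonormality and rigidity
1e-9/1e-12; end-to-end invariance 1e-6 Å on coordinates and grid values;
bias-scan spread 1e-4 kcal/mol. PDB round-trips are exact to the format's
3-decimal precision. Alternate locations keep the highest-occupancy
conformer; insertion codes are rejected; HETATM and waters are skipped.

## Known limitations

* Mutant-structure modeling (Rosetta-style) and conformational sampling are
  out of scope; mutant structures are inputs.
* The atom-typing table is an explicit approximation of pharmacophore typing
  at standard protonation; no pH or tautomer handling.
* Which 10 icosahedron vertices the bias scan should use is conventionally
  fixed here (non-polar vertices); other choices change the orientation set
  but not the diagnostic's conclusion.
* Flexible deformations (distinct conformers of the same protein) are not
  addressed by orientation standardization and will still produce different
  predictions.
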