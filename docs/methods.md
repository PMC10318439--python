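# Methods

## Problem and representation

Given a protein structure (one chain) and the carbohydrates resolved with
it, the task is binary per-residue classification: does the residue contact
a carbohydrate? The contact definition is geometric — a residue is positive
when any of its heavy atoms lies within 4.2 Å (inclusive) of any
carbohydrate heavy atom. Each residue is represented by a single spatial
anchor, its Cβ atom (Cα for glycine), because the Cβ position changes
little between unbound and ligand-bound states; side-chain conformational
changes on binding therefore do not perturb the input.

Per-residue features (fixed, versioned column order):

| block | size | default |
|---|---|---|
| amino-acid one-hot | 20 | order `ACDEFGHIKLMNPQRSTVWY` |
| SASA | 1 | Shrake–Rupley, probe 1.4 Å, 960 points/atom, normalized |
| hydrophobicity | 1 | Kyte–Doolittle, min-max scaled to [0, 1] |
| aromaphilicity | 1 | package table (below), [0, 1] |
| H-bond donor / acceptor | 2 | side-chain chemistry sets |
| orientation (voxel only) | 3 | unit Cα→Cβ vector; zero for glycine |
| torsion (graph only) | 4 | (sin φ, cos φ, sin ψ, cos ψ); zeros if undefined |

SASA is computed on the protein alone ("unbound": carbohydrates excluded)
with an in-package Shrake–Rupley implementation (KD-tree neighbor pruning;
golden-spiral sphere sampling). Raw areas are normalized by Tien-style
per-amino-acid theoretical maxima and clipped to [0, 1] so the feature
shares the scale of the other indices; raw Å² mode is available
(`compute_sasa(..., normalized=False)`). Because the sample directions are
fixed in the lab frame, SASA is rotation-invariant only up to quadrature
error (< 1–2% at 960 points); every other feature is exactly invariant.

The hydrophobicity, aromaphilicity and donor/acceptor tables are
configurable (`PropertyScales`, YAML-loadable). The aromaphilicity default
ranks side chains by their propensity to engage aromatic groups (W > Y > F
> H, then cation-π-capable R/K and sulfur-π M/C, then aliphatics); it is a
package default, documented as such, not a reproduction of any published
numeric table. Donors default to {R,K,W,N,Q,H,S,T,Y,C}, acceptors to
{D,E,N,Q,H,S,T,Y}.

Dihedrals come from the standard four-atom torsion; φ is undefined at the
first residue, ψ at the last, and both across chain breaks (detected by a
2 Å peptide-bond distance check). Undefined angles encode as sin = cos = 0
rather than dropping termini.

Non-canonical residues with a common parent (MSE→MET etc.) are remapped at
parse time; others are skipped with a warning, preserving the 20-letter
feature space. Altloc conflicts keep the highest occupancy, ties broken
alphabetically. Carbohydrate components are classified by a bundled
het-code lookup covering 16 monomer classes (Glc, GlcNAc, GlcA, Fuc, Man,
ManNAc, Gal, GalNAc, GalA, Neu/Sia, Ara, Xyl, Rib, Rha, Abe, Fru); unknown
sugar-like codes (per gemmi's component dictionary) map to "other", and
water/ions/amino acids are excluded. The lookup is implementer-compiled
from the PDB chemical component dictionary and configurable.

## Voxel pipeline

The Cβ centroid is placed at the center of a 72 Å box divided into 36³
voxels of 2 Å; residue→voxel assignment is `floor((cb − origin) / 2)` with
half-open cells. Voxels without a Cβ hold zero vectors. Two residues in
one voxel (possible at 2 Å resolution) have their features averaged and
labels OR-ed — order-independent and conservative for recall. Proteins
exceeding the box are rotated into their principal frame and partitioned
into non-overlapping 72 Å windows; each occupied window becomes one grid,
so every residue appears in exactly one grid (the orientation feature is
co-rotated). Predictions map back to residues through the stored
residue↔voxel map; co-resident residues share their voxel's probability.

Training-time augmentation rotates each structure freshly every epoch by
an angle uniform on [−180°, 180°] about the axis through a uniformly
chosen residue's Cβ and the protein center of mass (all-heavy-atom
centroid, unweighted); protein and carbohydrate coordinates co-rotate.
A degenerate axis (anchor at the centroid) is resampled.

## Graph pipeline

Nodes are residues; edges connect Cβ pairs with 0 < d ≤ 12 Å (inclusive
boundary — the cutoff convention is documented and tested). Edges are
stored once and expanded to both directions at message-passing time; the
edge attribute is the distance.

## Architectures

Both networks are implemented on numpy with reverse-mode automatic
differentiation (`autograd`); parameters are flat name→array dicts.
Convolutions are computed as sums of shifted GEMMs, transposed convolutions
(kernel = stride, non-overlapping) as einsum + reshape, so the whole
forward pass is traceable for training.

**Voxel UNet** (102,676,001 trainable parameters). An initial 5³
convolution with bias embeds 28→32 channels; all remaining double-conv
convolutions are bias-free because batch normalization follows
immediately. Four encoder blocks (double convolution = 2 × [5³ conv,
stride 1, pad 2 → batch norm → ReLU], then max pooling by 2,2,3,3) walk
32→64→128→256 channels over grids 36→18→9→3→1; a 512-channel double-conv
bottleneck sits at 1³; four decoder blocks upsample with transposed
convolutions (kernel = stride = 3,3,2,2, with bias), concatenate the
equal-size encoder output, and apply a double convolution
(512→256, 256→128, 128→64, 64→32); a final 5³ convolution (with bias)
condenses 32→1, followed by a sigmoid. Two points in the prose description
of this architecture family are ambiguous and were resolved so that the
construction reproduces the published parameter total exactly, which acts
as a checksum on the wiring: (a) decoder blocks upsample *before*
concatenating the skip (the standard UNet order; the alternative
concat-first order has no consistent partner at the bottleneck); (b) bias
placement as described above — biases everywhere (+2,912) or nowhere
(−513) both miss the printed total.

**EGNN** (236,009 trainable parameters). A linear layer lifts 29→64.
Eight EGCLs follow; per layer: edge MLP `Linear(130→64)–ReLU–Linear(64→64)–
ReLU` on (h_i, h_j, squared distance, distance); attention gate
`Linear(64→1)–sigmoid` multiplying the message; sum aggregation over
incoming edges; node MLP `Linear(128→64)–ReLU–Linear(64→64)` with residual
connection; coordinate MLP `Linear(64→64)–ReLU–Linear(64→1, no bias)`
scaling (x_i − x_j), averaged over incident edges (mean normalization
avoids magnitude blow-up). The scalar head adds a 64→1 projection of the
final embedding and a 29→1 projection of the raw input features (the input
residual), applies batch normalization over the resulting one-dimensional
logit, and a sigmoid. The head is the least-determined part of the
published description: the literal reading (project 64→29, add the input
features, BatchNorm(29), then reduce to a scalar) totals 237,885
parameters; the logit-space residual head implemented here is the unique
variant of the standard EGCL family that reproduces the printed 236,009
exactly, and the literal wiring remains selectable
(`EGNNConfig(head_style="feature_residual")`) so the choice can be
revisited against the count. Distances entering the edge MLP are scaled by
the 12 Å cutoff, and residual-branch output layers are initialized at 0.1×
Glorot scale: both are conditioning choices that keep an untrained
8-layer sum-aggregating network's logits O(1) (otherwise the sigmoid
saturates and invariance checks lose all resolution); neither changes the
parameter count or the functional family.

Node probabilities depend on coordinates only through pairwise distances,
so they are invariant under rigid transforms by construction (verified to
relative 1e-5 under 20 random transforms); updated coordinates are
equivariant. The UNet's conv/pool/upsample stack is translation-covariant
for shifts that are multiples of its cumulative pooling stride; this is
tested on a two-level configuration (stride 2), since the full
architecture pools to a global 1³ bottleneck whose receptive field spans
the entire grid, leaving no nontrivial shift that all pooling levels
preserve.

## Training

Loss: soft Dice complement `L = 1 − (2Σp·y + ε)/(Σp + Σy + ε)` on sigmoid
probabilities, ε = 1e-6 (differentiability; also defines the empty-empty
limit). Batch loss is the mean of per-item losses (per-structure balance).
Optimizer: Adam; default learning rate 1e-4, 1,000 epochs, batch = one
structure (graph) or 20 grids (voxel), matching the published recipe; all
randomness flows from one seeded generator, so a fixed seed reproduces a
run bit-for-bit. SASA is cached per structure across epochs (it is
rigid-invariant, so augmentation rotations do not change it). Non-finite
loss aborts with a diagnostic. The best checkpoint is selected by
validation Dice (binarized at 0.5); batch-norm running statistics
(momentum 0.1) make single-structure inference deterministic in eval mode.

Desk-scale training sizes used by the test suite: the overfitting check
trains the graph model on three ~40–50-residue synthetic structures for
200 epochs at learning rate 1e-3 (a deliberate memorization setting —
the task is to reproduce known labels, not to generalize), reaching
thresholded training Dice ≥ 0.9 on the majority of seeds in a few minutes
on one CPU. Voxel-model training tests use a narrow-channel configuration
(2–32 channels) of the same code path.

## Evaluation

Per structure: confusion counts at threshold 0.5 (inclusive) give Dice,
PPV, sensitivity and MCC; positive residues are clustered into
"independent sites" by single linkage on Cβ distances at 8 Å (the
published analyses never define the site notion operationally; 8 Å splits
spatially distinct patches while tolerating pocket curvature, and the
cutoff is configurable, including a degenerate all-one-site mode). DCC is
the distance from each predicted site center (mean member Cβ) to the
nearest true site center. Aggregation is macro (per structure, then mean);
coverage is the fraction of structures with any predicted positive; DCC
averages only over covered structures; success rates are the fraction of
structures with Dice > 0.6 and with best DCC < 4 Å. Degenerate
conventions: Dice = 1 when TP = FP = FN = 0 (flagged `vacuous`), MCC = 0
on zero denominator, PPV/sensitivity = 0 on 0/0.

## Synthetic structures

The generator builds ideal backbones from per-geometry (φ, ψ) — helix
(−57°, −47°), extended (−139°, 135°), or random coil sampled from
Ramachandran basins — with standard bond lengths/angles and trans peptide
bonds, random 20-letter sequences, and ideal tetrahedral pseudo-Cβ atoms.
Sites are planted as six-atom rings (~1.5 Å spacing, pyranose-sized;
chemically generic, since labeling depends only on heavy-atom geometry),
one ring per target residue, placed so that each target has a contact
within 4.2 − margin Å (margin 0.5 Å by default, contact distances kept
above 3.05 Å) and every non-target residue stays beyond 4.2 + margin Å.
Multi-site fixtures keep sites > 20 Å apart. Every fixture is certified by
the production labeler — a structure is only emitted when `label_contacts`
recovers the planted set exactly — so the generator can never silently
disagree with the labeling rule it is meant to exercise. Default dataset
imbalance targets ~5% positive residues, the frequency seen in curated
carbohydrate-bound structures.

What the fixtures do not emulate: real side-chain packing and rotamers,
sugar stereochemistry, crystallographic noise, binding-pocket concavity,
and any sequence–structure correlation. Passing tests therefore certify
the machinery (parsing, features, encodings, training dynamics, metrics) —
not real-data predictive accuracy, which would require the curated
structure corpus and full-length training.

## Numerical choices and limitations

- Probabilities use a tanh-based sigmoid (overflow-safe); batch-norm
  ε = 1e-5.
- Voxel collision policy (average/OR) and the 72 Å window splitting are
  choices where the architecture description is silent; both are
  configurable and tested.
- The EGNN aggregation matrices are dense (n_nodes × n_edges); fine for
  chains up to a few hundred residues, wasteful beyond.
- A full-size voxel UNet forward pass takes seconds on one CPU in this
  numpy implementation; full-scale 1,000-epoch training is out of its
  intended range (the training loop is exercised at reduced width).
- PDB output writes backbone + Cβ atoms natively; exotic side-chain atoms
  round-trip as generic carbons (coordinates preserved, names not).
- mmCIF, multi-chain complexes and covalent glycosylation detection are
  out of scope.
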