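# Methods

## Scope and design

`glycosite` predicts, per protein residue, the probability of membership in
a protein–carbohydrate and a protein–cyclodextrin binding interface. It
contains the full pipeline around that predictor: structure reading and
cleaning, vocabulary-driven subunit typing, contact labeling, identity-
limited dataset splitting, training, and a complete evaluation battery.
The published pretrained weights and the PDB-scale datasets behind the
published test-set scores are deliberately out of scope: everything here
trains and validates at desk scale on generated fixtures, and the tests
demonstrate the *contracts* of the method (equivariance, labeling
correctness, learnability, metric identities), not transferability to real
complexes.

## Structure processing

Files are read with gemmi (PDB and mmCIF). All models of a multi-model
file are merged into one entity; chains of models beyond the first get a
`#<k>` suffix to keep residue keys unique. Waters (`HOH`, `DOD`, `WAT`)
and hydrogen/deuterium atoms are removed. Alternate locations keep the
highest-occupancy conformer (the format is silent on this; it is the
common convention). Every discrete non-polymer molecule is renamed to
`<chain>:<index>` so each becomes its own subunit; two non-polymer
residues belong to the same molecule when their minimum heavy-atom
distance is below 1.8 Å, a light-weight covalent-link criterion that
groups glycosidically linked sugar rings (e.g. a xylotriose) into one
subunit without full bond perception. Preprocessing is idempotent.

Subunit classes are assigned from a user-overridable vocabulary of
chemical-component codes. Cyclodextrin codes (default `ACX`, `BCD`) take
priority over plain carbohydrate codes and are always also members of the
carbohydrate set — a cyclodextrin *is* a glucopyranose oligomer, labelled
distinctly. The shipped carbohydrate list covers the common PDB sugar
codes; any curated list can be supplied as a YAML file, since the exact
vocabulary is a modelling decision, not a property of the algorithm.
Cyclodextrins modelled as rings of standard glucose residues rather than
as a single assembly component are classified `carbohydrate` unless their
codes are added to the cyclodextrin list; detecting the ring topologically
would require bond perception, which is out of scope.

## Labels

A protein residue is positive for class *c* when its minimum heavy-atom
distance to any subunit of class *c* is ≤ 4.0 Å (inclusive boundary;
protein–sugar stacking contacts fall in the 3.3–4 Å range). The two
classes are labelled independently and are exclusive by partitioning: a
cyclodextrin contact does not make a residue carbohydrate-positive.
Distances use a KD-tree; the test suite pins the result to a brute-force
all-pairs scan.

## Splits

Sequences are compared by global alignment (match 1, mismatch 0, gap open
−0.5, extend −0.1) with identity defined as matches / alignment length.
Greedy leader clustering at a 30% identity ceiling is deterministic in
input order and dependency-light; the interface accepts any externally
computed cluster map, so an MMseqs2/CD-HIT-style tool can be substituted
for large corpora. Splitting shuffles *clusters* with the given seed and
apportions each to the split with the largest remaining deficit, so no
cluster ever spans two splits.

## The network

Hyperparameters (defaults): scalar state size S = 32 and the same number
of vector channels; 24 layers; 2 attention heads of key size 3; neighbor
schedule 6×8, 6×16, 6×32, 6×64; residue pooling with 4 heads; 3-layer
embedding and decoder MLPs; 30 element classes (29 named elements plus a
catch-all for anything else). Distances enter the keys scaled by 0.1 Å⁻¹
for conditioning. ELU nonlinearities throughout. The desk-scale
configuration used by the harness and tests is S = 16 with 4 layers and
schedule (8, 16, 32, 64).

The functional form of a layer: for every atom *i* and neighbor slot *j*,
an invariant pair feature `[q_i, q_j, p_i·R_ij, p_j·R_ij, 0.1·D_ij]` feeds
the keys, the scalar values, and three coefficient tracks. Queries come
from the central atom's invariants `[q_i, |p_i|]`. Attention is a softmax
over neighbor slots per head. The scalar update projects the attended
scalar values back to S features; the vector update forms, per head and
channel, `a_R·R_ij + a_p·p_j + a_i·p_i` with learned invariant
coefficients and projects the attended result — a linear composition of
geometric vectors, which is what guarantees exact rotation equivariance.
Both updates are residual. The first layer carries only the `R`
coefficient track, because its input vector state is identically zero and
gates on `p` would be dead parameters there.

Atoms with fewer real neighbors than the slot count attend to a sink
node: a neighbor with zero scalar and vector state and zero values. All
padding slots represent the *same* sink node, so only one of them enters
the softmax — this makes the padding width inert, which the tests assert
exactly.

Residue pooling attends over each residue's atoms (4 heads, masked
softmax over a padded atom axis) and pools both `q` and `p`; the decoder
sees the pooled scalar state concatenated with the per-channel Euclidean
norms of the pooled vector state, hence only rotation-invariant
quantities, and applies a sigmoid per output class.

The kNN graph is recomputed once per distinct neighbor count and shared by
the layers using it (an efficiency choice; the graph depends only on
coordinates). Ties in neighbor distance break by ascending atom index for
determinism. Checkpoints are `.npz` archives with the configuration
embedded as JSON and a format version number.

### Numerical backend

No deep-learning framework is a dependency: the package includes a small
reverse-mode autodiff engine over float64 NumPy arrays (`glycosite.autograd`)
implementing exactly the operator set the network needs, with gradients
unit-tested against central finite differences, plus a bias-corrected Adam.
In float64 the equivariance deviations observed across a 4-layer stack are
at machine precision (~1e-15); the documented test tolerances (1e-5 per
layer state, 1e-4 on final probabilities) leave headroom for a
single-precision port.

## Training

Loss: mean over residues and classes of
`−[w·y·log p + (1−y)·log(1−p)]` with `w = 0.9` multiplying the positive
term only — the reading of "weight on the positive label" adopted here;
a 0.9:0.1 two-sided reweighting is the main alternative and would only
rescale the negative term. Probabilities are clamped at 1e-7. The two
class losses enter with equal weight. Optimizer: Adam, learning rate
1e-4, no schedule, no early stopping beyond retaining the best-validation
parameters. Batching is one structure per step by default (gradient
accumulation over `batch_size` structures is available); training order is
reshuffled per epoch from the run seed, and parameter initialization is
seeded, so runs are exactly reproducible.

## Synthetic fixtures

The generator emulates the geometry that matters for this package —
known-by-construction interface labels — and nothing else. A chain of
compact 4-atom residues (elements N, C, C, O) sits on a jittered lattice
6 Å apart; residues far in chain distance from every contact residue bend
away from the ligand side so that non-contact residues end up strictly
farther than cutoff + 2 Å from all ligand atoms, while each contact
residue receives a ligand atom exactly `contact_distance` (default 3.5 Å)
above its topmost atom. Ligand atoms alternate C and O and carry a
residue code from the carbohydrate vocabulary (`GLC` by default, `BCD`
for cyclodextrin-class fixtures) so the partitioning pipeline classifies
them. Residue identities are drawn uniformly from the 20 standard amino
acids, which gives the clustering step realistic sequence diversity. The
generator validates its own geometric contract and refuses configurations
that cannot satisfy it.

What these fixtures do *not* model: sugar stereochemistry, glycosidic
geometry, realistic side chains, crystallographic noise, or the size and
class imbalance of real curated datasets. Tests passing on them show the
machinery is correct — labeling, equivariance, learnability, evaluation —
not that the model generalises to real protein–carbohydrate complexes;
that requires training on curated structures with the `curate`/`train`
CLI at scale.

## The overfit harness

`tiny_overfit` trains the desk-scale model on 5 generated complexes
(3 carbohydrate-bound, 2 cyclodextrin-bound, so both heads see positives)
for 300 epochs and reports the pooled train-set balanced accuracy and the
fractional loss reduction. The generated complexes are fixed study
conditions (data seed 7); the run seed controls initialization and
shuffling. On one CPU this takes roughly two minutes and reaches balanced
accuracy 1.0 with a > 99% loss reduction.

## Evaluation

The battery mirrors standard interface-prediction reporting: confusion
counts and all derived rates (TPR/TNR/PPV/NPV/ACC and complements), BACC,
MCC, F1 and Dice (identical for binary label sets, both reported), plus
ROC-AUC and PR-AUC. The decision threshold is 0.5 with `≥` mapping to
positive. Undefined rates (zero denominators) are carried as NaN and
propagate explicitly. MCC is computed from counts when they exist and
otherwise from the rate-product identity
`√(TPR·TNR·PPV·NPV) − √(FNR·FPR·FDR·FOR)`, which the tests verify agree
to 1e-12 on random confusion tables. ROC-AUC follows the Mann–Whitney
convention (ties count ½) and PR-AUC uses step interpolation over recall,
avoiding the optimistic bias of trapezoidal PR integration; both are
delegated to scikit-learn and pinned against exhaustive pair counting in
the tests. Per-structure aggregation uses the median for AUCs (the
method's reporting convention); threshold metrics can be aggregated either
as medians or by pooling confusion counts, with pooling the default since
a pooled table equals evaluation on the concatenated residues.

## Known limitations

- The greedy leader clustering is quadratic in the number of cluster
  representatives and meant for desk-scale corpora; swap in a dedicated
  clusterer for PDB-scale curation.
- Cyclodextrin detection is vocabulary-driven, not topological.
- The NumPy backend is single-threaded and CPU-bound; the default 24-layer
  configuration is usable for inference on small proteins but full-scale
  training requires porting the model definition to a GPU framework (the
  architecture and all contracts are framework-agnostic).
- Resolution filtering during curation relies on a user-supplied metadata
  table; header parsing for resolution is not implemented.
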