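# Methods

## Problem setting

`fragtox` predicts binary toxicity endpoints (e.g. blood-brain-barrier
permeability, hepatotoxicity, carcinogenicity) from molecular structure.
Toxicity is rarely explained by a single substructure: different organs are
sensitive to different toxicophores, and the relevant granularity ranges
from a single reactive functional group to a whole scaffold class.  The
package therefore represents each molecule simultaneously at atom
resolution and at three fragment resolutions, in both 2D topology and 3D
geometry, and supports joint (multi-task) training across endpoints.

## Molecular representation

A molecule is a heavy-atom graph in canonical SMILES atom order.  Each atom
carries a 35-dimensional descriptor vector (element, degree, formal charge,
hybridization, aromaticity, implicit-hydrogen count, ring membership,
chirality — one-hot with overflow buckets where applicable), 2D depiction
coordinates, and 3D coordinates from ETKDG conformer generation followed by
MMFF94 optimization (seeded; hydrogens added for embedding and removed
afterwards).  Molecules that fail parsing, sanitization, or embedding are
dropped and counted in a recovery log, so dataset loading reports
`parsed = embedded + dropped` accounting.  A 1024-bit radius-2
extended-connectivity fingerprint (ECFP) accompanies each molecule.

## Fragment views

Three fragmentation schemes each induce a partition of the atoms into
connected, disjoint, covering fragments:

* **BRICS** — retrosynthetic cleavage bonds are severed and connected
  components become fragments; membership stays on original atom indices
  and attachment dummies are never created.  Uncleavable molecules are one
  fragment.
* **Bemis–Murcko** — the scaffold (ring systems plus linkers, taken from
  the toolkit's scaffold extraction with an index-pruning fallback) is one
  fragment and every connected side-chain component is another; acyclic
  molecules are a single fragment.
* **Functional groups** — all matches of the RDKit functional-group SMARTS
  catalog are collected with attachment points excluded, overlapping
  matches are merged, merged groups are re-split into connected pieces, and
  unmatched atoms form connected backbone fragments.  Merging overlaps
  (rather than priority-ordering them) keeps the result a partition and
  makes it independent of match order.

A partition is lifted to a fragment graph: fragment features are sum-pooled
atom features, fragment coordinates are mass-weighted centers of the member
atoms (heavy-atom masses; applied to both 3D and 2D coordinates, the 2D
case mirroring the 3D definition so the fragment branch has a distance
matrix), and two fragments are adjacent iff a bond crosses between them.
Center-of-mass pooling commutes with rigid transforms, which the test-suite
asserts to 1e-9 in double precision.

## Network

Both branches run the same two-stage encoder; the atom branch has its own
parameters while one shared parameter set serves all three fragment views.

**Graph-augmented transformer.**  Node features are linearly embedded to
width `nf` (default 32, 4 heads, 1 layer).  Per head, the attention matrix
is a convex combination

    P = lam_attn * softmax(Q K^T / sqrt(d_k)) + lam_dist * D' + lam_adj * A'

where `D' = softmax(-D)` row-wise over the 2D distance matrix and `A'` is
the bond adjacency normalized by row sums (an isolated node falls back to a
self-weight of 1, avoiding division by zero).  The three weights are
non-negative and sum to 1 (default 1/3 each), so every row of `P` is a
probability distribution — the property the interpretation module relies
on.  The block then follows standard practice: per-head application to V,
concatenation, output projection, residual + layer norm, a SiLU feed-forward
sublayer, residual + layer norm.  `P` is recorded per layer and head for
interpretation.

**E(3)-equivariant convolution (EGCL).**  A k-nearest-neighbor graph
(default k=5, Euclidean distances on the conformer, ties broken by atom
index, symmetrized) restricts message passing.  Messages are
`m_ij = phi_e(h_i, h_j, ||c_i - c_j||^2, a_ij)`, aggregated by summation
over neighbors, features update as `h_i' = phi_h(h_i, m_i)`, and
coordinates update along weighted difference vectors
`c_i' = c_i + s * sum_j (c_i - c_j) phi_x(m_ij)`.  The scale `s` defaults
to 0.1, which keeps stacked coordinate updates well-conditioned for
molecule-sized graphs.  `phi_e`/`phi_h` are two-layer SiLU networks,
`phi_x` a small-initialized linear map.  Because geometry enters only
through pairwise distances, features are E(3)-invariant and coordinates
E(3)-equivariant; with 2 stacked layers (the default) the final layer
performs a feature-only update, since its updated coordinates would be read
by nothing — this also guarantees every allocated parameter receives
gradient.

**Readout, fusion, head.**  Node embeddings are mean-pooled (configurable
to sum), making the embedding permutation-invariant.  The three
fragment-view embeddings are fused by a convex combination with weights
`(lambda_b, lambda_m, lambda_f)` for BRICS / Murcko / functional groups
(default 1/3 each; per-endpoint tuning is the intended use).  A linear head
with sigmoid maps `concat(atom embedding, fused fragment embedding, ECFP)`
to per-task probabilities.  Updated EGCL coordinates never reach the head,
so predictions are invariant under rotations, translations and reflections
of the conformer; the suite checks this end to end at 1e-4 (observed at
machine precision in float64).

## Training

The loss is masked binary cross entropy: each task's loss is the mean over
its observed cells, a fully unobserved task contributes exactly zero (and
zero gradient), and the total is the sum over tasks.  Masked MSE is
available for regression.  Optimization is Adam (default lr 1e-3, batch 32
— chosen for reliable convergence at the problem sizes this package targets;
both are configurable).

For multi-task training, datasets are merged by canonical SMILES; labels
absent in a source are masked, and a molecule held out in any source stays
held out (test > val > train on conflict).  With gradient surgery enabled,
per-task gradients of all parameters are computed on the same batch by
separate backward passes; tasks are visited in random order and, for each
ordered pair with a negative dot product, the running gradient is projected
onto the normal plane of the other task's raw gradient (PCGrad).  The
projected gradients are summed (mean available) and handed to Adam.  With
one task, or no conflicts, the update reduces exactly to the plain summed
gradient.

Training is fully seeded (parameter init, batch shuffling, PCGrad ordering),
so loss histories repeat bitwise for equal seeds.  When a validation split
is present, the best-validation-AUROC parameters are restored at the end and
early stopping with configurable patience is available.  AUROC is computed
per task over observed cells (scikit-learn), tasks with a single class are
excluded from the mean with a warning.

## Interpretation

Atom scores come from the recorded attention of a chosen transformer layer
(last by default): heads are averaged and the score of an atom is the
column mean of the averaged matrix — attention *received*, averaged over
source atoms (row-mean is available; the choice between the two is a
genuine free parameter of the visualization, not dictated by the model).
Atoms strictly above the molecule-mean score are highlighted, and a bond is
highlighted when both endpoints are; intensities are min-max normalized
scores.  SVG rendering delegates to RDKit's drawer with a red intensity
ramp.

## Synthetic data

The fixture generator assembles molecules from ~14 ring/chain templates
(benzene, pyridine, pyrimidine, furan, thiophene, naphthalene, saturated
rings, short chains) with substituents drawn from rule-bearing marks
(nitro, carboxyl, halogens) and neutral/decoy groups, under a seeded RNG.
Labels are SMARTS indicators re-derived on the assembled molecule (nitro,
carboxylic acid, halogen, or aromatic-scaffold class), so label/structure
consistency holds by construction, every molecule parses and embeds, and
generation is byte-reproducible.  Defaults: 32 molecules, nitro rule,
positive fraction 0.5.

What this emulates — and what it does not: the fixtures give learnable,
noise-free, structurally grounded labels with enough scaffold diversity for
meaningful scaffold splits.  Real toxicity labels are noisy, imbalanced,
mechanistically heterogeneous and only partially structure-determined, so
passing the fixture-based checks demonstrates correct wiring and
optimization, not benchmark-level predictive performance.  Benchmark
evaluation requires user-supplied CSVs of the public toxicity sets.

## Numerical choices and problem sizes

* Double precision throughout; equivariance asserted at 1e-5 (layer) and
  1e-4 (end to end), far above the observed error.
* BCE probabilities are clipped to [1e-12, 1 - 1e-12] inside the log.
* kNN ties break by atom index; scaffold-split groups fill train → val →
  test in (size desc, scaffold string) order, deterministically.
* Verification runs use desk-scale sizes chosen as the package's own test
  conditions: a 32-molecule memorization run (≤ 200 epochs, AUROC ≥ 0.95
  expected) and a 250-molecule scaffold-split generalization run
  (~200 train / ~50 test, 3 seeds, 30 epochs, mean test AUROC ≥ 0.9
  expected, the rule being linearly detectable from atom descriptors).

## Known limitations

* One conformer per molecule; conformer ensembles are out of scope.
* No tautomer or protonation-state enumeration.
* The functional-group catalog is the toolkit's shipped list; domain-
  specific toxicophore SMARTS can be added only by editing that catalog.
* The NumPy autodiff engine favors clarity over throughput; it is sized for
  the package's molecule-scale graphs, not for large-batch GPU training.
* No pretraining, baseline encoders, or hyperparameter search.
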