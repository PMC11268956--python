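# Methods

`loopforge` models protein loops at heavy-atom resolution: given a structure
and a loop region (with both flanking anchor residues present), it generates
loop conformations and scores them. This note documents the model, the
numerical choices, and what the desk-scale experiments do and do not show.

## Problem setting

A loop task is (structure, chain, first/last loop residue). Two regimes are
supported:

* **reconstruction** — the loop conformation is unknown (e.g. a missing
  segment); initial coordinates are sampled around points interpolated
  between the two anchor residues;
* **refinement** — an approximate loop exists (e.g. from a whole-protein
  predictor); initial coordinates are sampled around the raw loop's centroid
  and the pocket is taken around the raw loop.

Only a *pocket* of nonloop residues is modeled, not the whole protein.
Hydrogens are ignored throughout; "full-atom" means all heavy atoms.

## Pocket selection

For reconstruction, the pocket is built from the anchor midpoint *m*:

1. radius `r = max(|a1 − a2|/2, min(2·L, 16))` Å, where `a1, a2` are the
   anchor-residue centroids and `L` the loop length in residues;
2. if `r > 20` Å the anchors are far apart: `L` pseudo-loop points are placed
   by linear interpolation between the anchors at fractions `i/(L+1)`, and
   residues with any atom within 12 Å of a pseudo-point are kept;
3. otherwise residues with centroid inside the sphere `S(m, r)` seed the
   pocket; the shell between `r` and `r + 12` Å is then scanned, dropping
   shell residues whose direction from *m* lies within 15° of some inner
   residue's direction (they sit behind already-selected residues); finally
   residues within 6 Å of any selected residue are added (the midpoint of the
   5–7 Å band; configurable).
4. both anchors are always included.

Centroids use unit masses (geometric centers). The 15° pruning angle and the
one-point-per-residue interpolation density are package choices; the selection
is fully deterministic. For refinement, the pocket is simply every nonloop
residue with a heavy atom within 12 Å of any raw loop atom.

## Initialisation

Loop atom coordinates start from isotropic per-axis Gaussians (per-atom
i.i.d., no rigid-residue geometry imposed):

| mode           | mean                                 | SD (Å) |
|----------------|--------------------------------------|--------|
| reconstruction | per-residue interpolated anchor point | 1.75   |
| refinement     | raw-loop centroid                     | 4.0    |
| multi-conformation | per-residue interpolated point    | 7.0    |

The 1.75 Å SD matches the training-time initialisation; 7 Å trades
single-sample accuracy for conformational diversity when several
conformations are requested.

## Graphs

* **Atom graph** (pocket + loop residues): nodes are heavy atoms, edges are
  covalent bonds from residue templates plus peptide bonds; a 1.9 Å distance
  fallback covers atoms outside the templates. Node features: element class
  one-hot (C/N/O/S/other), residue-type one-hot (20), backbone flag, degree
  one-hot (0–4+). Edge features: bond class (intra-residue vs peptide). No
  coordinates — the atom encoder is rigid-motion invariant by construction.
* **Residue graph** (pocket residues): a directed KNN graph (K = 30) on CA
  positions. Scalar node features: residue one-hot, backbone dihedral
  (φ, ψ, ω) sines/cosines with validity flags (dihedrals needing loop
  coordinates are marked invalid — loop geometry must not leak into nonloop
  features); vector features: unit CA→CA(±1) and CA→side-chain-centroid.
  Edge scalars: 16-bin Gaussian RBF of the CA distance over [0, 20] Å plus a
  signed, capped sequence-separation encoding; edge vectors: the unit
  displacement. KNN ties break toward the lower residue index and edge rows
  are emitted in canonical (receiver, sender) order, so construction is
  bit-stable under coordinate roundoff.
* **Interaction graph**: nodes are loop atoms plus pocket residues. Loop–loop
  and loop–residue pairs are fully connected; residue–residue edges reuse the
  KNN topology (full connection would be quadratic in pocket size for no
  benefit). Edge features are a type one-hot plus one distance channel:
  actual distances where geometry is known, −1 for loop–residue pairs at
  construction (the loop is still random). At recycle boundaries the distance
  channel is refreshed from current coordinates so later recycles see real
  geometry.

## Encoders

The **atom encoder** is a 6-layer edge-featured graph transformer. Per layer
and head, queries/keys/values and an edge projection are taken from
batch-normalised embeddings; the per-channel gate is
`softmax_neighbours((q ⊙ k)/√d_k ⊙ e)`; node updates sum gated values over
in-neighbours with a residual, edge updates concatenate the per-head gates;
both are followed by residual SiLU feed-forward blocks with an expansion
factor of 2.

The **residue encoder** is a stack of geometric-vector-perceptron (GVP)
layers. A gvp unit transforms vectors with two channel-mixing linear maps,
feeds the intermediate row norms into the scalar path, and (when activations
are enabled) gates vector rows with a sigmoid of their norms; scalars use
ReLU. Messages over each edge concatenate sender, edge and receiver features,
pass three gvp stages (activations on the first two) and are mean-aggregated;
residual connections use dropout; layer normalisation applies to scalar
channels only, because normalising vector components across channels would
break rotational equivariance. Sequence information enters as a learned
residue-type embedding concatenated to the scalar features.

The **feature-merging block** sums each residue's atom embeddings,
concatenates them to the residue embedding, and applies
linear → LeakyReLU → linear. Loop atoms take their embeddings straight from
the atom encoder (selected by the loop mask), so loop and pocket nodes reach
the generator at the same width.

## Generator

Eight attention-augmented E(n)-equivariant (EGNN) layers update loop-atom
positions; pocket-residue nodes provide context with frozen coordinates.
Per layer: an edge message is built from the edge embedding and the squared
inter-node distance; keys are gated by the message; per-channel logits
`w = q ⊙ k/√d_k` drive three things — the node update (sum of `w ⊙ v` over
neighbours, gate-combined with the previous state), the edge update (softmax
of `w²` over neighbours, linearly mixed), and the coordinate update (a
per-head scalar from a small MLP on `w`, scaling the unit difference vector,
combined across heads and summed over neighbours). Because only squared
distances and unit difference vectors touch geometry, translations commute
exactly and rotations to floating-point accuracy.

Recycling runs the layer stack R times (default 3); at each boundary node
embeddings are gate-combined with the first-pass embeddings
(`g = σ(W[h_new, h_old, h_new − h_old])`, output `GraphNorm(g ⊙ h_new + h_old)`)
and loop-incident edge distances are refreshed. Whether gradients cross
recycle boundaries is configurable: truncation (the
iterative-refinement-folding convention) bounds memory at scale, but at desk
scale full backpropagation through recycles with global-norm gradient
clipping (1.0) trains far better — with truncation the shared layer weights
must serve two different input regimes with only indirect coupling, and the
reduced-width overfit stalls several Å short. The small configuration
therefore backpropagates through recycles.

Numerical choices:

* squared distances enter the edge message in scaled units
  (`0.1 × d²`, i.e. d in √10 Å); with raw Å² inputs and unscaled output
  layers the coordinate feedback loop diverges already at random
  initialisation;
* the coordinate-update output layers start at 0.1× weight scale so early
  iterations make gentle moves;
* difference-vector normalisation is ε-guarded (ε = 1e−8) at coincident
  points;
* GraphNorm statistics are always taken from the current graph, so the
  model is deterministic in eval mode.

## Scoring

For every (loop atom, pocket residue) pair the mixture-density head predicts
a 10-component Gaussian over their distance — the minimum over the residue's
heavy atoms of the distance to the loop atom. Pair features are
`Dropout(ELU(BatchNorm(W[h_res, h_loop])))`; means use `ELU + 1` (> 0), SDs
`ELU + 1.1` (> 0.1), weights a softmax. The negative log-likelihood of the
true distances is the statistical-potential training loss, restricted to
pairs with true distance ≤ 12 Å (distant pairs carry no structural signal and
would dominate the loss; the cutoff is a package choice). The *confidence
score* of a candidate conformation is the summed log-likelihood over all
pairs, higher is better. The score ranks conformations; it is not calibrated
to RMSD.

## Training

Stage 1 fits the encoders + MDN on true conformations:
`L = L_MDN + 0.001·L_atom + 0.001·L_bond`, where the auxiliary cross-entropy
terms classify each atom node's element and each covalent edge's bond class
from the atom-encoder outputs (the auxiliary targets are a package
reconstruction — any cheap self-supervised labels on the atom graph serve the
same purpose and the heads are isolated behind one function). Stage 2 starts
from a stage-1 checkpoint, adds the generator, and appends the coordinate
loss with coefficient 1: `L = L_RMSD + L_MDN + 0.001·L_atom + 0.001·L_bond`,
with `L_RMSD` the RMSD between predicted and true loop coordinates in the
shared frame (no superposition).

Reference hyperparameters: Adam, batch 64, stage-1 lr 1e−3 with weight decay
1e−5, stage-2 lr 1e−4 without; early stopping on validation loss with
patience 70 ("rises for 70 consecutive epochs" is implemented as
no-improvement patience — literal consecutive increases would essentially
never trigger); train/validation split stratified by loop length 9:1.

### Desk-scale overfit protocol

The repository's experiments train a reduced model (width 32, 2 heads,
2 recycles, 2 GT layers, 1 GVP layer, 4 EGNN layers) on five synthetic
helix–loop–helix tasks (loop length 6). Optimisation choices specific to
this regime, exposed as `TrainConfig` options:

* **deep supervision**: the stage-2 coordinate term averages the RMSD over
  every EGNN layer's coordinates (all recycles) instead of the final ones
  only — credit assignment through 8 sequential coordinate updates is
  otherwise too slow; the reported `L_RMSD` remains the final-coordinate
  RMSD;
* **per-task steps**: one Adam step per task rather than one averaged step
  per epoch;
* **cosine learning-rate schedule** from 3e−3 (not the large-scale 1e−4,
  which barely moves a 100k-parameter model) annealed to 1e−4;
* **full backpropagation through recycles** with gradient clipping at
  global norm 1.0 (see above);
* **frozen encoders in stage 2**: stage 2 trains the generator and the
  mixture head while the stage-1 encoders stay fixed (their per-task outputs
  are computed once and cached). This reads the two-stage protocol as
  "pretrain the representation, then train the conformation modules", avoids
  the coordinate and likelihood objectives pulling the shared encoders in
  different directions, and cuts the per-epoch cost substantially;
* one fixed initialisation per task (seeded by the task id), so the
  generator learns a deterministic init → truth mapping.

With stage 1 at 60 epochs and stage 2 at 550 cosine-annealed epochs, one
training run takes several minutes on one CPU and reaches ~0.3–0.9 Å mean
training-loop RMSD depending on the parameter seed, versus ~6 Å for random
weights.

With this protocol the mean training loop RMSD reaches well below 1 Å in a
few minutes on one CPU, versus ~6 Å for random weights. This demonstrates
that the architecture and losses can represent and fit loop geometry; it
says nothing about generalisation to unseen loops, which would require the
full-scale training the method assumes (hundreds of thousands of loops).

## Synthetic structures

Fixtures are poly-alanine (optionally poly-leucine or glycine) chains built
atom-by-atom in internal coordinates with idealised bond lengths/angles
(N–CA 1.458, CA–C 1.525, C–N 1.329, C–O 1.231, CA–CB 1.521 Å; ω = 180°).
Helices use (φ, ψ) = (−57, −47), strands (−139, 135); loop torsions are drawn
from two broad Ramachandran basins and resampled (≤ 100 times) until no two
atoms from residues ≥ 2 apart are closer than 1.5 Å. What these fixtures
emulate: realistic local geometry, anchors, a structured pocket, and exact
ground truth. What they do not: sequence diversity, side-chain rotamers,
solvent, crystal contacts, or experimental noise — so green tests here
validate the machinery, not biological accuracy.

## Evaluation

Loop accuracy is heavy-atom RMSD over the loop, atoms matched by (chain,
residue index, atom name); unmatched reference atoms are an error, never
silently dropped. When frames differ, structures are first superposed on the
nonloop (framework) heavy atoms with the Kabsch algorithm
(reflection-corrected SVD). "Success" is loop RMSD ≤ 2 Å (boundary counts).
`best_of_n` reports both the oracle best (minimum RMSD) and the
confidence-selected conformation.

## Known limitations

* No trained weights ship with the package; predictions with random weights
  are only useful for property tests.
* The neural stack runs on a small numpy autograd engine: fine at pocket
  scale on a CPU, not meant for large-scale training.
* Poly-alanine fixtures make atoms of different residues locally
  indistinguishable to the (coordinate-free) atom encoder; the generator
  disambiguates them through geometry. Real sequences are easier in this
  respect.
* The MDN score ranks conformations but does not map linearly to RMSD.
* Loops at chain termini (missing one anchor) are rejected by design; the
  initialisation geometry requires both anchors.
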