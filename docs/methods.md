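# Methods

This note documents the models implemented in `redoxscreen`, the design
decisions behind them, what the synthetic data emulates, and the known
limitations of both.

## Atom descriptors

Each heavy atom of a molecule is described by 34 numbers laid out as
three charge-state blocks plus whole-atom terms:

| block | entries | meaning |
|---|---|---|
| neutral | occ₀..occ₄, E₀..E₄ | orbital occupancies (e⁻, ∈[0,2]) and energies (hartree) of up to five energy-ranked orbital slots |
| oxidized (radical cation) | same 10 | the same quantities after one-electron removal |
| reduced (radical anion) | same 10 | after one-electron addition |
| whole-atom | q(neutral), q(ox), q(red), χ | natural charges per state and Pauling electronegativity |

Hydrogens are not featurized; heavy atoms are indexed 0-based in the
parser's canonical order.  Orbital slots an atom does not populate
(e.g. no lone pairs) are imputed with 0.0 — the physical occupancy of
an empty orbital — so every vector is exactly 34 long and finite.
Atoms with more orbitals than slots are truncated to the five
highest-ranked slots with a logged warning.

Backends supply the orbital data behind a single `compute()` contract:

* `TableBackend` imports real population-analysis exports (CSV with
  `molecule_id, atom_index, charge_state, orbital_slot, occupancy,
  energy[, natural_charge]`).  It is a read-only parser; running
  electronic-structure software is out of scope.
* `MockQMBackend` computes deterministic pseudo-properties in closed
  form from the element, heavy-atom degree, ring membership and an
  electronegativity-equalization partial charge
  (qᵢ = 0.16 Σⱼ (χⱼ − χᵢ) over bonded neighbours, hydrogens included).
  Cation/anion shifts are element-local (susceptibility ∝ 1/χ for
  oxidation, ∝ χ for reduction).  Everything is a pure function of the
  local graph, so atoms in the same automorphism orbit receive
  identical vectors, repeated calls are bit-identical, and atoms in
  comparable environments of different molecules share values — the
  last point matters because the embedding discretizes these values
  into labels and needs cross-molecule label sharing to generalize.
  The numbers are structurally plausible (bounded occupancies,
  energy-ranked slots, systematic cation/anion shifts) but are not
  quantitative quantum chemistry.

## DFT-embedded fingerprint (graph2vec)

Nodes of the heavy-atom bond graph are labelled by a stable 64-bit hash
(truncated SHA-256, unsalted) of `(element, descriptor rounded to 3
decimals)`.  Rounding precision is configurable; 3 decimals keeps every
meaningful distinction of the mock backend while making the labels
discrete.  Weisfeiler-Lehman relabelling then produces one token per
node per depth 0..d: the depth-k token hashes the node's depth-(k−1)
token with the sorted multiset of its neighbours' depth-(k−1) tokens.
Bond-order tags are carried on edges but ignored by default during
aggregation (configurable).

Token multisets feed a PV-DBOW skip-gram model: each graph's document
vector is trained to predict its own tokens against 5 negative samples
drawn from the unigram^0.75 distribution, learning rate 0.025 decayed
linearly over 50 epochs, dimension 128, WL depth 3, seed 17,
single-threaded.  Documents are canonicalized to sorted token lists and
de-duplicated before training, which makes two properties *exact*
rather than approximate: identical graphs (and node-permuted copies of
isomorphic graphs) receive bit-identical vectors, and training is
reproducible byte-for-byte for a fixed corpus, configuration and seed.
Out-of-corpus molecules are embedded by `infer_vector` (new document
vector against frozen token vectors); tokens outside the vocabulary are
skipped and counted, and a fully out-of-vocabulary graph returns the
zero vector with a flag.  The recommended mode for screening, and the
pipeline default, is transductive: refit the embedding on the union of
training and screening molecules.  The embedding is unsupervised, so
this leaks no labels.

## Supervised models

**Oxidation-site classifier.**  L2 logistic regression on the raw
34-entry descriptors with balanced class weights (positives are ~8% of
atoms).  Two deliberate choices: no feature standardization, because
the descriptor entries share physically comparable magnitudes and
standardizing amplifies low-variance noise slots; and logistic
regression rather than gradient-boosted trees as the default family,
because tree probabilities form plateaus across atoms that are all
clearly unreactive, which destroys the per-atom rank-ordering the model
must provide (on held-out synthetic molecules, top-1 site recovery was
83% with boosted trees — every miss a probability tie at ~10⁻⁶
resolution — versus 100% with logistic regression).  Boosted trees
remain available via `SiteClassifierConfig(family="gbt")`.

**LOGO evaluation.**  One fold per reaction template: all atoms of the
held-out template form the test set, the other templates train the
model, so each fold predicts a reaction type absent from training.
Aggregate scores are pooled (micro): precision = ΣTP/(ΣTP+ΣFP), recall
= ΣTP/(ΣTP+ΣFN) over folds.  Pooling is the default because it stays
well-defined when a fold predicts no positives; macro averaging is
available by flag.  A fold whose training partition is single-class is
skipped with a warning and recorded in the report.

**PLS benchmark.**  `compare_representations` fits PLS regression
(components capped at the feature-matrix rank, default 5) on identical
random train/test splits for every representation, reporting per-split
R² and MAE.  Identical splits make the comparison paired.

**Competency ensemble.**  Ten `RidgeClassifier` members, each trained
on an independent random partition at the canonical 116:141 ratio and
scored on its 25-record complement.  Ridge α defaults to 1.0; per-member
cross-validated selection from {0.01, 0.1, 1, 10} can be enabled and is
the recommended (and pipeline-default) setting when the inputs are
128-dimensional embeddings.  Prediction: members vote ±1, probability =
(# votes of +1)/10, label = +1 iff the mean vote is strictly positive.
The tie (mean vote 0.0) is classified incompetent — conservative for
screening, where false leads cost bench time.

**Screening.**  Results are sorted by probability descending with
molecule-id ascending as the documented tie-break, ranked 1..n;
"likely reactive" means mean vote > 0 (the ensemble's natural decision
boundary), not a probability cutoff.  `select_candidates` takes the
top-k after an optional SMARTS substructure filter.  Commercial-analogue
verification is modelled as re-embedding and re-scoring the analogue
SMILES.

## Synthetic data

The generators emulate the statistical shape of the study corpora
without any download:

* Molecules: random valence-correct connected graphs over {C, N, O, S}
  (weights 0.70/0.12/0.12/0.06), 4–12 heavy atoms, single bonds, one
  optional ring closure (p = 0.35), rendered to SMILES.
* Site corpus: every atom scores w·f on a planted linear rule over the
  descriptors; scores are standardized, Gaussian noise of 0.1 SD added,
  and the top 8% labelled oxidized (quantile calibration, so realized
  fractions match the target).  Molecules carry one of five reaction
  templates (round-robin over a shuffled order, so all are non-empty),
  and the noiseless per-molecule argmax atom is recorded as truth.
* Competency corpus: 141 molecules by default, label = sign of the
  planted rule on mean atom features plus noise, calibrated to ~43%
  positives (60/141).  About half the positives are tagged `known`,
  the rest cycle AR/BN/CH/Misc; negatives are `unknown`.
* Property benchmark: targets are the molecule mean of an
  ionization-potential-like functional (frontier-orbital energies plus
  cation charge) of node attributes that include a **latent electronic
  state**: each molecule carries one of five quantized energy shifts
  (step 0.02) applied to all its orbital energies.  This emulates the
  defining property of real quantum-chemical attributes — they carry
  information (conformation, conjugation, solvation) that the 2D graph
  does not determine.  Without it every constructible target is a
  function of topology alone and a topology fingerprint is a ceiling-
  optimal representation, which would make representation comparisons
  meaningless.  The step size leaves the topology-only baseline with
  real skill (R² ≈ 0.2) rather than zeroing it out.
* Screening libraries: same molecule distribution, 10% planted
  positives by default; truth labels go to a separate file that the
  screening pipeline never accepts as input.

The default planted rule weights the neutral and cation
frontier-orbital energies, the cation frontier occupancy, the neutral
natural charge and electronegativity — the descriptors' electronically
meaningful entries under the mock backend.

What passing tests on these data do **not** show: quantitative
agreement with wet-lab outcomes, transferability of real NBO value
distributions, 3D/stereochemical effects, or condition–reactant
interactions (reaction conditions are fixed by construction).

## Determinism

All randomness flows from one master seed; per-component seeds are
`SHA-256(master:component) mod 2³¹`.  Embedding training is
single-threaded with a seeded generator; CSVs are written with a fixed
float format.  Two end-to-end runs (simulate → featurize → embed →
train → screen) with the same master seed produce byte-identical
result files.

## Problem sizes

The shipped demonstrations and the results script use desk-scale sizes
chosen to exercise every code path on one CPU in minutes: 141-record
competency training (the canonical geometry), 300-molecule corpora for
planted-rule recovery (~2,400 atoms for the site task), a 150-molecule
regression benchmark, and 1,000-molecule screening libraries.

## Known limitations

* **Tokenized-embedding accuracy ceiling.**  At n = 300 molecules with
  label noise 0.1, the competency ensemble on embeddings reaches
  ~0.82–0.89 held-out accuracy depending on the seed.  This is a
  representation limit, not a training defect: an oracle given the
  *exact* normalized WL-token histograms that the embedding compresses
  reaches only ~0.86–0.89 under the same protocol, while ridge on the
  raw mean atom descriptors reaches ~0.94–0.97.  WL tokens are opaque
  identifiers — the numeric descriptor values enter only through label
  identity — so molecules near the decision threshold cannot be
  separated from 116 training examples.  Larger training sets, coarser
  descriptor discretization tuned to the data, or hybrid
  representations that append mean descriptors to the embedding would
  be the routes around this ceiling.
* The mock backend derives everything from 2D topology; conclusions
  about representation quality transfer to real quantum-chemical
  attributes only to the extent that the latent-state emulation
  captures their beyond-topology content.
* Generated molecules are small, single-bonded and limited to four
  elements; aromaticity enters only through parsed real molecules.
* `train_site_classifier` assumes one template per molecule and
  molecule-level grouping; atom-level group assignment is unsupported.
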