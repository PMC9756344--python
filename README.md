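# redoxscreen

Machine-learning-guided discovery of electrochemical reactions.

`redoxscreen` is a toolkit for screening candidate molecules for
*reaction competency* in convergent paired electrolysis — reactions in
which a substrate oxidized at the anode couples with the persistent
radical anion of 1,4-dicyanobenzene (DCB) formed at the cathode.  It is
aimed at synthetic electrochemists and cheminformaticians who want to
prioritize large candidate libraries before committing bench time.

The toolkit implements four connected pieces:

1. **Quantum-chemical atom descriptors** (`qm_features`).  Every heavy
   atom gets a 34-dimensional vector of orbital occupancies and energies
   for the neutral molecule, its radical cation and its radical anion
   (3 states × 5 energy-ranked orbital slots × {occupancy, energy}, plus
   natural charges and electronegativity).  Orbital data come from a
   pluggable backend: a CSV importer for real population-analysis (NBO)
   tables, or a deterministic topology-derived mock for development and
   testing.
2. **DFT-embedded fingerprints** (`graph_embedding`).  Molecules become
   graphs whose node labels discretize the atom descriptors; iterative
   Weisfeiler-Lehman (WL) relabelling produces rooted-subgraph tokens,
   and a skip-gram model with negative sampling (graph2vec / PV-DBOW)
   learns one fixed-length vector per molecule:
   *d*(G) maximises Σ<sub>t∈WL(G)</sub> log σ(d·w<sub>t</sub>) +
   Σ<sub>neg</sub> log σ(−d·w<sub>t'</sub>).
3. **Supervised models** (`modeling`).
   - A per-atom *oxidation-site* classifier (L2 logistic regression,
     balanced class weights) evaluated by leave-one-group-out (LOGO)
     folds over reaction templates, with pooled precision
     ΣTP/(ΣTP+ΣFP) and recall ΣTP/(ΣTP+ΣFN).
   - A projection-to-latent-structures (PLS) regression harness for
     benchmarking molecule representations on electronic-property
     targets over shared random splits.
   - A *competency ensemble*: ten ridge classifiers, each trained on a
     random 116-record partition of a 141-record dataset (scaled
     proportionally for other sizes) and scored on the disjoint
     25-record rest.  Members vote ±1; the prediction probability is the
     fraction of +1 votes and the label is the sign of the mean vote
     (ties → incompetent).
4. **Library screening** (`screening` + CLI).  Embed a candidate
   library (transductively or by inference), score with the ensemble,
   rank by prediction probability, and shortlist top candidates with an
   optional SMARTS substructure filter.

Because no public dataset accompanies the underlying experimental
campaign, `synthetic` generates statistically matched stand-ins: random
valence-correct molecules over {C, N, O, S}, an 8%-positive atom-level
oxidation corpus across five reaction templates, a 141-record
competency set with ~43% productive labels, property-regression
benchmarks with latent electronic states, and unlabeled screening
libraries with held-apart truth files.

## Worked example

```python
from redoxscreen.config import RunConfig
from redoxscreen.pipeline import run_discovery
from redoxscreen.screening import screening_summary, select_candidates

run = run_discovery(RunConfig(master_seed=7), n_train=141, n_library=200)
print(f"competency records: {len(run.dataset.labels)} "
      f"({(run.dataset.labels.label == 1).sum()} productive)")
print(f"ensemble mean held-out accuracy: {run.ensemble.mean_accuracy:.3f}")
summary = screening_summary(run.results)
print(f"screened {summary['n_screened']} molecules, "
      f"{summary['n_predicted_reactive']} predicted reactive")
for r in select_candidates(run.results, 3):
    print(f"  rank {r.rank}: {r.molecule_id}  {r.smiles}  "
          f"p={r.probability:.1f}  vote={r.mean_vote:+.1f}")
```

prints

```
competency records: 141 (60 productive)
ensemble mean held-out accuracy: 0.780
screened 200 molecules, 78 predicted reactive
  rank 1: lib-0002  CC(C)CNO  p=1.0  vote=+1.0
  rank 2: lib-0006  CCC(C)C(C)SC  p=1.0  vote=+1.0
  rank 3: lib-0009  CCCC(C)CC  p=1.0  vote=+1.0
```

The mean held-out accuracy is the average test accuracy of the ten
ensemble members on their 25-record external test sets; the screening
report counts molecules whose mean vote is strictly positive ("likely
reactive") and ranks everything by the fraction of members voting +1.

The same chain is available from the shell:

```bash
redoxscreen simulate --kind competency --out-prefix comp --seed 7
redoxscreen embed --molecules comp_molecules.smi --out-prefix emb --seed 7
redoxscreen train-competency --embeddings emb_embeddings.csv \
    --labels comp_labels.csv --out ensemble.json
redoxscreen screen --library lib.smi --model ensemble.json \
    --embedding emb --out results.csv --top-k 20 --filter "[#16]"
```

Every command writes a JSON manifest (configuration, derived seeds,
SHA-256 digests of inputs and outputs); re-running with the same
manifest reproduces identical digests.

## Testing

```bash
python -m pytest tests/
```

The suite covers unit behaviour per module, property-based invariants
(WL tokenization against a brute-force rooted-subtree oracle,
permutation equivariance, seed determinism) and whole-pipeline
recovery of planted structure in the synthetic data.

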