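# probeal

Chemogenomic active learning for chemical-probe bioactivity profile
prediction.

`probeal` builds ligand–target interaction classifiers over a small protein
family and asks how well they predict the inhibition profiles of *probe*
compounds — compounds with exactly one active annotation and at least one
inactive annotation — when the model may only learn from non-probe data.
The pipeline covers:

- **Dataset preparation** — per-target Ki discretization with auto-derived
  30-fold-separated thresholds (inactive boundary = mean Ki, re-adjusted up
  to 1500 nM when the mean is stronger; active boundary = 30-fold stronger,
  min 50 nM), retention filters, and the probe / non-probe compound split.
- **Descriptors** — ligand blocks (96 physicochemical descriptors, a
  150-entry CATS-style pharmacophore atom-pair vector, and 512/1024/4096-bit
  hashed circular fingerprints) concatenated with target blocks (one-hot
  identity or overlapped sliding-window k-mer counts, k = 1..4).
- **Active learning** — a 100-tree random forest in a fit–predict–pick loop
  with `random`, `greedy` (max mean tree vote) and `curiosity` (max
  across-tree vote variance) pickers, seeded with one random active and one
  inactive pair, evaluated on the external probe set at every iteration.
- **Evaluation** — MCC / F1 / PPV / TPR / TNR from confusion counts, metric
  surfaces over (TNR, TPR) at a fixed class ratio, and *active projections*
  (trajectory overlays terminated once neither rate moves by ≥ 0.075).
- **Interpretation** — per-iteration z-scaled feature-weight matrices,
  decision-tree export to DOT (yellow = inhibitory, cyan = non-inhibitory,
  intensity = purity), target-descriptor root-node fractions with Student-t
  confidence intervals, and k-mer uniqueness indexing.
- **Yoked models** — replay of recorded picking histories into SVM (RBF /
  linear) and multi-layer-perceptron grids at training-budget checkpoints.
- **Synthetic data** — a generator producing bioactivity tables, target
  FASTA, compound features/SMILES and a ground-truth record (planted unique
  motifs, group motifs, per-target rules, probe membership) so the entire
  pipeline runs and is testable offline.

## Test

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, whose directional
replications run ~10-seed active-learning repeats and take several minutes
on one CPU; the rest of the suite finishes in well under a minute.

## Command line

The pipeline is exposed as subcommands of a single `probeal` entry point:

```bash
probeal simulate --seed 0 --out data/                       # synthetic dataset
probeal prepare  --bioactivity data/bioactivity.tsv --out data/
probeal run      --data-dir data/ --ligand-scheme raw --target-scheme dipeptide \
                 --strategy curiosity --repeats 10 --weight-interval 25 --out runs/
probeal project  --run-dir runs/ --name run_curiosity_seed0 --out proj.png
probeal weights  --run-dir runs/ --name run_curiosity_seed0 --out weights.png
probeal trees    --run-dir runs/ --name run_curiosity_seed0 --data-dir data/ --out trees/
probeal replay   --run-dir runs/ --name run_curiosity_seed0 --data-dir data/ \
                 --family mlp --out replay.tsv
probeal report   --run-dir runs/ --out report.tsv
```

`--ligand-scheme` accepts `raw` (precomputed feature vectors), `pchem`,
`cats`, `fp512`, `fp1024`, `fp4096` or `combined` (pchem + fp1024);
`--target-scheme` accepts `identity`, `residue`, `dipeptide`, `tripeptide`
or `tetrapeptide`. Every stage writes a JSON manifest recording its
configuration, seeds, library versions and outputs.

## Library use

```python
from probeal import synthetic
from probeal.pipeline import matrices_from_dataset
from probeal.al_engine import run_active_learning

dataset = synthetic.generate(synthetic.SynthConfig(n_compounds=300, rng_seed=0))
mats = matrices_from_dataset(dataset, target_scheme="dipeptide")
history = run_active_learning(
    mats.X_pool, mats.y_pool, mats.X_ext, mats.y_ext,
    strategy="curiosity", rng_seed=0,
)
print(history.to_frame().tail())
```
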