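# tmactive

Active learning for transmembrane (TM) helix prediction.

About 30% of genes encode membrane proteins, but only a tiny fraction have
experimentally determined structures — labeling a protein (resolving which
residues cross the bilayer) is expensive. `tmactive` implements a pool-based
active-learning pipeline that chooses a *minimal* set of proteins whose
labels, once revealed, train an accurate TM-helix predictor for the rest of
the pool.

## The method

1. **Property windows.** Each sequence is expanded into five categorical
   property tracks (charge, polarity, aromaticity, electronic property,
   size). A window of length *l* = 16 slides one residue at a time; window
   *i* yields a count vector R<sub>i</sub> = (C<sub>i1</sub>, …,
   C<sub>i16</sub>), where C<sub>ij</sub> counts how many window residues
   take property value *j*. The 16 coordinates partition into 5 groups, each
   summing to *l* exactly.
2. **Latent space.** All window vectors of the pool are stacked into a
   matrix A and factored A = U S Vᵀ; every window (pooled or new) is
   projected as Uᵀ R<sub>i</sub>, truncated to the top *k* = 4 dimensions,
   which typically carry the bulk of the variance ("energy",
   S<sub>j</sub>²/ΣS²).
3. **Clustering.** A 5×10 hexagonal self-organizing map (50 nodes) is
   trained once on 1000 randomly sampled projected windows; every window of
   every protein is then assigned to its nearest node.
4. **Selection strategies.** Per iteration one unlabeled protein is picked:
   *random* (passive baseline); *node-coverage* (density: most SOM nodes not
   yet covered by the labeled set); *confusion-rated* (uncertainty: highest
   mean node entropy E = −p₀log₂p₀ − p₁log₂p₁ over the protein's windows,
   where p₀/p₁ are the TM/non-TM fractions of a node's labeled windows);
   or *alternating* between the two.
5. **Classifier.** Windows wholly inside a TM segment are class +1, wholly
   outside −1, mixed windows are excluded. A 4-4-1 feed-forward network
   (tanh hidden and output units) is retrained from scratch after every
   selection. At prediction time each window firing above θ = 0.4 marks the
   8 residues at its start as TM; overlapping blocks union.
6. **Evaluation.** Segment-level benchmark metrics: Q_ok (% proteins with
   all segments correct), segment recall Q_obs^htm and precision
   Q_pred^htm (a predicted and an observed segment match if they share ≥ 3
   residues, matched one-to-one), their geometric mean F = √(recall ·
   precision), and residue accuracy Q₂.

Real structure databases are deliberately not required: the
`synthetic_data` module generates alpha-helical membrane-protein-like
sequences (hydrophobic TM stretches of 17–25 residues alternating with
polar loops, gold labels included), so the entire pipeline runs and is
tested fully offline.

## Worked example

```python
from tmactive import GeneratorParams, RunConfig, generate_dataset, run_active_learning
from tmactive.pipeline import prepare_study

config = RunConfig()
pool_records = [rec for rec, _ in generate_dataset(GeneratorParams(160, seed=1))]
test_records = [rec for rec, _ in generate_dataset(GeneratorParams(40, seed=500_001))]
pool, test, svd, som = prepare_study(pool_records, test_records, config, seed=1)

print(f"top-4 latent dimensions carry {100 * svd.energy_retained():.1f}% of the energy")
curve = run_active_learning(pool, test, strategy="coverage", n_iterations=3,
                            n_nodes=som.n_nodes, seed=1)
for it, (pid, rep) in enumerate(zip(curve.selected_ids, curve.reports), 1):
    print(f"iteration {it}: picked {pid} -> {rep}")
```

prints

```
top-4 latent dimensions carry 97.8% of the energy
iteration 1: picked syn0132 -> Qok=90.0% F=98.9% recall=98.9% precision=98.9% Q2=86.2% (n=40)
iteration 2: picked syn0005 -> Qok=82.5% F=98.1% recall=97.4% precision=98.9% Q2=85.7% (n=40)
iteration 3: picked syn0004 -> Qok=82.5% F=98.1% recall=96.8% precision=99.5% Q2=85.7% (n=40)
```

Already after one node-coverage-selected training protein the classifier
reaches a held-out segment F-score near 99% on the (cleanly separable)
synthetic pool — the signature behaviour of density-based selection: a
single protein covering many SOM nodes spans enough of the feature space to
train the network. Q₂ sits in the mid-80s because decoding marks 8-residue
blocks, which systematically shortens predicted segments relative to the
17–25-residue true helices without hurting segment-level matching.

The same study is available from the shell:

```bash
tmactive synth --n 160 --seed 1 --out-dir data/
tmactive run --strategy coverage --iterations 10 --repeats 10 --seed 1 --workdir runs/cov
tmactive report --curve runs/cov/curve.csv
```

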