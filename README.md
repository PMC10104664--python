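# pephat

Peptide secondary-structure prediction for short sequences (roughly 30–100
residues), built around three ideas:

1. **Hypergraph attention over the sequence.** A peptide is converted into a
   hypergraph whose hypernodes are overlapping residue groups (pairs by
   default — 400 possible tokens over the 20 amino acids) and whose
   hyperedges are longer overlapping fragments. A two-level multi-head
   attention network (node → edge, edge → node) propagates information at the
   residue-group and fragment scales simultaneously.
2. **Channel fusion.** The hypergraph features, scattered back to residues,
   are fused by element-wise multiplication with a per-residue embedding
   channel (one-hot, learned lookup, or an injected table of precomputed
   vectors, e.g. exported from a pretrained protein language model), then
   passed through a bidirectional LSTM.
3. **A CRF head with per-position transitions.** Emission scores e(y_i, i)
   and transition scores t(y_{i−1} → y_i) define a linear-chain conditional
   random field over label paths; the transition matrix at each position is a
   convex fusion (weight λ) of a global L×L matrix with a local matrix
   predicted from the encoder output. Training minimizes
   −log P(y|x) = log Z(x) − S(y) with the exact forward recursion; prediction
   uses Viterbi dynamic programming.

Labels are 3-state (helix H, strand E, coil C) or 8-state DSSP
(H, G, I, E, B, T, S, C, reduced to 3 states by the standard
H,G,I→H; E,B→E; T,S,C→C convention). Evaluation reports per-state and
overall accuracy, per-state F1 and macro-F1, and the SOV'99 segment-overlap
measure.

The package is pure Python on NumPy (the network runs on a small built-in
reverse-mode autodiff engine), so it installs and trains offline on a single
CPU. A synthetic-data module generates labeled peptides from a first-order
Markov chain over states — or from a deterministic motif rule for recovery
experiments — making every stage testable without downloads.

## Worked example

```python
from pephat import (GeneratorConfig, ModelConfig, TrainConfig, PeptideRecord,
                    generate_dataset, evaluate_dataset)
from pephat.pipeline import train, predict

train_data = generate_dataset(GeneratorConfig(
    n_sequences=100, mode="motif_rule", motif_window=3, seed=1))
test_data = generate_dataset(GeneratorConfig(
    n_sequences=30, mode="motif_rule", motif_window=3, seed=2))

ckpt = train(ModelConfig(), train_data,
             TrainConfig(epochs=10, seed=0, target_val_acc=97.0))
preds = predict(ckpt, [PeptideRecord(r.id, r.sequence) for r in test_data])
report = evaluate_dataset([(r.labels, p.labels)
                           for r, p in zip(test_data, preds)])
print(f"held-out accuracy: {report.acc:.2f}%")
print(f"held-out SOV:      {report.sov:.2f}%")
```

prints (exactly this, with these seeds):

```
held-out accuracy: 98.35%
held-out SOV:      93.75%
```

In motif-rule mode each label is a fixed deterministic function of the
3-residue window around it, so the Bayes-optimal accuracy is 100%; reaching
~98% on held-out peptides after 4 epochs shows the full pipeline —
hypergraph attention, fusion, Bi-LSTM and CRF — recovers local sequence
signal. SOV is the segment-level score: 93.75% means predicted
helix/strand/coil segments align with the true segments up to small
boundary shifts. The `examples/` directory has one short narrative script
per capability (data generation, hypergraph attention, exact CRF inference,
training, metrics).

## Command line

```bash
pephat synth    --config run.yaml --out-prefix data/
pephat train    --config run.yaml --fasta data/seqs.fasta \
                --labels data/labels.fasta --out model.ckpt
pephat predict  --checkpoint model.ckpt --fasta new.fasta --out pred.ssfa
pephat evaluate --checkpoint model.ckpt --fasta data/seqs.fasta \
                --labels data/labels.fasta --out report.tsv
```

Sequences and label strings travel as FASTA / FASTA-like files; precomputed
per-residue embeddings as TSV (`id  position  v0..v{d-1}`) or HDF5.

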