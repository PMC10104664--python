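# Methods

## Model

A peptide `x = x_1 … x_n` over the 20 canonical amino acids is labeled with
per-residue secondary-structure states `y_i` from a 3-state (H/E/C) or
8-state DSSP alphabet. The predictor composes four stages.

### Hypergraph construction

A sliding window of width `fragment_len` (default 8) and stride
`fragment_stride` (default 4) cuts the sequence into fragments; a smaller
window of width `group_len` (default 2) and stride `group_stride`
(default 1) cuts it into residue groups. Groups are hypernodes, fragments
are hyperedges, and a node belongs to an edge iff its residue span is fully
contained in the edge span. All spans are 0-based half-open.

Tail handling: whenever the last full-stride window does not reach the
sequence end, one extra window anchored at the end (`[max(0, n−w), n)`) is
appended, so fragments cover every residue for any sequence length.
Validity constraints on the configuration guarantee the structural
invariants for every sequence:

* `fragment_stride ≤ fragment_len` — fragments cover all residues;
* `group_stride ≤ group_len` — groups cover all residues;
* `group_stride ≤ fragment_len − group_len + 1` — every fragment contains
  at least one group.

A fourth bound, `fragment_stride ≤ fragment_len − group_len + 1`, makes
consecutive fragments overlap enough that *every* group window is contained
in some fragment regardless of length; the default configuration satisfies
it (4 ≤ 7), it is exposed as `HypergraphConfig.guarantees_node_coverage`,
and extraction raises if a config outside that bound produces an uncovered
node on a particular sequence.

Node identity is positional; the node's token (its residue-pair string, 400
possibilities for pairs, plus one shared wildcard token) indexes a learned
embedding shared across positions and sequences.

### Two-level hypergraph attention

Each of `n_layers` (default 2) layers runs two passes with LeakyReLU
(negative slope 0.01) as the activation σ:

* **Node → edge, multi-head** (`n_heads` default 4). Per head m, member k of
  edge j is scored by `a_m · σ(W_m h_k)`; softmax over the edge's members
  gives α_jk, and the head's edge representation is
  `σ(Σ_k α_jk W_m h_k)`. Heads are concatenated and compressed to
  `edge_dim` by a bias-free linear map `W_d` (no bias keeps the all-zero
  parameter case exactly zero, a useful degenerate test point).
* **Edge → node.** For node i and incident edge j,
  `V_ij = σ([W_fragment f_j ‖ W_residue h_i])` with
  `W_residue = (‖_m W_m)·W_d`; softmax of `a_fragment · V_ij` over the
  incident edges gives β_ij and the new node state is
  `σ(Σ_j β_ij W_fragment f_j)`. The score must depend on the receiving
  node, so V is indexed per (node, edge) pair — the only reading that
  type-checks.

All softmaxes use max-subtraction; α and β rows are probability
distributions to within 1e-6 by construction (property-tested). Node and
edge dims default to 64. The last layer's α/β are returned for
interpretability.

### Fusion and Bi-LSTM

Hypergraph node states are scattered to residues by averaging the states of
all nodes covering a position. The per-residue embedding channel is
pluggable: one-hot (dim 20), a learned 21-row lookup (20 residues plus a
wildcard), or an injected precomputed table, which is how vectors from an
external pretrained protein language model enter; no transformer is run or
needed inside the package. Both channels are linearly projected (with
biases) to a common width (default 64) and fused by element-wise
multiplication — projections are required whenever the channel widths
differ, and the multiplicative interaction is the package's fusion rule. A
single bidirectional LSTM (hidden 64 per direction, gate order i/f/g/o,
forget-gate bias 1) yields the encoder output of width 128.

### CRF head

Emission scores are a linear map of the encoder output to L states. The
transition slice for the step i−1 → i is
`(1 − λ)·G + λ·local(enc_{i−1})` where G is a global L×L matrix, `local` a
linear map to L² reshaped to L×L, and λ (`lambda_local`, default 0.5, fixed)
balances the global matrix against the per-position local one. The local
matrix is derived from the left endpoint of the step, so the last encoder
row influences only its emission. Learned start/end score vectors complete
the path score

    S(y) = Σ_i e(y_i, i) + t_start(y_1) + Σ_{i≥2} T_{i−1}(y_{i−1}, y_i) + t_end(y_n).

Training minimizes `log Z(x) − S(y_true)` with the forward recursion done
entirely in log space (log-sum-exp with max-subtraction; the literal
sum-of-exponentials form of the partition function is never materialized).
Viterbi decoding fills score (δ) and back-pointer (ψ) tables and breaks
ties toward the lowest state index, making prediction fully deterministic.

## Autodiff and optimization

No tensor-autograd framework is assumed: the network runs on an in-package
reverse-mode engine over float64 NumPy arrays (`pephat.autodiff`),
supporting broadcast arithmetic, matmul, gather, segment-sum and
segment-softmax (the hypergraph primitives), the pointwise nonlinearities,
and a stable log-sum-exp. Gradients are verified against central finite
differences in the test suite. Training uses Adam (lr 1e-3), mini-batches
of 8 sequences via gradient accumulation (each sequence keeps its own
hypergraph; no cross-sequence edges), gradient clipping at global norm 5, a
seeded 10% validation split, and an optional validation-accuracy early
stop. A non-finite loss aborts with the offending epoch/batch/record named.

## Synthetic data

The generator emulates the study conditions: peptide lengths uniform on
30–100, 3-state labels.

* **markov** — labels follow a first-order chain with sticky diagonal
  (0.80/0.80/0.75), giving mean segment runs of ≈4 residues (realistic
  3–8 range); residues are drawn from state-conditional distributions that
  up-weight helix formers (A,E,L,M,Q,K,R,H) under H, strand formers
  (V,I,Y,C,W,F,T) under E and coil formers (G,N,P,S,D) under C, a
  propensity-style association.
* **motif_rule** — residues are uniform i.i.d.; the label at i is a fixed
  deterministic vote over the width-3 window (each residue votes for
  `alphabet_index mod 3` weighted by proximity to the center; argmax, ties
  to the lowest state). The Bayes accuracy is 100% by construction, making
  this the recovery benchmark.

One integer seed drives everything; per-sequence streams are derived by
keyed seed-sequence spawning so record i's content is independent of how
many records are generated.

What the generator does *not* model: real residue–structure statistics from
PDB-derived data, long-range contacts, chain-break artifacts, class
imbalance across datasets. Passing the recovery benchmark therefore shows
the architecture and optimizer can extract local sequence→structure signal
end to end; it says nothing about accuracy on curated experimental
benchmarks, which additionally require pretrained-language-model embeddings
supplied via the precomputed-table channel.

## Problem sizes and numerics

The recovery benchmark trains on 300 sequences and evaluates on 60 (about
3,900 residues), with at most 30 epochs and early stop at 97% validation
accuracy; it typically converges in 2–4 epochs. Exact-inference checks use
n ≤ 6, L = 3 so all 3^n paths can be enumerated; normalization tolerances
are 1e-6. Metrics follow the SOV'99 definition with `int(·)` implemented as
floor; reference segments without an overlap partner contribute their
length to the normalizer and nothing to the numerator (required for the
all-H vs all-C case to be 0); dataset SOV pools numerators and normalizers
across sequences before dividing (per-sequence values are available by
evaluating pairs individually). Macro-F1 averages over states present in
the reference; a state neither predicted nor present is excluded, and 0/0
F1 is defined as 0. Overall accuracy equals the state-frequency-weighted
mean of per-state accuracies exactly (identity-tested).

## Known limitations

* Training is sequential per sequence (no vectorized batching across
  sequences), which is fine at desk scale but slow for corpora of many
  thousands of peptides.
* λ is a fixed hyperparameter rather than learned; making it trainable is a
  one-line change but was not needed for the benchmarks here.
* The 8-state pipeline is fully supported by the alphabets, metrics and CRF
  (64 transition features), but the built-in Markov generator defaults are
  3-state; 8-state generation requires supplying the chain matrices.
* Checkpoints are NumPy archives tied to the package's parameter ordering;
  a version field guards against loading mismatched formats.
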