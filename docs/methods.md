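# Methods

## Attribution model

The package explains predictions of encoder-decoder attention models by
decomposing gradient-weighted cross-attention. The unit of capture is one
attention layer: its post-softmax attention tensor `A` (heads × queries ×
keys), the projected query and key activations `Q`, `K`, and the
gradients of a scalar target score with respect to all three. Layers are
recorded from the output backwards, so "the first cross-attention layer
seen from the output" is always index 0 regardless of model depth.

**Target score and gradient sign.** The scalar differentiated during
capture is the target log-likelihood: `log p(c)` for a classification
target, or the summed log-probability of the target tokens for an
autoregressive model (the natural scalarization of a generative binder
model that estimates one chain's conditional probability given the
others). With this convention a positive attention gradient marks
evidence *supporting* the target, which is what the ReLU in the
importance map is meant to retain, and the perturbation metrics (which
measure the *drop* in target probability when top-ranked tokens are
masked) are consistent with the attribution: tokens with high scores are
tokens whose removal lowers the probability. Differentiating the
negative log-likelihood instead would flip every gradient's sign and
make the ReLU discard exactly the supporting evidence.
`compute_target_loss` still reports the conventional negative
log-likelihood as the loss value.

**Per-layer decomposition.** The importance map is
`S(A) = E_H[ReLU(∂L/∂A ⊙ A)]`, the GradCAM-style product of attention
weight and its gradient, head-averaged. The identity matrix modelling
the residual connection is added only when the map is square: for
cross-attention, query and key sequences differ, no residual connects
them, and `I` is not even defined for `N ≠ N′`.

The key side reads relevance directly off the map's columns (attention
already maps queries into key space): `ω^A′_j = max_i S(A)_{ij}`. The
query side cannot, because the map's rows mix all keys; instead the
approximate factorization `A ≈ QK^⊤` (softmax and the `1/√d` scale
treated as an approximation, applied to the post-softmax map) is undone
with the Moore-Penrose pseudoinverse: `X = S(A) · pinv(K^⊤)`, which
equals `S(A)·K(K^⊤K)^{-1}` and recovers the query factor exactly
whenever `K` has full column rank. The SVD-based pseudoinverse
(`rcond = 1e-10`) keeps rank-deficient keys well-defined; a condition
number above `1e8` logs a warning. The projected matrix may contain
negative entries, so a ReLU is applied before the per-token feature
maximum — this keeps the attention-conditioned score comparable with the
intrinsic score and keeps everything in the nonnegative cone that the
max/product aggregation relies on.

Both sides are combined with their intrinsic GradCAM-style scores
(`max_d ReLU(∂L/∂Q ⊙ Q)`, same for `K`) by element-wise maximum: the
strongest attribution from either source wins. Per-token scores are the
maximum *value* over the feature dimension, not the index — relevances
must be aggregable reals.

**Cross-layer aggregation.** Walking from the output backwards, the
query chain of the decoder accumulates `S(Q;A)` factors by element-wise
product (the chain rule through stacked blocks acting on the same token
axis); branches from different decoder blocks that converge on the same
key sequence merge by element-wise maximum. A literal element-wise
product between a key-side vector (length N′) and the downstream
running score (length N) is dimensionally undefined, so product applies
along a chain on the *same* sequence and max across converging branches
— the only reading under which both recursion rules are well-typed.
By default aggregation stops at the encoder boundary; an optional
`chain_encoders` flag further modulates each key sequence's scores by a
rollout pass through that sequence's encoder self-attention stack.

Reported scores come in two scales: raw, and a per-sequence min-max
normalization to [0,1] used for percentile metrics and cross-method
comparison. Normalization never changes ranking; a constant score vector
normalizes to zeros.

## Baselines

Raw attention (last layer's head-averaged attention, column-summed over
queries), attention rollout (product over layers of row-normalized
`0.5·(A+I)`, the residual weight of the method's convention), and
gradient-weighted attention (last layer's `E_H[ReLU(∂L/∂A ⊙ A)]`,
column-max — the key path of the main method with no query
decomposition, no pseudoinverse, no aggregation). On encoder-decoder
benchmarks these conventionally see only the self-attention stacks, each
chain scored from its own encoder; `gradcam_attention` accepts arbitrary
records, so it can also score a single cross-attention layer directly.

## Structural ground truth

Complexes are parsed with gemmi (PDB and mmCIF; model 1 of multi-model
files). Hydrogens are dropped and alternate locations resolved to the
highest-occupancy conformer — crystal structures rarely resolve H, so
"closest atom" means closest heavy atom. Inclusion filters: both TCR
chains present, peptide non-empty and fully resolved, every residue of
both CDR3 ranges present with atoms, peptide and MHC chain IDs distinct.
Filters return decisions with reasons, and the benchmark builder logs
every rejection so curation is auditable.

CDR3 ranges come from the manifest as explicit author-numbering
intervals; automatic germline numbering is deliberately out of scope
(keeps the module deterministic and dependency-free). Distances are
exact minimum Euclidean atom-pair distances (scipy `cdist`): each CDR3
residue against all peptide atoms, each peptide residue against the
union of CDR3α and CDR3β atoms (the regions the sequence models see; a
config switch can widen the target set when CDR1/2 ranges are
provided). Binding labels threshold these distances, swept 3-6 Å in
0.5 Å steps.

## Evaluation metrics

*ROC-AUC*: residues pooled across samples (one global curve per
threshold, the default) or averaged per sample behind a flag. A
threshold yielding a single class reports NaN with a warning.

*BRHR*: for fraction t, select `ceil(t·L)` residues by score (ties to
the lower position); a hit is a selected residue whose distance is
within the `ceil(t·L)` smallest — "top fraction of interaction
distances" reads as *smallest* distances because smaller distance means
stronger interaction. Distance ties at the cut all count as hits, which
favors no method systematically. The benchmark value is the mean over
samples. The metric depends on score ranks only.

*LOdds / AOPC*: re-run the model with the k highest-scoring tokens of
one chain replaced by the padding token. LOdds is the change in target
log-odds (more negative = better explanation); AOPC is the mean drop in
target probability over nested perturbations k = 1..K (higher =
better). Probabilities are clipped to `[1e-12, 1-1e-12]` with a warning.
Defaults k=4 for the CDR3 chains and k=7 for peptides, matching the
average number of contact residues per chain in TCR-pMHC interfaces.
Exact formulas are unit-tested against closed forms.

## Synthetic fixtures

The fixture module generates everything the test suite and the demo
pipeline consume; it emulates the *shape* of the real problem, not its
biology.

*Toy transformer* — a NumPy encoder-decoder with per-sequence
self-attention encoders, cross-attention decoder blocks, and a pooled
readout; forward and backward passes are written out analytically, and
the captured gradients match central finite differences to ~1e-11. All
weights derive from one seed. In *planted* mode the output is an exact
function of the embeddings at chosen key positions only: the planted
block's queries and keys come from positional encodings, its values are
zero outside the planted positions (squared projections, so
nonnegative), encoders pass inputs through, and the readout sees only
the planted block — so ablating any non-planted token changes the
output by exactly zero, giving an unambiguous recovery target.

*Planted complexes* — residues as single pseudo-atoms on a lattice with
10 Å spacing (the background distance); designated contact pairs sit at
3.5 ± 0.1 Å. Chains: TCRα/TCRβ with 3-residue flanks outside the CDR3
range, a 9-mer peptide (MHC-I-like), and a short far-away MHC chain.
Written as standard PDB text parseable by independent readers.

*Score/distance pairs* — distances uniform on [2, 10] Å; scores drawn
through a Gaussian copula with Pearson `ρ = 2·sin(π·r/6)` so the
Spearman rank association hits the requested r (exact monotone at ±1).

What passing tests on these fixtures shows: the formulas are computed
correctly, planted dependence is recovered, metrics behave at controlled
associations, and the pipeline is deterministic. What they do not show:
performance on a trained binding model or real crystal structures —
fixture attention is near-uniform, real interfaces are not lattices, and
real models entangle chains in ways the planted construction
deliberately avoids.

## Numerical and scale choices

Default toy sizes (d_model 16, 2 heads, 1 encoder layer, 1 decoder
round; CDR3 lengths 10-16, peptide 9) keep the full test suite and the
acceptance script within seconds on one CPU while exercising every code
path, including multi-head averaging and multi-block aggregation.
Embedding/positional/weight scales (0.6 / 0.05 / 0.3) keep softmax
attention away from saturation so gradients stay informative. Row
stochasticity is validated at 1e-5; rollout row sums at 1e-6; the
pseudoinverse recovery oracle at 1e-8 (observed ~1e-13). The planted
toy's positional-only keys keep the intrinsic key-gradient term orders
of magnitude below the planted attention signal, so recovery is strict
rather than statistical.

## Limitations

- The `A ≈ QK^⊤` factorization behind the query projection ignores
  softmax and the `1/√d` scale; the projection is applied to the
  post-softmax importance map and is exact only in the linearized sense.
- Value matrices and feed-forward sublayers are not attributed; the
  method speaks only about attention.
- The recursion through encoder self-attention below the first decoder
  layer is heuristic (rollout-style, off by default).
- Distance-as-importance is a proxy: residues can matter for folding or
  stability without being interface-proximal.
- The CLI drives the bundled toy model; attaching a production model
  means implementing the small capture protocol in `qcai.adapter`
  (one `capture()` method returning validated records).
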