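# Methods

## The model

`contextgo` treats a phage contig as a sentence whose tokens are its
proteins in genomic-coordinate order. Each protein is first reduced to
a fixed-width vector (a pooled per-residue embedding; see *Embeddings*
below). For a sentence of *n* proteins the token matrix is
`X ∈ R^{n×d_e}`; a learned position embedding `P[i]` is added to token
*i*, and the sum passes through `n_layers` Transformer blocks:

* **Multi-head self-attention.** Three independent linear maps produce
  Q, K, V; per head, `Attention(Q,K,V) = softmax(QKᵀ/√d_k)·V` with
  `d_k = d_e/n_heads`; head outputs are concatenated in head order and
  mapped by the output matrix `W^M ∈ R^{d_e×d_e}`. Padded token slots
  are excluded from the softmax (weight exactly 0), so attention rows
  sum to 1 over real tokens and padding can never change a real
  protein's score.
* **Feed-forward.** A two-layer ReLU MLP of hidden width `d_ff`
  (default `2·d_e`), applied per token.

Both sub-blocks are wrapped in residual connections. There is no layer
normalisation: at the widths this package targets the network trains
stably without it, and omitting it keeps the hand-written backward pass
short and exactly checkable against finite differences (a unit test
does precisely that). A consequence that matters for initialisation:
position embeddings must be initialised at unit scale, because with no
normalisation a 0.02-scale init cannot compete with token vectors of
norm ≈ √d_e and position information then takes implausibly long to
surface through the optimiser.

The final token representation feeds a linear layer with sigmoid
activation giving an *m*-vector of per-term scores in (0,1), where *m*
is the size of the ontology's label vocabulary. Training minimises the
multi-label binary cross-entropy — mean over proteins of the per-label
cross-entropy summed over the vocabulary — with Adam. One model is
trained per ontology (BP/CC/MF). All randomness (init, batch order,
validation split, dropout) flows from the single `seed` in
`ModelConfig`; two runs with the same seed produce identical histories.

Sentences longer than `max_sentence_len` (default 128) are split into
overlapping windows (overlap 32, stride = length − overlap; the last
window is left-shifted to stay full). Each protein's prediction is read
from the window where it sits most centrally (ties to the earlier
window); position indices are per-window. Whole-genome capacity and the
windowing policy are artifact choices — the underlying method is
agnostic to how long inputs are chunked.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `d_e` | 1280 | width of the large ESM2-33 backend (480 for the base ESM2-12 backend; 32 in the synthetic study) |
| `max_residues` | 1024 | ESM2's context window; N-terminal prefix kept when truncating (common PLM practice; the choice of end is a convention) |
| `n_layers`, `n_heads` | 2, 4 | smallest stack that can express pairwise context relations; configurable |
| `learning_rate` | 1e-4 | conservative default for large-width training; the desk-scale experiments use 1e-2, which the smaller width tolerates and which converges in ~150 epochs |
| `max_sentence_len` / overlap | 128 / 32 | covers virtually all phage genomes in one window |
| up-propagation of scores | off | the trained model tends to learn the parent ≥ child ordering implicitly; the projection (`up_propagate_scores`, exact max over in-vocabulary descendants) is exposed as a flag |
| vocabulary `min_count` | 200 | a label needs enough support to be learnable and evaluable; configurable (1 in the small synthetic studies) |
| β grid | 0.00…1.00 step 0.01 | tuned per ontology on validation protein-centric Fmax; ties resolve to the smallest β (prefer the alignment-free component only when it genuinely helps) |

### Embeddings

A backend maps a validated sequence (20 amino acids + X, `*` stripped,
capped at 1024 residues) to an `L×d_e` matrix. Poolers: `mean` and
`max` over the unpadded rows, and `fc` — one learned weight per residue
position, `x = Σ_{i<L} w_i·X₁[i]`, masked past the true length, which
reduces to the masked mean when all weights are 1/L. The fc weights are
linear in the loss, so their gradient is the inner product of the
token-gradient with the residue rows; they can be trained jointly with
the Transformer. A flattened `1024·d_e → d_e` dense map would need
~10⁹ weights; the per-position weighting is the parameter-light reading
of "an FC layer over the residue axis".

The `synthetic` backend derives a per-sequence RNG seed from a hash of
(seed, sequence), making embeddings bitwise reproducible and distinct
across sequences with overwhelming probability. The real ESM2 backends
import `esm`/`torch` lazily and raise a clear error naming the
synthetic fallback when the stack is absent.

## Evaluation

Protein-centric: at each threshold *t* of 0.01…1.00 (step 0.01, a term
counts as predicted at score ≥ *t*), per-protein precision
|P∩T|/|P| is averaged over the *n_t* proteins with at least one
prediction and recall |P∩T|/|T| over the proteins with a nonempty truth
set; Fmax is the maximum F1 of the two averages. Proteins with empty
truth are excluded from the recall average (the ratio is undefined) but
still count toward precision; when no threshold yields any prediction,
Fmax is 0 by convention. Micro AUPR concatenates all (protein, term)
pairs and uses the step-wise average-precision estimator
(scikit-learn). Term-centric: per-label Fmax over the same sweep and
per-label average precision, averaged over labels having at least one
positive; labels without positives are skipped with a warning, never
silently zero-filled. The per-label Fmax values are *averaged* (divided
by the number of evaluated labels) — treating the sum over labels as
unnormalised would make the statistic grow with vocabulary size.

Stratified reporting: labels are sorted by information content
(−log₂ training frequency, ties by GO id) and cut into three near-equal
groups; proteins are binned by best-hit identity against training data
into no-alignment, below-40%, and 40–100% (40.0 exactly goes to the
upper bin; identity only, coverage is not used in binning).

## Dataset construction

Genera are retained when the mean per-genome annotation rate (fraction
of proteins with ≥1 GO term) reaches the ontology's threshold
(inclusive; 30% is the usual choice for BP/MF and 20% for CC, where
annotations are scarcer); single-genome genera are excluded as
untrainable. All-vs-all DIAMOND hits (e ≤ 0.001, self-hits dropped, max
bitscore over the two directions as the symmetric edge weight) form a
similarity graph, clustered by MCL: the column-stochastic transition
matrix alternates expansion (squaring) and inflation (elementwise power
2.0 then column renormalisation, with pruning at 1e-9) to convergence
(tol 1e-6, ≤100 iterations); self-loops at each node's maximum incident
weight regularise the iteration; clusters are connected components of
the limit support read from attractor rows. Clusters are drawn in
seeded random order into training until the cumulative protein count
reaches 80% (stopping at ≥ target keeps train ≥ 80% while leaving the
held-out pool nonempty at exact boundaries); the held-out pool is then
halved into validation/test by grouping proteins on their exact
annotation signature and alternating assignments within each group,
which bounds the per-signature imbalance by one. No cluster ever spans
the train/held-out boundary.

## The synthetic corpus

The generator emulates the statistical structure the pipeline needs —
not protein biophysics. A layered random GO DAG (one root per
namespace, 1–2 `is_a` parents per term from the layer above) places the
deepest-layer terms as *classes* with power-law target frequencies
(exponent `label_imbalance`, mirroring real GO term imbalance). Each
genus draws a canonical class order i.i.d. from that distribution;
genomes of the genus realise the order with rare adjacent swaps
(probability 0.05 per junction), emulating the conserved-but-not-exact
gene order of real genera. A protein's annotation is the propagated
ancestor closure of its class term.

Informative proteins get `centroid[class] + N(0, σ²I)` vectors
(unit-scale Gaussian centroids, σ = 0.25 — small against the ≈ √(2·d_e)
centroid separation, so a nearest-centroid rule is near-perfect at
κ = 0). The planted signal: a fraction κ of the genome's slots —
conserved within the genus, never slot 0, non-adjacent when feasible —
are *context-only*: their vector is pure background noise while their
label stays that of their canonical slot. Their function is thus
recoverable only by recognising the genus from neighbouring proteins
and reading off the conserved order; a single-protein model is
structurally blind to them (at κ = 1 with σ = 0 its inputs are
literally zero). Keeping slot 0 informative guarantees at least one
anchor token per genome.

What passing the recovery experiment shows — and what it does not: on
the default conditions (6 genera × 10 genomes × 10 proteins, d_e = 32,
12 DAG terms, κ = 0.5, corpus seed fixed) full-sentence training beats
the single-protein ablation by ≈ 0.13–0.15 held-out term-centric AUPR,
monotonically in context length 1 → 2 → 10. This demonstrates that the
architecture can extract a genuine neighbour-borne signal end to end.
It does not certify performance on real phage data, where the context
signal is statistical rather than deterministic, embeddings carry
partial homology information, and label noise exists. Synthetic FASTA
sequences are random (they exercise file round-trips, not biology), and
alignment bitscores are not simulated beyond what the hybrid tests
construct directly.

## Numerical notes

* Softmax is computed with max-subtraction; the sigmoid uses the tanh
  form, safe against overflow for extreme logits.
* BCE clips probabilities at 1e-12 for the loss value; gradients use
  the exact `(score − target)` logit form.
* Attention-row normalisation is asserted to 1e-6 in tests; padding
  invariance likewise at 1e-6 (float64 throughout, typically ~1e-15).
* `up_propagate_scores` runs in one bottom-up topological pass, which
  is already the fixed point (verified against exhaustive
  transitive-descendant maxima).
* MCL is deterministic for a fixed graph; ties in cluster membership
  are resolved by the connected-component merge of overlapping
  attractor rows. Degenerate inputs: an empty graph yields no
  clusters; an isolated node becomes a singleton.
* Fmax of an all-zero score matrix is 0 by convention (no threshold
  produces a prediction); metric functions raise on inputs where every
  label/protein would be skipped rather than return a vacuous number.

## Known limitations

* The per-position FC pooler assumes a fixed residue cap; sequences are
  truncated N-terminally, and C-terminal signal beyond 1024 residues is
  invisible to all backends.
* β is a single scalar per ontology; no per-protein gating of the
  alignment component.
* The split balances validation/test by exact annotation signature;
  with many distinct multi-label signatures the per-term imbalance
  bound degrades gracefully but is no longer ≤ 1.
* Real-PLM backends run but are untested in this repository's suite
  (they require `esm`/`torch` at run time); the synthetic backend is
  the tested path.
* Cross-namespace relations (`part_of`, `regulates`) are deliberately
  ignored everywhere; only `is_a` defines ancestry and consistency.
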