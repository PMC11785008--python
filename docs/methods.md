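# Methods

This note documents the model, the training objective, the search pipeline,
the synthetic data generator, and the numerical and design choices behind
them. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Embedding model

The embedder is a 1-D residual convolutional stack over amino-acid
sequences. A learnable lookup table maps each of 21 symbols (20 canonical
amino acids plus one catch-all `X`; non-canonical letters B, Z, U, O, J
collapse to `X`) to a d-dimensional vector. Each of `n_blocks` residual
blocks then computes `x + Conv2(ELU(Conv1(ELU(x))))`, with two independent
length-preserving convolutions per block (kernel size `kernel_size`,
symmetric zero padding of `(kernel_size−1)/2`) and no weight sharing
anywhere. There are no normalization layers and no input/output projections
beyond the lookup: the block equation contains only convolutions and
activations, and the default parameter count (7,349,504 = 21·256 + 8·2·
(7·256² + 256), which rounds to 7M) is consistent with that minimal layout.

Key consequences, both tested as properties:

- **Length preservation** — the output has exactly one row per residue; there
  is no pooling.
- **Locality** — one output row depends on at most
  `1 + 2·n_blocks·(kernel_size−1)` input residues (97 for the defaults).
  Embeddings carry local context only; two residues in identical 97-residue
  windows embed identically regardless of the rest of the sequence.

Defaults: `embed_dim=256`, `n_blocks=8`, `kernel_size=7`, ELU activation.

Initialization is fan-in scaled: lookup entries N(0, 1/√d) so initial
residue vectors have roughly unit norm, conv weights N(0, 1/√(k·d)), zero
biases, all drawn from a caller-supplied seed. Every tested property holds
for any initialization; the scheme only affects optimization speed.

The network, its backward pass, and the optimizer are implemented directly
in numpy. The forward/backward code is small (one convolution primitive, one
block), runs in float64, and is verified against central finite differences
at 1e-10 absolute error in the test suite.

## Training objective

Supervision comes from pairwise alignments of homologous sequences. For a
pair (A, B), the target matrix `T` has `Tij = 1` exactly when residues Ai
and Bj share an alignment column (at most one per row and column; columns
strictly increasing in both coordinates). Both sequences are embedded
independently and the raw dot-product matrix `Dij = a⃗i·b⃗j` feeds a masked
N-pair loss plus L2 regularization:

    L = Σij −Rᵃi Rᵇj Tij log( e^{Dij} / Σw e^{Diw} )
        + (γ/n) ( Σi Rᵃi |a⃗i|² + Σj Rᵇj |b⃗j|² )

Numerical and interpretive choices:

- The softmax denominator runs over **all** residues w of B, masked or not;
  the repeat masks `Rᵃ, Rᵇ` multiply only the outer per-pair terms and the
  L2 contributions. This follows the loss formula as written; excluding
  masked residues from the denominator is a plausible variant we did not
  adopt.
- The loss is directional (softmax across B). A `symmetrized` option
  averages the A→B and B→A directions; it is off by default since the
  printed formula is one-directional.
- The L2 normalizer `n` is the number of unmasked residues in the pair
  (ΣRᵃ + ΣRᵇ), making the term a per-residue average that is stable across
  crop lengths.
- Softmax uses the standard log-sum-exp shift for stability.
- Although only aligned (i, j) pairs appear in the outer sum, the gradient is
  dense over the partner sequence: every residue in the softmax denominator
  receives signal, which is what pushes unaligned embeddings toward
  orthogonality. This is verified by finite differences.

Optimization uses AdamW (decoupled weight decay, β₁=0.9, β₂=0.999,
ε=1e-8). The batch loss is the mean of per-pair losses so learning-rate
semantics do not depend on batch size. Default recipe: 24,000 steps, batch
512, crop length 256, learning rate 1e-5, weight decay 1e-2, γ=5e-3.

Cropping to the configured sequence length: a window on A is drawn uniformly
among windows containing a randomly chosen aligned column; the window on B
spans the columns aligned inside it, clamped to the crop length; column
indices are re-mapped to the crops. Pairs whose alignment fits no window are
skipped with a warning. Training aborts with a diagnostic on a non-finite
loss.

## Repeat masking

Low-complexity and repetitive regions produce high similarity between
unrelated sequences, so masked residues (bit 0) are silenced at three
points: the training loss, target-index construction, and query-residue
selection. Masks normally come from an external repeat masker (tantan-style
lower-case FASTA, or BED intervals, both ingested directly). The built-in
fallback masker flags residue i when any window of `window` residues
(default 16, matching common masker settings) covering i has Shannon entropy
≤ `max_entropy_bits`. The default threshold of 1.5 bits flags homopolymer
runs (0 bits) and short-period repeats (≤1 bit for dimers) while leaving
typical protein windows (≈3.5–4 bits over 16 residues) untouched. The
fallback is a deterministic entropy rule, not a probabilistic tandem-repeat
model.

## Search pipeline

Target residue vectors (unmasked positions only) are L2-normalized and
indexed. Each unmasked query residue retrieves its k nearest neighbors by
cosine similarity (default k=150), each neighbor contributes
`max(0, cos − δ/√d)`, and contributions sum per (query, target) pair —
multiple residue matches against the same target all count. Hits are sorted
by query, then score descending, then target id.

- **Noise gate.** Cosine similarity between independent random
  d-dimensional vectors has standard deviation ≈1/√d, so the subtracted
  gate `δ/√d` has a consistent effect across dimensionalities; δ=3 cuts at
  about three standard deviations, removing ≈99.9% of chance similarities
  (the Monte-Carlo estimate in `scripts/acceptance.py` computes this
  number). The exponent on d is exposed (`gate_exponent`, default 0.5) for
  experimentation.
- **Exact backend.** A vectorized full cosine scan with deterministic
  tie-breaking (descending cosine, then (seq_id, position) lexicographic).
  Verified against an independent brute-force sort on randomized instances.
- **Quantized backend.** An inverted-file index: coarse k-means partitions
  the vectors into `nlist` cells (default ⌊√n⌋) and queries probe the
  `nprobe` nearest cells (default nlist/4); optional product quantization
  approximates in-cell similarities from per-subspace codebooks. It trades
  recall for speed; its recall against the exact backend is measured on the
  data at hand, never assumed. With exhaustive probing and no PQ it
  coincides with the exact backend, which the tests exploit as a contract
  check. It follows the IVF+PQ family of approximate indexes but is not a
  re-implementation of any particular library's layout.
- **Reversed orientation.** Optionally the queries are indexed and target
  residues probe them (useful when the target side is too large to index).
  Hits are keyed (query, target) either way; with exhaustive k the two
  orientations produce identical scores, which is tested. At moderate k the
  orientations differ slightly because the k-neighbor cut applies to
  different sides.
- Raw dot products drive training, but search scores use cosines; the two
  sections of the pipeline intentionally follow their respective
  definitions.

## Benchmarking

Truth labels stratify query–target pairs by alignment confidence:
`true_strong` (E ≤ 1e-10), `true_weak` (E ≤ 1e-3), `decoy_low_sim`
(E ≥ 10), `decoy_shuffled` (pairs against per-sequence residue
permutations), `unlabeled` (between the weak and decoy cuts; excluded from
both populations). Strong pairs count toward the weak stratum. Truth can be
supplied as an E-value table or as direct labels (what the simulator
emits).

The recall-vs-filtration curve sweeps thresholds over the distinct hit
scores, descending; at threshold t a pair is retained iff its score ≥ t.
Recall is the retained fraction of true pairs, filtration the removed
fraction of decoy pairs; truth pairs absent from the hit list score −∞ and
are never retained. `recall_at_filtration(curve, level)` returns the recall
at the smallest threshold whose filtration reaches the level (a step
function, no interpolation) — i.e. the best achievable recall at that
filtration. Decoy shuffling is a Fisher–Yates permutation per sequence,
conserving length and composition.

## Synthetic data generator

The simulator replaces curated homolog-pair datasets so the whole package is
testable offline. A common ancestor is drawn uniformly over the 20 amino
acids; each of two descendant copies independently applies, per ancestral
position: an indel event with probability `indel_rate` (insertion or
deletion with equal probability, lengths geometric with mean
`indel_len_mean`), then substitution with probability `sub_rate`, uniform
over the 19 alternatives. Ancestral positions surviving in both copies give
the true alignment columns, strictly increasing by construction. Expected
aligned-column identity is `(1−s)² + s²/19`, which the tests check against
simulation.

Defaults (`ancestor_len=256`, `sub_rate=0.3`, `indel_rate=0.05`,
`indel_len_mean=3`, `n_pairs=500`) emulate remote-but-detectable homologs at
≈50% expected identity. The generator does **not** model realistic
substitution matrices (BLOSUM), position-dependent rates, domain
architecture, or database cluster statistics; passing tests therefore show
that the pipeline learns and exploits alignment structure under a simple
uniform mutation process, not that it matches any particular tool's
behaviour on real protein databases.

The mini-benchmark generator gives each query one homologous target
(`true_strong`) plus unrelated targets of independent ancestry
(`unlabeled`), and shuffles every target into a decoy (`decoy_shuffled`);
the truth table covers the full cross product.

## Scaled-down training experiment

The end-to-end learning test (and the worked example in the README) uses a
deliberately small configuration chosen to demonstrate the training signal
quickly on one CPU: d=32, 2 blocks, kernel 7, 300 AdamW steps at batch 32,
crop 128, learning rate 1e-3, on 500 simulated pairs of ancestor length 150.
The larger learning rate compensates for the short schedule; the production
recipe (1e-5 over 24,000 steps at batch 512) is the package default. The
test asserts three effects on held-out simulated data: the 50-step smoothed
loss decreases; aligned residue pairs have a higher mean noise-gated cosine
than unaligned pairs; and recall at 90% shuffled-decoy filtration on a
50-query benchmark is at least 3× the 10% no-skill level (the observed value
is ≈0.98).

## Degenerate inputs and edge rules

- Empty sequences and non-alphabetic characters are rejected at encoding.
- Zero-vector residues are guarded with an ε during normalization.
- k-NN with fewer than k indexed vectors returns all of them.
- An index with zero unmasked residues is an error; a query whose residues
  are all masked simply contributes no matches.
- Accumulated hits with score 0 are retained when they have ≥1 match.
- Simulated pairs that come out empty (extreme indel settings) are resampled
  up to a retry cap, then rejected.

## Known limitations

- The embedder sees only local context (97 residues by default); it cannot
  represent long-range structural constraints.
- The accumulated score is uncalibrated — no E-value statistics are attached
  — so thresholds are chosen empirically per database.
- The quantized backend's recall depends on the data distribution and the
  probe budget; it is a desk-scale stand-in for production ANN indexes.
- Training-time and search-time masking use the same machinery; whether an
  external masker should run with identical settings in both roles is left
  to the user.
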