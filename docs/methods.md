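# Methods

This note documents the model as implemented, the synthetic data it is
validated on, and the numerical and design choices made where the design was
genuinely open.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model

**Inputs.** Drugs are described by one or more binary descriptor views
(drug × descriptor, entries 0/1) and a labeled interaction table
`(i, j, event_class)` with classes `1..C`.  Each view is converted to an
all-pairs Jaccard similarity matrix; a drug with an all-zero descriptor row
has no similarity evidence and receives similarity 0 everywhere (including
its own diagonal), with a warning, rather than the 0/0 the formula would
produce.  Views are concatenated column-wise into `X` (n × v·n).  The
interaction graph is binary and undirected — event classes never enter the
propagation operator — and is normalized with self-loops,
`Â = D̃^{-1/2}(A+I)D̃^{-1/2}`, whose spectrum lies in [−1, 1].

**Channels.** Both channels share the layer-width schedule (required so the
per-layer delivery mix is well-formed).  The feature channel is a ReLU
encoder on `X`; the topology channel is a GCN whose layer-l input is the
delivery mix `(1−α)Z^(l−1) + αH^(l−1)` with `Z^(0) = X` (the only available
node signal, making the first delivery a no-op).  The deliveries re-amplify
node-feature information at every depth, which is what keeps deep stacks
from collapsing all embeddings to indistinguishability; the test suite
checks this oversmoothing diagnostic directly (a 2-block graph under an
8-layer stack keeps a larger mean pairwise embedding distance at α = 0.5
than at α = 0).

**Attention fusion.** Scores `qᵀ tanh(w·xᵀ + b)` are computed per drug for
both final channel outputs with shared `w, b, q` (a per-channel switch for
`w, b` exists; `q` is always shared); the two scores are softmaxed, so the
coefficients are strictly inside (0, 1) and sum to 1 per drug.  The two-way
softmax is computed as a logistic of the score difference, which is exactly
equivalent and numerically stable.  The attention width defaults to the
final layer width.

**Decoder.** The autoencoder's inner-product decoder reconstructs the mean
of the per-view similarity matrices.  The decode is the **cosine** of the
final feature embedding (inner product of the row-normalized `H`), compared
by mean squared error.  Two alternatives were measured and rejected:

- a logistic link `sigmoid(H Hᵀ)`: since `H` is a ReLU output, `H Hᵀ ≥ 0`
  and the decode is bounded below by 0.5 while typical Jaccard targets are
  far below 0.5 — the unreachable target range turns the loss into a pure
  shrinkage penalty that collapses the feature channel (`reconstruction_loss`
  still offers this link for comparison);
- an unnormalized inner product: reachable, but it constrains the *scale* of
  `H` (‖H‖ ≈ target magnitude) while the topology channel is unconstrained;
  the resulting orders-of-magnitude scale gap between channels turns the
  attention coefficients into learned scale equalizers rather than
  importance weights.  The cosine decode constrains direction only, leaving
  both channel scales free and the attention interpretable.

**Head and loss.** Pair vectors (average, hadamard, element-wise absolute
difference, or concatenation of two rows of `E`) feed one affine layer +
softmax over the C classes — the minimal head that also covers the
2d-dimensional concatenation case.  Since the embedding width equals C, a
head-free variant (softmax over the pair vector itself) is available for
the d-dimensional combiners.  The total loss is mean cross-entropy over
training pairs plus λ times the reconstruction MSE, optimized end to end by
full-batch Adam (one update per epoch, as is standard for whole-graph GCN
training).

**Early stopping** monitors macro-F1 on a stratified 10% validation split
of the training pairs, restoring the best-epoch parameters.  Cross-entropy
is available as an alternative monitor but is not the default: measured on
the synthetic task, validation CE reaches its minimum long before the
attention routing has converged (CE degrades from growing over-confidence
while classification quality is still improving), and stopping there costs
roughly 0.1 macro-F1.

**Leakage control.** For every evaluation fold the propagation operator is
rebuilt from training-fold edges only; `run_fold` additionally asserts that
no test pair occurs in the training set.  In the cold-start tasks, held-out
drugs participate in inference as self-loop-only nodes, so their
predictions flow entirely from their descriptor features through the
delivery path.

## Synthetic data

The generator emulates the statistical shape of the public multitype-DDI
benchmarks (hundreds of drugs, a few descriptor views, a long-tailed class
histogram) at desk scale.  Defaults: 120 drugs in 4 equally sized
communities, 8 event classes, views of 60/40/20 bits, edge density ≈ 0.2
(within-community 0.5, across 0.1 at full topology signal), class rank
weights ∝ rank^−1.5.

- **Features:** each bit prefers one community (rate 0.8 vs 0.05);
  `feature_signal` interpolates the rates toward a flat 0.2, erasing the
  community information at 0.
- **Topology:** `topology_signal` interpolates edge probabilities between
  the uniform density and the community-pair densities.
- **Classes:** each unordered community pair owns a dominant class (pairs
  ranked by expected edge mass, classes cycled in rank order, so the class
  marginal is non-increasing in rank).  The dominant share is 0.9 with the
  remaining mass spread by the rank prior.  At 0.8 dominance the label noise
  alone caps even a Bayes-optimal classifier (which knows the true
  community pair) near macro-F1 0.8, leaving no room to demonstrate
  recovery; at 0.9 the Bayes ceiling is ≈ 0.90.
- **Attenuation:** the class↔community linkage is scaled by the total
  planted signal `s = 1−(1−f)(1−t)`.  Without this, a model can recover
  each drug's community *from its incident training labels alone*
  (collaborative filtering through supervision) and the nominally
  signal-free configuration is far above chance; with it, zero planted
  signal means classes are drawn from the global prior and the chance level
  is exactly the one implied by that prior (`chance_macro_f1` gives its
  closed form: for class prior `p` and test frequency `q`,
  `F1_c = 2 p_c q_c / (p_c + q_c)` for a predictor drawing i.i.d. from `p`).

What the generator does **not** emulate: real fingerprint bit correlations,
target promiscuity, degree heterogeneity beyond the block model, or any
chemistry.  Passing the planted-signal tests therefore shows that the
architecture recovers community-mediated signal through either channel and
routes attention sensibly — not that it attains any particular accuracy on
real pharmacological data.

## Experiment protocol at desk scale

The package-level defaults mirror the settings used for the full-scale
benchmark (573-bit-scale inputs, layers {2000, 256, 65}, average combiner,
learning rate 0.003, patience 20 of up to 1000 epochs, α = 0.5, λ = 1).
The 120-drug synthetic studies use a protocol calibrated for that scale
(`ddifuse.protocols`): widths (64, 64, 32, C), hadamard combiner, learning
rate 0.01, patience 150 of at most 600 epochs, α = 0.5, λ = 1.  The deeper,
narrower stack and the multiplicative combiner fit the community-pair
structure of the synthetic task (a pair's class is a non-additive function
of its two communities, which an averaged embedding separates poorly); the
long patience absorbs the noisy macro-F1 monitor on ~100 validation pairs.
One training run takes a few seconds on one CPU; the full acceptance script
(about twenty runs) a few minutes.

## Numerical choices

- Reverse-mode autodiff over numpy float64 with a topological-order
  backward pass; gradients are verified against central finite differences
  for every primitive and for a composite two-channel network.
- Glorot-uniform initialization, zero biases, all randomness through
  `numpy.random.default_rng(seed)`; identical seeds reproduce training
  bit-for-bit.
- Two-way softmax via `sigmoid(s_z − s_h)`; log-softmax with max-shift; the
  cross-entropy clamps zero probabilities at 1e−12.
- Ranked predictions break score ties lexicographically by
  (drug_a, drug_b, class) so reports are reproducible.
- Pair CV is stratified by event class; classes with fewer members than
  folds are dealt round-robin with a warning.  Macro metrics average only
  over classes present in the test labels.
- The drug-wise cold-start split holds out ⌈fraction·n⌉ drugs (20% of 572
  gives 115).

## Known limitations

- Full-batch training keeps the whole n × n similarity target in memory;
  fine for hundreds-to-thousands of drugs, not for tens of thousands.
- The classifier head is linear on the pair vector; event classes that are
  non-linear functions of the pair vector would need a deeper head.
- Attention coefficients are comparable between channels only because the
  decoder leaves channel scales free; if `recon_link="identity"` without
  normalization were used, coefficient magnitudes would reflect scale, not
  importance.
- The cold-start tasks use a single drug-wise split per seed (repeatable
  via seeds) rather than a rotated 5-fold drug partition.
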