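# Methods

## The fusion model

`neurofuse` treats N trained classifiers as information sources over K
classes. Source i carries a fuzzy density g_i ∈ (0, 1); the Sugeno
λ-measure extends the densities to every subset of sources via
g(A∪B) = g(A) + g(B) + λ g(A)g(B) for disjoint A, B, with λ the unique
root in (−1, ∞) \ {0} of λ + 1 = ∏(1 + λ g_i). When Σg_i = 1 the measure
is additive and λ = 0; Σg_i > 1 forces λ ∈ (−1, 0) (subadditive),
Σg_i < 1 forces λ > 0 (superadditive). Some texts misstate the λ range as
λ ≥ 1; the normalization equation itself only admits the (−1, ∞) range
used here.

Per sample and per class, the fused score is the max–min Sugeno integral
of the N class confidences with respect to this measure; the predicted
class is the argmax of fused scores with ties broken toward the lowest
index in the declared class-label order. Fused scores are reported raw:
the max–min form does not produce a probability simplex point, and ROC/AUC
only depends on score order. An optional flag renormalizes per sample when
a simplex is wanted.

### Numerical treatment of λ

h(λ) = ∏(1 + λg_i) − 1 − λ is a polynomial with zero constant term, so the
trivial root λ = 0 is divided out analytically: the remaining factor
q(λ) = (e₁ − 1) + e₂λ + … + e_N λ^{N−1}, with e_k the elementary symmetric
polynomials of the densities, has exactly one sign change on the relevant
bracket (q(−1) = −∏(1−g_i) < 0 and q(0) = Σg − 1 > 0 when Σg > 1; the
mirrored argument with an upward-doubled bracket when Σg < 1). Brent's
method on q with xtol 1e-12 then converges unconditionally, and the
accepted root must satisfy the original equation to residual < 1e-10 or a
`LambdaConvergenceError` names the offending density vector. Deflating the
trivial root avoids the ill-conditioning of root-finding near λ = 0 when
Σg is close to 1; |Σg − 1| ≤ 1e-9 is treated as exactly additive.

Subset measures are evaluated by left-folding the union rule in ascending
index order — an O(|A|) computation whose result is independent of fold
order for fixed λ (verified exhaustively in tests for N ≤ 5). Densities
are restricted to the open interval (0, 1): g_i = 0 makes a source
vacuous and g_i = 1 degenerates the normalization equation. For N = 1 no
nonzero root exists; the measure of the lone source is pinned at 1 by the
normalization axiom and fusion returns that classifier's output unchanged.

### Density assignment

How the per-classifier densities should be set is genuinely open; the
package makes it an explicit, logged configuration choice with three
strategies: `accuracy` (default — each classifier's validation accuracy,
the common convention for Sugeno ensembles, clipped into
[1e-6, 1 − 1e-6]), `uniform` (1/N, which makes the measure additive and
collapses the integral to a closed form), and `user` (explicit values).
One global measure is shared by all classes; densities are
per-classifier, not per-class.

### Behaviour of max–min aggregation

With highly accurate classifiers (Σg ≫ 1, λ → −1) the suffix-chain
measures saturate near 1 except for the last element, so the fused score
approximates the second-highest confidence capped by the top classifier's
density. This makes the integral robust to a single overconfident outlier
but coarser than averaging when errors are independent; its advantage
appears when classifier strengths are complementary or errors are
correlated, which is the regime the fusion targets.

## Baseline rules

Majority voting (plurality of argmaxes; ties broken by summed probability
across classifiers, then lowest class index — the tie-break chain is this
package's own convention), arithmetic averaging, and the multiplication
rule (per-entry floor 1e-12, computed in log space so zero probabilities
cannot produce NaN or a degenerate all-zero row). All three are
permutation-invariant over classifiers and agree with the Sugeno fusion on
unanimous one-hot inputs.

## Metrics

Accuracy = trace/total of the K×K confusion matrix; per-class one-vs-rest
precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean. Macro
averaging (unweighted class mean) is the default since multiclass reports
in this domain typically show precision well below accuracy — the
signature of macro averaging under class imbalance; micro is available by
flag and satisfies micro precision = micro recall = accuracy for
single-label problems. Zero-denominator classes contribute 0 with a
warning. The confusion-matrix convention is the standard one (rows =
true, columns = predicted). ROC/AUC use threshold sweeps with tied scores
grouped into one step and trapezoidal area; classes lacking both a
positive and a negative sample are skipped with a warning.

## Attention math and GELU

`squeeze` is the per-channel spatial mean of a C×H×W map (identical to
global average pooling); `excitation` is logistic(W₂·relu(W₁·z)) through a
C/r bottleneck (both nonlinearities are conventionally written with one
symbol; the inner one is a rectifier and the outer a logistic gate, the
standard squeeze-and-excitation design); `scale` multiplies channel c by
gate s_c. The reduction ratio defaults to r = 16, the standard choice,
configurable per block. GELU is implemented exactly as x·Φ(x) via the
error function rather than the tanh approximation (tests at 1e-7). Note
exact GELU is *not* monotone: it has a single interior minimum of ≈ −0.17
near x ≈ −0.75 and increases monotonically to its right; it always lies
between 0 and the identity.

## Architecture parameter accounting

Layer specs are declarative; only arithmetic is performed (conv =
out·(in·kh·kw/groups) + out·bias, batchnorm = 2C affine terms — running
statistics are not trainable — linear = out·(in+1), SE block = the two
bias-ful bottleneck maps). The modified AlexNet is the single-stream
variant (64/192/384/256/256 filters; the historical two-GPU split is not
used by modern pre-trained weights) with the two hidden dense layers
removed: 2,469,696 trunk parameters plus a 9216→K head, totalling
2,506,564 at K = 4 (2.5M). The VGG11_bn variant keeps conv biases
(matching common pre-trained weights) and replaces the dense head with
GAP plus one 512→K layer, totalling ≈ 9.23M at K = 4; the SE-ResNeXt-50
(32×4d) layout with one SE block (r = 16) per residual unit and a 2048→K
head totals ≈ 25.5M at K = 4. Only the AlexNet figure is treated as an
exact target; the reference VGG figure of 9.5M is not reproducible from
any standard layer widths we know of and the divergence is left standing.

## Synthetic data generator

The generator emulates the evaluation half of the pipeline — N trained
classifiers emitting per-class probability tables over K classes — without
images or training. Ground truth is uniform over K. Whether classifier n
is correct on sample j is a Bernoulli event with rate equal to its
configured skill; correlation between classifiers' errors is induced by a
Gaussian copula (a shared per-sample difficulty deviate mixed with weight
`error_correlation` into each classifier's uniform draw), which leaves
every marginal accuracy exactly calibrated at any correlation level.
Probability vectors are Dirichlet draws with concentration mass on the
predicted class (default concentration 8, giving sharply peaked
softmax-like vectors with typical top probability ≈ 0.7); the largest
entry is swapped into the predicted column on the rare stray draw so the
argmax equals the intended prediction by construction.

Defaults are three classifiers with skills (0.9537, 0.9673, 0.9478) —
the test accuracies of the three modified backbones — and K = 4, with a
12-class setting reachable by flag. The complementary scenario partitions
classes round-robin among classifiers; each is correct with its skill on
its own classes (peaked vectors) and guesses uniformly with near-flat
vectors (concentration 1.5) elsewhere, the regime in which a sound fusion
rule must beat every individual classifier (asserted over five fixed
seeds at n = 5000).

What the generator does **not** model: class imbalance, feature-level
correlation beyond the scalar difficulty, systematically miscalibrated
confidences, or label noise. Passing tests therefore demonstrate
correctness of the fusion arithmetic and its statistical behaviour under
calibrated, symmetric conditions — not performance on any real image
dataset.

## Problem sizes and determinism

Property tests run at N ∈ {2..6} sources with 1,000 randomized density
vectors for the measure axioms and 10,000 random cases against the
brute-force subset oracle; statistical tests use n = 5000 samples. All
randomness flows through seeded `numpy` generators; identical
configuration (including seed) reproduces output files byte for byte.

## Known limitations

Densities are not learned or optimized; the Choquet integral and non-λ
fuzzy measures are out of scope; the architecture module counts
parameters but does not instantiate, train or load networks; fused raw
scores are not calibrated probabilities.
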