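# Methods

## Problem setting

Fatigue alters the fine-grained temporal structure of speech. The
package operationalizes this through two scaling descriptors — the Hurst
exponent H (persistence of the signal's long-range correlations) and the
fractal dimension D of the signal graph (roughness; D = 2 − H for
self-affine series) — extracted frame-wise, compressed to a low
dimension by a learned measurement matrix, and classified.

## Preprocessing

First-order pre-emphasis y_n = x_n − μx_{n−1} with μ = 0.95 (y₀ = x₀;
the filter is undefined at n = 0 and the x₋₁ = 0 convention is the usual
one). Frames of 256 samples, stride 64, so n_frames =
⌊(N − 256)/64⌋ + 1 and adjacent frames share 192 samples; a trailing
partial frame is dropped rather than zero-padded, keeping every frame a
genuine 16 ms excerpt. The symmetric Hamming window
w(n) = 0.54 − 0.46 cos(2πn/(N−1)) tapers each frame. WAV integers are
scaled to [−1, 1]; the features are scale-invariant, but a fixed
convention keeps runs bit-reproducible.

## Feature estimators

**Wavelet-variance Hurst.** A Daubechies-4 pyramid decomposition yields
detail sequences d(l, ·); σ_l² is the mean squared coefficient at level
l and α the ordinary least-squares slope of log₂ σ_l² against l, giving
H = (1 + α)/2. When the depth is not specified the estimator uses up to
six levels (at least two): for long series the finest scale carries a
small systematic deviation from the asymptotic scaling law, and a deeper
regression dilutes it — with a four-level regression on 8192-sample
fractional Gaussian noise the bias at H = 0.2 is about −0.09, with six
levels within ±0.06 across H ∈ [0.2, 0.8]. The pH feature is
[H₀, H₁, …, H_l]: H of the series plus H of each detail sequence (depth
adapted to each sequence's length), defaulting to l = 4 so pH and SWFF
have equal length.

**Higuchi fractal dimension.** For delays k = 1..k_max (default 10) and
offsets m = 1..k, the normalized curve length

L_m(k) = (1/k) · Σ_i |X(m+ik) − X(m+(i−1)k)| · (N−1)/(⌊(N−m)/k⌋·k)

is averaged over m, and D is the least-squares slope of log L(k) against
log(1/k). The estimator is exactly scale-invariant and returns 1.0 for a
straight line.

A note on the D = 2 − H identity: it relates H of a noise process to
the *graph* dimension of its integrated, self-affine trace. Higuchi
applied to raw fGn measures the graph of an (asymptotically) totally
rough stationary sequence and returns D ≈ 2 for every H — still
monotonically ordered in H, but not 2 − H. Recovery checks therefore
integrate the noise first (cumulative sum → fBm-like trace), where the
estimator recovers 2 − H to well within ±0.1.

**Aggregation.** Per-frame feature vectors (length l+1 = 5) are
concatenated in frame order and truncated / right-zero-padded to a fixed
256-dimensional utterance vector. Concatenation preserves the coarse
time course of the utterance; with the default 0.25 s utterances, 52
frames supply 260 ≥ 256 values, so no padding occurs and the aggregation
is a pure truncation.

## Measurement-matrix construction

The construction seeks an M×N measurement matrix Φ and a paired sensing
dictionary Ψ (both M×N — the atoms must live in the same space for the
pairing ⟨εᵢ, φᵢ⟩ = 1 to be meaningful) whose Gram G = ΨᵀΦ has low
t-mean coherence μ_t (mean absolute off-diagonal among entries ≥ t; the
empty selection is defined as 0). The ideal Gram H has unit diagonal and
off-diagonals of magnitude t_E = √((N−M)/(M(N−1))) — the Welch bound,
attained by equiangular tight frames — signed like the current Gram
(sign(0) → +1).

Each outer round:

1. **Problem 1** — gradient descent on C(Φ) = ‖ΦᵀΦ − H‖²_F with
   ∂C/∂Φ = 4Φ(ΦᵀΦ − H) and step β = 0.001, H rebuilt from the current
   signs of ΦᵀΦ; stops on cost stagnation or after max_inner steps.
2. **Problem 2** — the off-diagonals of G = ΨᵀΦ are shrunk by
   ρ(g) = (4γ/π)·arctan(g), a strictly increasing odd map of [−1, 1]
   onto [−γ, γ] with γ = 0.4; the shrunk Gram is refactored through its
   SVD U S Wᵀ truncated to the M largest singular values:
   Ψ = S_M^{1/2} U_Mᵀ, Φ = S_M^{1/2} W_Mᵀ, so ΨᵀΦ is the best rank-M
   approximation of the shrunk Gram. Retaining exactly M singular values
   ties the factor shapes to the measurement dimension.
3. Columns renormalized: φᵢ ← φᵢ/‖φᵢ‖₂, εᵢ ← εᵢ/⟨εᵢ, φᵢ⟩ (both
   invariants hold to 1e−10 on every output).

The loop terminates when μ_t changes by < 1e−6 between rounds or after
max_outer rounds. The seeded random initialization is column-normalized
and then given the same ⟨εᵢ, φᵢ⟩ = 1 normalization, so the recorded
initial μ_t is measured on a valid sensing pair — an unpaired random
cross-Gram has mean |off-diagonal| ≈ √(2/(πM)), *below* the equiangular
magnitude t_E the construction targets, and is not a comparable object.
μ_t decreases monotonically across rounds in practice (alternating
schemes are not provably monotone; the report flags upticks rather than
failing). Library defaults are max_outer = 50, max_inner = 1000; the
pipeline and the study script use 12 × 300, by which point μ_t is within
a few percent of its converged value at the default 32×256 size.

OMP sparsity for the evaluation trace defaults to K = M/4. The
brute-force restricted-isometry constant is exact but exponential, so it
is guarded by a support-count cap and meant for N ≤ 16.

## Classifier

Fuzzy c-means (fuzzifier m = 2, the universal default) with C = 2 rules
partitions the training inputs; memberships satisfy Σᵢ μᵢⱼ = 1 and the
objective J_m is non-increasing. Per rule, an LS-SVM dual system

    [0  1ᵀ; 1  K + diag(1/(c·vⱼ))] [b; α] = [0; y]

is solved with RBF kernel exp(−γ‖·‖²), γ = 0.5, penalty
c = 9.7656·10⁻⁴ (≈ 2⁻¹⁰), and weights vⱼ the rule memberships (floored
at 10⁻⁶). A query's rule weights are P_i = Π_t exp(−|x_t − θ_it|/β_it)
with θ_i the cluster center and β_it = λ · membership-weighted
coordinate variance (λ = 1); the absolute (not squared) coordinate
distance in the exponent is deliberate. The decision value is the
P-weighted average of rule outputs — computed in log-space and shifted
by the maximum, which is exact because the combination is invariant to
positive rescaling of all P_i — and the label is its sign (sign(0) → +1).
Evaluation is stratified 6-fold cross-validation with a recorded seed;
824 items split as four folds of 137 and two of 138.

## Synthetic corpus

Exact fractional Gaussian noise comes from circulant embedding of the
fGn autocovariance γ(k) = (|k+1|²ᴴ − 2|k|²ᴴ + |k−1|²ᴴ)/2 (eigenvalues by
FFT; a non-PSD embedding — not observed for the sizes used — is clipped
with a warning). Unit variance and lag-1 autocorrelation 2^{2H−1} − 1
are exact.

Each utterance starts as an fGn draw at the class Hurst exponent
(normal 0.8, fatigued 0.3 — well separated by design; configurable to
study degradation), gets white noise at 20 dB SNR on the increments, and
is integrated to its running sum: the fBm-like 1/f-type trace whose
graph dimension 2 − H actually differs by class. Raw (unintegrated) fGn
utterances are available via `integrate=False` but are nearly
indistinguishable to the features once pre-emphasis whitens them. The
default 0.25 s duration at 16 kHz yields 59 frames, more than the 52
needed to fill the 256-dimensional utterance vector without padding;
412 utterances per class give a balanced 824-item corpus.

What the corpus does *not* emulate: formant structure, glottal
excitation, channel noise, speaker variability, or any linguistic
content. Passing tests demonstrate that the pipeline separates classes
that differ in scaling structure — the mechanism the features are built
to detect — not that it detects fatigue in real radiotelephony audio.

## Numerical conventions and degenerate inputs

- Pre-emphasis boundary y₀ = x₀; window endpoints 0.08 (never zero).
- Constant series are rejected by both estimators (zero detail variance
  / zero curve length).
- `t_mean_coherence` returns 0 for an empty selection; `target_gram`
  maps sign(0) to +1.
- Problem-1 divergence (cost above 1e12 or non-finite) raises with
  advice to reduce β.
- Degenerate cluster coordinates floor β_it at machine epsilon with a
  warning; extremely distant queries can then underflow P_i to 0 in
  linear space, which the log-space decision path avoids.
- Every stochastic stage derives its seed from the global run seed via
  a CRC-tagged SeedSequence, so pipeline reruns are bit-identical.

## Problem sizes

The default study runs 824 utterances of 0.25 s, a 32×256 construction
at 12 outer × 300 inner iterations, and 6-fold CV — about a minute on
one CPU. Estimator-recovery checks use 8192-sample series averaged over
20 seeds per grid point; OMP-versus-exhaustive checks enumerate supports
at N ≤ 12, where exhaustive L0 search is tractable and greedy recovery
is screened by the exact-recovery condition ‖A_S⁺ a_j‖₁ < 1 under which
OMP is provably optimal.

## Known limitations

- The pH feature, computed per 256-sample frame, is a noisy Hurst
  estimate (few usable scales) and separates the synthetic classes far
  less well than SWFF; the comparison table reflects this.
- The ICSCA-versus-Gaussian accuracy ordering on an easy, well-separated
  corpus is decided at the ceiling (both near 100%); the construction's
  clearer advantage is in OMP reconstruction error and worst-case
  coherence.
- RIP certification at realistic sizes is NP-hard and out of scope; the
  brute-force constant is a verifier for toy sizes only.
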