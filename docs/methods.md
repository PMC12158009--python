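# Methods

## The joint approximation problem

Given Q signals f{q} ∈ ℝ^N that are *similar* — i.e. all of them admit a
good approximation inside one low-dimensional subspace — and a redundant
dictionary 𝒟 = {d_n}_{n=1..M} of unit-norm atoms, the package finds a
common basis d_{ℓ1}, …, d_{ℓk} and per-signal coefficients c{q} such that

    f{q} ≈ Σ_n c{q}(n) d_{ℓn},     q = 1, …, Q,

judged by the weighted mean squared error
Ē_k = Σ_q p(q) ‖f{q} − f{q}_k‖², with nonnegative weights summing to one
(uniform 1/Q by default).  Finding the best k-subset of atoms is
combinatorial, so a greedy pursuit is used.

## SOOMP: stepwise-optimal selection with adaptive biorthogonalization

At iteration k+1 SOOMP selects

    ℓ_{k+1} = argmax_{n ∉ Γ}  Σ_q p(q) |⟨d_n, r{q}⟩|² / (1 − Σ_i |⟨d_n, w̃_i⟩|²),

where r{q} are the current residuals and the w̃_i are an orthonormal basis
of span{d_{ℓ1..ℓk}}.  The denominator is the squared distance of the
candidate atom to the selected span; dividing by it makes the rule
equivalent to exhaustively minimizing Ē_{k+1} over all candidates (the
numerator alone — the SOMP rule — only maximizes residual correlation).
The implementation maintains:

* Gram–Schmidt vectors w_n with one mandatory re-orthogonalization pass
  and a second pass triggered when the orthogonality check exceeds 1e−10
  ("twice is enough");
* dual vectors β_n with ⟨β_n, d_{ℓm}⟩ = δ_nm, updated in O(Nk) per step,
  so that coefficients are plain inner products c{q}(n) = ⟨β_n, f{q}⟩;
* residuals via r{q} ← r{q} − w ⟨w, f{q}⟩/‖w‖².

Correctness of this machinery is checked in the tests against
least-squares oracles: the approximation equals the orthogonal projection
onto the selected atoms at every iteration, the stacked duals equal the
Moore–Penrose pseudo-inverse of the selected-atom matrix, and the
selection matches brute-force one-step lookahead on small dictionaries.

Numerical policy: argmax ties break to the lowest atom index; candidates
whose denominator falls below 1e−10 are skipped (they are numerically in
the selected span, and by the zero-numerator argument they cannot reduce
the error); the basis extension itself rejects atoms whose orthogonalized
norm falls below 1e−7.  Both stopping rules are exposed — squared
(Σ p(q)‖r{q}‖² < ρ) and unsquared (Σ p(q)‖r{q}‖ < ρ) — because the
framewise audio driver budgets energy (squared) while the ECG codec's
PRDN tolerance is a norm (unsquared).  When the tolerance cannot be
reached (dictionary span exhausted or `max_atoms` hit) the result carries
a flag rather than raising, since partial approximations are still
useful.  Inner products against the full dictionary are recomputed each
iteration (complexity O(NMQ) per step); only the span-projection
denominators and duals use recursions, keeping the implementation close
to the algebra above and easy to audit.

## Dictionaries

**Redundant trigonometric dictionary.**  Cosine atoms
cos(π(2i−1)(n−1)/2M) and sine atoms sin(π(2i−1)n/2M), i = 1..L,
n = 1..M per family, each column divided by its numerically computed
norm (robust at edge frequencies, where closed-form normalization
factors would need case analysis).  M = 2L per family (redundancy four
in total) is the default used for audio-style frames; M = L reduces each
family to an orthogonal transform basis, which the tests exploit.

**CDF 9/7 wavelet dictionary.**  Atoms are translates of the
Cohen–Daubechies–Feauveau 9/7 scaling function φ and dilated wavelets
2^{j/2} ψ(2^j x − k/2), j = 0..levels−1, restricted to the sample
interval, with half-integer translation steps, each restricted atom
renormalized to unit norm.  Prototypes come from the cascade algorithm on
the CDF 9/7 analysis filter pair (via PyWavelets), sampled at spacing
2^{−iterations} (default 8) and evaluated between grid points by linear
interpolation.  The sample grid is x_i = (i−1)/2^levels: with this
scaling the finest wavelet level contributes one atom per signal sample
and the level populations halve toward coarser scales, so the total atom
count is ≈ 2N (measured 2.14N at N = 512, levels = 5).  A unit-spaced
grid with the same dilation labels would make the finest level 2^{levels−1}
times denser — a very different (16-fold redundant) dictionary; the
half-integer-step, redundancy-two construction is the intended design
point, and any affine rescaling of the grid together with a relabeling of
dilations reproduces it.  Atoms whose restriction to the interval has raw
norm below 1e−8 are dropped; exact duplicates from boundary restrictions
(inner product > 1 − 1e−12 with a kept atom) are removed.

## Framewise audio-style driver

Long multichannel signals are split into disjoint frames of length L
(trailing samples beyond ⌊N/L⌋·L are excluded), and each frame is pursued
to a per-frame energy tolerance ρ_i = 10^{−snr0/10} Σ_q p(q)‖f_i{q}‖², which
guarantees frame SNR ≥ snr0.  Sparsity is summarized by SR = 2N/K (two
channels, K atoms in total), quality by SNR in dB.

## ECG codec

1. **R-peak detection** — bandpass 5–15 Hz, derivative-squared energy,
   150 ms integration window, adaptive threshold (fraction of the 95th
   percentile), 200 ms refractory, refinement to the raw-signal extremum.
   This is a deliberately simple, pluggable detector; external
   annotations can be passed instead and take precedence.
2. **Segmentation/alignment** — beats span RR midpoints (first/last beat
   truncated at the record ends, so beats partition the record exactly);
   rows are zero-padded into a Q×L matrix with all R-peaks in one column.
   The record mean is subtracted before segmentation and stored in the
   header.
3. **Joint approximation** — SOOMP with uniform weights over the CDF 9/7
   dictionary built for length L, unsquared stopping at
   ρ = (PRDN0/100)·mean_q ‖f{q} − mean(f{q})‖ with PRDN0 = 0.8 × target
   PRDN: the approximation overshoots the target so quantization can
   spend the remaining error budget.  Per-beat means are taken over the
   full padded row (the padded array *is* the signal being approximated).
4. **Decorrelation** — similar beats have similar coefficient vectors, so
   the columns of the Q×k coefficient array C are highly correlated along
   q; an orthonormal DCT per column concentrates them, and orthonormality
   makes quantization error identical in the B and C domains.
5. **Quantization** — mid-tread uniform, bΔ = ⌊b/Δ + ½⌋ (floor semantics
   on negatives: −1.3 at Δ = 0.5 maps to −3, reconstruction error
   0.2 ≤ Δ/2).  Δ is tuned so the *decoded* record's PRDN matches the
   target within ±0.005.  PRDN(Δ) is only piecewise continuous —
   coefficients cross quantizer cell edges one at a time — and can be
   locally non-monotone when a few large coefficients dominate, so the
   tuner runs plain bisection first (sufficient for dense streams) and
   falls back to a geometric global scan (240 points) with two zoom
   rounds around the most promising candidates.  A target below the
   unquantized approximation's PRDN raises an infeasible-target error:
   the approximation stage must then be redone with a smaller PRDN0.
   The high-level `compress` automates both recoveries: when the tuner
   cannot land within ±0.005 (or reports infeasibility), it repeats the
   approximation stage with PRDN0 scaled by 0.8 — a tighter
   approximation yields a denser quantized stream with finer PRDN
   granularity — up to three times, keeping the attempt whose achieved
   PRDN is closest to the target.
6. **Entropy coding** — the quantized, column-major-vectorized array is
   stored as nonzero magnitudes, signs, and index gaps (first position,
   then successive differences).  Magnitudes, gaps, beat lengths h and
   beat left-extents are each coded with a self-describing canonical
   static Huffman block; signs are packed as raw bits (a binary alphabet
   gains nothing from Huffman).  The header carries the atom indices, Δ,
   the record mean, Q, k and the dictionary parameters, so the decoder
   rebuilds the identical dictionary instead of storing it.

The per-beat left extents are transmitted in addition to the lengths h:
reassembling the 1-D record requires knowing where inside each padded row
the beat's samples sit, which h alone does not determine.

Compression ratio is reported against samples × stored resolution
(11 bits by default, configurable), versus 8 × container bytes.

## Synthetic data

* **Joint-sparse sets** — a common support of k atoms, per-signal
  N(0, scale²) coefficients, optional white noise.  With zero noise and an
  incoherent (random Gaussian) dictionary these are exactly recoverable,
  enabling non-statistical assertions.
* **ECG-like records** — each beat is five Gaussian deflections
  (P, Q, R, S, T) with defaults (center, width, amplitude) =
  (−0.20 s, 0.025 s, 0.15), (−0.03, 0.010, −0.12), (0, 0.012, 1.20),
  (0.035, 0.012, −0.25), (0.25, 0.060, 0.35) — an upright ~1.2-unit R
  wave with the usual lateral waves at 360 Hz.  RR intervals are
  N(0.8 s, jitter²) with default jitter 0.04 s; per-beat amplitude scale
  N(1, 0.05²); additive white noise with default sd 0.02 (≈ 2% of the R
  amplitude, a plausibly clean clinical lead).  `aberrant_beats` scales
  selected beats to emulate ectopy/outliers.  The model reproduces what
  the codec relies on — quasi-periodicity, beat similarity, a dominant R
  deflection — but not baseline wander, lead polarity variation, or real
  arrhythmia morphology, so codec results on it say nothing clinical;
  they demonstrate rate control and losslessness of the container, not
  diagnostic quality.
* **Correlated multichannel signals** — shared off-grid sinusoids with
  channel-specific gains plus light noise; a stand-in for stereo audio in
  SOOMP-vs-SOMP comparisons.  Gains measured on it (≈ 30% mean SR gain)
  are fixture-dependent and only the *direction* of the advantage is
  asserted.

All generators are pure functions of their arguments including the seed.

## Problem sizes and defaults

The test suite and the acceptance script run on desk-scale sizes chosen
to exercise every code path with comfortable margins: 50 joint-sparse
fixtures (Q ≤ 8, N ≤ 128, M ≤ 256) for the projection oracle, ≤ 64-atom
dictionaries for exhaustive lookahead, 20 two-channel fixtures of 512
samples for the SOMP comparison, and one 2000-beat (~576 000-sample)
synthetic record at PRDN targets {5, 9, 15, 25} for the codec loop.

## Known limitations

* The R-peak detector is a simplified energy detector; on difficult real
  records a dedicated detector (or database annotations) should be
  plugged in via `peaks=`.
* Entropy coding is static canonical Huffman; an adaptive coder would
  shave the code tables and slightly improve compression ratios.
* Single-lead records only; beats are coded independently of any
  rhythm context.
* PRDN rate control is exact to ±0.005 only where the quantizer's
  discrete nature allows; for extremely sparse streams (very coarse
  targets on very clean records) the tuner returns the closest
  achievable value.
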