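# Methods

## Signal model

The observed series is a sum of `p` exponentially damped complex sinusoids
(cisoids) sampled uniformly at `fs`:

```
s(n) = Σ_{i=1..p} g_i z_i^n,   g_i = b_i e^{jψ_i π/180},
z_i = e^{(−d_i + j2πf_i)/fs},   n = 0..N−1.
```

Units: `f_i` in Hz within the Nyquist band `(−fs/2, fs/2]`, `d_i` in rad/s
(positive for decaying physical peaks), `b_i` linear amplitude, `ψ_i` phase
in degrees. The per-sample exponent divides by `fs`, which is the only
convention under which a table giving `d` in rad/s and `f` in Hz is
meaningful at arbitrary sampling rates; at `fs = 1` it reduces to the
per-index exponent familiar from the 0.2/0.22 Hz literature example.
Zero-order and per-peak phases are not separately identifiable from one
realization, so a single combined phase per peak is stored.

Measurement noise is circular complex white Gaussian: independent real and
imaginary perturbations, each i.i.d. `N(0, σ_v²)` per sample.

## Subspace estimation

All estimators exploit the Vandermonde structure of the `L×M` Hankel matrix
`S_H` with entry `(i, j) = s(i+j)` (`L + M − 1 = N`): noise-free, its rank is
exactly `p`, and deleting the top/bottom `D` rows gives a pair `S↓_D`, `S↑_D`
related by `X S↑_D = S↓_D`, whose minimum-norm solution has the decimated
poles `z_i^D` as its nonzero eigenvalues. Decimation multiplies pole angular
separations by `D`, which is what buys resolution for close peaks.

- **DESE_D** — default sizing `L = ⌈(N+1)/2⌉`, `M = N + 1 − L` (65×64 at
  N = 128); the shift pair loses only one row per unit of `D`. In noise the
  up-shift is replaced by its best rank-p approximation (SVD truncation,
  Eckart–Young) and `X = S↓_D pinv(S↑_D^e)` reuses that SVD, so `rank(X) ≤ p`;
  the `p` largest-magnitude eigenvalues are taken as decimated poles.
  `D = 1` is the matrix-pencil method (MATPEN); enhancing both shifts
  (`D = 1` only) is CSE. A truncated-TLS variant of the shift solve is
  exposed (`solver="tls"`) but excluded from benchmarks; classical TLS is
  nongeneric here because the enhanced up-matrix is rank deficient.
- **TLS/LS-ESPRIT(_D)** — the Hankel matrix is oriented `L = ⌊N/2⌋`,
  `M = N + 1 − L` (64×65 at N = 128, honoring `L ≤ M`); the first `p` left
  singular vectors `U_p` span the signal subspace, and the shift equation on
  `U_p` with top/bottom `D` rows deleted is solved in a total- or plain
  least-squares sense. The one-row orientation ambiguity has no effect on
  the exactness properties.
- **CONDE_D** — each decimated subsequence `c_k(n) = s(k + nD)`,
  `k = 0..D−1`, yields a Hankel matrix with `L = ⌊N/(2D)⌋` rows and all
  available columns; the concatenation `C` feeds the global covariance
  `R = C Cᴴ`, whose leading `p` eigenvectors replace `U_p` above (TLS shift
  solve with one-row deletions; eigenvalues are decimated poles). Using all
  columns, rather than truncating to a square `L×L` block, is what makes
  `CONDE_1` *exactly* the data-matrix TLS-ESPRIT (they operate on the same
  matrix), an identity the test suite asserts at 1e−8 on noisy data; the row
  dimension still matches the published sizes 32 (D = 2) and 21 (D = 3) at
  N = 128. Eigenvector phases are fixed deterministically (largest component
  made real positive).

Decimated poles are converted back by `f = angle(λ)·fs/(2πD)`,
`d = −ln|λ|·fs/D`. Amplitudes and phases always come from a final
least-squares Vandermonde fit `V g = s` over the full N samples
(`b_i = |g_i|`, `ψ_i = arg g_i`), never on decimated grids.

**Aliasing.** Decimation folds frequencies with `D·|f|/fs ≥ 1/2`. No
de-aliasing is implemented: blind estimation with `D > 1` emits an
`AliasingWarning`, and the benchmark driver refuses decimation factors that
wrap any true peak. This is why the two-peak (max 3·0.22 > 0.5) and
eleven-peak (3·530/3000 > 0.5) presets are benchmarked only up to `D = 2`,
while the five-peak signal admits `D = 3`.

**Determinism.** Eigenvalues are ordered by descending magnitude with ties
broken by ascending angle; estimated peaks are reported sorted by ascending
frequency with phases wrapped to `(−180°, 180°]`. Dense LAPACK
decompositions are used throughout — at `N = 128` there is nothing to gain
from structured Hankel solvers.

## Cramér–Rao bounds and failure intervals

For a deterministic signal in circular complex white Gaussian noise the
Fisher information over the 4p real parameters is

```
FIM[k,l] = (1/σ_v²) Σ_n Re( ∂s(n)/∂θ_k ∗ · ∂s(n)/∂θ_l ),
```

with analytic derivatives of the model (phase differentiated in radians
internally; bounds reported in Hz, rad/s, linear units and degrees). The
analytic Jacobian is verified against central finite differences in the
tests. sqrt-CRLBs are the square roots of the diagonal of the FIM inverse;
the full joint FIM is used (all peaks, all four parameters per peak).

The Monte-Carlo failure intervals are symmetric frequency intervals around
the true peaks whose half-widths derive from the CRLB: the separation `Δf`
of a chosen anchor pair is split in proportion to the two peaks' frequency
sqrt-CRLBs — the unique assignment that makes the two intervals touch.
Because the bounds are linear in `σ_v`, any common factor (reference sigma,
or a k-sigma interval convention) cancels; only the ratio matters. Remaining
peaks receive the larger anchor half-width. At N = 128 this reproduces the
published five-peak values (42.58 → 43 Hz for peak 4, 82.42 → 82 Hz for the
rest). For the two-peak signal the same construction yields 0.0070/0.0130 Hz,
not the published 0.0094/0.0106 Hz; no variant of the FIM (reduced parameter
sets, per-peak FIMs, real-part observation) reproduces that pair at N = 128,
so the presets carry the published half-widths verbatim for failure
classification while the constructive code reports what it computes. The
eleven-peak preset likewise ships its published half-widths without
derivation (its printed anchor values do not satisfy a touching split of the
16 Hz pair separation).

## Monte-Carlo protocol

A trial at noise level `σ_v` synthesizes the model, adds seeded noise, runs
one estimator, and optimally matches estimated to true peaks (Hungarian
assignment on absolute frequency error — frequency only, because the failure
rule is frequency-interval based). A trial *fails* when any matched
frequency misses its interval **or** any matched damping is nonpositive (the
disjunctive reading; a conjunctive rule would almost never trigger and would
defeat both clauses). Estimator exceptions (degenerate SVD/eigen cases)
count as failures rather than aborting a long sweep. RMSEs of all four
parameters, per peak, are accumulated over successful trials only — so a
method that fails rarely can legitimately show a *larger* RMSE than one that
discards its hard trials. Phase errors are compared on the circle.

Per-trial generators derive deterministically from
`(master seed, σ index, trial index)`, making sweeps reproducible and
trivially parallelizable. The default grid is 14 evenly spaced values in
`(0, 2.6]`.

Problem sizes: the benchmark defaults follow the reference protocol
(N = 128, M = 64, 500 trials; 3000 for RMSE-focused runs). The test suite
uses the same N but fewer trials (20–150 for the structural failure-curve
properties, 500 for the DESE2 vs LS-ESPRIT2 comparison at the top of the
noise range) — enough for the one-sided binomial-slack checks they make.

## What the synthetic generator does and does not emulate

It produces exactly the model class the estimators assume: finitely many
damped cisoids in circular white Gaussian noise, uniformly sampled. Real
FIDs violate this in known ways — baseline and solvent components,
non-Lorentzian lineshapes (field inhomogeneity), colored or correlated
noise, receiver dead-time truncation, frequency drift. Passing tests
therefore demonstrate correctness of the algorithms under the model, and the
benchmark ranks methods under exactly the published conditions; they do not
certify performance on experimental spectra, where model-order selection
(not addressed here — `p` is always user-supplied) is often the harder
problem.

## Numerical choices and limitations

- "Exact recovery" tolerances: 1e−8 relative on poles, 1e−6 on parameters
  (double-precision SVD/eig noise floor with margin); the acceptance checks
  use 1e−5 across all methods and presets.
- TLS uses the classical SVD partition of `[A | B]`; the nongeneric case
  (singular bottom-right block, condition > 1e12) raises a dedicated error.
- Degenerate inputs raise rather than return garbage: duplicate poles in the
  Vandermonde fit, coincident peaks in the FIM, infeasible `(N, D, p)`.
- The amplitude/phase fit is plain least squares; no weighting for the
  (white) noise is needed.
- Model-order selection, vendor NMR formats, non-uniform sampling and
  de-aliasing filters are out of scope.
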