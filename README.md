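# decspec

Decimative subspace spectral estimation for exponentially damped complex
sinusoids, aimed at time-domain quantification of NMR signals (FIDs).

A free-induction decay is modelled as

```
s(n) = Σ_{i=1..p}  b_i · e^{jψ_i} · e^{(−d_i + j2πf_i)·n/fs},    n = 0..N−1,
```

with frequencies `f_i` (Hz), damping factors `d_i` (rad/s), amplitudes `b_i`
and phases `ψ_i` (degrees), observed in circular complex white Gaussian noise
(per-component standard deviation `σ_v`). The task is to recover all 4p
parameters from N noisy samples — hard precisely when peaks are close
relative to their linewidths.

The core method, **DESE** (decimative state-space estimation), relates the
D-row-shifted pair `S↑_D`, `S↓_D` of the near-square Hankel data matrix: the
nonzero eigenvalues of `X = S↓_D · pinv(S↑_D)` are the *decimated* poles
`z_i^D`. Decimation multiplies angular pole separations by D — improving the
resolvability of close peaks — while the Hankel matrix keeps its full
`≈ N/2` size, so the usable model order does not shrink as D grows. In noise
the up-shift matrix is first replaced by its best rank-p approximation
(SVD truncation). The package also provides the comparison methods:

- **CONDE** — conventional decimation from the concatenated Hankel matrices
  of the D decimated subsequences and their global covariance (matrix size
  falls as `N/(2D)`);
- **TLS-ESPRIT / LS-ESPRIT** (HSVD) and their decimative versions, which
  shift the p-dimensional signal-subspace basis by D rows;
- **MATPEN** (= DESE with D = 1) and **CSE** (both shifts enhanced);

plus Cramér–Rao bound machinery that sizes the frequency "resolution"
intervals used to declare a Monte-Carlo trial a *failure* (bad run), and a
benchmark driver producing failure-rate and RMSE curves over noise grids.

## Worked example

Synthesize the classic two-peak reference signal (`f = 0.2, 0.22` Hz,
`d = 0.01, 0.02` rad/s, unit amplitudes, fs = 1) and quantify it with DESE at
decimation factor 2:

```sh
decspec simulate --preset two_peak --sigma 0 --N 128 --out two.csv
decspec estimate --in two.csv --method dese --p 2 --D 2 --out two_result.tsv
cat two_result.tsv
```

```
peak	f_hz	d_rad_s	amplitude	phase_deg
1	0.2	0.010000000000000139	1.000000000000009	1.57669401832992e-14
2	0.22000000000000003	0.019999999999999844	0.999999999999995	-1.7053025658242404e-13
```

Noise-free, the decimated pipeline returns every table parameter to machine
precision — frequencies 0.2/0.22 Hz, dampings 0.01/0.02 rad/s, unit
amplitudes, zero phases. The same works from Python:

```python
from decspec import DESE, preset, synthesize, add_noise

ps = preset("two_peak")
ts = add_noise(synthesize(ps.model, 128), sigma_v=0.5, seed=7)
est = DESE(p=2, D=2, fs=ps.model.fs).fit(ts)
est.frequencies_, est.dampings_, est.amplitudes_, est.phases_
```

CRLB-derived failure intervals, e.g. for the five-peak ³¹P liver-spectrum
preset whose closest pair is peaks 4 and 5 (353 and 478 Hz):

```sh
decspec crlb --preset five_peak_31p --pair 4 5
```

```
# touching half-widths (Hz), anchors 4 and 5: sigma* = 8.8386
peak	half_width_hz
1	82.4179
...
4	42.5821
5	82.4179
```

Peak 4 (lightly damped, well estimated) gets the small 43 Hz interval; the
heavily damped peak 5 gets 82 Hz; the two intervals exactly span the 125 Hz
separation. A Monte-Carlo failure/RMSE sweep:

```sh
decspec benchmark --preset two_peak --methods dese,ls_esprit --D 2 \
    --sigma-grid 0.2:2.6:14 --trials 500 --seed 1 --out bench.tsv
```

writes one TSV row per (method, noise level) with failure counts and
per-peak RMSEs over successful trials, plus a JSON manifest that makes the
run reproducible.

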