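# Methods

This note records the statistical models `syncflow` implements, the
assumptions behind them, and the reasoning for every default parameter.
Units are given for each quantity. The synthetic problem sizes used in
tests and in `scripts/acceptance.py` are the package's own choices, scaled
so that the full analysis runs on one CPU in under a minute per check.

## 1. Kinematic features

* **Acceleration magnitude** — the Euclidean norm of the 3-axis wrist
  accelerometer signal per sample. Magnitude is orientation-invariant, so
  performers wearing sensors at different angles remain comparable, at the
  cost of discarding direction.
* **Window averaging** (default 2 s) — block means on a coarser grid; a
  trailing partial window is averaged over the samples it contains rather
  than dropped, so the series' total duration is preserved.
* **Motion energy** — the summed absolute inter-frame pixel difference of a
  video, one value per frame transition. It is invariant to constant
  luminance offsets and zero iff consecutive frames are identical.
* **Sound energy** — mean squared audio amplitude per bin (power, not
  amplitude, so it is phase-invariant).
* **Resampling** (`resample_to_grid`) — bin means on the target grid;
  empty interior bins are linearly interpolated between the nearest filled
  bins, and edge bins clamp to the nearest filled value. Bin means (rather
  than pointwise interpolation) are used because all sources here are far
  denser than any target grid, and averaging is the natural anti-alias.

## 2. Cross-recurrence quantification analysis (CRQA)

Two series `x`, `y` on a common grid with spacing `dt` are optionally
delay-embedded (dimension `m`, delay `τ` samples); points `(i, j)` are
recurrent when `||X_i − Y_j|| ≤ ε` (inclusive radius). The **recurrence
rate** is the fraction of recurrent points in the diagonal band
`|i − j|·dt ≤ L`.

Defaults and their reasoning:

* `embedding_dim = 1`, `delay = 1` — acceleration magnitude is already a
  univariate state summary; higher embeddings are supported but not needed
  for band-restricted rate estimation.
* `lag_window = 2.0 s` — synchrony between dancers tolerates short
  leader–follower lags; a ±2 s band credits near-simultaneous movement
  without crediting coincidental matches at long lags.
* `radius = 10.0` raw accelerometer units — wrist accelerometers report
  integer counts of 1/64 g, so movement swings span tens of units; 10 units
  is a discriminative fraction of the trace spread at the synthetic
  amplitude (below). With `normalize=True` both series are z-scored first
  and the radius is in SD units (default then 0.5 SD), which removes
  amplitude differences; normalized mode is the right choice whenever the
  two series' scales are not physically comparable (e.g. rating streams),
  and whenever amplitude itself varies with the quantity under study.
* **Windowed recurrence** (default 3 s, non-overlapping, width = step) —
  when normalization is requested, the *whole series* is z-scored once and
  windows are cut afterwards; per-window normalization would change the
  meaning of the radius from window to window and is undefined for locally
  constant windows.
* **Group agreement** — rating streams are first bin-averaged to a 1 s
  grid (ratings move on a seconds timescale; the native sampling rate is
  interface jitter), then all unordered within-group pairs are windowed and
  averaged. Group differences use **Welch's t** (unequal variances,
  Welch–Satterthwaite degrees of freedom), since there is no reason to
  assume equal variance between, say, expert and novice groups.
* `pairwise_recurrence` reports **ordered** pairs (N(N−1) results, e.g. 90
  for 10 performers); the rate is symmetric at embedding dimension 1, and
  the unordered value is computed once and mirrored.

## 3. Inter-subject correlation (ISC)

For each voxel, ISC is the mean raw Pearson correlation over all unordered
subject pairs, computed via the identity
`sum_{i<j} z_i·z_j = ((Σz)² − Σz²)/2` on per-voxel z-scored series
(population SD). Zero-variance voxels are set to r = 0 and flagged rather
than raising, because masked-in but empty voxels are routine in real data.
Raw r (not Fisher z) is averaged for the summary map; Fisher z
(`atanh`, r clamped to ±(1 − 1e−7)) is applied where maps feed parametric
or permutation group tests, where variance stabilization matters.

* **Circular-shift bootstrap** — each resample rotates every subject's
  series by an independent uniform offset in [1, T−1] and recomputes the
  statistic; `p = (1 + #{null ≥ obs}) / (1 + n)`. Rotation preserves each
  series' autocorrelation, which is exactly the property that breaks naive
  parametric p-values for smooth time series. Z-scoring is shift-invariant,
  so it is done once.
* **FDR** — Benjamini–Hochberg step-up: reject all `p ≤ p_(k*)` with
  `k* = max{k : p_(k) ≤ kq/m}`, default `q = 0.05`.
* **Temporal high-pass** (cutoff 100 s) — projection onto the complement of
  an intercept + linear trend + discrete cosine basis (periods above the
  cutoff). 100 s is the conventional boundary separating scanner drift
  from stimulus-driven fluctuations; the linear term is included because a
  within-run monotone drift is the dominant artifact and is not fully
  captured by the truncated cosine set.
* **Spatial smoothing** — Gaussian kernel parameterized by FWHM in mm
  (σ = FWHM / 2√(2 ln 2)), default 3 mm on a 3 mm grid: enough to tame
  voxel noise in per-subject correlation maps without erasing cluster
  structure at the small synthetic grid sizes.
* **Permutation tests** — one-sample (sign flip) and two-sample (label
  exchange) max-statistic tests give family-wise corrected one-sided
  p-values. When `n_perm` reaches the full enumeration size (2^n or
  C(n, n_a)) the exact set is enumerated (with a warning) and p is the
  exact proportion. TFCE (E = 0.5, H = 2, dh = 0.1·max, 26-connectivity)
  is available as an alternative enhancement.

## 4. Dynamic ISC and the feature GLM

* **Sliding windows** — 10 volumes wide, stepped by 1 volume (TR = 3 s →
  30 s windows): long enough for a stable correlation estimate, short
  enough to track minute-scale changes in the performance. With T volumes
  the window count is `floor((T − w)/s) + 1`; 680 volumes give 671 maps.
  Window timestamps are the window centres, `(k·s + (w−1)/2)·TR`.
* **Regressor preparation** — each feature series is bin-averaged onto the
  window grid, min–max scaled to [0, 1] (a constant series becomes 0.5
  with a warning and is left unconvolved), then convolved with a Gaussian
  (σ = 2.8 s) whose centre is displaced by 5 s, *delaying* the regressor
  relative to the feature. This lagged Gaussian is an inexpensive stand-in
  for hemodynamic delay — appropriate because the regressand (windowed
  ISC) is itself already a 30 s smoothed quantity, which makes the precise
  shape of the response function secondary to its latency.
* **Orthogonalization** — sequential Gram–Schmidt over mean-centred
  columns in a declared order (the pipeline's default order is
  acceleration, visual motion, synchrony, sound). Later regressors are
  credited only with variance not explained by earlier ones, so betas for
  later columns are order-dependent — a deliberate, declared modelling
  choice, recorded in the design object. Rank deficiency raises an error
  naming the collinear pair.
* **GLM** — ordinary least squares with an always-included intercept; the
  same cosine high-pass is applied to both the design and the per-voxel
  ISC series so filtering cannot reintroduce spurious correlation.
  `df = n − p − 1`; t statistics are mapped through the t tail to normal
  quantiles, capped at |z| = 38 (beyond which the normal tail underflows
  double precision).
* **Cluster inference** — cluster-forming threshold z > 3.1 (one-sided
  p ≈ 0.001), 26-connectivity components; the null distribution of the
  maximum supra-threshold cluster extent is built by refitting the GLM
  with randomly permuted design rows. Row permutation destroys the
  temporal alignment of the design with the ISC series while exactly
  preserving both marginal distributions.

## 5. Synthetic data: generative models and assumptions

All generators take explicit seeds (NumPy `default_rng`) and record their
parameters in a `GroundTruth` object; identical seeds give bit-identical
output.

* **Performers** — each axis of each performer is
  `amplitude · (c·shared + (1−c)·private) + noise`, where `shared` and
  `private` are Gaussian white noise smoothed with a 0.5 s moving average
  (movement has no energy above a few Hz) and the coupling `c` follows the
  piecewise-constant synchrony schedule. The pairwise correlation of two
  performers' axes is `c² / (c² + (1−c)²)`, strictly monotone in `c`, so
  CRQA-derived synchrony provably tracks the schedule. `amplitude = 30`
  raw units matches the scale of integer 1/64 g accelerometer counts and
  makes the default CRQA radius of 10 raw units meaningful. *Known
  limitation:* the mixture variance is `c² + (1−c)²`, so trace amplitude
  dips at intermediate coupling; analyses that must isolate alignment from
  amplitude should use normalized (SD-unit) CRQA radii.
* **Ratings** — bounded [0, 1] random walks starting at 0.5, increments
  mixing a group-shared and a private stream with the same convex rule;
  step SD `0.25/√n` so a full-length walk spans about a quarter of the
  scale. Clipping at the bounds mimics slider saturation.
* **BOLD** — per voxel and subject,
  `y = Σ_f β_f · g_f(t) · η_f[v, t] + √sf · shared[v, t] + √(1−sf) · noise_s[v, t]`,
  where `g_f` is the feature as the GLM will see it (resampled, scaled,
  lag-convolved) and `η_f`, `shared` are group-shared standard-normal
  fields. With all betas zero the expected pairwise correlation equals the
  shared fraction `sf` exactly — that is what makes closed-form recovery
  checks possible. Feature coupling is **amplitude modulation of a shared
  stochastic carrier**, not an additive deterministic term: windowed ISC of
  an additive term would track the feature's within-window variance rather
  than its level, whereas carrier modulation raises the shared-variance
  share to `(sf + β²g²)/(1 + β²g²)` when the feature is high — precisely
  the effect a dynamic-ISC GLM is built to detect. *Limitations:* noise is
  white (no autocorrelation beyond what the carrier induces), the grid is
  small (e.g. 6×6×6 at 3 mm), and hemodynamics are reduced to the same
  lagged Gaussian the analysis uses.
* **Video/audio** — dots on a torus take 1-pixel steps with probability
  equal to the motion schedule, so expected inter-frame pixel change is
  proportional to the schedule; audio is white noise with amplitude equal
  to the schedule (so sound *energy* follows its square).
* **ROI labels** — contiguous equal C-order slabs labelled 1..n; label 0 is
  reserved for background.

## 6. Numerical and interface choices

* Correlations are computed on z-scored series with population SD; the
  pairwise sum identity avoids materializing all pairs.
* CSV series are written with `%.17g` and read with pandas'
  `float_precision="round_trip"`, so write→read is bit-exact for doubles.
  A mandatory strictly-increasing, uniform `time_s` column (relative
  tolerance 1e-6) is validated with the offending row named in errors.
* NIfTI files carry the TR in the 4th header zoom; an explicit TR override
  takes precedence (a non-positive header TR plus an override warns).
  Grid or affine mismatches beyond 1e-4 and non-finite values are format
  errors that name the offending indices.
* The pipeline writes a `run_log.json` with the package version, stage
  parameters, seeds and SHA-256 checksums of every artifact — enough to
  replay a run exactly.
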