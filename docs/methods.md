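# Methods

## Model

The divisive-normalization (DN) pRF model predicts the neural response of a
cortical location to a binary stimulus movie `S(x, y, t)` as

    p(t) = (a · G1·S + b) / (c · G2·S + d) − b/d,

with unnormalized Gaussian fields `G1, G2` (shared centre `(x0, y0)`,
sizes `σ1 < σ2` for activation and normalization pools), amplitudes `a, c`,
and constants `b, d`. `G·S` is the per-frame sum of the field over the lit
pixels — a raw pixel sum, so drives scale with pixel density as
`2π σ² / Δ²` for pixel spacing `Δ`. The blank-screen response is identically
zero. The BOLD prediction convolves `p(t)` with an HRF kernel sampled at the
frame duration.

Two algebraic facts shape everything downstream:

- **Scale degeneracy.** `(a, b, c, d) → λ(a, b, c, d)` leaves `p(t)`
  unchanged for any `λ > 0`. All recovery scoring and group comparisons
  therefore use the canonical ratios `a/d`, `b/d`, `c/d`; the reduced
  formulation with `d = 1` is available as a fitting mode (`fix_d`) and is
  algebraically exact.
- **Signatures.** Holding the rest fixed, larger `b/d` deepens the
  below-baseline deflections seen when only the normalization pool is
  driven (surround suppression); smaller `d` (relative to `c·G2·S`)
  strengthens sublinear response growth (compression).

### HRF

One-parameter kernel: the canonical double-gamma (gamma shapes 6 and 16,
undershoot ratio 1/6) plus `deriv_weight` times its temporal derivative,
rescaled to unit peak magnitude. The derivative is a backward-shifted
difference so the kernel stays causal with a zero first sample. The single
weight absorbs hemodynamic-speed differences across cortex; it is fitted at
the iterative stage of both the Gaussian and DN fits. An alternative
one-parameter choice (an explicit latency shift) would serve the same
purpose; the derivative weight was chosen because it stays within a fixed
linear basis.

### Stimulus

A bar of width 2° (default) sweeps a circular aperture of radius 8° in 8
directions at 45° increments, 16 steps per pass, 4 blank frames after each
pass (T = 160, frame duration 1 s). Bar offsets span
`±(extent − width/2)` so a field-wide bar degenerates to the full aperture,
and opposite directions are exact frame reversals. The visual-field grid
defaults to 100×100 pixels for forward use; synthetic studies use 50×50
(drives differ by well under 1% and simulation and fitting share the grid).

## Fitting

Per vertex, on mean-centred data (BOLD baselines are arbitrary; model
predictions are compared after removing their own mean):

1. **Gaussian grid.** Every (eccentricity × polar angle × σ) node — defaults
   12 log-spaced eccentricities in [0.1, 8]°, 16 angles, 8 sigmas in
   [0.2, 6]° — is scored by the correlation of its HRF-convolved drive with
   the data; amplitude and offset follow in closed form. Localization uses
   the correlation *magnitude*: a suppression-dominated time course
   anticorrelates with its own positive Gaussian prediction, while its
   negation resembles a Gaussian of the normalization-pool width. For such
   vertices the grid node is kept unrefined (refining a negative Gaussian
   drifts off-centre) and the DN stage does the work.
2. **Gaussian iterative.** Bounded trust-region least squares
   (`scipy.optimize.least_squares`, ftol 1e-6, max 500 evaluations) over
   position, size, amplitude and the HRF weight.
3. **DN grid.** With position frozen, a scan over
   `b, d ∈ geomspace(0.01, 100, 6)`, `σ2/σ1 ∈ {1.5, 3, 6}`,
   `c ∈ geomspace(1e-3, 10, 5)` and a σ1 ladder (×{1, 2, 4}, because the
   Gaussian-stage size is biased low under DN data; ÷ the ratio grid for
   suppression-dominated vertices). Scaling a zero-baseline DN prediction
   by a gain g is exactly the parameter map `(a, b) → (g·a, g·b)`, so the
   closed-form gain yields a valid start.
4. **DN iterative.** All eight DN parameters plus the HRF weight, restarted
   from the three best grid candidates plus a Gaussian-equivalent start
   (`b = c = 0, d = 1`; an inverted-Gaussian-equivalent start when the
   Gaussian amplitude was negative). The extra starts cost ~40% time and
   remove basin misses; the Gaussian start guarantees the nesting property
   (DN training R² ≥ Gaussian R² − 1e-6). Ties and non-convergence are
   flagged, never dropped.

**cvR²** fits each run separately and evaluates the regenerated prediction
(full parameter vector, including the HRF weight — never refitted
amplitudes) on the other run, averaging both directions. Participant
parameter maps come from the fit to the two-run average.

### Identifiability at realistic noise

At zero noise the fit recovers positions, sizes and all canonical ratios
essentially exactly. At the synthetic-study noise level (temporal SNR ≈ 3,
defined as sd(clean signal)/sd(noise) per vertex), positions remain
excellent (median error ≈ 0.05°), but the DN constants are weakly
identified: `σ2`, `c`, `b`, `d` trade against each other along near-flat
manifolds of the least-squares surface. Pseudoinverse Cramér–Rao analysis
(projecting out the exact scale null direction) puts the median attainable
relative error of `b/d` and `a/d` near or above 100% in this regime, and
σ1's near 25%; bounded multi-start estimation does somewhat better than the
unbiased bound (medians ≈ 80–100% for the ratios, 15–17% for σ1) but the
limit is informational, not algorithmic — fits started at the true
parameters drift to equally good solutions with very different ratios. This
is why population-level work weights and averages across many participants
rather than trusting single-vertex constants, and why all planted-effect
recovery in this package is evaluated at ROI level after cvR²-weighted
aggregation, where the relationships are recovered reliably.

## Aggregation

Group maps average each parameter across participants per vertex, weighted
by cvR²; participants with cvR² ≤ 0 at a vertex contribute nothing there
(negative values cannot be weights and indicate unreliable fits). Canonical
ratios are averaged as their own columns. The contributing-participant
count map is thresholded data-driven by Li's minimum cross-entropy — an
exhaustive scan over midpoints between distinct counts, minimizing
`−Σ_low v·log μ_low − Σ_high v·log μ_high` — and vertices with
`count ≥ ceil(threshold)` form the inclusion mask. ROI summaries take
cvR²-weighted means of DN parameters and *unweighted* means of receptor
densities (PET-like maps carry no cvR²) over exactly the masked vertices,
so both sides of every comparison see the same support; the ROI weight is
the mean cvR² in the ROI. Whole ROIs can be excluded (e.g. a V1-analogue
robustness re-analysis).

## Statistics

- **Weighted correlation (wCC):** weighted covariance over the product of
  weighted standard deviations; ROI weights are renormalized to mean 1
  (a no-op for the statistic, stabler to report).
- **Permutation test:** two-sided Fisher test permuting the independent
  variable with `y` and weights fixed in place; `p` is the fraction of
  permutations whose |wCC| reaches the observed value (tie-inclusive at
  1e-12). Exhaustive enumeration replaces sampling whenever `n! ≤ n_perm`.
  Zero exceedance is reported as `p < 1/n_perm` with a floor flag, never 0.
- **Receptor GLMs:** weighted least squares (same ROI weights as the
  correlations, for consistency) of one or two receptors plus intercept.
  Cross-validated comparison fits on one participant half's ROI table and
  correlates the prediction with the other half's values; one-receptor
  wCC(cv) carries the fitted slope's sign so anticorrelated receptors
  report negative values. Surrogate-pair tests permute one receptor while
  keeping the other, refit the two-receptor GLM to the true DN constant,
  and compare fit correlations (batched closed-form WLS).
- **PCA:** per-receptor z-scored by default (densities live on different
  scales; raw-covariance mode available), all components kept so variance
  fractions sum to 1, components oriented so the dominant loading is
  positive. Components above the `1/k` equivariance threshold are scanned
  against every DN parameter profile with wCC + permutation tests.

Participant halves for cross-validation are a single seeded random split.

## Synthetic studies

The generator emulates the structure the analysis chain needs, not cortical
anatomy. Defaults (the study conditions used throughout):

- **Truth:** 20 ROIs × 25 vertices. Geometric across-ROI gradients: `b/d`
  2.0 → 0.1 and `d` 3.0 → 0.3 (suppression and linearity both decline from
  early to late ROIs), `σ1` 0.5° → 3.0°, `σ2 = 2.5 σ1`, ROI centres at
  log-spaced eccentricities 1°–6° rotating by the golden angle. Per-vertex
  log-normal jitter (sd 0.1) on positive parameters, Gaussian jitter
  (0.3°) on positions, projected back inside 0.9 × extent.
- **Drive-aware amplitudes.** Because drives are raw pixel sums, `c` is set
  per vertex so the full-field normalization drive is 3 × `d` (the
  normalization constant neither vanishes nor saturates out of the
  response), and `a` so the peak positive response is ≈ 1 regardless of pRF
  size or suppression strength — early-visual-like vertices then show
  positive responses larger than their below-baseline flanks, matching the
  qualitative phenomenology the model is meant to capture.
- **BOLD runs:** two runs per participant sharing parameters, i.i.d.
  Gaussian noise per time point with per-vertex sd = sd(clean)/SNR
  (default SNR 3; AR(1) noise available, default off). Participant effects
  are multiplicative log-normal on ratios/sizes and additive on positions.
- **Receptors:** ROI-level profiles `ρ·z(target) + √(1−ρ²)·noise`, so `ρ`
  is the planted ROI-level correlation; defaults plant ρ = ±0.65 for the
  GABA/5-HT1A-like pair on `b/d` and the 5-HT1B/5-HT2A-like pair on `d`,
  plus weaker eccentricity/size-planted maps to fill a six-receptor set. A
  two-latent-factor construction (six receptors mixing two shared factors
  plus 5% noise) supports the PCA recovery analyses. Vertex values add
  small within-ROI noise; each receptor gets its own scale and intercept so
  standardization is exercised.
- **Participant models.** `"bold"` generates runs for full
  simulate-then-fit studies; `"estimates"` draws per-participant parameter
  estimates (truth + participant effect + estimation noise, cvR² declining
  across the hierarchy from 0.6 to 0.25 with sd 0.15, clipped to
  [−0.3, 0.95] so a few percent of fits are non-contributing). The
  estimates model is the default for replicate-level studies of the
  aggregation/statistics chain: fitting 500 vertices × 40 participants ×
  3 fits through nonlinear least squares is hours of compute and tests
  nothing the 200-vertex fitting benchmarks do not already test. What the
  estimates path does *not* exercise is fitting itself — its passing says
  nothing about fit quality, which is measured separately.

What passing synthetic tests do not show about real data: no cortical
geometry or spatial autocorrelation (receptor noise is exchangeable across
ROIs, so permutation nulls are exactly valid here but only approximately on
real maps), no resolution mismatch between modalities, no physiological
noise structure, and participant effects are symmetric around the truth.

## Numerical choices

- Trust-region reflective least squares, ftol 1e-6, 500 max evaluations,
  per-parameter characteristic scales; grid ties break to the lowest index.
- Bounds: positions ±1.25 × extent, σ1 ∈ [0.1, 10]°, σ2 ∈ [0.1, 40]°,
  `a ∈ [1e-6, 1e3]`, `b, c ∈ [0, 1e3]`, `d ∈ [1e-3, 1e3]`, HRF weight
  ∈ [−2, 2]. Finite bounds (with the grid start) are what pins the scale
  degeneracy in practice.
- Constant/all-zero vertices are flagged `BAD_DATA`; optimizer
  non-convergence keeps the best result found and flags it.
- Degenerate Li input (constant counts) raises; the pipeline falls back to
  `count > 0` with a warning.
- Benchmarks and tests run at sizes chosen for single-CPU minutes: 200
  vertices for recovery, 40 for cvR² contracts, 1000 datasets × 1000
  permutations for calibration, 20 replicate studies for end-to-end sign
  recovery.

## Known limitations

- Single-vertex DN constants are unreliable at realistic noise (see
  identifiability above); only aggregate, cvR²-weighted quantities should
  be interpreted.
- The permutation null assumes ROI exchangeability; spatially
  autocorrelation-preserving nulls are out of scope.
- No wedge/ring stimulus conditions, no surface geometry, no GPU batching.
- Negative (inverted) pRFs are not modelled; the DN model's own
  suppression regime covers negative-going responses instead.
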