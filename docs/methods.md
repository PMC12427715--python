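# Methods

This note documents the models implemented in `dateqi`, the parameters
that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Colorimetry

Color derivatives are computed from CIELAB readings as

* chroma = (a*² + b*²)^½,
* hue angle = atan2(b*, a*) in degrees mapped to [0, 360) — the
  two-argument arctangent is used because the single-argument form is
  quadrant-ambiguous,
* browning index BI = 100(x − 0.31)/0.17 with
  x = (a* + 1.75 L*)/(5.645 L* + a* − 3.012 b*),
* total color difference ΔE*ab = ((ΔL)² + (Δa)² + (Δb)²)^½.

Degenerate inputs raise rather than returning infinities: hue is
undefined at a* = b* = 0, and BI requires a positive denominator (it
goes non-positive only for heavily blue, very dark readings outside the
meaningful browning domain). A `strict_printed` flag on ΔE reproduces a
variant sometimes printed with a minus before the (Δb)² term, for
auditing against sources that carry that typographical form; it raises
when the radicand is negative. The choice of color reference (fresh
control vs. per-group time zero) is the caller's: `ColorReferencePair`
takes any reference reading.

## Composite quality index

Attributes are min–max normalized over the *training* dataset and
averaged with equal weights (no weighting scheme is implemented — none
is established for this use). Each attribute carries a direction tag so
that Qi = 1 always denotes best quality:

* higher is better: moisture content (retention), a_w, pH, hardness,
  all seven sensory scores;
* lower is better: TSS, browning index, ΔE, TVC, YE.

The a_w/pH/TSS/hardness directions are genuinely debatable (e.g. high
a_w favors microbial growth but tracks the moist, fresh state these
fruits are prized for); they default to the direction each attribute
drifts under storage degradation in this system and are configurable
per call. N in the Qi mean is the number of attributes averaged per
sample (default panel of 14: 7 physicochemical + 7 sensory).

A frozen `NormalizationSpec` serializes to JSON and is reapplied to new
data; values outside the frozen range are clipped to [0, 1] after
normalization instead of erroring, so a calibration spec can score
out-of-range future samples.

## Degradation model

Qi versus storage time t (months) is fitted by OLS as linear and
quadratic polynomials; the quadratic is stored in the sign convention
Qi = a·t² − b·t + c, so a positive printed b reads directly as an early
downward trend. Model comparison uses:

* Gaussian-profile AIC = n·ln(RSS/n) + 2k with k = (degree + 1) + 1
  (coefficients plus the error variance). Only AIC *differences* are
  meaningful; absolute values depend on the unknown error scale of the
  original data and are not reproduced.
* The nested extra-sum-of-squares F-test,
  F = (RSS_lin − RSS_quad)/(RSS_quad/(n − 3)), p from F(1, n−3). This
  is the standard construction for comparing two nested regressions on
  one response (a one-way ANOVA between the two model fits has no other
  coherent reading).

RSS = 0 (a perfect fit) makes the Gaussian AIC and the F-test
degenerate; both raise explicit errors. A helper reports the earliest
time at which the predicted Qi crosses a threshold (shelf-life root).

## Spectral preprocessing

Stage order: **window (410–990 nm) → absorbance → MSC → SG second
derivative**. The instrument reports percent diffuse reflectance on a
3 nm grid; modeling uses apparent absorbance A = log₁₀(100/R%), the
standard chemometric bridge. MSC regresses each absorbance row on a
reference spectrum (the training-set column mean, retained for replay
on held-out data) and corrects to (x − α)/β. The Savitzky–Golay second
derivative uses a second-order local polynomial, default window 13
points (≈39 nm on the 3 nm grid); output is trimmed to the fully
windowed interior — no edge padding, so every reported point is a true
local fit.

MSC-before-derivative is a choice (the reverse order is also seen in
practice); fitting MSC before differencing keeps the scatter model in
the space where multiplicative scatter is actually multiplicative.
Window size is configurable; 13 points suppresses channel noise without
washing out the ~30–60 nm bands the generator (and real fruit spectra)
carry. Note the window-11 filter's smoothing bias on a 3 nm grid is
~5% of a band with a 126 nm period (frozen in the tests); finer grids
reduce it quadratically.

All preprocessing is deterministic, never reorders samples, and
serializes its fitted state (window, MSC reference, SG settings) to
JSON for exact replay.

## Splitting and PLSR

Samples are partitioned 70/20/10 into calibration / testing /
independent-prediction subsets. The unit of integrity is the replicate
group — one measurement occasion of one fruit, whose triplicate scans
must never straddle subsets (samples are measured destructively, so
occasions are the independent units). Groups are shuffled with the seed
and assigned greedily to the partition with the largest remaining
deficit against largest-remainder targets; with singleton groups and a
divisible n the subset counts are exact.

PLSR is NIPALS PLS1: mean-centered X and y, no variance scaling (all
predictors share derivative-absorbance units), deflation of both X and
y, weight-iteration tolerance 1e−10 with a 500-iteration cap (the
univariate-response iteration converges in one pass; the loop is
numerical hygiene). Latent-variable count is chosen by grouped k-fold
(default k = 10) cross-validated RMSECV: the global minimum, with
RMSECVs within a machine-precision band (max(1e−8·min, 1e−12·sd(y)))
of the minimum treated as ties broken toward fewer components — without
that band a noiseless rank-k generator would chase rounding jitter past
k. An optional one-standard-error rule is deliberately not defaulted.

Figures of merit: R² (one minus residual over total sum of squares),
RMSEC on calibration, RMSECV from
grouped CV, RMSEP on the independent subset, REP% = 100·RMSEP/ȳ and
RER = range(y)/RMSEP, both on the independent subset, so
RER·RMSEP = range and REP·ȳ = 100·RMSEP hold exactly by construction.
Zero RMSEP reports REP/RER as infinite with a warning. Combined
(cross-cultivar) summary rows average per-cultivar RMSEP/REP/RER in
exact decimal arithmetic and round half-up at 3/2/1 decimals.

## Neural regressor

A deliberately small feed-forward network: default one hidden layer of
32 tanh units, linear output, MSE loss, Adam (lr 2e−3 in the pipeline,
β₁ = 0.9, β₂ = 0.999), mini-batches of 64 reshuffled each epoch from
the seeded generator, early stopping on a replicate-disjoint validation
split (patience 60, max 500 epochs in the pipeline) with restoration of
the best-validation weights. Inputs are standardized per wavelength
with training statistics only; Qi predictions are clipped to [0, 1] at
the interface since the index is defined there. Architecture, epochs
and optimizer are package decisions — no reference topology exists —
and are all exposed in `MLPConfig`. Training is bit-reproducible under
a fixed seed.

In the pipeline, the network's cross-validated predictions come from
grouped 5-fold CV on the calibration subset, with each fold fit
early-stopping on the 20% testing subset — that subset is
replicate-disjoint from every calibration fold, so no fold row enters
its own stopping criterion.

## Microbial release rules

Per composite sample, in log₁₀ CFU/g: TVC accept ≤ 5.0, hold (5.0,
6.0], reject > 6.0; yeast accept ≤ 4.0, hold (4.0, 5.0], reject > 5.0.
Counts exactly at an acceptance limit are accepted (≤ semantics); the
printed hold bands overlap the acceptance bound, so half-open intervals
resolve the boundary. The two analytes combine by worst case. At batch
level any reject excludes the batch; any hold flags it for re-plating
and review; only all-accept batches are released. The decision is
monotone in both counts.

## Synthetic-data generator

The generator emulates the study design latent-first. Per fruit and
month, a latent quality state follows the cultivar quadratic
(Sukkary a = −0.0007, b = 0.0102, c = 0.9719; Khlass a = 0.0021,
b = 0.0521, c = 0.9554), with the decline b·t − a·t² scaled by a
severity multiplier: temperature {25: 1.5, 5: 1.0, −18: 0.5} ×
packaging {OCC: 1.30, CCC: 1.15, CCSPB: 1.00, SSPC: 0.90, PSSPC: 0.65}.
Each family averages to 1.0 over the full factorial, so the design-mean
trajectory equals the generating quadratic and refitting on cell means
recovers the coefficients. Gaussian noise (sd 0.015) is added to the
latent state.

Attributes derive deterministically from that state plus noise:
moisture declines from the group draw (dry-basis means/SDs per cultivar
and hydration group, e.g. Sukkary group A 10.531 ± 0.035%) at 20% of
the initial value per year at severity 1; a_w is affine in moisture;
TSS concentrates as moisture leaves; BI, ΔE, pH and hardness are affine
in the severity-scaled decline (gains 180, 80, −1.2, −40 respectively,
bases documented in `TrajectoryParams`); microbial log-counts
interpolate linearly through month-3/month-12 anchors taken from the
published count tables (Sukkary: full 6-group × 3-temperature grid in
the reference packaging; Khlass anchored at 25 °C with the Sukkary
temperature deltas transferred), with packaging offsets of 0–1.1 log
and noise sd 0.1 (the printed within-cell SDs are ~0.05–0.4); sensory
scores are 1 + 8·q plus sd-0.5 noise, rounded and truncated to the
1–9 hedonic scale.

Spectra are built in absorbance on the 194-point 411–990 nm grid:
a flat 0.45 baseline plus Gaussian bands whose amplitudes are affine —
with small quadratic terms on the water and main pigment bands — in the
linked attributes (970 nm/moisture, 550 and 450 nm/BI, 660 nm/ΔE,
840 nm/TSS). Each scan (3 per fruit-month, sharing a replicate-group
id) applies a multiplicative/additive scatter pair (sd 0.03/0.01), a
random baseline tilt (±0.05 per 1000 nm) and channel noise (sd 0.002),
and is emitted as R% = 100·10⁻ᴬ so the preprocessing conversion path is
exercised. The quadratic band terms are what make the network/PLSR
comparison informative: a linear model cannot fully invert them.

What the generator does **not** emulate: real fruit tissue optics (no
radiative transfer, no instrument-specific noise spectrum), panelist
effects beyond ordinal noise, attribute cross-couplings beyond the
shared latent state, or the published cultivar contrast in microbial
counts (the two published count tables are mutually inconsistent on
that point, so each cultivar is anchored to its own table). Passing
tests on synthetic data therefore demonstrate that the pipeline
recovers signals *of the assumed structure* at realistic noise — not
that real-spectra performance figures are reproduced; the published
absolute calibration R²/RMSEC values for real fruit are out of reach
without the original spectra and are not claimed.

## Problem sizes

The desk-scale design (2 cultivars × 3 moisture groups × 2 temperatures
× 2 packagings × 5 fruits × 13 months × 3 scans = 4,680 spectra) is the
package's default working size: large enough for stable 70/20/10 splits
and grouped CV, small enough that the full simulate → preprocess →
calibrate → evaluate cycle runs in well under a minute on one CPU. The
full published-scale factorial (2 × 6 × 3 × 5 × 7 fruits) is available
via `StudyDesign()` defaults.

## Known limitations

* Qi's equal weighting makes it sensitive to the attribute panel
  composition; adding correlated attributes implicitly up-weights them.
* PLS1 only (single response); multivariate-Y NIPALS is out of scope.
* The MLP has no regularization beyond early stopping; with very small
  calibration sets its CV spread grows.
* Microbial trajectories are piecewise-linear in log counts — adequate
  between the anchor months, but no lag/stationary-phase kinetics.
* The strict-form ΔE flag exists for auditability only; its domain
  error on negative radicands makes it unsuitable for analysis.
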