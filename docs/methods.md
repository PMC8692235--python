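# Methods

## Spectra and containers

A measurement is a vector of detector counts on the instrument's
wavelength grid (default: 3648 uniformly spaced channels spanning
345–1041 nm, ~0.19 nm spacing).  All measurements from one session share
the grid; datasets with mismatched grids are rejected rather than
resampled, because resampling would silently alter noise correlation and
band shapes.  Spectra and metadata are stored as a wide CSV pair
(UTF-8, comma-delimited, 17-significant-digit floats), which makes round
trips bit-exact; background (`BG`) and white-reference (`WHITE`) columns
are addressable references, not analysis rows.

## Preprocessing

Steps run in a fixed order; each is linear except the final
normalization:

1. **Background subtraction** `X = XR − B` removes ambient light.
   Negative values are kept — clipping would bias the subsequent moving
   average upward.
2. **White-reference division (DR only)** `X = (XR − B) / W`.  `W` is
   the PTFE reference, itself background-corrected by default
   (`white_background_corrected=True`): room light contaminates the
   reference exactly as it does the tissue signal.  Channels where `W`
   falls below `1e-6 × max(W)` are masked (NaN) rather than divided;
   if more than 20% of in-window channels are masked the calibration is
   rejected as unusable.
3. **Smoothing**: centered moving average over a 10 nm window.  The
   half-width in samples is `round(window / (2 × median spacing))`, so
   the window is always an odd number of samples — a symmetric,
   phase-free filter.  At the spectrum edges the window shrinks
   symmetrically (it never extends past the grid), which keeps the
   filter unbiased for locally linear signals; the affected edge
   channels are discarded by the windowing step anyway.  Masked channels
   are excluded from neighbours' averages and stay masked.
4. **Windowing** to the closed interval 435–900 nm (AF) or 450–900 nm
   (DR), dropping the noisy spectral extremes.  The pipeline order is
   smooth-then-window; the two do not commute at the window edges.
5. **Peak normalization** `XN = X / max(X)`.  The maximum becomes
   exactly 1 (ties need no special handling — the division is by the
   value, not the location); negative channels scale, they are not
   clipped.  A spectrum whose maximum is not positive has no meaningful
   shape and is rejected.

## PCA features

Covariance-PCA (mean-centering only): normalized spectra already share a
common scale, and per-wavelength variance scaling would inflate the
quiet spectral regions.  The fit is the SVD of the centered matrix;
explained-variance fractions are taken against the total variance, so a
full-rank fit's fractions sum to one.  Loadings are sign-fixed by making
each component's largest-magnitude coefficient positive, which makes
stored models reproducible across linear-algebra backends.  Three
components are retained by default: in the bundled simulations (and, by
design, in tissue spectra dominated by a few chromophore/fluorophore
factors) they carry > 97% of the variance.

## Classification and evaluation

The quadratic discriminant classifier models each class as a Gaussian
with its own covariance:

    δ_k(x) = −½ ln|Σ_k| − ½ (x−μ_k)ᵀ Σ_k⁻¹ (x−μ_k) + ln π_k

with empirical priors π_k = n_k/n and sample covariances
(n_k − 1 denominator).  A ridge `γ = 1e-8 × trace(Σ_k)/d` is always
added to the diagonal: replicate probe placements can be nearly
collinear in score space, and the ridge guarantees positive-definite
covariances without measurably moving well-conditioned fits.  Posteriors
are the softmax of the discriminants, computed with log-sum-exp.

Cross-validation is stratified fivefold: within each class a seeded
permutation deals rows round-robin into folds, so per-class fold sizes
differ by at most one; if the smallest class has fewer than five
members the fold count drops to that size (with a warning).  Held-out
posteriors are pooled into a single ROC per comparison — one AUC per
comparison, not a per-fold average.  The ROC sweeps unique score
thresholds with ties grouped, and the trapezoidal AUC then equals the
pairwise concordance `P(s⁺ > s⁻) + ½P(s⁺ = s⁻)` exactly.  Multiclass
comparisons report one-vs-rest AUCs, each scored by that class's own
posterior.

Two PCA scopes are available in the pipeline.  `pca_scope="fold"`
(default) refits the PCA inside each training fold and projects the test
fold — the leakage-free protocol.  `pca_scope="global"` fits one PCA on
the whole comparison and cross-validates only the classifier, matching
the conventional presentation in which feature extraction precedes
classification; on the bundled scenarios the two differ negligibly, but
both are exposed because the choice matters for small samples.
Fold stratification is per measurement; replicates of one animal can
therefore fall on both sides of a split.  A `collapse`-style grouping by
animal is deliberately out of scope here and flagged as a caveat: with
per-measurement pooling, AUCs on real triplicate data are optimistic.

## Pointwise statistics

Per-wavelength group means carry t-based 95% confidence intervals
(`mean ± t_{0.975, n−1} · sd/√n`); t rather than normal because group
sizes are small (a few animals × sides × triplicates), with
`method="normal"` available.  Two groups are "separable" at a
wavelength where the CIs do not overlap, or where a two-sample Welch
t-test (unequal variances — no reason to assume homoscedastic groups)
rejects at α = 0.05.  Contiguous flagged channels merge into intervals.
No multiple-testing correction is applied across wavelengths; the bands
are descriptive localization of spectral differences, and at the null
~5% of channels (isolated single-channel flags) are expected by
construction.

## Synthetic data generator

The generator emulates the measurement physics well enough to exercise
every pipeline stage with known ground truth:

- **AF**: `raw = g · A·Σ_f c_f E_f(λ) · exp(−Σ_c k_c μ_c(λ)) + ambient + ε`,
  where `E_f` are Gaussian emission bands, and the Beer–Lambert factor
  also attenuates fluorescence (a fiber-optic AF signal is a hybrid of
  emission and the absorption/scattering that shapes DR; a flag disables
  this for ablation).
- **DR**: `raw = g · W(λ) · a(λ/500)^{−b} · exp(−Σ_c k_c μ_c(λ)) + ambient + ε`,
  with `W` a smooth lamp-like curve and a power-law scattering term.
- **Variability**: concentrations are lognormal around class means
  (multiplicative, so they stay positive) with configurable CV; the
  per-acquisition gain `g` is lognormal (probe contact / source power);
  read noise is additive Gaussian; the ambient background is flat.

Defaults: fluorophore bands at 475 nm (collagen), 550 nm (flavin/FAD),
650 nm (porphyrin), 600 nm (lipofuscin), widths 15–20 nm; chromophore
bands at 542/576 nm (oxy-heme), 556 nm and 760 nm (deoxy-heme);
scattering exponent b = 1; signal scale 1000 counts, gain jitter 5%,
read noise 20 counts (2%), ambient 50 counts; concentration CV 20%.
All magnitudes are synthetic modeling choices — quantitative optical
coefficients for these tissue classes are not available — anchored only
to qualitative band positions.  The default `muscle_types` scenario
puts all class structure into three fluorophore factors under a shared
fixed attenuation, so the preprocessed data are (up to noise) a
three-dimensional family — the regime the three-component default is
designed for.  Disease scenarios scale single factors: `nf1_like`
doubles collagen and halves heme; `dystrophic_aging` raises lipofuscin
2.5×.

What the generator does **not** emulate: photon transport (no diffusion
theory or Monte Carlo), wavelength-dependent instrument response,
detector nonlinearity/saturation, autofluorescence bleaching, intra-
animal correlation between replicates, or left/right asymmetries.
Passing tests therefore validate the *analysis chain* — calibration
algebra, feature extraction, classifier calibration, ROC behaviour,
statistical error rates — not the biological fidelity of any particular
AUC value on real tissue.

## Problem sizes and numerical choices

Validation studies use 30–50 measurements per class on the full
3648-channel grid; null calibration averages 100 seeded repetitions and
power/recovery checks use 25.  These sizes give Monte-Carlo standard
errors well inside the asserted bounds (a single 50-vs-50 null AUC has
~0.08 spread; its 100-rep mean ~0.008).  Degenerate inputs fail loudly:
empty windows, non-positive normalization maxima, classes with fewer
than two members, zero-variance matrices.  CSV outputs are written with
fixed float formats so identical configs reproduce byte-identical
reports.

## Known limitations

- Pointwise separability bands are uncorrected; treat them as
  descriptive, not confirmatory.
- QDC with 3-D scores needs ≥ ~10 members per class for stable
  covariances; below that the ridge dominates and posteriors flatten.
- The wide-CSV format holds the full grid in memory; a session of
  thousands of measurements would warrant a chunked store.
- One shared background/white per simulated session; per-site background
  capture is supported by the file format but not generated.
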