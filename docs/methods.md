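# Methods

This note documents the models, conventions and design choices behind
`rsfusion`, in the order the pipeline runs.

## Synthetic cohorts

The generator produces two-group 4D BOLD grids in which each downstream
measure has a planted, parameterized cause:

- **Background.** Every voxel carries independent Gaussian noise
  (sd `baseline_noise_sd`, default 1, the unit of all effect sizes) on a
  constant baseline (`baseline_mean`, default 100) plus a subject-wide
  linear drift (slope ~ N(0, 0.5) over the scan). The positive baseline
  puts Rician corruption at σ ≈ 1–2 in the high-SNR regime typical of
  magnitude MR images; detrending removes it before any measure is
  computed, so it affects nothing else.
- **Latent signals** are sums of five sinusoids with frequencies drawn
  uniformly in 0.01–0.1 Hz and uniform phases, scaled to unit variance.
  This guarantees in-band spectral energy, so ALFF/fALFF effects are
  well-defined by construction.
- **Effects.** `alff` regions add an independent such oscillation per voxel,
  scaled by `effect_size` (an amplitude in noise-sd units). `reho` regions
  add one shared latent series to every region voxel with mixing weight
  `effect_size` ∈ [0, 1], raising within-neighbourhood concordance. `vmhc`
  regions (mirror-closed voxel sets) add one latent per mirrored pair to
  both partners, raising homotopic correlation.
- **Determinism.** Subject i of a cohort uses seed
  `cohort_seed · 10⁶ + i`, with separate noise and signal streams, so any
  subject can be regenerated in isolation and identical specs give
  bit-identical cohorts.

The desk-scale default spec — 12×14×12 grid of 3 mm voxels, T = 120 at
TR = 2 s, 10 + 10 subjects — keeps a full multi-scheme pipeline run in the
tens of seconds on one CPU while leaving ≥ 37 DFT bins in the analysis band.
`default_effect_regions()` defines the package's standard strong-effect
condition: three disjoint 3×3×3 regions (the VMHC one a mirrored pair) with
an ALFF amplitude of 4, ReHo mixing 0.9 and VMHC mixing 1.0. These values
are chosen so each family's planted voxels separate the groups by roughly an
order of magnitude more than the between-subject noise (two-sample t of
18–47 at the region core), i.e. a regime where recovery is expected and a
failure indicates a pipeline defect, not sampling luck.

What the generator does **not** emulate: haemodynamic response shapes,
motion, physiological (cardiac/respiratory) noise, spatial autocorrelation
of the background, anatomy, or scanner drift beyond a linear term. Passing
tests therefore demonstrate the correctness and leakage-freedom of the
machinery, not expected accuracy on real cohorts.

## Preprocessing

Volumes are assumed already aligned to a common grid (spatial registration
is out of scope). Per in-mask voxel:

1. **Linear detrend** — least-squares line (intercept + slope·t) removed.
2. **Ideal bandpass** (ReHo/VMHC path only) — rectangular frequency-domain
   filter: DFT bins with 0.01 ≤ f ≤ 0.1 Hz retained, everything else
   including DC zeroed. An ideal filter (rather than, say, Butterworth)
   matches the dominant convention of resting-state toolchains. Bins are
   tested with an ε = 1e−12 edge tolerance so bin-edge ties are stable.
3. **Spatial smoothing** of the final maps — separable Gaussian with
   per-axis sd = FWHM/(2√(2 ln 2))/voxel_size, as mask-renormalized
   convolution (smooth the masked map, divide by the smoothed mask). This
   preserves constants exactly for any mask and avoids edge dimming.

ALFF and fALFF are computed on *detrended-only* series: bandpassing to the
analysis band first would make fALFF identically 1. ReHo and VMHC are
computed on detrended + filtered series. Maps are z-scored per subject over
the mask (population-sd convention) and then ALFF/fALFF/ReHo maps are
smoothed with 4 mm FWHM; VMHC is not re-smoothed (its mirrored structure is
already spatially pooled and re-smoothing would mix flagged midline voxels
into their neighbours).

## Activity measures

- **ALFF** uses the one-sided amplitude spectrum `2|X(f)|/T` and averages
  over in-band bins. "Amplitude" rather than power follows the measure's
  standard usage; mean power would simply square the per-bin terms and is
  trivially derivable from the same spectrum.
- **fALFF** divides in-band amplitude mass by the mass over all positive
  frequencies up to Nyquist; 0/0 (a constant series) is defined as 0.
- **ReHo** ranks each voxel's series over time (average ranks at ties, no
  tie correction — BOLD values are continuous, so ties have measure zero)
  and computes Kendall's W over the K ≤ 27 in-mask voxels of the centred
  3×3×3 cube. Edge voxels use their available K < 27 neighbours; isolated
  voxels (K < 2) get W = 0 and a flag.
- **VMHC** correlates each voxel with its mirror across the first grid
  axis; r is clipped to ±(1 − 1e−7) before `atanh` so perfect homotopy stays
  finite. Self-mirrored (odd-grid midline), unpaired and zero-variance
  voxels get 0 and a flag. The grid is assumed left–right symmetric, which
  synthetic grids are; real data would need a symmetric template.

## Feature selection

In-mask voxels of the requested measures are concatenated in fixed
(measure, voxel-index) order; requesting several measures is feature-level
fusion, and selection always runs *after* fusion. All rankers standardize
features internally from the data they are given (training subjects only,
in CV contexts) and break score ties by ascending feature index, making
rankings deterministic and permutation-equivariant.

- **FSV** minimises
  `(1−λ)·(mean class-A slack + mean class-B slack) + λ·Σⱼ(1 − e^{−α vⱼ})`
  over a separator (w, γ) with |w| ≤ v, by successive linearization: each
  iteration replaces the concave term with its tangent and solves an LP
  (HiGHS). Defaults λ = 0.5, α = 5, tol = 1e−6, max 50 iterations — the
  method's canonical settings. The iteration starts from the
  slack-minimising separator (first LP with negligible cost on v), because
  v = 0 is always a fixed point of the linearization on standardized data
  at these settings and would select nothing. Like any concave program the
  result is a local solution; on separable data the retained support can
  include weakly-contributing features.
- **L0** trains the linear SVM, multiplies each feature's scale by |wⱼ|,
  and repeats (default 10 rounds) until the normalised scales change by
  < 1e−6; accumulated scales are the scores. An all-zero round falls back
  to the first round's |w|.
- **Relief** min-max scales features, then for each subject adds
  |x − nearest-miss| − |x − nearest-hit| per feature (1 hit/miss, all
  subjects sampled by default).
- **Wilcoxon** uses the exact rank-sum distribution when both groups have
  ≤ 10 subjects and the feature is tie-free, otherwise the normal
  approximation with tie correction; constant features get p = 1.

**Sequential forward selection** evaluates k = 1..k_max by the supplied
validation accuracy and returns the *smallest* k attaining the maximum.
k_max is capped at min(feature count, 200) at desk scale.

**Pre-screening.** Inside nested CV the ranker can be preceded by a
mass-univariate screen keeping the `n_prescreen` largest-|t| features of the
training subjects (the pipeline default is 64). This keeps the FSV LPs small
and, equally important at n ≈ 18 training subjects, uses a continuous score:
an exact rank-sum screen has a granularity floor there, which lets
chance-perfect noise voxels tie with genuinely strong ones.

## Classification and fusion

The classifier is the hinge-loss soft-margin linear SVM (libsvm backend)
with C = 10 on per-feature standardized inputs; standardization statistics
come from the training subjects and travel with the model. Patients are the
positive class; the decision value is d(x) = w·x − γ and d = 0 maps to
"patient" (a measure-zero convention). Decision fusion majority-votes the
labels of three single-measure classifiers trained on identical folds; its
reported decision value (for ROC) is the mean of the three. Feature fusion
concatenates measures' matrices before selection.

## Evaluation protocol

Nested CV: per repetition, stratified outer folds (default 10); per outer
fold, ranking and the inner CV run on outer-training subjects only, the
inner CV (stratified, default 10-fold) choosing *only* the number of
features; the final model trains on all outer-training subjects. Fold
counts are capped at the minority-class size of the set being split, so the
desk-scale 10+10 cohort (9 per class in the outer-training set) gets a
9-fold inner loop instead of failing stratification. Test subjects can
influence nothing — not the screen, the ranking, k*, the standardization or
the weights — and the suite asserts this directly by perturbing held-out
rows.

Aggregation: metrics are computed on pooled confusion counts within each
repetition and averaged across repetitions; the spread is reported as the
across-fold standard deviation of per-fold accuracy, and Wilson 95%
intervals are computed on the overall pooled counts. ROC curves come from
test-fold decision values and are vertically averaged (TPR linearly
interpolated at 101 fixed FPR points, endpoints pinned); AUC is the
trapezoid rule on the averaged curve.

The 5×2-CV paired t-test uses t = p₁⁽¹⁾ / √((1/5)Σᵢ sᵢ²) with
sᵢ² = (pᵢ⁽¹⁾−p̄ᵢ)² + (pᵢ⁽²⁾−p̄ᵢ)², compared two-sided against the t
distribution with 5 df (critical value ≈ 2.57 at α = 0.05). Degenerate
cases: all-zero variance with zero difference gives t = 0; with nonzero
difference, t is reported infinite with a warning. It runs as an
independent protocol (its own 2-fold splits), not nested inside the 10-fold
results.

Discriminative maps use the pooled-variance two-sample t per voxel,
two-sided p, and Benjamini–Hochberg (not BY) at q = 0.05 over in-mask
voxels; zero-variance voxels get p = 1 and a flag. Clusters are
26-connectivity components of the significance mask; each contributes its
max-|t| voxel as a peak. An optional `min_abs_t` pre-threshold (off by
default) reproduces z-threshold-style cluster masking.

The Rician robustness protocol corrupts only test-fold volumes
(v → √((v+n₁)² + n₂²), n ~ N(0, σ²)), re-extracts their maps and re-applies
the stored per-fold selection and models without any retraining; σ = 0 is
an exact identity (implemented as a short-circuit — the magnitude
construction would otherwise rectify negative values) and reproduces the
noiseless metrics bit-for-bit. σ is expressed in the same arbitrary units
as the synthetic BOLD values (baseline noise sd 1); no absolute MR intensity
scale is implied.

## Numerical conventions

- Band-edge bin inclusion tolerance 1e−12; VMHC correlation clip 1e−7;
  FSV convergence in the ∞-norm at 1e−6; L0 scale stabilisation at 1e−6.
- Wilson bounds are snapped to exact 0/1 at k = 0 and k = n.
- All stochastic components (cohort generation, fold shuffling, Relief
  subsampling, noise injection) derive from explicit integer seeds; repeated
  runs are bit-identical.

## Known limitations

- The synthetic background is spatially white; smoothing therefore helps
  planted regions more than it would on real, spatially correlated noise.
- At desk scale the inner validation accuracy saturates under strong
  effects, so the smallest-k tie rule typically selects k* = 1–4, far below
  the tens of features a 140-subject study selects; the protocol is
  identical, only the operating point differs.
- FSV's successive linearization finds local solutions; rankings below the
  retained support are driven by the tie rule.
- VMHC assumes grid mirror-symmetry; no symmetric-template registration is
  provided.
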