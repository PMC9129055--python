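# rsfusion

Voxel-wise resting-state fMRI activity analysis and classifier fusion for
two-group (patient vs control) studies, built for methodological work on
schizophrenia detection from resting-state BOLD, where single measures are
combined at the decision level (majority voting) or the feature level
(concatenation before selection).

The pipeline computes four standard activity measures per voxel:

- **ALFF** — amplitude of low-frequency fluctuations: the mean one-sided
  spectral amplitude `2|X(f)|/T` over 0.01–0.1 Hz;
- **fALFF** — fractional ALFF: in-band spectral mass over the total mass in
  (0, Nyquist] (0.25 Hz at TR = 2 s);
- **ReHo** — regional homogeneity: Kendall's coefficient of concordance
  `W = 12 Σ_t (R_t − K(T+1)/2)² / (K²(T³−T))` over the K ≤ 27 time series of
  a voxel's 3×3×3 neighbourhood;
- **VMHC** — voxel-mirrored homotopic connectivity: the Fisher
  z-transformed Pearson correlation `atanh(r)` between a voxel and its
  left–right mirror.

Maps are built from linearly detrended (ALFF/fALFF) or detrended +
ideal-bandpassed 0.01–0.1 Hz (ReHo/VMHC) series, z-scored over the brain
mask and spatially smoothed (4 mm FWHM; VMHC excepted). In-mask voxels
become features; four rankers order them by discriminability — **FSV**
(feature selection via concave minimization, solved by successive LP
linearization), an **L0**-norm approximation by iterative weight rescaling,
**Relief**, and the **Wilcoxon** rank-sum test — and sequential forward
selection picks the feature count that maximises inner-CV validation
accuracy. Classification is a soft-margin linear SVM (C = 10), evaluated by
repeated nested stratified 10-fold cross-validation with confusion-count
metrics, Wilson 95% intervals, vertically averaged ROC curves, the 5×2-CV
paired t-test (threshold |t| > 2.57 at 5 df), voxel-wise two-sample-t
discriminative maps with Benjamini–Hochberg FDR control, and a Rician-noise
robustness protocol that corrupts only test-fold volumes.

Because real cohort data cannot ship with the package, a first-class
synthetic-cohort module generates two-group 4D BOLD grids with planted,
parameterized effects in each measure family (band-limited oscillations for
ALFF/fALFF, shared latent signals for ReHo, mirrored latent signals for
VMHC), so every stage is testable end to end.

## Worked example

```python
import rsfusion as rf

spec = rf.CohortSpec(effect_regions=rf.default_effect_regions(), seed=7)
cohort = rf.generate_cohort(spec)            # 10 patients + 10 controls
mask = rf.full_mask(spec.grid)               # 12x14x12 grid, T=120, TR=2s
features = rf.extract_feature_matrices(cohort, mask)

config = rf.CvConfig(n_repetitions=1, k_max=10, n_prescreen=64, seed=3)
for scheme in (rf.Scheme.single("reho"),
               rf.Scheme.decision_fusion(),
               rf.Scheme.feature_fusion(("alff", "falff", "reho", "vmhc"))):
    report = rf.nested_cv(features, scheme, config)
    s = report.summary()
    print(f"{s['scheme']}: accuracy={s['pooled']['accuracy']:.2f} "
          f"AUC={s['auc']:.3f} mean k*={s['mean_selected_k']:.1f}")
```

prints

```
single:reho: accuracy=1.00 AUC=1.000 mean k*=1.0
decision_fusion:falff+reho+vmhc: accuracy=1.00 AUC=1.000 mean k*=3.3
feature_fusion:alff+falff+reho+vmhc: accuracy=1.00 AUC=1.000 mean k*=1.0
```

The planted effects are strong by design, so each scheme recovers the group
structure essentially perfectly from one to a handful of selected voxels
(`mean k*`); on a zero-effect cohort the same pipeline stays at chance. The
`tests/` suite verifies both, along with the measure-level oracles.

A thin CLI mirrors the library:

```bash
rsfusion simulate --spec spec.yaml --out cohort/ --seed 3
rsfusion extract --measure reho --in cohort/ --out maps/
rsfusion evaluate --scheme feature-fusion:alff+falff+reho+vmhc \
    --cohort cohort/ --out report.json --seed 1
```

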