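# vbmorph

Vertebrobasilar morphometry and white-matter-hyperintensity (WMH)
laterality analysis.

The basilar artery (BA) is formed by the confluence of the two vertebral
arteries (VA). The VAs are usually asymmetric in calibre, the asymmetric
inflow is thought to bend the basilar artery away from the dominant side,
and the resulting hemodynamics have been linked to lateralized white-matter
damage in the posterior circulation. `vbmorph` implements the full
measurement and analysis chain needed to study this on time-of-flight (TOF)
angiography and FLAIR readings:

1. **Reconstruction** — double-threshold segmentation of a TOF-like volume
   (defaults 850/2500 gray levels), largest-component selection,
   marching-cubes surface extraction and Taubin λ|μ mesh smoothing.
2. **Centerlines** — 3D thinning to a skeleton graph with spur pruning;
   automatic artery labeling from the single junction (the vertebrobasilar
   confluence): the branch ending most superiorly is the BA, and the VA
   with greater mean *x* is the left one (+x = subject left).
3. **Morphometry** — per branch: arc length *L*, discrete Frenet curvature
   κ = |r′×r″|/|r′|³ and torsion τ = (r′×r″)·r‴/|r′×r″|², tortuosity
   *L*/chord − 1, tube volume, cross-sectional area π r(s)², and mean
   diameter (2 × median inscribed radius). Two classification rules:
   **vertebral dominance** (diameter difference ≥ 0.3 mm) and **basilar
   curve direction** (lateral deviation of the BA centerline from the
   confluence-to-top chord, "even" below 1 mm).
4. **WMH scoring** — per-region/side ARWMC ratings (0 none / 1 focal /
   2 confluent / 3 diffuse) from annotated lesion records, laterality by
   higher score with a ≥5 mm lesion-count tie-break, WMH/control group
   assignment, and the posterior-communicating-artery (PCom) gate that
   selects subjects whose posterior cerebral arteries depend on the BA.
5. **Statistics** — Mann-Whitney U with tie-corrected z and effect size
   r = |z|/√N; Fisher's exact test with the odds ratio reported as the
   conditional maximum-likelihood estimate of the noncentral
   hypergeometric odds parameter; Spearman correlation on laterality codes
   (right = −1, even = 0, left = +1); logistic regression; and a battery
   that runs the whole comparison set with Bonferroni adjustment at
   α = 0.001.

Because no patient data ship with the package, a **synthetic module**
generates (a) ground-truthed vascular phantoms — a Y-shaped vertebrobasilar
system with configurable VA diameters and planted BA bending, voxelized
into TOF-like intensities — and (b) cohorts whose marginal frequencies and
planted associations (dominance–curve anticorrelation ρ = −0.56,
lateralized lesion burden) match the observational study the battery
expects. Every pipeline stage is tested against these analytic ground
truths.

## Worked example

```bash
vbmorph demo --seed 1 --out demo_out
```

prints (abridged):

```
phantom measurement:
  planted dominance: left (diff 0.60 mm) -> measured left (diff 0.57 mm)
  planted curve: right 3.0 mm -> measured right 3.19 mm
                        test   n   statistic        z  effect_r  odds_ratio        p_raw  significant
                age_by_group 290  4419.5      7.754124  0.455338        NaN  8.90e-15         True
       hypertension_by_group 290  2.42e-17         NaN       NaN  11.284570  2.99e-17         True
  va_laterality_by_dominance  70  3.47e-11         NaN       NaN   0.012870  3.51e-11         True
      ba_laterality_by_curve  52  4.17e-09         NaN       NaN   0.000000  4.17e-09         True
 dominance_by_curve_spearman 290 -0.562913        NaN -0.562913        NaN   1.22e-25         True
       pca_wmh_logistic_full 290  64.587715        NaN       NaN   1.049784  5.45e-08         True
```

Reading this: the phantom's planted left-dominant VA pair (3.4 vs 2.8 mm)
and rightward 3 mm basilar bow are recovered by the voxel pipeline; in the
synthetic 290-subject cohort the WMH group is older (Mann-Whitney z = 7.75,
r = 0.46), hypertension is strongly associated with WMH (conditional-MLE
OR = 11.3), cerebellar WMH lateralizes away from the dominant VA
(OR = 0.013 « 1), pontine WMH lateralizes opposite the basilar curve, and
vertebral dominance anticorrelates with basilar curve direction
(Spearman ρ = −0.56).

The same stages are available programmatically:

```python
import vbmorph as vb

vol, gt = vb.generate_vb_phantom(
    vb.PhantomConfig(ba_bend_mm=3.0, ba_bend_side="right"), seed=1)
row = vb.run_subject(vol)            # one flat morphometry record
row["dominance"], row["curve_direction"]   # -> 'left', 'right'

subjects, lesions = vb.generate_cohort(vb.EffectConfig(n=290), seed=1)
scored = vb.score_cohort(subjects, lesions)
report = vb.analysis_battery(scored, lesions)
```

CLI subcommands: `vbmorph simulate` (phantom NIfTI + cohort CSV),
`vbmorph measure <volume.nii.gz>` (per-subject morphometry CSV),
`vbmorph analyze` (battery report), `vbmorph demo`. Shared flags:
`--config <yaml/json> --seed --lower --upper --dominance-threshold
--even-threshold --flip-lr --out`.

## Documentation

`docs/methods.md` describes the model and estimator choices, default
parameters with units and rationale, what the synthetic generators emulate
(and what they deliberately do not), and known limitations.
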