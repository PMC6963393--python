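# iphquant

Quantification of carotid **intraplaque hemorrhage (IPH)** on MPRAGE-like MR
volumes, and the agreement analysis between manual and semi-automatic
segmentation — run entirely in silico on synthetic phantom cohorts.

IPH is bleeding inside an atherosclerotic carotid plaque; on T1-weighted
MPRAGE images it appears as a hyperintense focus, conventionally defined
relative to the signal of adjacent neck muscle. Clinical practice quantifies
it two ways:

* **Manual reading** — a reader delineates the hyperintensity; plaque
  software typically assists with a region-based (Mumford–Shah family)
  level-set contour.
* **Semi-automatic thresholding** — a voxel is IPH when its intensity exceeds
  a fixed fraction of the mean of three sample points in the
  sternocleidomastoid muscle (SCM): `I > r · μ_SCM` with r ∈ {1.50, 1.75,
  2.00}, retained only where the hyperintensity persists for ≥ 2 consecutive
  slices.

This package implements both routes plus everything needed to compare them:

* `iphquant.phantom` — synthetic subjects (64×64×16 voxels at 0.31 × 0.31 ×
  1.0 mm) with a tubular vessel wall, an eccentric plaque, an ellipsoidal IPH
  at a configurable multiple of the muscle mean, a muscle reference block,
  and Rician noise; ground-truth masks and exact IPH volumes included.
* `iphquant.segment_semiauto` — muscle reference sampling, strict `>`
  thresholding, 26-connectivity components with the two-consecutive-slice
  rule, and the three metrics: total volume (mm³), maximal axial volume
  (mm³), length (mm).
* `iphquant.segment_levelset` — a two-phase piecewise-constant (Chan–Vese)
  region contour restricted to the plaque, the manual-reading proxy.
* `iphquant.agreement` — intraclass correlation from the two-way ANOVA mean
  squares (one-way, consistency, and absolute-agreement forms; default
  ICC(A,1)), 95% CIs (Fisher-z or exact F), the six-band interpretation
  scale (poor → almost perfect), the one-sided Fisher-z comparison of two
  ICCs `z = (z(ρ̂_a) − z(ρ̂_b)) / √(1/(n_a−3) + 1/(n_b−3))`, and Bonferroni
  correction.
* `iphquant.study` — the full pipeline: simulate a cohort → segment every
  subject four ways → ICC table → pairwise comparisons, with CSV/JSON
  exports.

## Worked example

```bash
python examples/05_full_study.py
```

```
ICC of IPH volume vs the manual proxy (two-way absolute agreement):
  manual vs 150%: 0.770 (0.604, 0.873)  substantial
  manual vs 175%: 0.501 (0.224, 0.703)  moderate
  manual vs 200%: 0.404 (0.106, 0.636)  moderate

One-sided Fisher-z comparisons (Bonferroni m = 2):
  150%>200%: z = 2.5484, adj. p = 0.01082
  175%>200%: z = 0.5229, adj. p = 0.601
```

Each ICC measures how well that threshold's per-subject IPH volumes agree
with the level-set manual proxy across the 40 simulated subjects (contrast
ratios uniform on 1.3–3.0, Rician noise). The ordering ICC(150%) ≥
ICC(175%) ≥ ICC(200%) arises because stricter thresholds zero out
low-contrast hemorrhages entirely, while the contrast-based contour still
finds them; the Fisher-z rows test whether the strictest criterion agrees
significantly worse. The other examples (`examples/01…04`) walk through the
phantom, each segmentation route, and the statistics in isolation.

A thin CLI wraps the same library:

```bash
iphquant simulate --out cohort/ --seed 1
iphquant run-study --out study/ --seed 1
```

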