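# bodymap

Statistical analysis of body-image assessments collected on a standard 2D
manikin and a parameterized 3D avatar.

Body image disturbance — a distorted perception of one's own size, shape or
appearance — is central to anorexia nervosa and body dysmorphic disorder and
varies across non-clinical populations too. Digital assessments capture it in
two complementary ways: subjects **outline areas of concern** on a fixed
manikin figure (annotating each area with concern types, emotions and an
intensity rating), and they **adjust per-part size sliders** on a 3D avatar
to show how large they perceive each body part to be. `bodymap` provides the
statistics for both streams, for researchers analyzing such cohorts:

- **Proportional body maps.** Each subject's outlines are filled into a
  binary pixel mask (even-odd rule, pixel-center containment, union across a
  subject's concerns); the group map holds, per pixel, the proportion of
  subjects marking that pixel.
- **Statistical body maps.** Per pixel, the pooled two-proportion z
  statistic compares groups,
  `z = (p₁ − p₂) / √( p̄(1−p̄)(1/n₁ + 1/n₂) )`,
  with significance from a group-relabeling permutation test
  (`p = (1 + #{b : |z_b| ≥ |z_obs|}) / (B + 1)`) and family-wise control by
  cluster extent: 8-connected supra-threshold clusters survive only if their
  pixel extent reaches the (1−α) quantile of the permutation null of the
  maximum cluster extent. Maps can be smoothed with a Gaussian kernel
  specified by its FWHM (σ = FWHM / 2√(2 ln 2)).
- **Avatar calibration and discrepancy scores.** Slider positions map to
  centimeters through two linear segments anchored at in-engine measurements
  taken at slider 0, 0.5 and 1; the discrepancy score is perceived minus
  tape-measured size (negative = underestimation), plus a scaled body
  average across the seven measured parts.
- **Table statistics.** Welch t from summary data (mean, SD, n), Pearson
  chi-square on contingency tables, per-group endorsement tallies,
  Benjamini–Hochberg adjustment, and one-way MANCOVA (Wilks' Λ from
  hypothesis/error cross-product matrices, Rao's F) with post hoc ANCOVA.
- **Synthetic cohorts.** A generator with known ground truth (group-specific
  spatial concern probabilities over named elliptical regions, planted
  perception biases, measurement noise) so every analysis path can be
  validated end to end without patient data.

## Worked example

`examples/statistical_body_map.py` plants a region where concern probability
is 0.6 in one group and 0.2 in the other (40 subjects each, 64×128 raster)
and runs the full map-inference pipeline with 500 relabelings:

```
group a: peak proportion 0.70 over n=40
group b: peak proportion 0.20 over n=40
max |z| = 4.52, min p = 0.0020
clusters found: 1, null 95% max-extent = 293 px
surviving pixels: 838, Jaccard vs planted region: 0.54
```

The observed group difference forms one supra-threshold cluster of 838
pixels, well above the 293-pixel null critical extent, and overlaps the
planted ground-truth region with Jaccard 0.54 — the corrected map localizes
the true effect rather than scattering false positives. The other example
scripts cover cohort synthesis (`synthesize_cohort.py`), slider calibration
and discrepancy profiles (`avatar_discrepancy.py`), and summary-table
statistics including MANCOVA (`summary_tables.py`).

A thin CLI wraps the same library calls:

```sh
bodymap synth --kind default --seed 1 --out cohort.json
bodymap validate cohort.json
bodymap stats2d --cohort cohort.json --perms 5000 --fwhm 6 --seed 1 --out maps/
bodymap calib3d --cohort cohort.json --out discrepancy/
bodymap tables --cohort cohort.json --out tables/
```

Each run writes its rasters (CSV + PNG), tables (CSV) and a JSON manifest
recording the config, seed, input digests and outputs; deterministic stages
reproduce bit-identical CSVs when re-run.

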