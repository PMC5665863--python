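# germaquant

Quantitative 3D image analysis of follicle precursor cells in the
*Drosophila* germarium.

Follicle stem cells at the region 2a/2b boundary of the germarium produce
precursor cells that gradually commit to main-body (Eya⁺ Cas⁻) or
polar/stalk (Eya⁻ Cas⁺) fates while moving posteriorly. Testing how
signalling gradients drive that choice requires measuring marker levels
cell by cell in intact 3D tissue, placing every cell on the
anterior–posterior (AP) axis, and comparing genetically mosaic clones with
their wild-type neighbours inside the same sample. `germaquant`
implements that workflow as a reusable, fully tested Python library:

- **Synthetic phantoms** — seeded germarium-like multi-channel stacks
  (nuclei on a curved epithelial shell, AP expression gradients, mosaic
  clone patches, depth attenuation, PSF blur, shot/read noise) with
  complete ground truth, so every stage can be validated without imaging
  data.
- **Two-pass nuclear detection** — scale-matched blob detection of
  ~2.5 µm follicle-cell nuclei on the nuclear stain, refined to 1.75 µm
  core spots at the masked intensity centroid so that only the strong,
  even nuclear centre is quantified; robust outlier flags for dividing /
  dying / damaged cells.
- **Canonical geometry** — least-squares mid-sagittal plane, rotation to a
  canonical frame ("anterior to the left"), AP coordinate and region
  labels (R1, R2a, R2b_A, R2b_P, R3_S1, …).
- **Quantification** — per-cell mean intensities in the core sphere,
  background estimation from 8–12 core-sized spots in two Z planes,
  floored background subtraction, top/middle/bottom depth-bias QC, and
  three normalization modes: per-sample maximum, internal-control mean,
  and one-phase-decay prediction
  `y(x) = plateau + (y0 − plateau)·e^(−K·x)` fitted to internal-control
  cells.
- **Fate calls and statistics** — bivariate Eya/Cas thresholding into four
  fate states; a variance-gated test tree (F-test → unpaired *t* or
  Mann–Whitney; Brown–Forsythe → ANOVA+Tukey or Kruskal–Wallis+Dunn);
  Fisher's exact test on clone-composition tables; Tukey box-plot
  summaries; fold-change CIs for clone effects.

## Worked example

`examples/02_full_pipeline.py` generates a 50-cell phantom at SNR 10
(seed 42), tilts it by a random 30° rotation, runs the full pipeline, and
scores the result against the generator's ground truth:

```
cells detected: 49  recall 0.98  precision 1.00  localization error 0.046 um
AP axis recovered within 1.19 degrees
eya: normalized intensity vs truth, Spearman rho = 0.959
cas: normalized intensity vs truth, Spearman rho = 0.989
{'R2a': 11, 'R2b_A': 11, 'R1': 10, 'R3_S1': 9, 'R2b_P': 8}
```

Recall/precision score the two-pass spot detection against true nucleus
centres; the axis error is the angle between the recovered and true AP
axes after canonical rotation; the Spearman ρ values show that the
background-subtracted, per-sample-normalized intensities preserve the true
per-cell expression ordering. `examples/04_clone_statistics.py` runs the
mosaic-clone arm of the analysis and prints:

```
fold change: 1.80 (95% CI 1.65-1.97); injected truth 1.83
mann_whitney: p = 4.94e-13 (gate f_test p = 0.000)
composition table [[0, 75], [6, 76]], Fisher exact p = 0.0292
```

The other examples cover phantom generation (`01`) and gradient fitting /
decay normalization (`03`). A thin CLI mirrors the library
(`germaquant phantom|detect|run|stats --help`).

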