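# retitort

Retinal vessel tortuosity analysis for diabetic-retinopathy (DR)
cohort studies, with a fully synthetic fundus benchmark.

Quantitative tortuosity of the retinal vasculature — especially of
**branch arteries** — is an early marker of DR onset and severity.
This package implements the complete analysis chain that turns fundus
images into per-patient, per-vessel-class tortuosity values and
cohort-level statistics:

1. **Synthetic fundus generation** — scenes with a bright optic disk,
   radiating vessel trunks and branches, artery/vein contrast and
   caliber gaps, illumination gradients, noise — and exact closed-form
   centerline curvature as ground truth (`retitort.synthetic`).
2. **Segmentation** — local normalization, rotating multiscale
   second-order Gaussian-derivative vesselness, Otsu-anchored
   hysteresis thresholding (`retitort.segmentation`).
3. **Vessel graph** — skeleton-based centerlines with radii, and the
   optic-disk region-growing criterion separating *main* vessels (the
   largest-caliber vessels originating at the disk) from *branch*
   vessels (`retitort.graph`).
4. **Artery/vein classification** — ten intensity statistics per
   segment (circular regions + centerline samples) into a logistic
   regression (`retitort.av`).
5. **Tortuosity** — the image is lifted to an orientation score
   `U(x, theta)` with anisotropic cake wavelets; at each centerline
   point the constant-curvature lifted curve (exponential curve of the
   roto-translation group) maximizing the integral of `U` gives a
   local curvature `kappa_i` and a confidence `c_i`; a vessel class's
   overall tortuosity is the confidence-weighted mean

   `tau = sum_i c_i |kappa_i| / sum_i c_i`,   reported `x 1e4`

   (`retitort.tortuosity`).
6. **Cohort statistics** — per-class group means ± SD, mean
   differences, and one-way ANOVA for DR-vs-non-DR and across severity
   groups V1/V2/V3 (`retitort.stats`).

See `docs/methods.md` for the model details, defaults, and numerical
choices.

## Worked example

Run the full pipeline on a 20-patient synthetic cohort (the demo
cohort injects a severity effect only into branch-artery curvature;
every other class is a true null):

```sh
retitort all --out runs/demo --seed 7 --config demo.yaml
```

with `demo.yaml`:

```yaml
cohort: {n_patients: 20, image_size: [256, 256]}
```

or equivalently in Python:

```python
from retitort.pipeline import run_pipeline
manifest = run_pipeline({"seed": 7,
                         "cohort": {"n_patients": 20, "image_size": [256, 256]}},
                        "runs/demo")
```

This writes `patients.csv` (one row per patient: group and the four
tau values), the two cohort tables, and a run manifest.  The genesis
table (`table_genesis.csv`) from the run above:

```
 vessel_class  mean_nonDR  mean_DR  difference      F     p  significant
  main_artery      38.956   37.034      -1.922  0.119 0.734        False
    main_vein      34.952   37.773       2.821  0.676 0.422        False
branch_artery      29.853   57.195      27.342 16.374 0.001         True
  branch_vein      42.581   43.208       0.627  0.012 0.914        False
```

and the severity table (`table_severity.csv`):

```
 vessel_class  mean_V1  mean_V2  mean_V3  difference     F     p  significant
  main_artery   32.730   39.903   38.469       5.739 0.657 0.536        False
    main_vein   38.680   36.484   38.154      -0.526 0.152 0.861        False
branch_artery   42.501   62.448   66.636      24.135 8.658 0.005         True
  branch_vein   40.366   43.101   46.156       5.791 0.406 0.675        False
```

Means are tortuosity `x 1e4` in px^-1 units; `difference` is
DR − nonDR (or V3 − V1); `F`/`p` are the one-way ANOVA.  The injected
branch-artery effect is recovered as the only significant row in both
comparisons — the signature pattern of the underlying study design —
while the null classes stay non-significant.  The manifest's QC block
for this run: mean segmentation Dice 0.877 against the ground-truth
masks, and 100% main/branch and artery/vein label accuracy.

Stage-level subcommands (`simulate`, `segment`, `graph`, `classify`,
`tortuosity`, `cohort`) expose the same steps for single images; run
`retitort --help`.

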