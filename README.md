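# pkseg — preclinical PET/CT organ segmentation and pharmacokinetics

`pkseg` is a toolkit for quantitative analysis of whole-body mouse PET/CT
in nanomedicine and radiotracer development. Longitudinal imaging studies
produce hundreds of co-registered anatomical (CT) and functional (PET)
volumes; extracting biodistribution readouts from them requires 3D organ
contours that are prohibitively slow to draw by hand. `pkseg` provides the
full pipeline:

* **Ingestion** — NIfTI volumes and integer label maps with a fixed organ
  index table (1 heart, 2 lungs, 3 liver, 4 spleen, 5 kidneys, 6 tumor),
  JSON acquisition metadata sidecars, affine co-registration, dataset
  manifests and subject-grouped cross-validation folds.
* **Preprocessing** — CT foreground cropping, global CT normalization from
  a pooled-foreground dataset fingerprint, per-volume PET Z-scoring, and
  resampling to a canonical (0.80, 0.15, 0.15) mm geometry.
* **Segmentation** — an anisotropic 3D U-Net (patch (64, 160, 160), six
  downsampling steps, 32→320 channels, instance norm + leaky ReLU,
  strided-conv downsampling, transposed-conv upsampling, skip
  connections), trained with soft Dice + cross-entropy on oversampled
  foreground patches and applied by Gaussian-weighted sliding-window
  inference. The network and its backpropagation are implemented directly
  on NumPy/BLAS, so training and inference run on a plain CPU.
* **Pharmacokinetics** — per-organ %ID/cc, %ID, SUV statistics, raw PET
  intensity statistics, organ volume, and trapezoidal AUC exposure
  (%ID/cc·h) over a timeseries, using the injected dose decay-corrected to
  each imaging timepoint.
* **Evaluation** — Dice similarity coefficient (DSC) and relative volume
  difference (VD) against reference masks; MAE, RMSE, MARE, RMSRE and U95
  error statistics; Pearson correlation; Bland–Altman tables; one-sided
  Welch t-tests with Bonferroni correction for comparing models.
* **Saliency** — Grad-CAM heatmaps explaining per-organ decisions.
* **Phantoms** — a digital-mouse generator producing cohorts of paired
  CT/PET/label volumes with two-phase blood clearance (slow half-life
  5–11 h) and uptake–washout organ kinetics, with closed-form
  pharmacokinetic ground truth for every organ.

The core readouts, for an organ mask with voxel volume `v` (cc),
concentration `c_i` (kBq/cc) and injected dose `D` decay-corrected to the
scan time `t` (`D(t) = D0 · 2^(−t/T½)`):

    %ID    = 100 · Σ_i c_i v / D(t)
    %ID/cc = %ID / (N v)
    SUV    = c / (D(t) / body weight)
    DSC    = 2|G∩S| / (|G| + |S|),   VD = |V(S) − V(G)| / V(G)

## Worked example

Generate one digital mouse, image it at the five study timepoints, and
extract its pharmacokinetics from the ground-truth contours:

```python
from pkseg import PhantomSpec, render_phantom, pk_report

spec = PhantomSpec(seed=7)           # tumor-bearing subject, Cu-64, 8 MBq
cases = []
for t in (1.0, 3.5, 6.0, 24.0, 48.0):
    ct, pet, labels, meta = render_phantom(spec, t)
    cases.append((pet, labels, meta))
per_tp, auc = pk_report(cases)
```

Heart and liver rows of `per_tp` (values rounded):

```
 timepoint_h organ  volume_cc  pid_per_cc   pid  suv_mean
         1.0 heart      0.178       8.087 1.436     1.779
         1.0 liver      1.204       2.028 2.441     0.446
         6.0 heart      0.178       3.312 0.588     0.729
         6.0 liver      1.204       6.759 8.139     1.487
        48.0 heart      0.178       0.064 0.011     0.014
        48.0 liver      1.204       4.360 5.250     0.959
```

The heart (blood pool) starts at ~8 %ID/cc and clears with the subject's
slow-phase half-life, while the liver accumulates to a ~7 %ID/cc peak
around 6 h and washes out slowly — the early-perfusion / late-accumulation
contrast reversal typical of lipid-based agents. The AUC table integrates
exposure over the full series (`liver 275.2 %ID/cc·h` vs
`heart 67.2 %ID/cc·h` here).

The same pipeline runs end to end from the shell:

```bash
pkseg phantom --out raw/ --subjects 6 --seed 7
pkseg prepare --manifest raw/manifest.csv --out prep/
pkseg train   --manifest prep/manifest.csv --out model.npz --fold 0
pkseg predict --model model.npz --ct prep/m000/0001.0h/ct.nii.gz \
              --pet prep/m000/0001.0h/pet.nii.gz --out pred.nii.gz
pkseg pkreport --pet ... --labels pred.nii.gz --meta ... --out pk.csv
pkseg evaluate --pred pred.nii.gz --ref prep/m000/0001.0h/labels.nii.gz \
               --out eval.csv
```

plus `pkseg study` to train modality / timepoint / tumor-status /
organ-subtracted subset models and compare them against the parent model
with Bonferroni-corrected one-sided t-tests.

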