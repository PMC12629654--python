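# eatseg

Automated **epicardial adipose tissue (EAT) volumetry** from non-contrast
cardiac CT (e.g. coronary calcium scoring scans), for imaging researchers
who need a fully automatic, auditable alternative to manual pericardium
contouring.

EAT — the fat enclosed by the pericardial sac — is a biomarker of
coronary artery disease risk, but measuring it manually takes an expert
20+ minutes per scan. `eatseg` implements the standard two-stage automated
design end to end:

1. **Pericardium segmentation** with a 3D UNet++ (nested dense skip
   pathways; blocks of 3³ conv → instance norm → LeakyReLU(0.1); encoder
   channels [32, 32, 64, 128, 256]) on 128³ cubes resampled to 1.6 mm,
   intensity-clipped to [−800, 1200] HU and normalised to [0, 1].
   Training uses per-voxel binary cross-entropy summed over class
   channels, RMSProp, batch size 1 — plus an auxiliary **redundant class**
   (fat-density voxels −198…−80 HU outside the pericardium in the
   inferior 20% of slices) that sharpens the difficult apical boundary.
2. **HU-window fat extraction** on the native-resolution image:

   EAT = { voxels v : pericardium(v) = 1 and −190 ≤ HU(v) ≤ −30 },
   V_EAT = |EAT| · sx·sy·sz / 1000 cm³

Around the core sit the supporting tools a study needs: NIfTI/DICOM I/O
with orientation canonicalization, shape-based interpolation of sparse
(every-5th-slice) manual contours, the agreement-statistics suite (Dice,
relative volume error 100·|V_pred − V_ref|/V_ref, Pearson r, Bland–Altman
bias ± 1.96·SD, ICC(2,1) with F-based CI), and a **synthetic thorax
phantom generator** with analytically known pericardium geometry and EAT
volume — the test substrate for the whole pipeline. The phantom includes
paracardial fat outside the sac, so naive global thresholding demonstrably
fails (> 40% overestimation) while the constrained pipeline recovers the
analytic volume to ~0.1% at 0.8 mm resolution.

The network (forward *and* backward passes) is a self-contained
numpy/numba implementation — no deep-learning framework required — which
keeps the package runnable and its training loop reproducible on a single
CPU.

## Worked example

Generate a phantom, quantify its EAT with the ground-truth pericardium,
and compare against the analytic truth:

```bash
eatseg phantom --n 1 --seed 7 --out work/phantom
eatseg quantify \
    --image work/phantom/case000_image.nii.gz \
    --pericardium work/phantom/case000_pericardium.nii.gz \
    --out work/quant
```

The `quantify` step prints

```json
{
  "volume_cm3": 138.656,
  "n_voxels": 17332
}
```

and writes `eat_report.json` with the HU window, per-slice volume profile
(inferior-first) and the inferior-share statistic, plus the EAT mask as
NIfTI. For this spec the phantom's analytic fat volume is 140.03 cm³, so
the default 2 mm rendering recovers it to ~1%. `eat_report.json` also
shows `inferior_share_20pct ≈ 0.30`: the most inferior fifth of
EAT-containing slices holds ~30% of the volume, the apex-heavy
distribution that makes automated apical segmentation matter.

Train the reduced network on 20 phantoms and evaluate agreement on 5
held-out phantoms from Python:

```python
from eatseg.evaluation import end_to_end_phantom_benchmark
r = end_to_end_phantom_benchmark(seed=0)
print(r["median_dice"], r["median_rel_vol_err_pct"])
# 0.981 6.79  (≈ 6 min on one CPU core)
```

Subcommands `preprocess`, `train`, `predict` and `evaluate` expose the
same stages on your own NIfTI data; every run writes a resolved-config
JSON and version stamp into its output directory.

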