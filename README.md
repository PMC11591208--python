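# orthotrack

Markerless, real-time lung-tumor tracking from orthogonal X-ray
projection images, for researchers in image-guided radiotherapy.
Respiratory motion moves lung tumors by a centimetre or more during
treatment; `orthotrack` implements a patient-specific, segmentation-based
pipeline that localizes the tumor centroid in 3D from a single pair of
kV projections, without implanted fiducial markers.

The pipeline has four stages:

1. **Hybrid deformable augmentation.** From a planning 4D CT (10
   respiratory phases, one annotated phase), the end-exhale volume is
   registered to every other phase, giving deformation fields
   `phi_i`. Training deformations mix inter-phase motion and random
   intra-phase 3D thin-plate-spline (TPS) warps:

   `phi1 = alpha phi_i + (1-alpha) phi_j`,   `phi3 = w1 phi1 + w2 phi2`,

   with `alpha, w1, w2 ~ U(0,1)` and `phi2` a regularized TPS on 20-60
   random control points. Warping the volume and tumor mask by each
   `phi3` manufactures an arbitrarily large labelled training set.
2. **DRR synthesis.** Each synthetic volume and mask is projected to
   digitally reconstructed radiographs at the orthogonal 45/135-degree
   gantry pair (parallel-beam line integrals).
3. **Segmentation.** A TransUNet-style CNN-Transformer network delineates
   the tumor in each view, trained with the composite loss
   `L = 0.6 L_Dice + 0.4 L_BCE`.
4. **3D regression.** A residual CNN maps the two view masks to the
   tumor centroid `(x_LR, y_AP, z_SI)` in mm from the isocenter,
   trained with an MSE loss. A closed-form dual-view triangulation is
   included as a learning-free cross-check.

Evaluation covers Dice similarity (DSC), 95th-percentile Hausdorff
distance (HD95), per-axis and combined centroid RMSE
(`sqrt((e_LR^2+e_AP^2+e_SI^2)/3)`), IoU, tracking success rate (TSR),
phase-binned reports and a Gaussian-noise robustness sweep
(S^2 = 0, 5, 15, 25 on a [0,255] display scale).

Because clinical 4D CT is external data, the package ships a synthetic
4D thorax phantom (ellipsoidal body/lungs/tumor, breathing diaphragm,
moving parenchymal texture, 1-cos respiratory trajectory) with exact
analytic ground truth; the whole pipeline runs end to end on it in
about 10-15 minutes on one CPU.

## Worked example

```python
from orthotrack import RunConfig, run_end_to_end

cfg = RunConfig.tiny(seed=17)          # 64^3 phantom, 200 samples, tiny nets
report, sweep, manifest = run_end_to_end(cfg, "runs/tiny17")
print(sweep.table.to_string(index=False))
print(manifest["metrics"]["test_split_dsc_mean"],
      manifest["metrics"]["phase_noiseless_rmse3d_mm"])
```

prints (about 6-7 minutes of training on one CPU core):

```
  s2  center_error_mm      iou  tsr_percent
 0.0         0.622167 0.874672        100.0
 5.0         0.789538 0.855919        100.0
15.0         0.811980 0.829580        100.0
25.0         0.753420 0.840018        100.0
0.926347078839822 0.42855039820897517
```

Reading this: on the phantom's 10-phase respiratory trajectory the full
cascade (segment both views, regress to 3D) localizes the tumor centroid
with a mean 3D error of 0.62 mm on clean images and 0.75 mm under heavy
Gaussian noise (S^2 = 25), tracking every frame within the 2 mm success
threshold (TSR 100%); held-out synthetic projections are segmented at a
mean DSC of 0.926, and the noiseless trajectory RMSE is 0.43 mm. `iou`
is the mean overlap of predicted and true 2D masks at each noise level.

The same study is scriptable from the shell:

```bash
orthotrack run --preset tiny --seed 17 --out runs/tiny17
orthotrack phantom --preset tiny --seed 17 --out runs/phantom
orthotrack augment --phantom runs/phantom --n 200 --out runs/aug
```

with further subcommands `project`, `train-seg`, `train-reg`, `track`,
`evaluate`, `sweep-noise` for stage-by-stage use (see `--help`).

## Documentation

`docs/methods.md` describes the models, conventions, parameter choices
and numerical details, what the synthetic phantom does and does not
emulate, and known limitations.
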