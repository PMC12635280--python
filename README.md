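# tizmap

Mapping tumor- and immune-cell infiltration in peritumoral edema from
magnetic-susceptibility MRI.

Peritumoral edema around aggressive brain tumors (glioblastoma in
particular) is not just water: it hides infiltrating tumor and immune
cells that conventional MRI cannot separate from vasogenic fluid.
Infiltrated tissue accumulates iron-rich, paramagnetic material
(tumor-associated macrophages, microbleed products) while losing myelin
and other diamagnetic structure.  Quantitative susceptibility mapping
(QSM) measures only the *net* voxel susceptibility, where these opposite
contributions cancel; separating each voxel's signal into a Paramagnetic
Component Susceptibility (PCS >= 0) and a Diamagnetic Component
Susceptibility (DCS <= 0) makes the cancellation visible.  The marker of
interest is their ratio,

    PDR = PCS / |DCS|,

which in infiltrated edema rises orders of magnitude above healthy
values.  The Tumor and Immune cell Infiltration Zone ("TIZ") is
delineated automatically: within the hemisphere contralateral to the
tumor, gray matter is isolated (subcortical structures removed), PDR
values above each reference tissue's 95th percentile are trimmed, and
the maximum retained gray-matter PDR becomes the subject-specific
threshold; every edema voxel whose PDR exceeds it — and which is not
dominated by blood according to perfusion (nCBV) and permeability
(Ktrans) percentile rules — is assigned to the TIZ.

`tizmap` implements this entire measurement chain end-to-end on a
synthetic, exactly mirror-symmetric digital tumor-brain phantom with a
planted infiltration pocket, so every stage is testable against ground
truth without any data download:

* `tizmap.phantom` — symmetric head + tumor complex (necrotic core,
  enhancing rim, edema shell, TIZ pocket), multi-echo GRE (8 echoes,
  TE1/dTE = 5/5 ms, 3 T), gamma-variate DSC and extended-Tofts DCE
  dynamics with variable-flip-angle baselines;
* `tizmap.qsm` — Laplacian phase unwrapping, mask erosion with tumor
  re-union, multi-echo field fitting, V-SHARP-style background removal,
  and two dipole inversions (thresholded k-space division and
  Tikhonov-regularized conjugate gradients);
* `tizmap.decompose` — constrained PCS/DCS separation from chi and the
  reversible dephasing rate R2' under a static-dephasing model;
* `tizmap.hemodynamics` — DSC nCBV with Boxerman leakage correction,
  VFA T1 + extended-Tofts Ktrans, and the blood-voxel exclusion mask;
* `tizmap.pdr_tiz` — PDR, reference trimming, automatic threshold, TIZ
  segmentation, Dice overlap;
* `tizmap.stats` — logPDR histogram features, Wilcoxon rank-sum (exact
  and corrected-normal paths), Pearson correlation, and the iterative
  t-based unequal-variance sample-size calculation;
* `tizmap.pipeline` / `tizmap.cli` — orchestration, NIfTI + JSON I/O,
  and the `tizmap` command line.

## Worked example

Run the full pipeline on the default phantom (64^3 voxels, 2 mm
isotropic, complex noise SD 2% of white-matter signal):

```sh
tizmap run-all --out runs/demo --seed 1234
```

which prints (identically on reruns with the same seed):

```
report: runs/demo/report.json
dice[tiz_cross_algorithm] = 0.913
dice[tiz_iterative_vs_truth] = 0.716
dice[tiz_tkd_vs_truth] = 0.791
thr_ncbv = 1.9933
thr_ktrans = 0.0076
theta_tiz_tkd = 7.0066
theta_tiz_iterative = 4.6700
```

Reading these numbers: `thr_ncbv` is the 95th percentile of normalized
cerebral blood volume over the mirrored tumor region (voxels above it
are excluded as hyperperfused — here every enhancing-tumor voxel and no
edema voxel); `thr_ktrans` is the 5th percentile of the transfer
constant in enhancing tumor (min^-1); `theta_tiz_*` is the automatic
PDR threshold (maximum retained contralateral-GM PDR) for each dipole-
inversion algorithm.  The recovered TIZ overlaps the planted
ground-truth pocket with Dice 0.79 (TKD chain), and the TIZ masks from
the two inversion algorithms agree with Dice 0.91 — the pipeline's
algorithm-stability measure.  The report also contains the per-subject
statistical battery; e.g. the rank-sum test between TIZ PDR and its
mirrored contralateral region rejects decisively (p < 1e-77).

The sample-size calculation that the method motivates (how many
subjects per group would detect the TIZ vs contralateral-GM median-PDR
difference in an unpaired comparison, given group means 86.29 vs 1.04
and SDs 149.84 vs 0.08) is a one-liner:

```sh
tizmap sample-size --mean1 86.29 --sd1 149.84 --mean2 1.04 --sd2 0.08
# n per group = 27
```

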