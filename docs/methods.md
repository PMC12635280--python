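# Methods

`tizmap` maps a tumor- and immune-cell infiltration zone ("TIZ") in
peritumoral edema from quantitative susceptibility MRI.  The core idea:
infiltrated edema accumulates iron-rich (paramagnetic) material while
losing myelin and other diamagnetic structure, so the ratio of the
paramagnetic to the absolute diamagnetic sub-voxel source susceptibility
(PDR = PCS / |DCS|) rises far above anything seen in healthy tissue.  The
package implements the full measurement chain on a synthetic, exactly
mirror-symmetric tumor-brain phantom, from multi-echo gradient-echo (GRE)
signal through susceptibility reconstruction, source separation,
perfusion/permeability-based blood-voxel exclusion, automatic
threshold selection and TIZ segmentation, to the statistical battery.

## The phantom

The phantom (module `tizmap.phantom`) is an ellipsoidal head — GM shell,
WM core, mirrored ventricles and subcortical nuclei, a midline venous
sinus — built on a 64x64x64 grid at 2 mm isotropic resolution, exactly
symmetric about the mid-sagittal index plane so that "contralateral"
reference logic is exact by construction rather than by registration.  A
one-sided tumor complex is added: nested necrotic core (NCR),
contrast-enhancing rim (ET) and edema shell (ED), plus a planted
high-iron / low-myelin pocket inside the edema that constitutes the TIZ
ground truth.

Every label carries a paramagnetic source `c_para >= 0` and a diamagnetic
source `c_dia <= 0` (ppm).  Defaults (WM 0.01/-0.05, GM 0.03/-0.02,
ED 0.02/-0.02, TIZ 0.15/-0.005 ppm) are synthetic plausibility values
chosen so the PDR ordering WM < ED < GM << TIZ holds; they are not
literature measurements.  The forward model ties the sources to the two
measurable quantities:

* net susceptibility `chi = c_para + c_dia`, dipole-convolved into a
  field map (`D(k) = 1/3 - kz^2/|k|^2`, `D(0) = 0`);
* apparent transverse relaxation
  `R2* = R2_baseline + kappa (c_para + |c_dia|)` with
  `kappa = (2 pi / 9 sqrt(3)) gamma_bar B0 1e-6` per ppm — the
  static-dephasing sphere coefficient, about 51.5 s^-1/ppm at 3 T.

The multi-echo GRE protocol is eight echoes, TE1/dTE = 5/5 ms, B0 = 3 T,
with additive complex Gaussian noise (SD 0.02 of the WM equilibrium
signal by default; Rician magnitude statistics are not modeled, which is
adequate in this high-SNR regime).  DSC uses a gamma-variate arterial
bolus (120 frames, TR 1.5 s) with a Boxerman-form leakage term confined
to ET; DCE uses an extended-Tofts forward model (80 frames, 5 s spacing)
with nonzero Ktrans only in ET, plus variable-flip-angle (5/10/15 deg)
SPGR baselines.  Because the decomposition and the leakage correction
share their forward models with the phantom, noiseless recovery is exact
by design — passing those tests validates internal consistency, not
fidelity to any particular in-vivo tissue model.

## Susceptibility reconstruction

`tizmap.qsm` implements the chain: Laplacian phase unwrapping (a Neumann
/ DCT Poisson solve of `lap(phi) = cos(phi) lap(sin phi) - sin(phi)
lap(cos phi)`; results are wrap-free up to a harmonic component), brain
mask erosion by 3 mm with the tumor mask added back, per-voxel weighted
least-squares fitting of phase against echo time (weights proportional to
squared magnitude; a per-echo constant offset is absorbed by the
intercept and by the final mean-centering), V-SHARP-style multi-radius
spherical-mean-value background removal (radii 12 down to 2 mm), and two
dipole inversions.

Background removal faces a genuine identifiability trade-off: the
spherical-mean filter is only valid where the sphere fits inside the
mask, and within that eroded support the far field of a source sitting
near the mask edge is harmonic — indistinguishable from background.
`vsharp` therefore offers two restoration modes sharing the same filter
bank and Tikhonov parameter (lambda = 0.05): `interior` (the default)
filters the mask-zeroed field and restores each radius's filtered field
spectrally with iterated Tikhonov, preserving near-boundary source
fields (the implicit zero-field boundary condition also stabilizes the
boundary against noise) — appropriate when the field is dominated by
in-mask sources, as for the phantom; `strict`
deconvolves only support-valid filter values by conjugate gradients,
rejecting external harmonic fields essentially exactly at the cost of
some in-mask far-field content — appropriate when strong external
sources (air cavities) are present.  Very close external sources (a few
voxels from the mask) are suppressed only approximately in either mode:
the discrete spherical mean has a large quadrature error in their
violent near field.  The two inversions:

* **TKD**: thresholded k-space division at |D| >= 0.2, followed by
  division by the kernel's mean point response (about 0.76 at t = 0.2) —
  the standard scalar compensation for TKD's systematic underestimation;
* **Tikhonov-CG**: conjugate-gradient minimization of
  `||M (D*chi - f)||^2 + lam ||grad chi||^2` (lam = 1e-2) with chi
  constrained to the mask support.  Without the support constraint the
  data null-space lets apparent sources drift outside the brain and
  recovered amplitudes shrink by tens of percent.

Chi maps are reference-free; each map is mean-centered over its mask, and
all recovery metrics compare maps after removing each one's mean over the
comparison region.

One field map is fitted across all echoes before inversion by default —
better conditioned at this matrix size than processing echoes
individually; a `per_echo` mode reconstructs a chi map from each echo's
own field estimate and averages them, for fidelity to per-echo
processing conventions, at roughly the echo count times the cost.

Two distinct inversion algorithms are carried through the whole pipeline
deliberately: the TIZ masks they produce are compared by Dice overlap as
a reproducibility (algorithm-stability) measure.

## Sub-voxel source separation

`tizmap.decompose` solves, per voxel, the box-constrained least squares

    min (pcs + dcs - chi)^2 + (pcs - dcs - R2'/kappa)^2
    s.t. pcs >= 0, dcs <= 0

whose interior solution is `pcs = (chi + s)/2`, `dcs = (chi - s)/2` with
`s = R2'/kappa`, and whose boundary cases follow from the KKT conditions.
`R2' = max(R2* - R2_baseline, 0)`; the baseline comes from a per-label
table in simulation mode or from the contralateral-NAWM median in
application mode.  This is a deliberately static two-equation inversion
with a single global kappa; it does not claim equivalence to
multi-compartment temporal-model decompositions, whose internals are not
reproduced here.

### Noise regularization of the rate map

PDR is an extreme-value statistic (the TIZ threshold is the maximum of a
trimmed reference distribution), so it is acutely sensitive to voxelwise
noise in R2'.  At the default SNR the raw per-voxel R2* fit has a ~1
s^-1 error (0.02 ppm in source units — the size of the tissue |DCS|
itself), which makes |DCS| collapse to its floor in a few percent of
reference voxels and inflates the threshold by an order of magnitude.
The pipeline therefore smooths the echo magnitudes inside the brain mask
(mask-normalized Gaussian, sigma 2.5 voxels = 5 mm, about 1.2 cm FWHM)
before the R2* fit — comparable to the smoothing used in group-level
relaxometry — trading spatial resolution of the rate map for the
stability the extreme-value threshold requires.  The mask-normalized
form prevents background signal from bleeding into the cortical rim.
The chi map is left unsmoothed (its fit noise is several times smaller
in source units).

## PDR and TIZ delineation

`tizmap.pdr_tiz` computes `PDR = PCS / max(|DCS|, eps)` with
eps = 1e-4 ppm.  Voxels whose |DCS| hits the floor keep their (large,
finite) PDR value and are only flagged: near-total loss of diamagnetic
structure is exactly the signature of interest, so capped values are
signal, not error.

The threshold rule mirrors the clinical procedure: in the hemisphere
contralateral to the tumor, subcortical structures are removed from the
GM mask, PDR values above each tissue's own 95th percentile are trimmed
(per-tissue trimming is the default reading; pooled trimming is available
behind a flag), and the maximum retained GM PDR becomes the subject-
specific threshold.  Edema voxels strictly above the threshold — and
outside the blood-exclusion mask — form the TIZ.

## Hemodynamics and blood-voxel exclusion

DSC: signal to delta-R2* conversion, AIF selection as the mean of the
five highest-peak vessel voxels (ties by earlier peak, then voxel index),
Boxerman-style leakage correction against the mean non-enhancing tissue
curve, CBV as the tissue/AIF AUC ratio, and normalization by the median
CBV over contralateral NAWM (median rather than mean, for robustness).
DCE: linearized (DESPOT1) VFA T1 fit, SPGR inversion to concentration,
and bounded multi-start extended-Tofts fitting (12 starts over the
parameter box; Ktrans in [0,5] min^-1, kep in [0,10] min^-1, vp in
[0,1]).  Map-level fitting skips voxels without sustained enhancement
(mean late-half concentration < 0.03 mM), a detection-limit screen that
is robust to single-frame noise excursions.

Exclusion thresholds are per-subject percentiles: nCBV above the 95th
percentile of the mirrored tumor region excludes hyperperfused tumor
voxels; a valid Ktrans above the 5th percentile of the contrast-enhancing
tissue excludes BBB-compromised voxels.  Failed fits never trigger
exclusion.

## Statistics

logPDR features (base-10; the base only shifts location, and
correlations are base-invariant) are the median, the 10th percentile and
the mode, the last estimated as the center of the tallest
Freedman-Diaconis histogram bin with ties resolved to the lower bin.
The rank-sum test uses exact enumeration for tie-free samples with
min(n, m) <= 10 and the tie- and continuity-corrected normal
approximation otherwise.  Pearson correlations use the t-transform
p-value.

The unequal-variance sample-size calculation iterates

    n >= (t_{1-alpha/2,nu} + t_{power,nu})^2 (s1^2 + s2^2) / delta^2

to a fixed point with nu the Welch-Satterthwaite degrees of freedom at
the current n, floored at n = 2.  The t-based iteration is the default
(a z-approximation is available behind a flag and returns a smaller n).

## What the phantom does and does not establish

Passing the phantom suite establishes that the implementation inverts its
own forward models correctly, that the threshold/exclusion logic behaves
as specified, and that the pipeline is deterministic and seed-stable.  It
does not establish in-vivo validity: the phantom has piecewise-constant
tissues, no partial-volume mixing beyond voxel quantization, no B0/B1
inhomogeneity, no motion, born-co-registered modalities, and susceptibility
values chosen for plausibility rather than measured.  Near-boundary
background fields (e.g., from air cavities a few voxels away from the
brain) are suppressed only approximately by the discrete spherical-mean
filter; the analysis mask erosion exists precisely to keep such regions
out of the reference distributions.

## Numerical choices

* FFT conventions: zero frequency at index 0; axis 2 is the B0 axis;
  arrays are (x, y, z), 0-based; the mid-sagittal plane bisects axis 0.
* All CG solves run a fixed maximum iteration count with tight relative
  tolerance, making reruns bit-identical.
* Volumes are written float32 (masks uint8) NIfTI-1 with metadata in
  JSON sidecars; every run writes a provenance block (config hash, seed,
  computed thresholds).
* Degenerate inputs: empty reference masks raise; an all-identical
  pooled sample in the rank-sum test returns p = 1 with a warning; Dice
  of two empty masks is defined as 1 and logged.
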