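# Methods

## Problem setting

Ultra-low-dose CT (tube current cut from 200 mAs to 24 mAs, roughly a
10x dose-length-product reduction) trades patient dose for image noise.
This package implements an unpaired image-to-image enhancement model
that maps low-dose CT (LDCT) images toward normal-dose CT (NDCT)
appearance, together with the objective image-quality instrumentation
needed to audit it (CNR, LCV, UI, NPS, MTF, MAE/MSE), and a synthetic
sensitometry-phantom simulator so the whole system can be exercised and
validated without patient data.

## Phantom simulator

`uldct.phantom` renders a CTP404-style sensitometry module: a
water-equivalent cylinder (default 200 mm diameter, 0 HU) with seven
cylindrical inserts (air -1000, PMP -200, LDPE -100, polystyrene -35,
acrylic 120, Delrin 340, Teflon 990 HU; 12.5 mm diameter on a 58 mm
ring). The insert HU values are editable defaults chosen at nominal
material values, not claims about any physical phantom. Disk rims are
anti-aliased by area-weighted supersampling (factor 4) so ROI means are
unbiased and edges are usable for MTF estimation. A scaled-down variant
(`small_phantom`: 56 mm body, 8 mm inserts on a 20 mm ring) keeps every
structure measurable in a 64 x 64 image for desk-scale experiments.

Dose-dependent noise is generated by filtered back-projection of a
pure-noise parallel-beam sinogram (180 views, Hann-apodized ramp
filter) added to the clean image. This gives spatially correlated,
band-limited noise whose radial power spectrum peaks at low-to-middle
frequencies, the texture characteristic of smooth-kernel CT
reconstructions; a stationary filtered-Gaussian fallback (`method="fast"`)
exists for speed-sensitive tests. Projection noise variance scales
inversely with tube current, so uniform-ROI noise sigma scales as
`sqrt(reference_mAs / dose_mAs)` exactly in expectation. The amplitude
default (7.0 line-integral units at 200 mAs) was fixed once so that the
normal-dose scan shows ~12 HU and the 24 mAs scan ~35 HU in a uniform
ROI — a realistic clinical pair that puts the low-dose CNR of the
120 HU acrylic insert near 2.

Unpaired corpora jitter each image's insert positions (+/- 2 mm) and HU
values (+/- 3%) with per-image seeds from non-overlapping streams, so
the two dose domains share no pixel-aligned pairs; a CycleGAN trained on
pixel-aligned domains would degenerate toward the identity.

What the simulator does not emulate: patient anatomy, scatter, beam
hardening, photon starvation streaks, 3D/helical geometry, or detector
electronics. Passing the end-to-end tests therefore demonstrates that
the training system can learn dose-texture translation under controlled
conditions, not that it reaches clinical image quality.

## Preprocessing

Network inputs are Min-Max normalized from the HU window
`[-1000, 0.9 x max HU over the training set]` to `[-1, 1]`, values
outside clipped. The ceiling rule follows the wording "90% of the
maximum CT value" literally (0.9 x max; a percentile mode exists behind
a flag). Clipping is why very dense, bone-like values cannot round-trip
exactly — a property of the windowing, kept deliberately. The fitted
window is frozen into the checkpoint so inference uses identical
scaling. Augmentation is strictly geometric (vertical flips,
scale-and-clip, random crop-resize, rotation); intensities are never
transformed. "Central random cropping" is implemented as a random crop
whose center is uniform within the central 50% window of the image.

For the phantom smoke profile, rotations default to exact right angles
(pixel permutations). Continuous-angle rotation resamples the image
bilinearly, which smooths the noise field by an angle-dependent amount;
at desk scale this erases precisely the amplitude statistic that
separates the two dose domains (measured: a discriminator that reaches
0.81/0.11 real/fake separation under flips-only augmentation stays at
0.50/0.50 under continuous rotation). At clinical scale with rich
anatomy the full augmentation set is appropriate and remains the
default of the full profile.

## Enhancement model

Two content-noise generators translate between domains: `G_A` (LDCT to
NDCT, the enhancer) and `G_B` (NDCT to LDCT), each trained adversarially
against a patch discriminator on its target domain (`D_B`, `D_A`). The
generators are residual encoder-decoders (7x7 stem, two stride-2
downsampling stages, residual blocks, two nearest-neighbour upsampling
stages, 7x7 tanh head) that predict a noise map subtracted from the
input, so an untrained generator is exactly the identity and training
only has to shape the noise component. A width multiplier scales all
channel counts so tiny variants train in CI.

Losses (all reductions are means, so weights are patch-size-free):

* adversarial, vanilla log/BCE form with sigmoid discriminators;
  the generator maximizes `log D(G(x))` (non-saturating form, same
  fixed points);
* cycle consistency `|I_A - G_B(G_A(I_A))|_1 + |I_B - G_A(G_B(I_B))|_1`,
  weight `lambda_cyc = 20`;
* identity `|I_B - G_A(I_B)|_1 + |I_A - G_B(I_A)|_1`, weight
  `lambda_iden = 0.5`;
* total = adv_A + adv_B + 20 cyc + 0.5 iden.

Training: Adam (betas 0.5/0.999), lr 2e-4 held for 150 of 250 epochs
then decayed linearly to exactly zero, batch size 4, Gaussian
N(0, 0.02^2) weight init, one discriminator step per generator step,
discriminator updates drawn from a 50-image replay buffer of past fakes
(the standard CycleGAN stabilization; without it the generators track
and neutralize the current discriminator state at small scale).

Two further choices matter at desk scale and were made after observing
the adversarial dynamics on simulated phantoms:

* **Norm-free discriminators.** Instance normalization inside the
  discriminator divides out per-sample feature amplitude — the very
  statistic (noise sigma) that separates a 24 mAs patch from a 200 mAs
  patch. With InstanceNorm the discriminator never left chance level;
  without it, it separates the domains cleanly.
* **Discriminator warmup and width.** The discriminators are trained
  alone for a configurable number of steps (300 in the smoke profile)
  before alternation starts, and keep full width even when the
  generators are narrowed. An uninformative adversary supplies no
  gradient, and the short smoke schedule cannot afford the ~15 epochs
  it otherwise takes the discriminator to become confident; a weakly
  confident discriminator also makes the identity mapping near-optimal
  for the generator, because the adversarial gain from denoising must
  out-weigh the `lambda_cyc`-weighted cycle cost of discarding
  unreproducible noise.

## Image-quality metrics

All sigmas are population standard deviations (divide by n). ROIs are
circles specified in mm relative to the phantom center; a pixel belongs
to an ROI if its center falls inside the disk.

* CNR: `|mean_m - mean_b| / sqrt(sigma_m^2 + sigma_b^2)` per insert
  against a central background ROI.
* LCV: `2 |mean_LDPE - mean_PS| / (sigma_LDPE + sigma_PS)`; "PS" is the
  polystyrene insert.
* UI: `|mean_periphery - mean_center| / (mean_center + 1000)` in
  percent; default periphery is the average of four ROIs at 12/3/6/9
  o'clock, with the maximum-deviation variant also reported.
* NPS: per-ROI subtraction of a fitted first-order 2D polynomial
  (removes DC and low-frequency shading), then the periodogram
  `|DFT|^2 x0 y0 / (Nx Ny)` averaged over ROIs; radial profile by
  annular binning; Parseval (integral of NPS = detrended variance)
  holds to numerical precision and is asserted in tests.
* MTF: circular-edge method on a high-contrast insert — radial binning
  of pixel values into an oversampled ESF (bin width = spacing/4),
  light Savitzky-Golay smoothing (window 5, quadratic), adjacent-bin
  differencing to the LSF (the half-bin shift is pure phase), Tukey
  (alpha 0.5) taper, FFT magnitude normalized at zero frequency; MTF50
  and MTF10 from the first downward crossings by linear interpolation.
  On a 0.5 mm Gaussian-blurred synthetic edge the estimator matches the
  analytic `exp(-2 pi^2 sigma^2 f^2)` within 0.05 absolute up to half
  Nyquist; residual bias comes from the pixel aperture and is inherent
  to measuring from sampled images.
* MAE/MSE: pixelwise against the noise-free reference.

Automatic ROI placement thresholds the body at -500 HU, takes its
centroid, and lays ROIs at spec-relative offsets (insert ROI radius =
0.6 x insert radius); peripheral uniformity ROIs shrink inward when the
scaled-down phantom leaves no room between the center and the insert
ring.

## Problem sizes and profiles

The smoke profile — 64 x 64 images at 1 mm spacing, 8 images per
domain, 32 x 32 patches, 16 patches per image per epoch, 30 epochs
(lr constant for 18), generator width multiplier 0.25 with 2 residual
blocks — was chosen as the smallest configuration at which the
adversarial dynamics described above are visible; one trial trains in a
few minutes on one CPU. The full profile (512 x 512, 68 + 68 images,
256 x 256 patches, 250 epochs, full width, 6 residual blocks) mirrors a
clinical-scale setup and needs GPU-class compute; it ships as
configuration only.

## Known limitations

* The NumPy training engine is single-threaded-ish (BLAS matmuls
  aside); clinical-scale training is out of reach by design.
* Quality recovery at smoke scale is a stochastic property of an
  adversarial game; the acceptance property is therefore majority-vote
  over seeds, not per-seed.
* DICOM support covers single-frame axial CT with rescale tags; no
  multi-frame, compression, or full IOD conformance.
* The simulator's DLP values are protocol metadata; noise keys off mAs
  only, so the implied DLP ratio (10.4x) and mAs ratio (8.3x) are not
  reconciled.
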