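# Methods

## The matching model

tomopick localizes a known macromolecular density (the *template*, T) in a
cryo-electron tomogram (V) by exhaustive translational and rotational
search.  The score at tomogram position x and orientation v is the locally
normalized cross-correlation

    LCC(x, v) = (1/P) * sum_i [T'_v(i) M_v(i) (V(i + x) - Vbar(x))] / sigma_{M_v V}(x)

where T'_v is the template rotated to v, convolved with the Fourier-space
weight W, and normalized to zero mean and unit variance under the rotated
mask M_v; P is the sum of the mask values; and sigma_{M_v V}(x) is the local
standard deviation of the tomogram under the mask centered at x.  The
translational search is exhaustive via FFT correlation; per voxel the
maximum over all orientations (LCC_max) and the index of the best
orientation are retained.

Assumptions: the particle's density matches the template up to the imaging
PSF and additive noise; the noise background of the LCC is zero-mean and
vastly outnumbers true positives; local contrast variations are captured by
the masked local standard deviation.

### PSF weights

Two models of the tomographic transfer function weight the template:

* **Tilt-weighted PSF.** For every tilt j, a 2D CTF at that tilt's defocus
  is damped by the accumulated-dose B-factor (B = 4 A^2 per e-/A^2, i.e.
  exp(-dose * q^2)), scaled by cos(theta_j), multiplied by a linear ramp
  rising from 0 at the tilt axis to 1 at the overlap frequency with the
  nearest neighboring tilt (1/(box * voxel * sin dtheta)), then rotated by
  theta_j about the tilt (y) axis and deposited into the nearest 3D Fourier
  voxel, accumulating by summation with a final clip to [-1, 1].  Nearest-
  voxel deposition tiles Fourier space densely only up to radius
  ~1/dtheta voxels; beyond it the planes fan out and leave gaps, which is
  the expected behavior of this construction and grows milder with box
  size.  The cosine weighting is applied before clipping.
* **Binary wedge.** Weight 1 inside the double wedge of in-plane angles
  [min_tilt, max_tilt] in the (q_x, q_z) plane (tilt axis y always
  sampled), 0 in the missing wedge, optionally multiplied by a single
  radial CTF whose defocus should be that of the first-collected tilt.

The CTF is CTF(q) = -[sqrt(1 - A^2) sin chi + A cos chi], chi = pi lambda d
q^2 - (pi/2) Cs lambda^3 q^4, with underfocus positive, so CTF(0) = -A; a
phase-flip option returns |CTF| for tomograms reconstructed from
phase-flipped stacks.

### Background normalization

* **Whitening:** the filter 1/sqrt(PSD(q)), from the radially averaged power
  spectrum of the tomogram in integer-radius shells, normalized to max 1;
  applied to the tomogram as preprocessing and multiplied into the template
  weight.  The profile is stored against physical frequency so template and
  tomogram boxes may differ.
* **Phase randomization:** a decoy template with identical Fourier
  amplitudes and uniformly permuted phases (independent half-spectrum only;
  Hermitian symmetry enforced; DC and self-conjugate coefficients keep
  their phase).  Both templates run the full search; the corrected map is
  lcc_max - lcc_max_decoy + mean(lcc_max_decoy), the mean taken over the
  search region.  Randomization is applied once; the tracked background
  sigma comes from the original-template search only.

### Orientation sampling

Sphere directions are HEALPix RING pixel centers computed directly from the
closed-form ring equations (12 nside^2 pixels; any positive nside), with
nside the smallest integer whose mean pixel spacing sqrt(pi/3)/nside is at
most the angular increment; in-plane angles are ceil(360/increment) uniform
psi steps.  At 7 degrees this gives nside 9, 972 x 52 = 50,544 orientations.
The increment follows the Crowther criterion degrees(1/(D * q_max)) for
particle diameter D and the Nyquist or low-pass frequency q_max.  Euler
angles are intrinsic ZYZ (rot, tilt, psi), the RELION convention; the
HEALPix center (phi, theta) maps to (rot, tilt) and psi starts at 0.  Any
consistent mapping preserves coverage; this one is documented rather than
canonical.

### Extraction thresholds

The base cut-off is tau = sigma * sqrt(2) * erfc^-1(2 FP_ratio / N_total)
with sigma the tracked background standard deviation (running sum of
squared LCC values over the search region and all rotations, divided by
N_total = N_voxels * N_rotations) and FP_ratio = 1 by default.  Peaks are
extracted from highest to lowest while above tau, zeroing a Euclidean
sphere of the exclusion radius around each visited peak.

The tophat constraint additionally requires the white tophat transform of
the score map (input minus its grayscale opening with the connectivity-1
structuring element by default) to reach tau_tophat = mu + sigma_fit *
sqrt(2) * erfc^-1(2 FP_ratio / N_total) at the peak, where (mu, sigma_fit)
are obtained by fitting a Gaussian to the background of the tophat
histogram.  Two conventions left open by the method's description are
treated as parameters with these defaults: N_total includes the rotations,
and the fitted mean mu is added (the tophat background is not zero-mean).

## Numerical choices

* Volumes are processed in float32 with FFT correlation (scipy.fft); the
  variance tracker accumulates in float64.  Correlation is periodic; a
  margin of half the template box at the tomogram edges is excluded from
  the search region instead of padding.  The forward transform of the
  zero-padded template is built axis by axis over the occupied rows only,
  which saves most of its cost for templates much smaller than the
  tomogram.
* Local standard deviations below sqrt(1e-10 x global variance) are flagged
  invalid (score forced to 0, excluded from extraction).  The relative
  floor masks the float roundoff of the two FFT convolutions, which would
  otherwise turn flat regions into spurious huge scores; a constant
  tomogram is invalid everywhere.
* Rotation uses trilinear interpolation about the voxel box_size // 2 with
  zero fill; templates are masked, so the fill never enters the mask.
* Tophat histogram: nonzero values in 50 equal-width bins spanning
  min(1.5 x the 99.9th percentile, median + 10 robust standard deviations),
  so a handful of extreme peak values cannot crush the background into one
  bin.  The curvature sign used to find the Gaussian flank is taken on
  counts smoothed with a 5-bin moving average, single-bin interruptions are
  bridged, and the first run with at least 3 populated bins is fitted by a
  parabola on log counts weighted by sqrt(count).  The fit is rejected (with
  guidance to re-extract without the constraint) when the log fit is not
  concave — i.e. when the histogram shows no Gaussian background.
* Greedy nearest-available matching (descending score) labels candidates
  against ground truth; the default tolerance is half the particle
  diameter.  Ties and ordering are deterministic.

## The phantom generator

Phantoms emulate the statistical structure the matcher faces: weak-contrast
particles (the default template is an asymmetric four-lobe Gaussian blob,
lobe sigma 1.6-2.2 voxels, ~10 voxels across, peak 1) at random
non-overlapping positions and orientations drawn from a uniform 10-degree
rotation set (so truth orientations are exactly representable in a search
set); strongly scattering spherical decoys (radius 5 voxels, amplitude 8x
the particle peak — a ~10 nm gold bead at 10 A voxels) that produce
extended patches of high score; missing-wedge filtering of the assembled
signal (+-60 degrees by default); and additive white Gaussian noise at 0.5x
the particle peak.  Everything is deterministic under the spec's seed.

What the phantom does *not* emulate: CTF oscillations and defocus
gradients, structured cellular background (membranes, crowding), correlated
reconstruction noise (the noise is added after the wedge filter and is
white), and detector statistics.  Passing tests therefore demonstrate the
algorithmic contracts and the qualitative classification behavior, not
performance on experimental tomograms.

One consequence is worth stating explicitly.  On these phantoms the white
tophat of the score maps has a mode-at-zero, roughly exponential-tailed
value distribution — the score field is smooth at the template scale, so
peak prominences have no characteristic positive mode.  The automated
tophat cut-off presumes a *Gaussian* tophat background (as observed on
experimental score maps); on the phantoms the background fit correctly
reports that no Gaussian background exists and extraction falls back with
guidance.  The shape-filtering mechanism itself is real and testable: the
extended shoulder responses of bright decoys have tophat value exactly 0
and are removed by any positive cut-off, which the test suite demonstrates
on constructed score maps whose background does satisfy the Gaussian
premise.

## Problem sizes

The test suite exercises the full engine at desk scale: oracle equivalence
on 24-box tomograms with 8-box templates and 4 rotations; classification
properties on 128-box phantoms with a 15-degree search (4,608 orientations,
five seeds) and on 64-box phantoms with ten seeded phase-randomization
runs.  These sizes keep a complete run in the tens of minutes on one CPU
core while leaving every code path identical to production-scale runs.

## Known limitations

* No GPU path; single-volume, single-process execution.
* Astigmatism and phase-plate shifts are not modeled; dose weighting uses
  accumulated dose only.
* The tilt-weighted PSF's ramp parameterization (linear in in-plane
  distance from the tilt axis, per-tilt overlap frequency from the nearest
  angular neighbor) is one reading of the method's description; the exact
  authorial geometry is not published.
* The tophat cut-off calibration depends on the Gaussian-background premise
  discussed above; on data where it fails, the baseline threshold plus the
  qualitative tophat filter (manual cut-off) remain usable.
* Single-pass phase randomization suppresses the *extended* score response
  of a bright solid decoy (the ring of high values around its edge, which
  is what extraction would otherwise pick up repeatedly) very reliably, but
  its effect on the score at the decoy's flat center is a single random
  draw: the zero-mean decoy template has no expected response against a
  flat interior, so the central peak is reduced in only about half of
  seeded runs.  Averaging several randomizations would stabilize this at
  extra cost; the pipeline applies a single pass.
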