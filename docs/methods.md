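# Methods

## Signal model of the synthetic generator

The generator emulates the statistical features of infra-slow BOLD
activity that the lag analysis depends on, and nothing more. Latent
sources are Gaussian processes with power ∝ 1/f^α (α = 1 by default)
restricted to the infra-slow passband 0.01–0.1 Hz. The band matters:
spectral power at periods longer than the epoch cannot be distinguished
from a trend and would make single-epoch cross-covariance estimates
erratic, while power above the analysis band is removed by the 0.1 Hz
low-pass anyway. Within this band the ~5-minute epochs used throughout
(150 frames at TR = 2.08 s) support lag estimation to a few hundredths
of a second on noiseless pairs.

Sources are synthesized on a fine grid (TR/32 by default) so that
fractional, sub-TR delays are representable exactly. Voxel *v* observes

    y_v(t) = Σ_k w[v,k] · s_k(t − d[v,k]) + ε + baseline,

with cubic-spline interpolation realizing the fractional shifts, white
Gaussian noise ε of configurable SD (unit-variance sources, so
noise_sd = 0.2 corresponds to an amplitude SNR of 5), and an EPI-like
baseline intensity of 1000 so that the percentage-based censoring
threshold has its conventional meaning (0.5 % ≡ 5 intensity units).
The generator does **not** model hemodynamic response shape, spatial
autocorrelation of noise, physiological rhythms, or realistic anatomy;
conclusions from passing tests are about the estimator and inference
machinery, not about biology.

Defaults mirror the sampling regime of overnight EEG–fMRI studies:
TR = 2.08 s and ≥150 frames per epoch; voxels live on an explicit 3-D
lattice so cluster adjacency and an optional Gaussian lattice smoother
are well-defined.

## Lag estimation

Lagged cross-covariance is computed at integer offsets within ±4 frames
(±8.32 s at TR 2.08 s) with per-offset demeaning over the frames that
are valid at both ends of each product; offsets with fewer than 30
overlapping valid frames are unusable, and a pair with fewer than 30
overlapping frames at lag zero is an error. Normalized (correlation)
curves are the default; the lag is invariant to this choice, the
amplitude is not, and both variants are available.

The extremum is located as the maximum of |C| and refined by the
parabola through the extremum and its two neighbors on the signed
curve; the vertex gives lag and signed amplitude. Pairs whose extremum
falls on the window edge have no interpolation neighbor and are marked
invalid rather than clamped; invalid pairs are excluded from
projections, block means and group averages. A degenerate (zero
curvature) triple returns the integer-offset estimate with a flag.

Sign convention: `td[i][j] > 0` means voxel *i* is late relative to
voxel *j*. The lag projection is the row mean of TD, so early voxels
are negative. Negative offsets of the curve are evaluated through the
identity `C_{12}(−a) = C_{21}(+a)` using the same arithmetic, and the
TD lower triangle is the exact negation of the upper, so anti-symmetry
holds to the bit and the mean over any full diagonal block of a
network-sorted TD matrix cancels exactly.

With full-frame masks all pairwise curves are assembled from one matrix
product per offset; the masked path computes pairs individually. Both
paths share the demeaning and normalization conventions, and the
vectorized path is verified against a brute-force double loop over
frames.

## Preprocessing

Stage order is detrend → low-pass → nuisance regression → censoring.
The low-pass is a second-order Butterworth applied forward and backward
(zero phase, effective fourth order): any group delay would bias the
measurand directly. Filtering runs over the full frame axis without
gap interpolation. Nuisance regression fits intercept, user-supplied
regressors, and optionally the global mean over valid frames, and
subtracts the prediction everywhere; a rank-deficient design raises an
error naming the collinear columns.

The censoring statistic is the RMS frame-to-frame intensity change as a
percentage of the grand mean intensity (DVARS-like). Because
detrending removes the mean the threshold is relative to, the pipeline
computes the statistic on the raw input data and applies the resulting
mask after the linear stages; computing it on processed data instead is
available as a switch, with an explicit reference intensity. The later
frame of each super-threshold transition is flagged (an isolated spike
therefore removes two frames: its rise and its fall), the first frame
of the epoch is kept by convention, and surviving valid runs shorter
than 10 contiguous frames are invalidated entirely. An epoch where
nothing survives is returned with an all-false mask, a reportable
outcome rather than an exception.

## Lag threads and dimensionality

Thread extraction column-centers the TD matrix (invalid entries imputed
with the column mean, i.e. zero after centering — the
least-informative completion), treats columns as observations of an
n-dimensional spatial variable, and eigendecomposes their covariance.
Components are reported scaled by the RMS projection amplitude
(√eigenvalue), which carries units of seconds; an earlier idea of
averaging the projections of centered columns onto each eigenvector
degenerates (the projections average to ~0) and was replaced by this
standard loading scale. Components are defined up to sign.

Dimensionality is selected by Minka's Laplace-approximation evidence
over candidate PCA ranks (including rank 0, the isotropic model),
implemented from the published closed form and cross-checked in the
test suite against scikit-learn's independent implementation of the
same criterion.

A structural point discovered while building the generator: a forward
model with *k* simultaneous sources does **not** produce a rank-k
centered TD matrix. The measured pairwise lag is a weight-dependent
mixture of per-source delay differences, and the centered column space
generically spans 2k−1 dimensions (k = 1 gives the familiar rank-1
delay-difference structure; uniform weights collapse everything to the
rank-1 mixture mean). Thread-count recovery is therefore evaluated on
TD matrices with rank-k structure planted directly at the TD level
(`synthdata.planted_thread_td`): anti-symmetric combinations of k
orthonormal topographies plus anti-symmetric white noise at the target
SNR. At n = 60 voxels and SNR 5 the ML criterion recovers the planted
count in ≳95 % of replicates.

## Group statistics

All tests permute state labels with the subject as the exchangeable
unit: subjects contributing both states have their labels flipped with
probability ½, remaining labels are shuffled freely. Family-wise error
over clusters, blocks, or ranks uses the max-statistic method, and
p-values use the (1 + count)/(n_perm + 1) convention.

* **Cluster test**: voxelwise z (difference of state means over the
  Welch pooled standard error), supra-threshold voxels grouped by
  6-connectivity on the lattice (or a user adjacency; with no
  adjacency every voxel is its own cluster and the test reduces to a
  voxelwise FWE test), corrected p from the null distribution of the
  maximal cluster extent.
* **Block Spearman**: ρ between two states' lag values over each
  block's valid pairs; the null permutes the entry correspondence
  within each block and the correction uses the minimum null ρ across
  blocks. Because that null is centered at ρ ≈ 0, the low tail flags
  actively reversed structure (ρ < 0); a merely decorrelated block is
  indistinguishable from the null by construction. Blocks with fewer
  than 10 valid pairs are flagged without a p-value.
* **Block means**: per-subject mean lag per off-diagonal block,
  state difference studentized by the permutation SD, max-|t|
  correction over the 21 off-diagonal blocks. Diagonal blocks are
  reported as exactly zero (see anti-symmetry above).
* **Lag SD contrast**: per-subject SD over valid upper-triangle lags,
  two-sided label-permutation test of the state difference (10,000
  permutations by default). One subject per state leaves no
  permutation space; the p-value is reported as undefined.
* **FC-difference PCA**: Fisher-z FC matrices averaged per state, the
  difference column-centered and eigendecomposed; each rank's observed
  eigenvalue is compared with the 95th percentile of its own
  permutation-null distribution.

Calibration note: with very small samples and a cluster-forming
threshold as high as z = 4.5, no voxel is ever supra-threshold and the
cluster test trivially never rejects. Calibration simulations therefore
use z = 1.5, where clusters actually form; the max-extent correction
then achieves a family-wise false-positive rate of ~0.05 under the
global null. For calibration the null subject maps are drawn directly
as i.i.d. Gaussian voxel maps, identical for both states — calibration
concerns the exchangeability machinery, which does not depend on the
forward model. Heavily tied, paired-only designs (2^6 distinct sign
flips) make the discrete max-extent null conservative; the calibration
design uses unpaired groups (C(12,6) = 924 relabelings).

## Problem sizes

Defaults used by the test suite and the acceptance script: two-state
demonstration studies on a 6×6×3 lattice (108 voxels, 6 subjects per
state, one 150-frame epoch each); calibration on a 10×10×3 lattice
(300 voxels) with 1000 null datasets × 200 permutations; delay-recovery
sweeps over 50 pairs; thread recovery over 100 replicates per planted
count at 60 voxels. These sizes were chosen so the planted effects are
comfortably detectable while a full run remains a desk-scale
computation.

## Known limitations

* The forward model is linear mixing of delayed band-limited sources —
  a stand-in for acquired BOLD, not a hemodynamic model; absolute
  amplitudes and noise spectra of real data differ.
* Lag estimates assume a single well-defined cross-covariance extremum,
  which band-limited aperiodic signals provide; strongly periodic
  signals would produce multiple extrema the parabolic step does not
  arbitrate.
* The Spearman block test detects reversal, not mere decorrelation
  (see above).
* Group TD matrices averaged over subjects with differing validity
  patterns can lose exact anti-symmetry at entries where contributors
  differ; downstream consumers treat such entries through the validity
  mask.
* Real-data spatial smoothing is provided only as a Gaussian lattice
  smoother for lattice geometries, not a general volumetric smoother.
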