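# Methods

This note documents the models, estimators, parameter choices, and known
limitations of `circfish`.

## Imaging model and synthetic scenes

Every simulated RNA molecule is rendered as an anisotropic 3D Gaussian,

    I(r) = A · exp(−((x−x₀)² + (y−y₀)²)/2σ_xy² − (z−z₀)²/2σ_z²),

with σ_z > σ_xy.  This is the same functional form the fitting stage
assumes, which keeps every intensity oracle closed-form: the continuous
integral of a spot is A·(2π)^{3/2}·σ_xy²·σ_z, and on the voxel grid the
sum over a ±5σ window matches it to <10⁻⁵ relative.  We deliberately do
not model a physical (Gibson–Lanni) PSF, camera gain, or photobleaching:
the purpose of the generator is to give every estimator a ground truth in
the units it reports, not to emulate a specific instrument.

Defaults emulate a widefield 60×/1.4 NA acquisition: 100 nm xy pixels,
300 nm z steps, σ_xy = 130 nm, σ_z = 300 nm, and a constant camera
baseline with optional Poisson shot noise and Gaussian read noise.  Spot
SNR is defined as amplitude over read-noise sd.  Noise levels and spot
densities are not reported quantities for this kind of experiment, so the
defaults are chosen for testability: dense enough to exercise the
pipeline, sparse enough (minimum separation 3σ_xy within a channel) that
single molecules are resolvable, which is the counting regime the
species-classification method assumes.  Crowded signal is exercised
separately through granules.

Two-color species rendering follows the reporter logic: a mature mRNA
carries only the exon cassette (exon channel), a spliced intron only the
intron cassette (intron channel), an unspliced pre-mRNA both at the same
physical position.  Chromatic aberration is applied as a true affine
transform to the exon channel only; the intron channel is the reference
frame, mirroring the convention that one channel anchors the coordinate
system during bead calibration.

Cells are ellipsoidal nuclei inside ellipsoidal cell boundaries.  The
default cell keeps two z-steps clear of the stack faces — as in real
acquisitions, where the stack brackets the cell axially — so no molecule
sits where its PSF would be clipped.

## Spot detection and the single-RNA unit

Detection is a three-stage pipeline: (1) wide-Gaussian background
subtraction with a kernel ≥ 10× the PSF width (a 10× kernel depresses a
spot's amplitude by ~0.1% per axis); (2) Laplacian-of-Gaussian filtering
at the expected PSF scale, with candidates taken as local maxima above 5
robust standard deviations (1.4826·MAD) of the response — maxima within
2σ of a stack face are suppressed, because filter padding inflates the
response there; (3) trust-region least-squares refinement of amplitude,
sub-voxel center, both widths, and a local background on a ±4σ window.

Two numerical details matter.  The subtraction used for fitting is left
*unclipped*: truncating negative noise at zero biases the fitted widths
(hence integrated intensities) low by ~20% at SNR 10.  And fits are
rejected, not silently kept, when the amplitude is not clearly positive
or a fitted width leaves [0.3, 3]× the expected value — the upper bound
excludes unresolved multi-molecule foci from the singles pool (foci are
handled by the granule stage), the lower bound excludes noise.

The single-RNA intensity unit — the denominator for all copy counting —
is the mode of a Gaussian KDE of the *log* integrated intensities
(median below 50 spots; minimum 20).  The mode is robust to the
multi-copy tail that granules and doubles contribute, and taking it in
log space makes it unbiased under the roughly multiplicative scatter of
single-molecule intensities (for log-normal scatter the log-mode is
exactly the scale parameter, while the linear-space mode sits e^{−σ²}
below it).

Measured on seeded scenes at SNR 10 and ≥3σ separation, the round trip
achieves ≥95% recall, ≤5% false discovery, and <30 nm mean localization
error; these are regression-tested.

## Chromatic registration

A full d·(d+1)-parameter affine map (not a similarity transform) is fit
by linear least squares to paired bead positions, in 2D or 3D (default
3D).  Fitting is exact for noise-free affine-related sets of sufficient
rank; degenerate geometry (e.g. coplanar beads in 3D) is an error, not a
warning.  The synthetic bead generator places beads uniformly over a
field centered on the optical axis (coordinates span ±field/2).  That
centering is deliberate: it decorrelates the translation estimate from
the linear part, giving a translation standard error of σ/√n (≈0.5 nm at
5 nm bead noise, n = 100) instead of σ·√(10/n) for a corner-origin frame
— and it is also where chromatic aberration is smallest on a real
instrument.  Held-out residual reporting (`registration_report`) guards
against channel mis-pairing, which shows up as residuals far above the
colocalization radius.

## Species classification and granules

Colocalization uses mutual nearest neighbors within 200 nm, after the
exon channel is registered into the intron frame.  Mutual NN (rather
than greedy first-come matching) is deterministic and order-independent;
it provably equals the exhaustive minimal-distance search, which the
tests verify by brute force on small instances.  Paired spots become one
pre-mRNA record; unpaired intron spots are spliced introns; unpaired
exon spots are mRNAs.  Compartments come from Otsu-thresholded DAPI
projections (nuclei) with a fixed-radius dilation for the cell region
when no cell stain is given; touching nuclei may merge, which is a
documented limitation of global thresholding.

Foci ("granules") are admitted when their integrated intensity reaches
six single-RNA units in at least one channel.  Integration is done on
the **raw** stack over a ±4σ padded box with a border-annulus (median)
local background — not on the background-subtracted stack, whose wide
kernel absorbs ~1.5% of the focus's own mass, enough to push a
six-copy focus below the admission threshold.  Copy numbers are left as
real numbers (no rounding).  Single spots whose centers fall inside an
admitted focus footprint are absorbed into the focus to avoid double
counting.

The granule composition slope is the free-intercept OLS slope of intron
copies against exon copies over colocalized foci: pure pre-mRNA granules
give slope 1, an equal mixture of spliced introns and pre-mRNAs gives
slope 2 (each pre-mRNA contributes one intron and one exon; each spliced
intron one intron).  The granule generator's brightness jitter is a
per-granule multiplicative factor shared by both channels — modeling
illumination and hybridization-efficiency variation, which affect the
two probe sets of one granule together.  Under a shared factor the
(exon, intron) points stay on the true ray and OLS is consistent;
channel-independent noise of the same magnitude would attenuate the
slope by ~5–10% through errors-in-x, and is available separately
(`channel_cv`) for sensitivity work.

RNase-R retention treats cells, not molecules, as replicates: retained =
(mean treated count per cell)/(mean control count per cell) per
compartment × species stratum, with a bootstrap over cells for the CI.
The circularity signature is cytoplasmic-intron retention near 1 with
mRNA retention near 0.

## Translation sites

The single mature-protein unit is estimated (same log-KDE mode) from
protein spots farther than 200 nm from any intron, where freely
diffusing mature proteins dominate.  For each intron the brightest
protein spot within the search radius is examined and admitted as a
translation site only if strictly brighter than one mature protein;
nascent-peptide count = intensity/unit, reported as a real number.  The
search radius is not independently specified by the quantification
protocol beyond "the distance threshold", so the 200 nm colocalization
criterion is adopted and exposed as a flag (`radius_nm`); results at
150–300 nm can be tabulated by looping that flag.  A consequence of the
strict one-protein threshold is that genuinely translating RNAs carrying
a single nascent peptide are indistinguishable from mature proteins and
are not called — the generator reproduces this, and the fraction-recovery
tests account for it.  An independent 300 nm nearest-exon check flags
sites that may sit on unspliced pre-mRNA.

## Tracking and diffusion

Detections are linked frame-to-frame by mutual nearest neighbors within
a maximum displacement (scaled by the gap length when gap closing is
enabled).  This is intentionally a simple linker adequate for the low
densities simulated here; it is not a replacement for LAP/Kalman
trackers at high density.

Tracks longer than five frames (≥6 positions) enter analysis.  The MSD
is the time-averaged mean over all ordered position pairs k frames
apart, at lags k = 1..7 ("first seven displacements" is interpreted as
the first seven lags of the time-averaged MSD; the alternative reading —
only the first seven frame-to-frame steps — is not used).  D comes from
a weighted linear fit MSD(τ) = 4Dτ + b (2D, hence the factor 4), with
weights proportional to the number of displacement pairs per lag (the
leading-order variance structure of the time-averaged MSD) and a free
intercept b = 4σ_loc² absorbing localization noise, which would
otherwise bias D upward by σ_loc²/dt.  Negative fitted slopes are
clamped to D = 0 and flagged.  Mobility is "free" iff D strictly
exceeds 0.01 µm²/s.  At the reference conditions (200 tracks, 20
frames, dt = 0.1 s, 30 nm noise) the population mean D is unbiased
within ~4% standard error; the regression tests assert 10%.

## Branch-site calling

A circular intron joins position p (the branch adenosine, 1-based) to
position 1; its junction reads are windows of the circularized string
`intron[:p]`.  For every candidate adenosine in the last 100 nt of the
intron (non-A candidates behind a flag, since branch points are
canonically adenosine), the caller aligns each read at every offset that
keeps the junction covered with ≥10 nt on both sides and records the
minimum Hamming distance.  A read supports the candidate with the
uniquely smallest distance, provided it is within the mismatch budget;
ambiguous reads (tied best candidates) are discarded.  The budget
defaults to 10% of the read length rather than a fixed count: a fixed
small budget (e.g. 2) would reject most 300-nt reads already at a 1%
substitution rate (the expected three errors per read exceed it), while
a proportional budget keeps essentially all reads assignable yet still
rejects non-junction (linear) reads, which mismatch at ~75%.  Support
fractions are reported relative to all assigned junction-spanning reads,
so two branch sites used in a 70/30 mixture yield fractions 0.7/0.3.
Reported distance to the 3′ splice site counts the nucleotides after the
branch base (distance = intron length − p), so a branch at position
length−40 reads as "40 nt before the 3′ splice site"; the generator and
caller share this convention and the tests pin it.  `N` bases never
match.  The caller is verified against an exhaustive all-rotations
oracle on small instances.

This is an exact-match/mismatch-bounded comparison, not a full aligner:
it is deterministic, oracle-checkable, and appropriate for the
synthetic-read scale; indel errors and genome-scale read mapping are out
of scope.

## G-content profiles

Circular-intron G content is G count over full length (N counts in the
denominator only).  The genome-wide background removes the last 30 nt
before the 3′ splice site — the average branch-to-3′ss distance, i.e.
the tail a circle would not retain — and keeps sequences longer than
25 nt.  Positional profiles anchor all introns at the 5′ or the 3′
splice site (the 3′ anchor walks 5′-ward from the last base); at each
position the G fraction is computed over the introns long enough to
reach it, so the denominator is non-increasing with distance from the
anchor.  The structure-analysis selection (length 100–600 nt, then the
30-nt trim) only prepares sequences; folding free energies are ingested
from an external predictor's output and converted to −ΔG/nt, never
computed here.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.default_rng` seeded from the
scene or run configuration; identical configurations are bit-identical,
and every output table of a pipeline run carries the SHA-256 digest of
the scientific parameters that produced it.  The regression and
acceptance suites use compact problem sizes chosen to make their
statistical tolerances meaningful: 100-spot fields of 16×256×256 voxels
for detection round trips, 100 rendered granules for stoichiometry, 200
tracks of 20 frames per diffusion condition, 500 junction reads of
300 nt for branch calling, and ≤200-nt instances for the exhaustive
oracle comparisons.

## Known limitations

- Gaussian PSF and noise model only; no optical aberrations beyond the
  affine chromatic term, no spatially varying aberration field.
- Overlapping PSFs: spot pairs closer than ~1σ merge into one candidate.
- Global Otsu nucleus segmentation can merge touching nuclei.
- The frame linker is not assignment-optimal at high particle density.
- The junction caller handles substitutions only (no indels) and assumes
  the circle is at least one read length long.
- Statistical comparisons between biological conditions (t-tests etc.)
  are out of scope; the package reports estimates and bootstrap CIs.
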