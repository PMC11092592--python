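# Methods

This note records the models, conventions and numerical choices behind
`tomokit`, in the order data flows through the package.

## Metadata model and project layout

A project is a directory with one `ts_NNN/` subdirectory per tilt-series
(raw frames under `ts_NNN/frames/`, the acquisition `.mdoc`, and per-stage
stacks), a project-level `tomograms/` directory kept separate because
tomograms are bulky and always regenerable, and the *tomolist* — one record
per tilt-series holding acquisition geometry, dose bookkeeping, curation
state, alignment, fitted CTF and stage file paths. The tomolist is
persisted as a single HDF5 file (one group per series; scalars as
attributes, arrays as datasets; alignment and CTF as subgroups) with a
`schema_version` attribute that must match exactly on load — a version
mismatch is an explicit migration error, never a silent reinterpretation. A
JSON mirror is written next to it purely for human inspection and diffing.

The mdoc parser accepts both `[ZValue = n]` and `[FrameSet = n]` section
headers, keeps every key verbatim and in order (unknown keys survive
round trips), treats keys as case-sensitive, and stores Windows
`SubFramePath` values untouched while exposing a separator-tolerant
basename accessor. Typed accessors (tilt angle, exposure dose, ...) fail
loudly on malformed values. Alignment files follow the IMOD convention:
`.tlt` holds one angle per retained image, `.xf` six numbers per line
(2×2 linear part + pixel shift). On write, angles carry 4 decimals and xf
entries 7, so fixtures quantized to the printed precision round-trip
bit-exactly. Image data uses MRC2014 mode-2 float exclusively, with the
pixel size from the MRC header and the mdoc `PixelSpacing` as fallback.

## Dose bookkeeping

The acquisition scheme fixes the order in which tilt images were recorded;
pre-exposure is the prefix sum of per-image doses in that order,
re-sorted when the stack is assembled by ascending tilt angle (ties broken
by acquisition rank). The exposure *assigned* to an image for filtering is
a documented convention: cumulative dose up to **and including** the image
(`post`, the default), with `pre` and `mid` (half the image's own dose)
available — acquisition software and papers differ on this point, so it is
a parameter rather than an assumption. Curation drops rows from every
per-image array consistently and re-ranks the surviving acquisition order
so it remains a dense permutation with relative order preserved; removing
every image is refused (the series should be marked skipped instead).

## Exposure filtering

The critical-exposure model is the empirical power law
Nₑ(f) = a·f^b + c (e⁻/Å², f in 1/Å) with the published constants
(0.24499, −1.6649, 2.8141) as configurable defaults, and amplitude
attenuation q(f, N) = exp(−N / 2Nₑ(f)), so q = 1/e exactly at N = 2Nₑ.
The DC term is defined as q = 1, which also preserves the image mean.

Per-frame filtering weights each aligned frame's spectrum by its own q and
normalizes by √(Σqᵢ²/n). Two consequences are intentional and tested:
with q ≡ 1 the result is exactly the plain frame sum, and for i.i.d. frame
noise every frequency band keeps the noise power of the unweighted sum
(verified to within 2% over 20 Monte-Carlo repetitions in eight annular
bands). For a single frame the weight cancels entirely — the "filter" is
then the identity, which is what noise-power preservation implies at n = 1.

## Frame alignment

Global per-frame shifts are estimated by FFT cross-correlation with
quadratic (three-point parabola) subpixel peak interpolation, each frame
registered against the **leave-one-out** mean of the currently aligned
movie. Including the frame in its own reference biases the correlation
peak toward zero correction and the iteration then converges to damped
shifts; with the frame excluded the fixed-point iteration converges to the
programmed shifts (integer shifts recovered to <10⁻³ px noiselessly,
subpixel shifts to <0.25 px at signal-to-noise 2). Passes repeat until the
largest correction falls below 10⁻³ px (cap 20). The global offset is
fixed by a zero-mean-shift convention; shifts are applied by Fourier phase
ramps (periodic boundaries).

## CTF model and tiltCTF-style estimation

Conventions, fixed for interchange: defocus Δf > 0 means underfocus; the
tilt-axis angle ψ is measured counterclockwise from the image y axis; the
handedness h = ±1 is the sign of the defocus gradient. With
χ(g) = πλg²Δf − (π/2)Cs·λ³g⁴ + φ and amplitude contrast w,
CTF(g) = −(√(1−w²)·sin χ + w·cos χ); λ is the relativistic electron
wavelength. A tile centered at signed in-plane distance d (Å) from the
tilt axis sits at defocus Δf + h·d·tan θ.

The tilt-compensated power spectrum tiles the image (default 256 px tiles,
50% overlap), computes each tile's |FFT|² (mean-subtracted, no window),
radially rescales it by √(Δf_ref / (Δf_ref + Δz)) about the DC pixel —
which maps the tile's Thon rings onto those of the reference defocus — and
averages. Cs is neglected in the rescaling factor because |Δz| ≪ Δf in
practice; with 45° tilts, micron-scale fields and 2–3 µm defoci the ratio
is below 10%. For an fftshifted even-size spectrum the DC pixel is at index
n/2, not the geometric center — using the wrong center skews the radial
profile by half a pixel and measurably degrades fits.

Defocus fitting radially averages the spectrum, removes the smooth
envelope by subtracting a Gaussian-smoothed copy (σ = 5 Fourier pixels,
applied identically to the model |CTF|² so both are band-passed the same
way), and maximizes the normalized cross-correlation over the fit band
(default 5–90% of Nyquist) by grid search followed by golden-section
refinement to step/100. A spectrum whose background-subtracted profile is
identically zero is returned flagged with score 0. Astigmatism and phase
plates are not fitted — the fit is 1D radial by design.

In practice the reference defocus for compensation comes from a first
uncompensated fit; the compensated spectrum is then refitted. Handedness is
determined by running compensation + fitting under both candidate signs on
images with |θ| ≥ 20° and comparing mean scores; a margin below 0.002 is
reported as undetermined rather than guessed. On simulated 45° micrographs
(1024², 3 Å/px, 2–3 µm defocus) compensation beats the plain fit in
20/20 trials and the handedness is recovered in 20/20.

Phase-flip CTF correction processes strips parallel to the tilt axis
(which must lie along the image y axis — apply the in-plane alignment
first): each strip receives the full-image spectrum multiplied by
sign(CTF(g; Δf + Δz_strip)), and strips are blended by a linear cross-fade
over half a strip width. At θ = 0 all strips share one filter and the
operation is an exact involution. Phase flipping corrects the sign of the
transfer but not its magnitude; this matters for the end-to-end behavior
discussed below.

## Reconstruction

Geometry is single-axis with the tilt axis along y; in-plane transforms
from alignment files are applied (inverse-mapped, bilinear) to bring stacks
into that frame. Each tilt's projection operator is assembled once as a
sparse matrix over the (z, x) plane — rays are independent of y — with
linear interpolation onto the detector; backprojection is the exact matrix
transpose, so the pair passes a dot-product adjointness test at 1e−6
(measured ~1e−15) and SIRT's convergence analysis applies as written.
WBP ramp-filters along the detector coordinate with a Hann rolloff
reaching zero at Nyquist (suppresses ringing on small test volumes) and
scales by π/2N. SIRT is the standard simultaneous iteration
x ← x + λ·Aᵀ((b − Ax)/row_sum)/col_sum from x₀ = 0 with λ = 1 by default;
per-iteration residual norms are returned, and three consecutive residual
increases abort with advice to lower λ. This is genuine iterative SIRT,
not a frequency-domain "SIRT-like" filter; the two agree qualitatively
but not numerically. Fourier-crop binning keeps the central Fourier block
(factor must divide each dimension) and rescales so the mean is preserved;
band-limited content is reproduced exactly.

## Interchange

Wedge lists carry one row per retained tilt (angle, defocus, cumulative
exposure under the documented dose convention, optics) in a STAR loop.
The RELION-4-style export writes a tomogram star plus per-series
`rank,angle` order lists (rank 1-based, acquisition order); the Warp-style
export writes per-tilt images, alignment files, and a rewritten mdoc
containing only retained sections with renumbered ZValues. All exporters
are pure functions of the tomolist: re-export is byte-identical.

Orientations convert between STOPGAP's intrinsic zxz and RELION's intrinsic
zyz Euler conventions through the rotation matrix, so the physical
orientation is bit-preserved (round-trip matrix deviation < 1e−10 over
1000 random orientations); at gimbal lock the canonical triple with third
angle zero is returned. Positions convert between STOPGAP's 1-based voxel
centers and RELION's 0-based coordinates by a single offset constant of 1,
centralized because origin mistakes are the most common interchange bug.
Defocus is Å internally and converted at dialect boundaries.

## Pipelines and archival

Tasks are validated against a fixed partial order (import < assemble <
clean < {dose_filter, ctf} < recon < export < archive). Parameter files
are `key = value` text with typed coercion (int, float, bool, comma list,
string); unknown keys are rejected at parse time with the nearest valid
key suggested. Every completed task appends its full parameter snapshot
(including the pipeline seed) to the series task log; a series that
already completed a task with identical parameters is skipped, giving
resume-after-interrupt and rerun-is-a-no-op semantics. Failures are
isolated per series. Reconstruction prefers the exposure-filtered stack
when one exists — the filter is the matched weighting for dose-decayed
signal — while CTF fitting always uses the unfiltered stack, where the
high-frequency Thon rings survive.

Minimal-project export keeps raw frames, per-series stacks, metadata and
parameter files; tomogram directories and unclassified intermediates are
excluded and their byte count logged. Every kept file is listed in a JSON
manifest with size and SHA-256; revival re-verifies every checksum (hard
error naming each mismatched file), loads the tomolist, validates every
record, and reports stage products that are absent but regenerable
(tomograms) as reconstructible rather than as failures. Reconstruction is
deterministic given parameters, so a revived project regenerates
bit-identical tomograms.

## The synthetic-data generator

The generator emulates a dose-symmetric or sequential acquisition of a
phantom (spheres, grid, or points; object coordinates recorded in a
ground-truth manifest): projections via the package's own forward
projector, per-strip CTF modulation with the programmed defocus gradient
and handedness, exposure decay of the specimen signal following the same
critical-exposure model the filter uses (so filtering statistically undoes
it), movie frames with programmed shifts, and matching .mdoc files with
TiltAngle / ExposureDose / PriorRecordDose / SubFramePath / NumSubFrames /
DateTime per section. Same spec + seed is bit-reproducible.

Default study conditions: 128 px images at 4 Å/px, 64-voxel thickness,
±60° in 3° steps, dose-symmetric, 3 e⁻/Å² per tilt, 300 kV, Cs 2.7 mm,
amplitude contrast 0.07, 2.5 µm underfocus, four frames per tilt. The
pixel size reflects binned tilt images as used for tomography; at much
finer sampling a 2.5 µm defocus packs Thon rings closer than the radial
resolution of a 128 px tile and per-image fitting is degenerate.

Two modelling choices deserve emphasis. Noise is additive Gaussian with
variance proportional to dose — not Poisson, no detector MTF/DQE — chosen
for speed and analytic tractability; passing tests therefore demonstrate
correct signal processing and bookkeeping, not robustness to real detector
physics. Second, dose decay is applied to the specimen's coherent signal
but not to a separate broadband "solvent" noise term that is CTF-modulated
alongside it: real specimens keep scattering after radiation damage, which
is why Thon rings remain fittable on late, heavily exposed tilts. Without
this term, per-image CTF estimation on late tilts of a synthetic series is
impossible at any noise level.

One known limitation follows from the scope of CTF correction: phase
flipping restores the sign of the transfer function but not the amplitudes
|CTF| attenuates, so the full-physics end-to-end chain (CTF on, dose decay,
noise, phase-flip + WBP) plateaus near NCC ≈ 0.67 against the phantom under
the default conditions, while the same chain without CTF modulation reaches
NCC ≥ 0.7 and the clean-projection reconstruction benchmark reaches
NCC ≈ 0.79. Amplitude-restoring (Wiener-style) correction would close the
gap but is deliberately out of scope.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the whole suite completes in a few minutes on one CPU: 512²–1024²
micrographs for CTF recovery (20 repetitions per condition), 64³ phantoms
for reconstruction benchmarks, and a four-series, 41-tilt, 128² project
for the end-to-end pipeline. All simulation parameters above are the
package's defaults, not tuned per test.
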