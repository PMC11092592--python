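"""Tilt-series assembly, dose bookkeeping, curation and frame handling.

Acquisition schemes (sequential, dose-symmetric, ...) determine the order in
which tilt images were recorded and therefore how much exposure the specimen
had accumulated before each one.  Assembly sorts images into ascending tilt
angle while recording the acquisition rank and the accumulated (pre-)
exposure per image, which downstream exposure filtering and STA exports
depend on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdoc import MdocDocument

__all__ = [
    "DoseSchedule",
    "assemble_tilt_series",
    "AssembledSeries",
    "clean_stack",
    "sum_frames",
    "align_frames",
]


@dataclass
class DoseSchedule:
    """Per-image dose and accumulated pre-exposure, in acquisition order."""

    per_image_dose: np.ndarray  # e-/A^2
    pre_exposure: np.ndarray  # e-/A^2 accumulated before each image

    @classmethod
    def from_doses(cls, per_image_dose, initial_dose: float = 0.0) -> "DoseSchedule":
        dose = np.asarray(per_image_dose, dtype=float)
        if np.any(dose < 0) or initial_dose < 0:
            raise ValueError("doses must be nonnegative")
        pre = initial_dose + np.concatenate([[0.0], np.cumsum(dose[:-1])])
        return cls(per_image_dose=dose, pre_exposure=pre)

    def exposure_for_filtering(self, convention: str = "post") -> np.ndarray:
        """Exposure assigned to each image for filtering purposes.

        ``post`` (default): cumulative dose up to and including the image.
        ``pre``: dose accumulated before the image.
        ``mid``: pre-exposure plus half the image's own dose.
        """
        if convention == "post":
            return self.pre_exposure + self.per_image_dose
        if convention == "pre":
            return self.pre_exposure.copy()
        if convention == "mid":
            return self.pre_exposure + 0.5 * self.per_image_dose
        raise ValueError(f"unknown dose convention {convention!r}")


@dataclass
class AssembledSeries:
    """Angle-sorted stack plus the per-image bookkeeping derived from it."""

    stack: np.ndarray  # (n, ny, nx) sorted ascending by tilt angle
    tilt_angles: np.ndarray  # degrees, ascending
    acquisition_order: np.ndarray  # sorted index -> acquisition rank (0-based)
    per_image_dose: np.ndarray  # e-/A^2, sorted order
    pre_exposure: np.ndarray  # e-/A^2 accumulated before each image, sorted order


def assemble_tilt_series(
    images: np.ndarray, doc: MdocDocument, initial_dose: float = 0.0
) -> AssembledSeries:
    """Sort an acquisition-order stack by tilt angle, tracking dose.

    ``images`` must hold one slice per mdoc section, in acquisition order.
    Ties in angle are broken by acquisition rank.
    """
    images = np.asarray(images)
    n = len(doc.sections)
    if len(images) != n:
        raise ValueError(f"{len(images)} images but {n} mdoc sections")
    if n == 0:
        raise ValueError("mdoc has no sections")
    angles = np.array([sec.tilt_angle for sec in doc.sections])
    doses = np.array([sec.exposure_dose for sec in doc.sections])
    schedule = DoseSchedule.from_doses(doses, initial_dose=initial_dose)
    order = np.argsort(angles, kind="stable")  # stable = ties by acquisition rank
    # acquisition_order[k] is the 0-based acquisition rank of sorted slice k;
    # order[k] is exactly the acquisition index placed at sorted position k.
    return AssembledSeries(
        stack=images[order],
        tilt_angles=angles[order],
        acquisition_order=order.copy(),
        per_image_dose=doses[order],
        pre_exposure=schedule.pre_exposure[order],
    )


def clean_stack(
    stack: np.ndarray, series: AssembledSeries, bad_indices
) -> AssembledSeries:
    """Remove curated-out slices from a sorted series, consistently.

    ``bad_indices`` are 0-based indices into the *current* sorted stack.
    Angles, doses, pre-exposures and acquisition ranks are dropped together;
    remaining acquisition ranks are re-ranked to stay a permutation while
    preserving relative order.
    """
    n = len(series.tilt_angles)
    bad = sorted(set(int(i) for i in np.atleast_1d(np.asarray(bad_indices, int))))
    if bad and (bad[0] < 0 or bad[-1] >= n):
        raise IndexError(f"bad indices {bad} out of range for {n} images")
    if len(bad) == n:
        raise ValueError(
            "removing every image: mark the whole series as skipped instead"
        )
    keep = np.array([i for i in range(n) if i not in set(bad)], dtype=int)
    ranks = series.acquisition_order[keep]
    return AssembledSeries(
        stack=stack[keep],
        tilt_angles=series.tilt_angles[keep],
        acquisition_order=np.argsort(np.argsort(ranks)),
        per_image_dose=series.per_image_dose[keep],
        pre_exposure=series.pre_exposure[keep],
    )


def sum_frames(movie: np.ndarray, mode: str = "all") -> np.ndarray:
    """Pixelwise sum of movie frames; ``odd``/``even`` by 0-based index parity.

    Frame 0 is "even", so ``sum(all) == sum(odd) + sum(even)`` exactly.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3 or len(movie) == 0:
        raise ValueError(f"expected a nonempty (n, ny, nx) movie, got {movie.shape}")
    if mode == "all":
        # computed as even + odd so the parity split partitions the total
        # sum exactly, not just to roundoff
        total = movie[0::2].sum(axis=0)
        if len(movie) > 1:
            total = total + movie[1::2].sum(axis=0)
        return total
    if mode == "even":
        selected = movie[0::2]
    elif mode == "odd":
        selected = movie[1::2]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(selected) == 0:
        raise ValueError(f"mode {mode!r} selects no frames from a {len(movie)}-frame movie")
    return selected.sum(axis=0)


def _subpixel_peak(corr: np.ndarray) -> np.ndarray:
    """Peak of a cross-correlation surface, quadratic subpixel refinement."""
    ny, nx = corr.shape
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    shift = np.array([float(iy), float(ix)])
    for axis, (idx, dim) in enumerate([(iy, ny), (ix, nx)]):
        if axis == 0:
            c0, c1, c2 = corr[(iy - 1) % ny, ix], corr[iy, ix], corr[(iy + 1) % ny, ix]
        else:
            c0, c1, c2 = corr[iy, (ix - 1) % nx], corr[iy, ix], corr[iy, (ix + 1) % nx]
        denom = c0 - 2 * c1 + c2
        if denom != 0:
            shift[axis] += 0.5 * (c0 - c2) / denom
    shift[0] = (shift[0] + ny / 2) % ny - ny / 2
    shift[1] = (shift[1] + nx / 2) % nx - nx / 2
    return shift


def _phase_corr_shift(reference: np.ndarray, image: np.ndarray) -> np.ndarray:
    """(dy, dx) such that shifting ``image`` by it registers it to reference."""
    f_ref = np.fft.rfft2(reference)
    f_img = np.fft.rfft2(image)
    corr = np.fft.irfft2(f_ref * np.conj(f_img), s=reference.shape)
    return _subpixel_peak(corr)


def _fourier_shift(image: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Move image content by +shift (dy, dx) pixels, periodic boundaries."""
    ny, nx = image.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.rfftfreq(nx)[None, :]
    phase = np.exp(-2j * np.pi * (fy * shift[0] + fx * shift[1]))
    return np.fft.irfft2(np.fft.rfft2(image) * phase, s=image.shape)


def align_frames(
    movie: np.ndarray, tol: float = 1e-3, max_passes: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and correct global per-frame shifts of a movie.

    Each frame is registered by cross-correlation (quadratic subpixel peak
    interpolation) against the leave-one-out mean of the currently aligned
    movie — excluding the frame itself from its reference removes the
    self-correlation bias that otherwise damps the estimated shifts.
    Passes repeat until the largest per-pass correction drops below ``tol``
    pixels.  Returns (aligned movie, shifts) where shifts[i] is the (dy, dx)
    applied to frame i; the arbitrary global offset is fixed by a zero mean
    shift.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or len(movie) < 2:
        raise ValueError("frame alignment needs a movie of at least 2 frames")
    if np.allclose(movie, 0):
        raise ValueError("movie is identically zero; nothing to align")
    n = len(movie)
    shifts = np.zeros((n, 2))
    aligned = movie.copy()
    for _ in range(max_passes):
        largest = 0.0
        total = aligned.sum(axis=0)
        for i in range(n):
            reference = (total - aligned[i]) / (n - 1)
            delta = _phase_corr_shift(reference, aligned[i])
            shifts[i] += delta
            largest = max(largest, float(np.abs(delta).max()))
            aligned[i] = _fourier_shift(movie[i], shifts[i])
        if largest < tol:
            break
    shifts -= shifts.mean(axis=0)
    for i in range(n):
        aligned[i] = _fourier_shift(movie[i], shifts[i])
    return aligned, shifts
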