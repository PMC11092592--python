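"""Exposure (dose) filtering of tilt images and frame movies.

Radiation damage destroys high-resolution signal first.  The empirical
critical-exposure model of Grant & Grigorieff describes, per spatial
frequency f (1/A), the exposure Ne(f) at which signal is optimally weighted:

    Ne(f) = a * f**b + c          (a > 0, b < 0, c > 0)

and an image that has accumulated exposure N retains amplitude

    q(f, N) = exp(-N / (2 * Ne(f)))  in (0, 1].

Per-tilt filtering multiplies one image's spectrum by q at its cumulative
exposure.  Per-frame filtering weights each movie frame by its own q and
renormalizes so that the noise power of the weighted sum matches the plain
sum where no attenuation occurred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRANT_GRIGORIEFF_A",
    "GRANT_GRIGORIEFF_B",
    "GRANT_GRIGORIEFF_C",
    "ExposureFilterSpec",
    "critical_exposure",
    "filter_amplitude",
    "apply_tilt_filter",
    "apply_frame_filter_normalized",
]

# Empirical critical-exposure constants (300 kV), configurable per spec.
GRANT_GRIGORIEFF_A = 0.24499
GRANT_GRIGORIEFF_B = -1.6649
GRANT_GRIGORIEFF_C = 2.8141


@dataclass(frozen=True)
class ExposureFilterSpec:
    """Critical-exposure curve constants plus the sampling geometry."""

    pixel_size: float  # A/px
    a: float = GRANT_GRIGORIEFF_A
    b: float = GRANT_GRIGORIEFF_B
    c: float = GRANT_GRIGORIEFF_C

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0 or self.b >= 0:
            raise ValueError(
                f"critical-exposure constants must satisfy a>0, b<0, c>0; "
                f"got a={self.a}, b={self.b}, c={self.c}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")


def critical_exposure(f, spec: ExposureFilterSpec):
    """Critical exposure Ne(f) in e-/A^2 at spatial frequency f (1/A), f > 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("critical_exposure requires f > 0 (DC is handled as q=1)")
    return spec.a * f**spec.b + spec.c


def filter_amplitude(f, n_exposure: float, spec: ExposureFilterSpec):
    """Amplitude attenuation q(f, N) = exp(-N / (2 Ne(f)))."""
    if n_exposure < 0:
        raise ValueError(f"cumulative exposure must be >= 0, got {n_exposure}")
    return np.exp(-n_exposure / (2.0 * critical_exposure(f, spec)))


def _radial_freq_grid(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """|f| in 1/A on the rfft2 grid of a (ny, nx) image."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_size)[:, None]
    fx = np.fft.rfftfreq(nx, d=pixel_size)[None, :]
    return np.hypot(fy, fx)


def _q_grid(shape, n_exposure: float, spec: ExposureFilterSpec) -> np.ndarray:
    freq = _radial_freq_grid(shape, spec.pixel_size)
    q = np.ones_like(freq)
    nonzero = freq > 0
    q[nonzero] = np.exp(-n_exposure / (2.0 * critical_exposure(freq[nonzero], spec)))
    return q


def apply_tilt_filter(image: np.ndarray, n_exposure: float, spec: ExposureFilterSpec):
    """Exposure-filter one real 2D image at cumulative exposure N (e-/A^2)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if n_exposure < 0:
        raise ValueError(f"cumulative exposure must be >= 0, got {n_exposure}")
    q = _q_grid(image.shape, n_exposure, spec)
    return np.fft.irfft2(np.fft.rfft2(image) * q, s=image.shape)


def apply_frame_filter_normalized(
    movie: np.ndarray, exposures, spec: ExposureFilterSpec
) -> np.ndarray:
    """Exposure-filter movie frames and return the normalized filtered sum.

    Each frame i (cumulative exposure N_i, nondecreasing) is weighted by
    q_i(f); the weighted spectral sum is divided by sqrt(sum_i q_i^2 / n) so
    that (a) with q_i = 1 everywhere the result is exactly the plain frame
    sum, and (b) for i.i.d. frame noise every frequency shell keeps the noise
    power of the unfiltered sum.  DC is untouched (q = 1), so the output mean
    equals the plain sum's mean.
    """
    movie = np.asarray(movie, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if movie.ndim != 3:
        raise ValueError(f"expected a (n_frames, ny, nx) movie, got {movie.shape}")
    if len(exposures) != len(movie):
        raise ValueError(
            f"{len(movie)} frames but {len(exposures)} exposure values"
        )
    if np.any(np.diff(exposures) < 0):
        raise ValueError("per-frame cumulative exposures must be nondecreasing")
    shape = movie.shape[1:]
    num = np.zeros(
        (shape[0], shape[1] // 2 + 1), dtype=complex
    )
    qsq = np.zeros_like(num, dtype=float)
    for frame, n_exp in zip(movie, exposures):
        q = _q_grid(shape, float(n_exp), spec)
        num += q * np.fft.rfft2(frame)
        qsq += q * q
    norm = np.sqrt(qsq / len(movie))
    return np.fft.irfft2(num / norm, s=shape)
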