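"""Contrast transfer function model, tilt-compensated power spectra, and
defocus fitting.

On a tilted specimen the defocus varies linearly with the signed in-plane
distance from the tilt axis: a point at distance d (A) from the axis sits at

    defocus(d) = defocus_at_axis + h * d * tan(theta)

where theta is the stage tilt and h = +/-1 the geometric handedness (which
side of the axis is closer to focus).  Averaging raw tile power spectra
across such an image blurs the Thon rings; the tilt-compensated spectrum
rescales each tile's radial frequency axis so its rings land where they
would for the reference defocus before averaging, restoring ring contrast
and enabling reliable defocus fitting on tilted images.

Conventions (fixed and documented for interchange):

* defocus is positive for underfocus; Delta-z > 0 means farther from focus;
* ``tilt_axis_angle`` is measured counterclockwise from the image y axis;
* CTF(g) = -( sqrt(1 - w^2) sin(chi) + w cos(chi) ) with
  chi(g) = pi lambda g^2 dz - (pi/2) Cs lambda^3 g^4 + phase_shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

__all__ = [
    "CtfParams",
    "TiltGeometry",
    "CtfResult",
    "HandednessResult",
    "electron_wavelength",
    "ctf_value",
    "tile_defocus_offset",
    "tilt_compensated_ps",
    "radial_average",
    "fit_defocus",
    "determine_handedness",
    "phase_flip_correct",
]


@dataclass(frozen=True)
class CtfParams:
    """Optical constants plus defocus for one image."""

    voltage: float  # kV
    cs: float  # mm
    amplitude_contrast: float  # fraction in [0, 1)
    pixel_size: float  # A/px
    defocus: float = 0.0  # A, positive = underfocus
    phase_shift: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError(f"voltage must be positive, got {self.voltage}")
        if not 0 <= self.amplitude_contrast < 1:
            raise ValueError(
                f"amplitude contrast must be in [0, 1), got {self.amplitude_contrast}"
            )
        if not math.isfinite(self.defocus):
            raise ValueError("defocus must be finite")

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage)


@dataclass(frozen=True)
class TiltGeometry:
    """Tilt geometry of one image."""

    tilt_angle: float  # degrees
    tilt_axis_angle: float = 0.0  # degrees CCW from image y axis
    handedness: int = 1  # +1 or -1
    center: tuple[float, float] | None = None  # (x, y) px; None = image center

    def __post_init__(self) -> None:
        if self.handedness not in (-1, 1):
            raise ValueError(f"handedness must be +1 or -1, got {self.handedness}")
        if not -90.0 < self.tilt_angle < 90.0:
            raise ValueError(
                f"tilt angle must lie in (-90, 90) degrees, got {self.tilt_angle}"
            )


@dataclass(frozen=True)
class CtfResult:
    """Outcome of a defocus fit for one image."""

    defocus: float  # A
    score: float  # normalized cross-correlation in [-1, 1]
    fit_range: tuple[float, float]  # 1/A
    flagged: bool = False  # True when the spectrum carried no usable signal


@dataclass(frozen=True)
class HandednessResult:
    handedness: int | None  # None = undetermined
    score_positive: float
    score_negative: float


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in A for a voltage in kV."""
    if voltage_kv <= 0:
        raise ValueError(f"voltage must be positive, got {voltage_kv}")
    v = voltage_kv * 1e3
    return 12.2639 / math.sqrt(v + 0.97845e-6 * v * v)


def ctf_value(g, p: CtfParams):
    """CTF at spatial frequency g (1/A); array-valued for array input."""
    g = np.asarray(g, dtype=float)
    lam = p.wavelength
    cs_a = p.cs * 1e7  # mm -> A
    chi = (
        math.pi * lam * g**2 * p.defocus
        - 0.5 * math.pi * cs_a * lam**3 * g**4
        + p.phase_shift
    )
    w = p.amplitude_contrast
    return -(math.sqrt(1.0 - w * w) * np.sin(chi) + w * np.cos(chi))


def tile_defocus_offset(
    tile_center: tuple[float, float], geom: TiltGeometry, pixel_size: float,
    image_shape: tuple[int, int] | None = None,
) -> float:
    """Defocus offset (A) of a tile at pixel position ``(x, y)``.

    The signed in-plane distance from the tilt axis is measured along the
    axis normal ``(cos psi, sin psi)``; the offset is ``h * d * tan(theta)``.
    """
    theta = math.radians(geom.tilt_angle)
    psi = math.radians(geom.tilt_axis_angle)
    if geom.center is not None:
        cx, cy = geom.center
    elif image_shape is not None:
        cy_, cx_ = image_shape
        cx, cy = (cx_ - 1) / 2.0, (cy_ - 1) / 2.0
    else:
        raise ValueError("either geom.center or image_shape must provide the center")
    dx = tile_center[0] - cx
    dy = tile_center[1] - cy
    d_px = dx * math.cos(psi) + dy * math.sin(psi)
    return geom.handedness * d_px * pixel_size * math.tan(theta)


def _tile_origins(extent: int, tile: int, step: int) -> list[int]:
    if extent == tile:
        return [0]
    origins = list(range(0, extent - tile + 1, step))
    if origins[-1] != extent - tile:
        origins.append(extent - tile)
    return origins


def tilt_compensated_ps(
    image: np.ndarray,
    geom: TiltGeometry,
    p: CtfParams,
    tile: int = 256,
    overlap: float = 0.5,
    defocus_ref: float | None = None,
) -> np.ndarray:
    """Tile-averaged power spectrum with per-tile defocus-gradient compensation.

    Each tile's ``|FFT|^2`` is radially rescaled by
    ``sqrt(defocus_ref / (defocus_ref + dz_tile))`` so its Thon rings map onto
    those of the reference defocus (Cs is neglected in the rescaling, valid
    while ``|dz| << defocus``), then tiles are averaged.  ``defocus_ref``
    defaults to ``p.defocus`` and must be positive, as must every tile's
    local defocus.

    Returns the fftshifted 2D power spectrum (tile x tile), DC at the center.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    if tile > min(ny, nx):
        raise ValueError(f"tile size {tile} exceeds image {image.shape}")
    if defocus_ref is None:
        defocus_ref = p.defocus
    if defocus_ref <= 0:
        raise ValueError(f"reference defocus must be positive, got {defocus_ref}")
    step = max(1, int(round(tile * (1.0 - overlap))))
    acc = np.zeros((tile, tile))
    center = tile // 2  # DC position of an fftshifted even-size spectrum
    yy, xx = np.meshgrid(np.arange(tile), np.arange(tile), indexing="ij")
    n_tiles = 0
    for oy in _tile_origins(ny, tile, step):
        for ox in _tile_origins(nx, tile, step):
            tile_center = (ox + (tile - 1) / 2.0, oy + (tile - 1) / 2.0)
            dz = tile_defocus_offset(tile_center, geom, p.pixel_size, image.shape)
            dz_total = defocus_ref + dz
            if dz_total <= 0:
                raise ValueError(
                    f"tile at origin ({ox}, {oy}) has non-positive defocus "
                    f"{dz_total:.1f} A"
                )
            patch = image[oy : oy + tile, ox : ox + tile]
            ps = np.abs(np.fft.fftshift(np.fft.fft2(patch - patch.mean()))) ** 2
            scale = math.sqrt(defocus_ref / dz_total)
            if abs(scale - 1.0) < 1e-12:
                acc += ps
            else:
                coords = np.array(
                    [center + (yy - center) * scale, center + (xx - center) * scale]
                )
                acc += map_coordinates(ps, coords, order=1, mode="nearest")
            n_tiles += 1
    return acc / n_tiles


def radial_average(ps: np.ndarray) -> np.ndarray:
    """Radial mean of an fftshifted square power spectrum; bin = Fourier px."""
    n = ps.shape[0]
    center = n // 2  # DC position of an fftshifted even-size spectrum
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.rint(np.hypot(yy - center, xx - center)).astype(int)
    nbins = n // 2
    mask = r < nbins
    counts = np.bincount(r[mask], minlength=nbins)
    sums = np.bincount(r[mask], weights=ps[mask], minlength=nbins)
    return sums / np.maximum(counts, 1)


def _profile_ncc(profile: np.ndarray, model: np.ndarray) -> float:
    a = profile - profile.mean()
    b = model - model.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _score_for_defocus(
    defocus: float,
    resid: np.ndarray,
    freqs: np.ndarray,
    band: np.ndarray,
    p: CtfParams,
    bg_sigma: float,
) -> float:
    model = ctf_value(freqs, replace(p, defocus=defocus)) ** 2
    model = model - gaussian_filter1d(model, bg_sigma)
    return _profile_ncc(resid[band], model[band])


def fit_defocus(
    ps: np.ndarray,
    p: CtfParams,
    search_range: tuple[float, float] = (5000.0, 70000.0),
    search_step: float = 100.0,
    fit_range: tuple[float, float] | None = None,
    background_sigma: float = 5.0,
) -> CtfResult:
    """Fit defocus to an fftshifted power spectrum by Thon-ring matching.

    The radial profile and the model ``CTF^2`` both have their smooth
    (Gaussian, ``sigma = background_sigma`` Fourier px) envelope removed; the
    defocus maximizing their normalized cross-correlation over ``fit_range``
    (1/A, default 0.05 x Nyquist .. 0.9 x Nyquist) is located by grid search
    and refined by golden-section search to ``search_step / 100``.
    """
    lo, hi = search_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid defocus search range {search_range}")
    profile = radial_average(ps)
    n = len(profile)
    nyquist = 1.0 / (2.0 * p.pixel_size)
    freqs = np.arange(n) / n * nyquist
    if fit_range is None:
        fit_range = (0.05 * nyquist, 0.9 * nyquist)
    f_lo, f_hi = fit_range
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"fit range {fit_range} extends beyond Nyquist {nyquist:.4f}")
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if band.sum() < 8:
        raise ValueError(f"fit band {fit_range} selects too few radial bins")
    resid = profile - gaussian_filter1d(profile, background_sigma)
    if np.allclose(resid[band], 0.0):
        return CtfResult(defocus=lo, score=0.0, fit_range=fit_range, flagged=True)

    def score(dz: float) -> float:
        return _score_for_defocus(dz, resid, freqs, band, p, background_sigma)

    grid = np.arange(lo, hi + search_step / 2, search_step)
    scores = np.array([score(dz) for dz in grid])
    best = int(np.argmax(scores))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    # golden-section refinement to search_step / 100
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    tol = search_step / 100.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = score(c), score(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = score(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = score(d)
    dz_hat = (a + b) / 2.0
    return CtfResult(defocus=float(dz_hat), score=score(dz_hat), fit_range=fit_range)


def determine_handedness(
    images: list[np.ndarray],
    geoms: list[TiltGeometry],
    p: CtfParams,
    tile: int = 256,
    overlap: float = 0.5,
    defocus_ref: float | None = None,
    min_tilt: float = 20.0,
    score_margin: float = 0.002,
    **fit_kwargs,
) -> HandednessResult:
    """Determine the defocus-gradient handedness from tilted images.

    Runs gradient-compensated spectrum generation and defocus fitting under
    both candidate signs and returns the sign with the higher mean fit score.
    When the mean scores differ by less than ``score_margin`` the result is
    undetermined (``handedness=None``).
    """
    usable = [
        (img, g) for img, g in zip(images, geoms) if abs(g.tilt_angle) >= min_tilt
    ]
    if not usable:
        raise ValueError(
            f"handedness needs at least one image with |tilt| >= {min_tilt} deg"
        )
    means = {}
    for h in (1, -1):
        scores = []
        for img, g in usable:
            g_h = replace(g, handedness=h)
            ps = tilt_compensated_ps(
                img, g_h, p, tile=tile, overlap=overlap, defocus_ref=defocus_ref
            )
            scores.append(fit_defocus(ps, p, **fit_kwargs).score)
        means[h] = float(np.mean(scores))
    if abs(means[1] - means[-1]) < score_margin:
        return HandednessResult(None, means[1], means[-1])
    winner = 1 if means[1] > means[-1] else -1
    return HandednessResult(winner, means[1], means[-1])


def _strip_filter_apply(
    image: np.ndarray,
    geom: TiltGeometry,
    p: CtfParams,
    strip_width: int,
    transfer,
) -> np.ndarray:
    """Apply an x-position-dependent Fourier filter in strips.

    The tilt axis must lie along the image y axis (|tilt_axis_angle| small);
    the defocus then varies along x only.  Each strip of width ``strip_width``
    receives the full-image filter evaluated at its own local defocus; strips
    are blended by a linear cross-fade over half a strip width.
    """
    if abs(geom.tilt_axis_angle) > 1e-6:
        raise ValueError(
            "strip-based correction requires the tilt axis along the image "
            "y axis; apply the in-plane alignment first"
        )
    ny, nx = image.shape
    if strip_width < 16:
        raise ValueError(f"strip width {strip_width} px < 16 px is unstable")
    fy = np.fft.fftfreq(ny, d=p.pixel_size)[:, None]
    fx = np.fft.rfftfreq(nx, d=p.pixel_size)[None, :]
    g = np.hypot(fy, fx)
    ft = np.fft.rfft2(image)
    centers = np.arange(strip_width / 2.0 - 0.5, nx, strip_width)
    x = np.arange(nx)
    out = np.zeros_like(image, dtype=float)
    weight = np.zeros(nx)
    fade = strip_width / 2.0
    for cx_strip in centers:
        # axis along y: the y coordinate of the strip center is irrelevant
        cy = (ny - 1) / 2.0 if geom.center is None else geom.center[1]
        dz = tile_defocus_offset((cx_strip, cy), geom, p.pixel_size, (ny, nx))
        p_local = replace(p, defocus=p.defocus + dz)
        filt = transfer(g, p_local)
        corrected = np.fft.irfft2(ft * filt, s=image.shape)
        w = np.clip(1.0 - np.abs(x - cx_strip) / (strip_width / 2.0 + fade), 0.0, 1.0)
        out += corrected * w[None, :]
        weight += w
    return out / weight[None, :]


def phase_flip_correct(
    image: np.ndarray,
    geom: TiltGeometry,
    p: CtfParams,
    strip_width: int = 64,
) -> np.ndarray:
    """Strip-based 2D phase-flip CTF correction of one tilt image.

    Each strip parallel to the tilt axis is multiplied (in Fourier space) by
    ``sign(CTF(g; defocus + dz_strip))``; ``p.defocus`` must hold the fitted
    defocus at the tilt axis.
    """
    if p.defocus <= 0:
        raise ValueError("phase flipping requires a fitted positive defocus")

    def transfer(g, p_local):
        s = np.sign(ctf_value(g, p_local))
        s[s == 0] = 1.0
        return s

    return _strip_filter_apply(np.asarray(image, dtype=float), geom, p,
                               strip_width, transfer)


def ctf_modulate(
    image: np.ndarray,
    geom: TiltGeometry,
    p: CtfParams,
    strip_width: int = 64,
) -> np.ndarray:
    """Multiply an image by the (tilted) CTF in strips — the forward model
    used by the simulator; shares the strip machinery with phase flipping."""

    def transfer(g, p_local):
        return ctf_value(g, p_local)

    return _strip_filter_apply(np.asarray(image, dtype=float), geom, p,
                               strip_width, transfer)
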