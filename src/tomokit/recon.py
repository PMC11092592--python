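"""Single-axis tomographic projection and reconstruction.

Geometry: the tilt axis is the image/volume y axis.  A volume is indexed
``(nz, ny, nx)``; a tilt stack is ``(n_tilts, ny, nx_det)`` with the
detector coordinate u along x.  A ray at tilt theta maps voxel (z, x) to

    u = (x - cx) cos(theta) + (z - cz) sin(theta) + cu

independently of y, so each tilt's projection is a sparse matrix acting on
the (z, x) plane, applied to every y row at once.  Backprojection is the
exact transpose of that matrix, which makes the projector/backprojector
pair adjoint to numerical precision — a property SIRT's convergence
analysis relies on.

Weighted back projection ramp-filters each projection along u (with a Hann
rolloff at Nyquist to suppress ringing on small volumes) before
backprojecting.  SIRT iterates

    x_{k+1} = x_k + lambda * A^T( (b - A x_k) / row_sum ) / col_sum
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

from .alignment import AlignmentFile

__all__ = [
    "ReconSpec",
    "project_forward",
    "backproject",
    "wbp_reconstruct",
    "sirt_reconstruct",
    "fourier_crop",
    "apply_transforms",
]


@dataclass
class ReconSpec:
    """Geometry of a single-axis reconstruction."""

    tilt_angles: np.ndarray  # degrees
    thickness: int  # nz voxels
    width: int  # nx voxels (detector width)
    height: int  # ny voxels (along the tilt axis)
    alignment: AlignmentFile | None = None
    filter: str = "ramp"  # "ramp" | "none"

    def __post_init__(self) -> None:
        self.tilt_angles = np.asarray(self.tilt_angles, dtype=float)
        if self.thickness <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")
        if self.filter not in ("ramp", "none"):
            raise ValueError(f"unknown filter {self.filter!r}")


def _projection_matrix(theta_deg: float, nz: int, nx: int, nu: int) -> sp.csr_matrix:
    """Sparse (nu, nz*nx) line-integral matrix with linear interpolation."""
    theta = math.radians(theta_deg)
    cz = (nz - 1) / 2.0
    cx = (nx - 1) / 2.0
    cu = (nu - 1) / 2.0
    z, x = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
    u = (x - cx) * math.cos(theta) + (z - cz) * math.sin(theta) + cu
    u0 = np.floor(u).astype(int)
    w1 = u - u0
    w0 = 1.0 - w1
    cols = np.arange(nz * nx)
    rows = np.concatenate([u0.ravel(), u0.ravel() + 1])
    data = np.concatenate([w0.ravel(), w1.ravel()])
    cols2 = np.concatenate([cols, cols])
    valid = (rows >= 0) & (rows < nu)
    return sp.csr_matrix(
        (data[valid], (rows[valid], cols2[valid])), shape=(nu, nz * nx)
    )


class _Projector:
    """Cached per-angle sparse matrices for one geometry."""

    def __init__(self, spec: ReconSpec):
        self.spec = spec
        nz, nx, nu = spec.thickness, spec.width, spec.width
        self.matrices = [
            _projection_matrix(t, nz, nx, nu) for t in spec.tilt_angles
        ]

    def forward(self, volume: np.ndarray) -> np.ndarray:
        nz, ny, nx = volume.shape
        flat = volume.transpose(0, 2, 1).reshape(nz * nx, ny)
        stack = np.stack([(m @ flat).T for m in self.matrices])
        return stack  # (n_tilts, ny, nu)

    def adjoint(self, stack: np.ndarray) -> np.ndarray:
        nz, nx = self.spec.thickness, self.spec.width
        ny = stack.shape[1]
        acc = np.zeros((nz * nx, ny))
        for m, proj in zip(self.matrices, stack):
            acc += m.T @ proj.T
        return acc.reshape(nz, nx, ny).transpose(0, 2, 1)


def project_forward(volume: np.ndarray, spec: ReconSpec) -> np.ndarray:
    """Line-integral projections of a volume at each tilt angle."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != (spec.thickness, spec.height, spec.width):
        raise ValueError(
            f"volume shape {volume.shape} does not match spec "
            f"({spec.thickness}, {spec.height}, {spec.width})"
        )
    return _Projector(spec).forward(volume)


def backproject(stack: np.ndarray, spec: ReconSpec) -> np.ndarray:
    """Adjoint of :func:`project_forward` (unfiltered backprojection)."""
    return _Projector(spec).adjoint(np.asarray(stack, dtype=float))


def _ramp_filter(stack: np.ndarray) -> np.ndarray:
    """Ramp filter along u with a Hann rolloff reaching zero at Nyquist."""
    nu = stack.shape[-1]
    freq = np.fft.rfftfreq(nu)
    window = freq * (0.5 + 0.5 * np.cos(np.pi * freq / 0.5))
    ft = np.fft.rfft(stack, axis=-1)
    return np.fft.irfft(ft * window, n=nu, axis=-1)


def apply_transforms(stack: np.ndarray, alignment: AlignmentFile) -> np.ndarray:
    """Bring raw images into the aligned frame using per-image xf transforms.

    IMOD convention: the xf rows map input image coordinates to aligned
    coordinates about the image center; resampling uses the inverse map.
    """
    if len(alignment) != len(stack):
        raise ValueError(
            f"{len(stack)} images but alignment has {len(alignment)} rows"
        )
    out = np.empty_like(stack, dtype=float)
    ny, nx = stack.shape[1:]
    center = np.array([(ny - 1) / 2.0, (nx - 1) / 2.0])
    for i, (img, m, s) in enumerate(
        zip(stack, alignment.transforms, alignment.shifts)
    ):
        # xf acts on (x, y); ndimage works in (row=y, col=x) order.
        # aligned = M (input - center) + center + shift, so resampling uses
        # input = M^-1 (aligned - center - shift) + center.
        m_rc = np.array([[m[1, 1], m[1, 0]], [m[0, 1], m[0, 0]]])
        s_rc = np.array([s[1], s[0]])
        inv = np.linalg.inv(m_rc)
        offset = center - inv @ (center + s_rc)
        out[i] = ndimage.affine_transform(
            img, inv, offset=offset, order=1, mode="constant", cval=0.0
        )
    return out


def wbp_reconstruct(stack: np.ndarray, spec: ReconSpec) -> np.ndarray:
    """Weighted back projection of an aligned tilt stack."""
    stack = np.asarray(stack, dtype=float)
    if len(stack) != len(spec.tilt_angles):
        raise ValueError(
            f"{len(stack)} projections but {len(spec.tilt_angles)} tilt angles"
        )
    if spec.alignment is not None:
        stack = apply_transforms(stack, spec.alignment)
    if spec.filter == "ramp":
        stack = _ramp_filter(stack)
    vol = _Projector(spec).adjoint(stack)
    return vol * (math.pi / (2.0 * len(spec.tilt_angles)))


def sirt_reconstruct(
    stack: np.ndarray,
    spec: ReconSpec,
    n_iter: int = 15,
    relaxation: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """SIRT reconstruction; returns (volume, per-iteration residual norms)."""
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    if not 0 < relaxation <= 2:
        raise ValueError(f"relaxation must lie in (0, 2], got {relaxation}")
    stack = np.asarray(stack, dtype=float)
    if spec.alignment is not None:
        stack = apply_transforms(stack, spec.alignment)
    proj = _Projector(spec)
    ones_vol = np.ones((spec.thickness, spec.height, spec.width))
    row_sum = proj.forward(ones_vol)
    row_sum[row_sum == 0] = 1.0
    col_sum = proj.adjoint(np.ones_like(stack))
    col_sum[col_sum == 0] = 1.0
    x = np.zeros_like(ones_vol)
    residuals = []
    rising = 0
    for _ in range(n_iter):
        resid = stack - proj.forward(x)
        residuals.append(float(np.linalg.norm(resid)))
        if len(residuals) >= 2 and residuals[-1] > residuals[-2]:
            rising += 1
            if rising >= 3:
                raise RuntimeError(
                    "SIRT residual increased for 3 consecutive iterations; "
                    "reduce the relaxation factor"
                )
        else:
            rising = 0
        x = x + relaxation * proj.adjoint(resid / row_sum) / col_sum
    residuals.append(float(np.linalg.norm(stack - proj.forward(x))))
    return x, np.asarray(residuals)


def fourier_crop(data: np.ndarray, factor: int) -> np.ndarray:
    """Bin an image or volume by keeping the central Fourier region.

    Each dimension shrinks by ``factor`` (which must divide it); the result
    is rescaled so the mean value is preserved.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return np.asarray(data, dtype=float).copy()
    data = np.asarray(data, dtype=float)
    for dim in data.shape:
        if dim % factor:
            raise ValueError(
                f"factor {factor} does not divide dimension {dim} in {data.shape}"
            )
    ft = np.fft.fftshift(np.fft.fftn(data))
    slices = tuple(
        slice((dim - dim // factor) // 2, (dim - dim // factor) // 2 + dim // factor)
        for dim in data.shape
    )
    cropped = np.fft.ifftshift(ft[slices])
    out = np.fft.ifftn(cropped).real
    return out / factor**data.ndim
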