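"""Minimal MRC2014 image I/O.

Only the subset of the format the toolkit needs: 2D images, 2D stacks and 3D
volumes stored as 32-bit float (mode 2), with the voxel size carried in the
``cella``/``m{x,y,z}`` header words.  Data are written C-contiguous with the
MRC axis convention (x fastest), i.e. a numpy array of shape ``(nz, ny, nx)``
maps directly onto the file.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

HEADER_SIZE = 1024
_MAP_ID = b"MAP "

#: little-endian machine stamp
_MACHST_LE = bytes((0x44, 0x44, 0x00, 0x00))


class MrcError(ValueError):
    pass


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC file.

    Returns
    -------
    data : ndarray
        float32 array of shape (nz, ny, nx); singleton z is squeezed to 2D.
    pixel_size : float
        Voxel size in A/px along x (0.0 if the header carries none).
    """
    raw = Path(path).read_bytes()
    if len(raw) < HEADER_SIZE:
        raise MrcError(f"{path}: file shorter than an MRC header")
    nx, ny, nz, mode = struct.unpack("<4i", raw[:16])
    if mode != 2:
        raise MrcError(f"{path}: unsupported MRC mode {mode} (only mode 2 float)")
    mx, my, mz = struct.unpack("<3i", raw[28:40])
    cella = struct.unpack("<3f", raw[40:52])
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    n = nx * ny * nz
    offset = HEADER_SIZE + nsymbt
    data = np.frombuffer(raw, dtype="<f4", count=n, offset=offset)
    data = data.reshape(nz, ny, nx).astype(np.float32)
    pixel_size = float(cella[0] / mx) if mx > 0 and cella[0] > 0 else 0.0
    if nz == 1:
        data = data[0]
    return data, pixel_size


def write_mrc(path: str | Path, data: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write ``data`` (2D or 3D) as an MRC2014 mode-2 file."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise MrcError(f"expected 2D or 3D data, got ndim={data.ndim}")
    nz, ny, nx = data.shape
    header = bytearray(HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    dmin, dmax, dmean = float(data.min()), float(data.max()), float(data.mean())
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<i", header, 88, 0)  # ispg: image stack
    header[208:212] = _MAP_ID
    header[212:216] = _MACHST_LE
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data, dtype="<f4").tobytes())
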