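"""IMOD-convention tilt-series alignment files (.tlt / .xf).

A ``.tlt`` file carries one tilt angle (degrees) per retained image; the
matching ``.xf`` carries one in-plane transform per line as six numbers
``a11 a12 a21 a22 dx dy`` — a 2x2 linear part plus a pixel shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlignmentFile", "AlignmentError", "read_alignment", "write_alignment"]


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentFile:
    """Per-image tilt angles and invertible in-plane transforms."""

    tilt_angles: np.ndarray  # (n,) degrees
    transforms: np.ndarray  # (n, 2, 2) linear parts
    shifts: np.ndarray  # (n, 2) pixel shifts (dx, dy)

    def __post_init__(self) -> None:
        self.tilt_angles = np.asarray(self.tilt_angles, dtype=float)
        self.transforms = np.asarray(self.transforms, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        n = len(self.tilt_angles)
        if self.transforms.shape != (n, 2, 2) or self.shifts.shape != (n, 2):
            raise AlignmentError(
                f"inconsistent lengths: {n} angles, {len(self.transforms)} "
                f"transforms, {len(self.shifts)} shifts"
            )
        dets = np.linalg.det(self.transforms) if n else np.empty(0)
        if n and np.any(dets == 0):
            bad = int(np.flatnonzero(dets == 0)[0])
            raise AlignmentError(f"transform {bad} is singular (det = 0)")

    def __len__(self) -> int:
        return len(self.tilt_angles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignmentFile):
            return NotImplemented
        return (
            np.array_equal(self.tilt_angles, other.tilt_angles)
            and np.array_equal(self.transforms, other.transforms)
            and np.array_equal(self.shifts, other.shifts)
        )

    @classmethod
    def identity(cls, tilt_angles) -> "AlignmentFile":
        n = len(tilt_angles)
        return cls(
            tilt_angles=np.asarray(tilt_angles, dtype=float),
            transforms=np.tile(np.eye(2), (n, 1, 1)),
            shifts=np.zeros((n, 2)),
        )

    def select(self, indices) -> "AlignmentFile":
        """Row subset (used when curation drops images)."""
        idx = np.asarray(indices, dtype=int)
        return AlignmentFile(
            self.tilt_angles[idx], self.transforms[idx], self.shifts[idx]
        )


def _parse_numbers(text: str, what: str) -> list[list[float]]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        values = []
        for tok in stripped.split():
            try:
                values.append(float(tok))
            except ValueError:
                raise AlignmentError(
                    f"{what} line {lineno}: non-numeric token {tok!r}"
                ) from None
        rows.append(values)
    return rows


def read_alignment(tlt_text: str, xf_text: str) -> AlignmentFile:
    tlt_rows = _parse_numbers(tlt_text, ".tlt")
    xf_rows = _parse_numbers(xf_text, ".xf")
    for lineno, row in enumerate(tlt_rows, start=1):
        if len(row) != 1:
            raise AlignmentError(f".tlt line {lineno}: expected 1 value, got {len(row)}")
    for lineno, row in enumerate(xf_rows, start=1):
        if len(row) != 6:
            raise AlignmentError(f".xf line {lineno}: expected 6 values, got {len(row)}")
    if len(tlt_rows) != len(xf_rows):
        raise AlignmentError(
            f"line count mismatch: {len(tlt_rows)} tlt vs {len(xf_rows)} xf"
        )
    angles = np.array([r[0] for r in tlt_rows])
    xf = np.array(xf_rows).reshape(-1, 6) if xf_rows else np.empty((0, 6))
    transforms = xf[:, :4].reshape(-1, 2, 2)
    shifts = xf[:, 4:6]
    return AlignmentFile(angles, transforms, shifts)


def write_alignment(a: AlignmentFile) -> tuple[str, str]:
    """Serialize to (tlt_text, xf_text); 7-decimal fixed format as in IMOD."""
    if len(a) == 0:
        raise AlignmentError("refusing to write an empty alignment")
    tlt = "\n".join(f"{ang:.4f}" for ang in a.tilt_angles) + "\n"
    xf_lines = []
    for (m, s) in zip(a.transforms, a.shifts):
        xf_lines.append(
            f"{m[0, 0]:.7f} {m[0, 1]:.7f} {m[1, 0]:.7f} {m[1, 1]:.7f} "
            f"{s[0]:.7f} {s[1]:.7f}"
        )
    return tlt, "\n".join(xf_lines) + "\n"
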