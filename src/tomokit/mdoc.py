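"""SerialEM .mdoc metadata documents.

An mdoc file is a global header of ``key = value`` lines (optionally
interleaved with ``[T = ...]`` title lines) followed by one
``[ZValue = n]`` (or ``[FrameSet = n]``) block per acquired image.  The
parser keeps every key verbatim and in order so that unknown keys survive a
parse -> write -> parse round trip byte-for-byte (modulo line endings).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import PureWindowsPath

__all__ = ["MdocSection", "MdocDocument", "MdocError", "parse_mdoc", "write_mdoc"]

_SECTION_RE = re.compile(r"^\[(ZValue|FrameSet)\s*=\s*(\d+)\]\s*$")
_TITLE_RE = re.compile(r"^\[T\s*=\s*(.*)\]\s*$")
_KV_RE = re.compile(r"^([^=\[\]]+?)\s*=\s*(.*)$")


class MdocError(ValueError):
    """Malformed mdoc content or a malformed value behind a typed accessor."""


@dataclass
class MdocSection:
    """One per-image block. Keys are case-sensitive and order-preserving."""

    z_value: int
    keys: dict[str, str] = field(default_factory=dict)
    header_name: str = "ZValue"

    def _require(self, key: str) -> str:
        if key not in self.keys:
            raise MdocError(f"section {self.z_value}: missing key {key!r}")
        return self.keys[key]

    def _as_float(self, key: str) -> float:
        raw = self._require(key)
        try:
            return float(raw)
        except ValueError:
            raise MdocError(
                f"section {self.z_value}: key {key!r} has non-numeric value {raw!r}"
            ) from None

    @property
    def tilt_angle(self) -> float:
        """Stage tilt angle at acquisition, degrees."""
        return self._as_float("TiltAngle")

    @property
    def exposure_dose(self) -> float:
        """Dose applied by this image, e-/A^2."""
        return self._as_float("ExposureDose")

    @property
    def prior_record_dose(self) -> float | None:
        """Dose accumulated before this image, e-/A^2 (optional key)."""
        if "PriorRecordDose" not in self.keys:
            return None
        return self._as_float("PriorRecordDose")

    @property
    def sub_frame_path(self) -> str | None:
        """Frame-movie path, stored verbatim (may be a Windows path)."""
        return self.keys.get("SubFramePath")

    @property
    def sub_frame_basename(self) -> str | None:
        """Basename of SubFramePath, tolerant of Windows separators."""
        raw = self.sub_frame_path
        if raw is None:
            return None
        return PureWindowsPath(raw.replace("\\", "/")).name

    @property
    def date_time(self) -> datetime:
        raw = self._require("DateTime")
        for fmt in ("%d-%b-%Y %H:%M:%S", "%d-%b-%y %H:%M:%S", "%Y-%m-%d %H:%M:%S"):
            try:
                return datetime.strptime(raw.strip(), fmt)
            except ValueError:
                continue
        raise MdocError(f"section {self.z_value}: unparseable DateTime {raw!r}")

    @property
    def num_sub_frames(self) -> int | None:
        if "NumSubFrames" not in self.keys:
            return None
        raw = self.keys["NumSubFrames"]
        try:
            return int(raw)
        except ValueError:
            raise MdocError(
                f"section {self.z_value}: NumSubFrames not an integer: {raw!r}"
            ) from None


@dataclass
class MdocDocument:
    """Parsed mdoc: ordered global header, title lines, ordered sections."""

    global_header: dict[str, str] = field(default_factory=dict)
    titles: list[str] = field(default_factory=list)
    sections: list[MdocSection] = field(default_factory=list)

    @property
    def pixel_spacing(self) -> float | None:
        """PixelSpacing from the global header, A/px."""
        if "PixelSpacing" not in self.global_header:
            return None
        return float(self.global_header["PixelSpacing"])

    @property
    def voltage(self) -> float | None:
        """Acceleration voltage, kV."""
        if "Voltage" not in self.global_header:
            return None
        return float(self.global_header["Voltage"])


def parse_mdoc(text: str, require_tilt_angle: bool = True) -> MdocDocument:
    """Parse SerialEM mdoc text.

    Every key of every block is retained verbatim; sections appear in file
    order.  Duplicate section indices and (by default) sections lacking a
    TiltAngle are rejected because downstream assembly needs both.
    """
    doc = MdocDocument()
    current: MdocSection | None = None
    seen: set[int] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        m = _SECTION_RE.match(stripped)
        if m:
            z = int(m.group(2))
            if z < 0:
                raise MdocError(f"line {lineno}: negative section index {z}")
            if z in seen:
                raise MdocError(f"line {lineno}: duplicate section index {z}")
            seen.add(z)
            current = MdocSection(z_value=z, header_name=m.group(1))
            doc.sections.append(current)
            continue
        m = _TITLE_RE.match(stripped)
        if m:
            doc.titles.append(m.group(1))
            continue
        m = _KV_RE.match(stripped)
        if m:
            key, value = m.group(1).strip(), m.group(2).strip()
            target = current.keys if current is not None else doc.global_header
            target[key] = value
            continue
        raise MdocError(f"line {lineno}: unparseable mdoc line {stripped!r}")
    if require_tilt_angle:
        for sec in doc.sections:
            if "TiltAngle" not in sec.keys:
                raise MdocError(f"section {sec.z_value}: missing TiltAngle")
    return doc


def write_mdoc(doc: MdocDocument) -> str:
    """Serialize a document; output re-parses to an equal document."""
    lines: list[str] = []
    for key, value in doc.global_header.items():
        lines.append(f"{key} = {value}")
    if doc.global_header:
        lines.append("")
    for title in doc.titles:
        lines.append(f"[T = {title}]")
    if doc.titles:
        lines.append("")
    for sec in doc.sections:
        lines.append(f"[{sec.header_name} = {sec.z_value}]")
        for key, value in sec.keys.items():
            lines.append(f"{key} = {value}")
        lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"
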