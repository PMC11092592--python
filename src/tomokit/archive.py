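"""Minimal-project export and revival with checksummed manifests.

A minimal project keeps the raw frames, (curated) tilt stacks, metadata and
parameter files — everything needed to restore the project to its exact
preprocessing state — while dropping tomograms and per-task intermediates,
which dominate disk usage and can be regenerated from the kept metadata.
Every kept file is listed in a JSON manifest with its size and SHA-256
checksum so that revival can verify bit-exact transfer.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from .tomolist import TomoList, load_tomolist, validate_record

__all__ = ["Manifest", "ArchiveError", "export_minimal", "revive"]

MANIFEST_NAME = "manifest.json"
MANIFEST_SCHEMA = 1

#: project-level directories never included in a minimal export
EXCLUDED_DIRS = ("tomograms",)

KEEP_CLASSES = ("raw_frames", "stack", "metadata", "parameter")


class ArchiveError(RuntimeError):
    pass


@dataclass
class ManifestEntry:
    path: str  # relative to the project root
    size: int
    sha256: str
    file_class: str


@dataclass
class Manifest:
    schema_version: int = MANIFEST_SCHEMA
    entries: list[ManifestEntry] = field(default_factory=list)
    tomolist_checksum: str = ""
    excluded_bytes: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": self.schema_version,
                "tomolist_checksum": self.tomolist_checksum,
                "excluded_bytes": self.excluded_bytes,
                "files": [
                    {
                        "path": e.path,
                        "size": e.size,
                        "sha256": e.sha256,
                        "class": e.file_class,
                    }
                    for e in self.entries
                ],
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        raw = json.loads(text)
        return cls(
            schema_version=raw["schema_version"],
            tomolist_checksum=raw["tomolist_checksum"],
            excluded_bytes=raw["excluded_bytes"],
            entries=[
                ManifestEntry(f["path"], f["size"], f["sha256"], f["class"])
                for f in raw["files"]
            ],
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _classify(rel: Path) -> str | None:
    """File class for a path relative to the project root; None = exclude."""
    parts = rel.parts
    if parts[0] in EXCLUDED_DIRS:
        return None
    name = rel.name
    if name.startswith("tomolist") or name.endswith((".mdoc", ".json")):
        return "metadata"
    if name.endswith((".tlt", ".xf")):
        return "metadata"
    if name.endswith(".param") or name.endswith(".txt"):
        return "parameter"
    if len(parts) >= 2 and parts[1] == "frames":
        return "raw_frames"
    if name.endswith(".mrc"):
        return "stack"
    return None


def export_minimal(
    project_dir: str | Path, out_dir: str | Path, keep_frames: bool = True
) -> Manifest:
    """Copy the minimal keep-set of a project to ``out_dir`` with a manifest.

    Tomogram directories and unclassified intermediates are excluded; their
    total byte count is recorded in the manifest.  ``keep_frames=False``
    records raw frame movies in the manifest by reference (class
    ``raw_frames``, checksum computed in place) without copying them.
    """
    project_dir = Path(project_dir)
    out_dir = Path(out_dir)
    if not (project_dir / "tomolist.h5").exists():
        raise ArchiveError(f"{project_dir} has no tomolist.h5")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()
    for path in sorted(project_dir.rglob("*")):
        if not path.is_file():
            continue
        rel = path.relative_to(project_dir)
        file_class = _classify(rel)
        if file_class is None:
            manifest.excluded_bytes += path.stat().st_size
            continue
        if file_class == "raw_frames" and not keep_frames:
            manifest.entries.append(
                ManifestEntry(str(rel), path.stat().st_size, _sha256(path),
                              "raw_frames")
            )
            continue
        dest = out_dir / rel
        dest.parent.mkdir(parents=True, exist_ok=True)
        shutil.copy2(path, dest)
        manifest.entries.append(
            ManifestEntry(str(rel), dest.stat().st_size, _sha256(dest), file_class)
        )
    manifest.tomolist_checksum = _sha256(out_dir / "tomolist.h5")
    (out_dir / MANIFEST_NAME).write_text(manifest.to_json())
    return manifest


@dataclass
class RevivalReport:
    tomolist: TomoList
    verified_files: int
    reconstructible: list[str]  # stage paths absent but regenerable
    validation: dict[int, list[str]]  # tomo_num -> violated invariants


def revive(minimal_dir: str | Path) -> RevivalReport:
    """Verify a minimal project and load it for continued processing.

    Every manifest checksum is re-verified (hard error on any mismatch);
    the tomolist is loaded and each record validated.  Stage paths that
    point at excluded products (tomograms, per-task intermediates) are
    reported as reconstructible-from-metadata rather than as failures.
    """
    minimal_dir = Path(minimal_dir)
    manifest_path = minimal_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise ArchiveError(f"no {MANIFEST_NAME} in {minimal_dir}")
    manifest = Manifest.from_json(manifest_path.read_text())
    bad: list[str] = []
    for entry in manifest.entries:
        path = minimal_dir / entry.path
        if not path.exists():
            bad.append(f"{entry.path}: missing")
            continue
        if _sha256(path) != entry.sha256:
            bad.append(f"{entry.path}: checksum mismatch")
    if bad:
        raise ArchiveError(
            "minimal project failed verification:\n  " + "\n  ".join(bad)
        )
    tomolist = load_tomolist(minimal_dir / "tomolist.h5")
    reconstructible: list[str] = []
    validation: dict[int, list[str]] = {}
    for record in tomolist:
        problems = []
        for issue in validate_record(record):
            if issue.startswith("stage") and "missing file" in issue:
                stage_path = issue.split("missing file ", 1)[1]
                reconstructible.append(stage_path)
            else:
                problems.append(issue)
        if problems:
            validation[record.tomo_num] = problems
    return RevivalReport(
        tomolist=tomolist,
        verified_files=len(manifest.entries),
        reconstructible=reconstructible,
        validation=validation,
    )
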