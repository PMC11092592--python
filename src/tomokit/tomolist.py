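"""The tomolist: per-tilt-series project metadata and the project layout.

One :class:`TiltSeriesRecord` per tilt-series is the single source of truth
for everything later steps need — acquisition geometry, dose bookkeeping,
curation state, alignment, fitted CTF, and the file paths of each processing
stage.  The collection is persisted as a single hierarchical HDF5 file (one
group per series, scalars as attributes, arrays as datasets) with a
``schema_version`` attribute, plus a human-readable JSON mirror alongside.

Project layout::

    <project>/
        tomolist.h5  (+ tomolist.h5.json mirror)
        ts_001/
            <basename>.mdoc
            frames/           raw frame movies
            ...               per-task stage outputs
        tomograms/            reconstructions, outside the series dirs
"""

from __future__ import annotations

import json
import re
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .alignment import AlignmentFile
from .ctf import CtfResult
from .mdoc import parse_mdoc
from .stack_ops import DoseSchedule

__all__ = [
    "SCHEMA_VERSION",
    "TiltSeriesRecord",
    "TomoList",
    "TomolistError",
    "import_project",
    "save_tomolist",
    "load_tomolist",
    "validate_record",
]

SCHEMA_VERSION = 1


class TomolistError(ValueError):
    pass


@dataclass
class TiltSeriesRecord:
    tomo_num: int
    root_dir: str = ""
    frames_dir: str = ""
    mdoc_path: str = ""
    pixel_size: float = 0.0  # A/px
    voltage: float = 0.0  # kV
    tilt_angles: np.ndarray = field(default_factory=lambda: np.empty(0))  # sorted
    acquisition_order: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )
    per_image_dose: np.ndarray = field(default_factory=lambda: np.empty(0))
    pre_exposure: np.ndarray = field(default_factory=lambda: np.empty(0))
    removed_images: list[int] = field(default_factory=list)
    skip: bool = False
    skip_reason: str = ""
    alignment: AlignmentFile | None = None
    ctf: list[CtfResult] | None = None
    stage_paths: dict[str, str] = field(default_factory=dict)
    task_log: list[dict] = field(default_factory=list)

    def n_tilts(self) -> int:
        return len(self.tilt_angles)

    def exposure_for_filtering(self, convention: str = "post") -> np.ndarray:
        """Cumulative exposure per retained (sorted) image, e-/A^2."""
        sched = DoseSchedule(
            per_image_dose=self.per_image_dose, pre_exposure=self.pre_exposure
        )
        return sched.exposure_for_filtering(convention)

    def log_task(self, task: str, params: dict, timestamp: float | None = None) -> None:
        self.task_log.append(
            {
                "task": task,
                "params": dict(params),
                "timestamp": time.time() if timestamp is None else timestamp,
            }
        )

    def completed(self, task: str, params: dict) -> bool:
        """True if ``task`` already ran with exactly these parameters."""
        for entry in self.task_log:
            if entry["task"] == task and entry["params"] == dict(params):
                return True
        return False

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TiltSeriesRecord):
            return NotImplemented
        scalars = (
            self.tomo_num == other.tomo_num
            and self.root_dir == other.root_dir
            and self.frames_dir == other.frames_dir
            and self.mdoc_path == other.mdoc_path
            and self.pixel_size == other.pixel_size
            and self.voltage == other.voltage
            and self.removed_images == other.removed_images
            and self.skip == other.skip
            and self.skip_reason == other.skip_reason
            and self.stage_paths == other.stage_paths
            and self.task_log == other.task_log
            and self.alignment == other.alignment
            and self.ctf == other.ctf
        )
        return (
            scalars
            and np.array_equal(self.tilt_angles, other.tilt_angles)
            and np.array_equal(self.acquisition_order, other.acquisition_order)
            and np.array_equal(self.per_image_dose, other.per_image_dose)
            and np.array_equal(self.pre_exposure, other.pre_exposure)
        )


@dataclass
class TomoList:
    records: list[TiltSeriesRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums = [r.tomo_num for r in self.records]
        if len(nums) != len(set(nums)):
            raise TomolistError(f"duplicate tomo_num in {nums}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TomoList):
            return NotImplemented
        return self.records == other.records

    def get(self, tomo_num: int) -> TiltSeriesRecord:
        for r in self.records:
            if r.tomo_num == tomo_num:
                return r
        raise KeyError(f"no tilt-series with tomo_num {tomo_num}")

    def tomo_nums(self) -> list[int]:
        return [r.tomo_num for r in self.records]

    def add(self, record: TiltSeriesRecord) -> None:
        if record.tomo_num in self.tomo_nums():
            raise TomolistError(f"tomo_num {record.tomo_num} already present")
        self.records.append(record)


# ---------------------------------------------------------------------------
# import

_TRAILING_INT = re.compile(r"(\d+)(?=\D*$)")


def _tomo_num_from_name(name: str, taken: set[int]) -> int:
    m = _TRAILING_INT.search(Path(name).stem)
    if m:
        num = int(m.group(1))
        if num not in taken:
            return num
    num = 1
    while num in taken:
        num += 1
    return num


def import_project(
    raw_dir: str | Path,
    project_dir: str | Path,
    initial_dose: float = 0.0,
    copy_frames: bool = True,
) -> TomoList:
    """Scan ``raw_dir`` for .mdoc files and build/extend the project.

    One subdirectory ``ts_NNN`` is created per tilt-series.  Re-running
    appends only new series (matched by tomo_num parsed from the mdoc
    basename) and never touches existing records.
    """
    raw_dir = Path(raw_dir)
    project_dir = Path(project_dir)
    mdocs = sorted(raw_dir.glob("*.mdoc"))
    if not mdocs:
        raise TomolistError(f"no .mdoc files found in {raw_dir}")
    project_dir.mkdir(parents=True, exist_ok=True)
    tomolist_path = project_dir / "tomolist.h5"
    if tomolist_path.exists():
        tomolist = load_tomolist(tomolist_path)
    else:
        tomolist = TomoList()
    imported_mdocs = {Path(r.mdoc_path).name for r in tomolist}
    taken = set(tomolist.tomo_nums())
    for mdoc_file in mdocs:
        if mdoc_file.name in imported_mdocs:
            continue
        tomo_num = _tomo_num_from_name(mdoc_file.name, taken)
        taken.add(tomo_num)
        doc = parse_mdoc(mdoc_file.read_text(), require_tilt_angle=False)
        ts_dir = project_dir / f"ts_{tomo_num:03d}"
        ts_dir.mkdir(exist_ok=True)
        frames_dir = ts_dir / "frames"
        frames_dir.mkdir(exist_ok=True)
        dest_mdoc = ts_dir / mdoc_file.name
        shutil.copy2(mdoc_file, dest_mdoc)
        record = TiltSeriesRecord(
            tomo_num=tomo_num,
            root_dir=str(ts_dir),
            frames_dir=str(frames_dir),
            mdoc_path=str(dest_mdoc),
        )
        if not doc.sections:
            record.skip = True
            record.skip_reason = "mdoc has no image sections"
            tomolist.add(record)
            continue
        missing = [s.z_value for s in doc.sections if "TiltAngle" not in s.keys]
        if missing:
            raise TomolistError(
                f"{mdoc_file.name}: sections {missing} lack TiltAngle"
            )
        record.pixel_size = doc.pixel_spacing or 0.0
        record.voltage = doc.voltage or 0.0
        angles = np.array([s.tilt_angle for s in doc.sections])
        doses = np.array([s.exposure_dose for s in doc.sections])
        schedule = DoseSchedule.from_doses(doses, initial_dose=initial_dose)
        order = np.argsort(angles, kind="stable")
        record.tilt_angles = angles[order]
        record.acquisition_order = order.copy()
        record.per_image_dose = doses[order]
        record.pre_exposure = schedule.pre_exposure[order]
        if copy_frames:
            for sec in doc.sections:
                base = sec.sub_frame_basename
                if base is None:
                    continue
                src = raw_dir / base
                if src.exists() and not (frames_dir / base).exists():
                    shutil.copy2(src, frames_dir / base)
        record.log_task("import", {"raw_dir": str(raw_dir)})
        tomolist.add(record)
    save_tomolist(tomolist, tomolist_path)
    return tomolist


# ---------------------------------------------------------------------------
# persistence

def _write_record(group: h5py.Group, r: TiltSeriesRecord) -> None:
    group.attrs["tomo_num"] = r.tomo_num
    group.attrs["root_dir"] = r.root_dir
    group.attrs["frames_dir"] = r.frames_dir
    group.attrs["mdoc_path"] = r.mdoc_path
    group.attrs["pixel_size"] = r.pixel_size
    group.attrs["voltage"] = r.voltage
    group.attrs["skip"] = r.skip
    group.attrs["skip_reason"] = r.skip_reason
    group.create_dataset("tilt_angles", data=np.asarray(r.tilt_angles, float))
    group.create_dataset(
        "acquisition_order", data=np.asarray(r.acquisition_order, np.int64)
    )
    group.create_dataset("per_image_dose", data=np.asarray(r.per_image_dose, float))
    group.create_dataset("pre_exposure", data=np.asarray(r.pre_exposure, float))
    group.create_dataset(
        "removed_images", data=np.asarray(r.removed_images, np.int64)
    )
    if r.alignment is not None:
        ag = group.create_group("alignment")
        ag.create_dataset("tilt_angles", data=r.alignment.tilt_angles)
        ag.create_dataset("transforms", data=r.alignment.transforms)
        ag.create_dataset("shifts", data=r.alignment.shifts)
    if r.ctf is not None:
        cg = group.create_group("ctf")
        cg.create_dataset("defocus", data=np.array([c.defocus for c in r.ctf]))
        cg.create_dataset("score", data=np.array([c.score for c in r.ctf]))
        cg.create_dataset(
            "fit_range", data=np.array([c.fit_range for c in r.ctf])
        )
        cg.create_dataset(
            "flagged", data=np.array([c.flagged for c in r.ctf], dtype=bool)
        )
    group.attrs["stage_paths"] = json.dumps(r.stage_paths)
    group.attrs["task_log"] = json.dumps(r.task_log)


def _read_record(group: h5py.Group) -> TiltSeriesRecord:
    r = TiltSeriesRecord(
        tomo_num=int(group.attrs["tomo_num"]),
        root_dir=str(group.attrs["root_dir"]),
        frames_dir=str(group.attrs["frames_dir"]),
        mdoc_path=str(group.attrs["mdoc_path"]),
        pixel_size=float(group.attrs["pixel_size"]),
        voltage=float(group.attrs["voltage"]),
        skip=bool(group.attrs["skip"]),
        skip_reason=str(group.attrs["skip_reason"]),
        tilt_angles=group["tilt_angles"][()],
        acquisition_order=group["acquisition_order"][()].astype(int),
        per_image_dose=group["per_image_dose"][()],
        pre_exposure=group["pre_exposure"][()],
        removed_images=[int(i) for i in group["removed_images"][()]],
        stage_paths=json.loads(group.attrs["stage_paths"]),
        task_log=json.loads(group.attrs["task_log"]),
    )
    if "alignment" in group:
        ag = group["alignment"]
        r.alignment = AlignmentFile(
            ag["tilt_angles"][()], ag["transforms"][()], ag["shifts"][()]
        )
    if "ctf" in group:
        cg = group["ctf"]
        r.ctf = [
            CtfResult(
                defocus=float(d),
                score=float(s),
                fit_range=(float(fr[0]), float(fr[1])),
                flagged=bool(fl),
            )
            for d, s, fr, fl in zip(
                cg["defocus"][()], cg["score"][()], cg["fit_range"][()],
                cg["flagged"][()],
            )
        ]
    return r


def save_tomolist(tomolist: TomoList, path: str | Path) -> None:
    """Write the HDF5 container plus a JSON mirror at ``<path>.json``."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["n_records"] = len(tomolist)
        for r in tomolist:
            _write_record(fh.create_group(f"series_{r.tomo_num:05d}"), r)
    mirror = {
        "schema_version": SCHEMA_VERSION,
        "records": [_record_to_json(r) for r in tomolist],
    }
    Path(str(path) + ".json").write_text(json.dumps(mirror, indent=1, sort_keys=True))


def _record_to_json(r: TiltSeriesRecord) -> dict:
    out = {
        "tomo_num": r.tomo_num,
        "root_dir": r.root_dir,
        "frames_dir": r.frames_dir,
        "mdoc_path": r.mdoc_path,
        "pixel_size": r.pixel_size,
        "voltage": r.voltage,
        "tilt_angles": list(map(float, r.tilt_angles)),
        "acquisition_order": list(map(int, r.acquisition_order)),
        "per_image_dose": list(map(float, r.per_image_dose)),
        "pre_exposure": list(map(float, r.pre_exposure)),
        "removed_images": r.removed_images,
        "skip": r.skip,
        "skip_reason": r.skip_reason,
        "stage_paths": r.stage_paths,
        "task_log": r.task_log,
    }
    if r.alignment is not None:
        out["alignment"] = {
            "tilt_angles": r.alignment.tilt_angles.tolist(),
            "transforms": r.alignment.transforms.tolist(),
            "shifts": r.alignment.shifts.tolist(),
        }
    if r.ctf is not None:
        out["ctf"] = [
            {"defocus": c.defocus, "score": c.score,
             "fit_range": list(c.fit_range), "flagged": c.flagged}
            for c in r.ctf
        ]
    return out


def load_tomolist(path: str | Path) -> TomoList:
    path = Path(path)
    if not path.exists():
        raise TomolistError(f"tomolist not found: {path}")
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise TomolistError(f"cannot open tomolist {path}: {exc}") from None
    with fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise TomolistError(
                f"tomolist schema version {version} != supported "
                f"{SCHEMA_VERSION}; explicit migration required"
            )
        records = [
            _read_record(fh[name]) for name in sorted(fh.keys())
        ]
    return TomoList(records=records)


# ---------------------------------------------------------------------------
# validation

def validate_record(r: TiltSeriesRecord) -> list[str]:
    """Return the list of violated invariants (empty = valid); never mutates."""
    problems: list[str] = []
    n = r.n_tilts()
    if n and np.any(np.diff(r.tilt_angles) < 0):
        problems.append("tilt_angles not sorted ascending")
    if len(r.acquisition_order) != n or (
        n and sorted(r.acquisition_order.tolist()) != list(range(n))
    ):
        problems.append("acquisition_order is not a permutation of 0..n-1")
    if np.any(np.asarray(r.pre_exposure) < 0):
        problems.append("negative pre_exposure")
    if n and len(r.acquisition_order) == n and sorted(
        r.acquisition_order.tolist()
    ) == list(range(n)):
        in_acq = np.asarray(r.pre_exposure)[np.argsort(r.acquisition_order)]
        if np.any(np.diff(in_acq) < 0):
            problems.append("pre_exposure decreasing in acquisition order")
    if any(i < 0 for i in r.removed_images):
        problems.append("negative removed_images index")
    timestamps = [e["timestamp"] for e in r.task_log]
    if any(b < a for a, b in zip(timestamps, timestamps[1:])):
        problems.append("task_log timestamps decreasing")
    for stage, path in r.stage_paths.items():
        if path and not Path(path).exists():
            problems.append(f"stage {stage!r}: missing file {path}")
    return problems
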