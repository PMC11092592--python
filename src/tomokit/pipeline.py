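"""Task registry and the sequential pipeline runner with per-series resume.

A pipeline is an ordered list of (task, parameters).  Tasks run per
tilt-series in a fixed dependency order::

    import < assemble < clean < {dose_filter, ctf} < recon < export < archive

Each completed task appends one entry (task name, full parameter snapshot,
timestamp) to the series' task log; a series that already completed a task
with identical parameters is skipped on re-runs, so an interrupted pipeline
resumes exactly where it stopped.  A failure in one series is isolated: the
remaining series still run, and the failures are summarized in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import exporters, recon, stack_ops
from .alignment import AlignmentFile
from .archive import export_minimal
from .ctf import (
    CtfParams,
    TiltGeometry,
    fit_defocus,
    phase_flip_correct,
    tilt_compensated_ps,
)
from .exposure import ExposureFilterSpec, apply_tilt_filter
from .mdoc import parse_mdoc
from .mrc import read_mrc, write_mrc
from .params import ParamFile
from .tomolist import TiltSeriesRecord, TomoList, import_project, load_tomolist, save_tomolist

__all__ = [
    "TASK_ORDER",
    "TASK_KEYS",
    "Pipeline",
    "PipelineReport",
    "PipelineError",
    "run_pipeline",
]

TASK_ORDER = [
    "import", "assemble", "clean", "dose_filter", "ctf", "recon", "export",
    "archive",
]
# rank used to validate ordering; dose_filter and ctf share a rank (either order)
_TASK_RANK = {
    "import": 0, "assemble": 1, "clean": 2, "dose_filter": 3, "ctf": 3,
    "recon": 4, "export": 5, "archive": 6,
}

TASK_KEYS: dict[str, set[str]] = {
    "import": {"raw_dir", "initial_dose"},
    "assemble": {"odd_even", "align_frames"},
    "clean": {"bad_indices", "series", "skip_series", "bad_*"},
    "dose_filter": {"a", "b", "c", "dose_convention"},
    "ctf": {"defocus_min", "defocus_max", "defocus_step", "tile", "overlap",
            "tilt_axis_angle", "handedness", "cs", "amplitude_contrast"},
    "recon": {"thickness", "method", "n_iter", "relaxation", "binning",
              "ctf_correct", "strip_width", "cs", "amplitude_contrast"},
    "export": {"targets", "out_dir"},
    "archive": {"out_dir", "keep_frames"},
}


class PipelineError(RuntimeError):
    pass


@dataclass
class Pipeline:
    steps: list[ParamFile]

    def __post_init__(self) -> None:
        ranks = []
        for step in self.steps:
            if step.task not in _TASK_RANK:
                raise PipelineError(f"unknown task {step.task!r}")
            ranks.append(_TASK_RANK[step.task])
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise PipelineError(
                f"tasks out of dependency order: {[s.task for s in self.steps]}"
            )


@dataclass
class PipelineReport:
    executed: list[tuple[int, str]] = field(default_factory=list)
    skipped: list[tuple[int, str]] = field(default_factory=list)
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


# ---------------------------------------------------------------------------
# task implementations (each operates on one record, mutating it)

def _movie_paths(record: TiltSeriesRecord):
    doc = parse_mdoc(Path(record.mdoc_path).read_text())
    frames_dir = Path(record.frames_dir)
    return doc, [
        frames_dir / sec.sub_frame_basename for sec in doc.sections
    ]


def _task_assemble(record: TiltSeriesRecord, params: dict, seed: int) -> None:
    doc, movie_paths = _movie_paths(record)
    sums, odd_sums, even_sums = [], [], []
    pixel_size = record.pixel_size
    do_odd_even = bool(params.get("odd_even", True))
    do_align = bool(params.get("align_frames", False))
    for path in movie_paths:
        movie, pix = read_mrc(path)
        if movie.ndim == 2:
            movie = movie[None]
        pixel_size = pixel_size or pix
        if do_align and len(movie) >= 2:
            movie, _ = stack_ops.align_frames(movie)
        sums.append(stack_ops.sum_frames(movie, "all"))
        if do_odd_even and len(movie) >= 2:
            odd_sums.append(stack_ops.sum_frames(movie, "odd"))
            even_sums.append(stack_ops.sum_frames(movie, "even"))
    series = stack_ops.assemble_tilt_series(np.stack(sums), doc)
    record.tilt_angles = series.tilt_angles
    record.acquisition_order = series.acquisition_order
    record.per_image_dose = series.per_image_dose
    record.pre_exposure = series.pre_exposure
    ts_dir = Path(record.root_dir)
    name = f"ts_{record.tomo_num:03d}"
    stack_path = ts_dir / f"{name}.mrc"
    write_mrc(stack_path, series.stack, pixel_size=pixel_size)
    record.stage_paths["motion_corrected"] = str(stack_path)
    if record.alignment is None:
        # identity alignment until an external aligner supplies a real one
        record.alignment = AlignmentFile.identity(series.tilt_angles)
    if odd_sums and even_sums:
        order = np.argsort([s.tilt_angle for s in doc.sections], kind="stable")
        for tag, sums_ in (("odd", odd_sums), ("even", even_sums)):
            path = ts_dir / f"{name}_{tag}.mrc"
            write_mrc(path, np.stack(sums_)[order], pixel_size=pixel_size)
            record.stage_paths[f"{tag}_stack"] = str(path)


def _task_clean(record: TiltSeriesRecord, params: dict, seed: int) -> None:
    skip_series = params.get("skip_series", [])
    if isinstance(skip_series, int):
        skip_series = [skip_series]
    if record.tomo_num in skip_series:
        record.skip = True
        record.skip_reason = "marked bad during curation"
        return
    if f"bad_{record.tomo_num}" in params:  # per-series key form
        bad_here = params[f"bad_{record.tomo_num}"]
    else:
        bad = params.get("bad_indices", {})
        if isinstance(bad, dict):
            bad_here = bad.get(record.tomo_num, [])
        else:
            bad_here = bad if params.get("series") in (None, record.tomo_num) else []
    if isinstance(bad_here, int):
        bad_here = [bad_here]
    if not bad_here:
        return
    stack, pix = read_mrc(record.stage_paths["motion_corrected"])
    series = stack_ops.AssembledSeries(
        stack=stack if stack.ndim == 3 else stack[None],
        tilt_angles=record.tilt_angles,
        acquisition_order=record.acquisition_order,
        per_image_dose=record.per_image_dose,
        pre_exposure=record.pre_exposure,
    )
    curated = stack_ops.clean_stack(series.stack, series, bad_here)
    record.tilt_angles = curated.tilt_angles
    record.acquisition_order = curated.acquisition_order
    record.per_image_dose = curated.per_image_dose
    record.pre_exposure = curated.pre_exposure
    record.removed_images = sorted(set(record.removed_images) | set(bad_here))
    if record.alignment is not None:
        keep = [i for i in range(len(series.tilt_angles)) if i not in set(bad_here)]
        record.alignment = record.alignment.select(keep)
    path = Path(record.root_dir) / f"ts_{record.tomo_num:03d}_curated.mrc"
    write_mrc(path, curated.stack, pixel_size=pix)
    record.stage_paths["curated_stack"] = str(path)


def _input_stack(
    record: TiltSeriesRecord,
    stages: tuple[str, ...] = ("curated_stack", "motion_corrected"),
) -> tuple[np.ndarray, float]:
    for stage in stages:
        if stage in record.stage_paths:
            stack, pix = read_mrc(record.stage_paths[stage])
            return (stack if stack.ndim == 3 else stack[None]), (
                pix or record.pixel_size
            )
    raise PipelineError(f"series {record.tomo_num}: no assembled stack found")


def _task_dose_filter(record: TiltSeriesRecord, params: dict, seed: int) -> None:
    stack, pix = _input_stack(record)
    spec = ExposureFilterSpec(
        pixel_size=pix,
        a=params.get("a", ExposureFilterSpec.__dataclass_fields__["a"].default),
        b=params.get("b", ExposureFilterSpec.__dataclass_fields__["b"].default),
        c=params.get("c", ExposureFilterSpec.__dataclass_fields__["c"].default),
    )
    exposures = record.exposure_for_filtering(params.get("dose_convention", "post"))
    filtered = np.stack(
        [
            apply_tilt_filter(img, float(n), spec)
            for img, n in zip(stack, exposures)
        ]
    )
    out_dir = Path(record.root_dir) / "dose_filt"
    out_dir.mkdir(exist_ok=True)
    path = out_dir / f"ts_{record.tomo_num:03d}_dose_filt.mrc"
    write_mrc(path, filtered, pixel_size=pix)
    record.stage_paths["dose_filtered"] = str(path)


def _task_ctf(record: TiltSeriesRecord, params: dict, seed: int) -> None:
    stack, pix = _input_stack(record)
    base = CtfParams(
        voltage=record.voltage or 300.0,
        cs=params.get("cs", 2.7),
        amplitude_contrast=params.get("amplitude_contrast", 0.07),
        pixel_size=pix,
    )
    tile = int(params.get("tile", min(256, stack.shape[-1])))
    search = (
        float(params.get("defocus_min", 5000.0)),
        float(params.get("defocus_max", 60000.0)),
    )
    step = float(params.get("defocus_step", 200.0))
    defocus_ref = 0.5 * (search[0] + search[1])
    results = []
    for img, angle in zip(stack, record.tilt_angles):
        geom = TiltGeometry(
            tilt_angle=float(angle),
            tilt_axis_angle=float(params.get("tilt_axis_angle", 0.0)),
            handedness=int(params.get("handedness", 1)),
        )
        ps = tilt_compensated_ps(
            img, geom, base, tile=tile,
            overlap=float(params.get("overlap", 0.5)),
            defocus_ref=defocus_ref,
        )
        results.append(fit_defocus(ps, base, search_range=search, search_step=step))
    record.ctf = results


def _task_recon(record: TiltSeriesRecord, params: dict, seed: int,
                project_dir: Path | None = None) -> None:
    # reconstruct from the exposure-filtered stack when one exists: the
    # filter is the matched weighting for dose-decayed signal
    stack, pix = _input_stack(
        record, ("dose_filtered", "curated_stack", "motion_corrected")
    )
    if params.get("ctf_correct", False):
        if record.ctf is None:
            raise PipelineError(
                f"series {record.tomo_num}: ctf_correct needs fitted CTF results"
            )
        base = CtfParams(
            voltage=record.voltage or 300.0,
            cs=params.get("cs", 2.7),
            amplitude_contrast=params.get("amplitude_contrast", 0.07),
            pixel_size=pix,
        )
        strip = int(params.get("strip_width", max(16, stack.shape[-1] // 8)))
        stack = np.stack(
            [
                phase_flip_correct(
                    img,
                    TiltGeometry(tilt_angle=float(angle)),
                    replace(base, defocus=res.defocus),
                    strip_width=strip,
                )
                for img, angle, res in zip(stack, record.tilt_angles, record.ctf)
            ]
        )
    thickness = int(params.get("thickness", stack.shape[-1] // 2))
    spec = recon.ReconSpec(
        tilt_angles=record.tilt_angles,
        thickness=thickness,
        width=stack.shape[-1],
        height=stack.shape[-2],
        alignment=None,
    )
    method = params.get("method", "wbp")
    if method == "wbp":
        volume = recon.wbp_reconstruct(stack, spec)
    elif method == "sirt":
        volume, _ = recon.sirt_reconstruct(
            stack, spec, n_iter=int(params.get("n_iter", 15)),
            relaxation=float(params.get("relaxation", 1.0)),
        )
    else:
        raise PipelineError(f"unknown reconstruction method {method!r}")
    binning = int(params.get("binning", 1))
    if binning > 1:
        volume = recon.fourier_crop(volume, binning)
    tomo_dir = (
        project_dir / "tomograms" if project_dir is not None
        else Path(record.root_dir).parent / "tomograms"
    )
    tomo_dir.mkdir(exist_ok=True)
    path = tomo_dir / f"ts_{record.tomo_num:03d}_{method}.mrc"
    write_mrc(path, volume, pixel_size=pix * binning)
    record.stage_paths[f"tomogram_{method}"] = str(path)


# ---------------------------------------------------------------------------
# runner

def run_pipeline(
    pipeline: Pipeline,
    project_dir: str | Path,
    series: list[int] | None = None,
    seed: int = 0,
) -> tuple[TomoList, PipelineReport]:
    """Execute a pipeline over a project, with resume semantics.

    Returns the updated (and saved) tomolist plus a report of executed,
    skipped and failed (series, task) pairs.
    """
    project_dir = Path(project_dir)
    report = PipelineReport()
    tomolist: TomoList | None = None
    for step in pipeline.steps:
        snapshot = dict(step.params)
        snapshot["seed"] = seed
        if step.task == "import":
            tomolist = import_project(
                Path(step.params["raw_dir"]), project_dir,
                initial_dose=float(step.params.get("initial_dose", 0.0)),
            )
            report.executed.append((-1, "import"))
            continue
        if tomolist is None:
            tomolist = load_tomolist(project_dir / "tomolist.h5")
        if step.task == "export":
            _run_export(tomolist, step.params, project_dir)
            report.executed.append((-1, "export"))
            continue
        if step.task == "archive":
            out = Path(step.params.get("out_dir", project_dir.parent / "minimal"))
            export_minimal(project_dir, out,
                           keep_frames=bool(step.params.get("keep_frames", True)))
            report.executed.append((-1, "archive"))
            continue
        for record in tomolist:
            if series is not None and record.tomo_num not in series:
                continue
            if record.skip and step.task != "clean":
                continue
            if record.tomo_num in report.failures:
                continue  # a failed series gets no further tasks
            if record.completed(step.task, snapshot):
                report.skipped.append((record.tomo_num, step.task))
                continue
            try:
                _TASK_FUNCS[step.task](record, step.params, seed)
            except Exception as exc:  # noqa: BLE001 - isolate per series
                report.failures[record.tomo_num] = f"{step.task}: {exc}"
                continue
            record.log_task(step.task, snapshot)
            report.executed.append((record.tomo_num, step.task))
        save_tomolist(tomolist, project_dir / "tomolist.h5")
    if tomolist is not None:
        save_tomolist(tomolist, project_dir / "tomolist.h5")
    else:
        tomolist = load_tomolist(project_dir / "tomolist.h5")
    return tomolist, report


def _run_export(tomolist: TomoList, params: dict, project_dir: Path) -> None:
    targets = params.get("targets", ["wedgelist", "relion4", "warp"])
    if isinstance(targets, str):
        targets = [targets]
    out_dir = Path(params.get("out_dir", project_dir / "export"))
    out_dir.mkdir(parents=True, exist_ok=True)
    if "wedgelist" in targets:
        (out_dir / "wedgelist.star").write_text(
            exporters.export_wedgelist(tomolist)
        )
    if "relion4" in targets:
        star, orders = exporters.export_relion4(tomolist)
        (out_dir / "tomograms.star").write_text(star)
        for tomo_num, text in orders.items():
            (out_dir / f"order_ts_{tomo_num:03d}.csv").write_text(text)
    if "warp" in targets:
        exporters.export_warp_dir(tomolist, out_dir / "warp")


_TASK_FUNCS = {
    "assemble": _task_assemble,
    "clean": _task_clean,
    "dose_filter": _task_dose_filter,
    "ctf": _task_ctf,
    "recon": _task_recon,
}
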