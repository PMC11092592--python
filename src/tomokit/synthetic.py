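"""Synthetic cryo-ET raw data with known ground truth.

Generates phantom volumes, tilted projections with an (optional) per-strip
CTF including the tilted-specimen defocus gradient, exposure-dependent
signal decay following the critical-exposure model, dose-scaled Gaussian
noise, frame movies with programmed shifts, and matching SerialEM-style
.mdoc files in either sequential or dose-symmetric acquisition order.  The
output directory is directly consumable by :func:`tomokit.import_project`;
a ground-truth manifest (JSON) records everything the generator knew.

The noise model is additive Gaussian with variance proportional to dose —
not Poisson counting noise, and there is no detector MTF/DQE — so these
fixtures exercise the bookkeeping and the signal-processing chain, not
physical image formation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from . import recon
from .ctf import CtfParams, TiltGeometry, ctf_modulate, ctf_value
from .exposure import ExposureFilterSpec, apply_tilt_filter
from .mdoc import MdocDocument, MdocSection, write_mdoc
from .mrc import write_mrc
from .stack_ops import DoseSchedule

__all__ = [
    "SimSpec",
    "acquisition_angles",
    "make_phantom",
    "simulate_tilt_series",
    "simulate_ctf_micrograph",
]


@dataclass
class SimSpec:
    """Study conditions of one simulated tilt-series acquisition."""

    image_size: int = 128  # px (square images)
    thickness: int = 64  # voxels
    phantom: str = "spheres"  # spheres | grid | points
    n_objects: int = 6
    tilt_min: float = -60.0  # degrees
    tilt_max: float = 60.0
    tilt_step: float = 3.0
    scheme: str = "dose_symmetric"  # or "sequential"
    dose_per_tilt: float = 3.0  # e-/A^2
    pixel_size: float = 4.0  # A/px (binned tilt images)
    voltage: float = 300.0  # kV
    cs: float = 2.7  # mm
    amplitude_contrast: float = 0.07
    defocus: float = 30000.0  # A at the tilt axis
    tilt_axis_angle: float = 0.0  # degrees (0 = axis along y)
    handedness: int = 1
    apply_ctf: bool = True
    apply_dose_decay: bool = True
    #: pre-CTF "solvent" noise: broadband structure that, like the specimen,
    #: is modulated by the CTF — this is what makes Thon rings fittable on
    #: the simulated tilt images
    structural_noise_sigma: float = 1.0
    noise_sigma_per_sqrt_dose: float = 0.05  # Gaussian sigma per sqrt(e-/A^2)
    frames_per_tilt: int = 4
    frame_shift_px: float = 0.0  # programmed inter-frame drift amplitude
    seed: int = 0

    def ctf_params(self) -> CtfParams:
        return CtfParams(
            voltage=self.voltage,
            cs=self.cs,
            amplitude_contrast=self.amplitude_contrast,
            pixel_size=self.pixel_size,
            defocus=self.defocus,
        )


def acquisition_angles(
    tilt_min: float, tilt_max: float, step: float, scheme: str
) -> np.ndarray:
    """Tilt angles in acquisition order for the given scheme.

    ``sequential`` sweeps from tilt_min to tilt_max; ``dose_symmetric``
    alternates around zero: 0, +s, -s, +2s, -2s, ...
    """
    n_neg = int(round(-tilt_min / step))
    n_pos = int(round(tilt_max / step))
    if scheme == "sequential":
        return np.arange(-n_neg, n_pos + 1) * step
    if scheme == "dose_symmetric":
        angles = [0.0]
        for k in range(1, max(n_neg, n_pos) + 1):
            if k <= n_pos:
                angles.append(k * step)
            if k <= n_neg:
                angles.append(-k * step)
        return np.array(angles)
    raise ValueError(f"unknown acquisition scheme {scheme!r}")


def make_phantom(spec: SimSpec) -> tuple[np.ndarray, list[dict]]:
    """Deterministic phantom volume plus the list of object descriptors."""
    rng = np.random.default_rng(spec.seed)
    nz, n = spec.thickness, spec.image_size
    volume = np.zeros((nz, n, n))
    objects: list[dict] = []
    if spec.phantom == "spheres":
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(n), np.arange(n), indexing="ij"
        )
        for _ in range(spec.n_objects):
            r = float(rng.uniform(0.04, 0.10) * n)
            cz = float(rng.uniform(0.25, 0.75) * nz)
            cy = float(rng.uniform(0.2, 0.8) * n)
            cx = float(rng.uniform(0.2, 0.8) * n)
            volume += (
                (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            ).astype(float)
            objects.append({"center_zyx": [cz, cy, cx], "radius": r})
    elif spec.phantom == "grid":
        step = max(4, n // max(spec.n_objects, 1))
        for z in range(nz // 4, 3 * nz // 4, max(4, nz // 4)):
            for y in range(step // 2, n, step):
                for x in range(step // 2, n, step):
                    volume[z, y, x] = 1.0
                    objects.append({"center_zyx": [z, y, x], "radius": 0.0})
    elif spec.phantom == "points":
        for _ in range(spec.n_objects):
            z = int(rng.integers(nz // 4, 3 * nz // 4))
            y = int(rng.integers(n // 4, 3 * n // 4))
            x = int(rng.integers(n // 4, 3 * n // 4))
            volume[z, y, x] = 1.0
            objects.append({"center_zyx": [z, y, x], "radius": 0.0})
    else:
        raise ValueError(f"unknown phantom type {spec.phantom!r}")
    return volume, objects


def _project_series(volume: np.ndarray, spec: SimSpec, angles_acq: np.ndarray):
    rspec = recon.ReconSpec(
        tilt_angles=angles_acq,
        thickness=spec.thickness,
        width=spec.image_size,
        height=spec.image_size,
    )
    return recon.project_forward(volume, rspec)


def simulate_tilt_series(
    volume: np.ndarray,
    spec: SimSpec,
    out_dir: str | Path,
    name: str | None = None,
    tomo_num: int = 1,
) -> dict:
    """Write one simulated raw tilt-series (frame movies + .mdoc).

    Per image, in acquisition order: project the phantom, modulate by the
    tilted CTF (strip-wise defocus gradient), attenuate by the exposure
    filter at the image's cumulative dose (so dose filtering statistically
    undoes it), split into frames with programmed shifts, and add Gaussian
    noise of variance proportional to the per-frame dose.  Returns the
    ground-truth manifest (also written as ``<name>_truth.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if name is None:
        name = f"TS_{tomo_num:03d}"
    rng = np.random.default_rng(spec.seed)
    angles = acquisition_angles(spec.tilt_min, spec.tilt_max, spec.tilt_step,
                                spec.scheme)
    projections = _project_series(volume, spec, angles)
    doses = np.full(len(angles), spec.dose_per_tilt)
    schedule = DoseSchedule.from_doses(doses)
    cumulative = schedule.exposure_for_filtering("post")
    filt_spec = ExposureFilterSpec(pixel_size=spec.pixel_size)
    params = spec.ctf_params()
    n_frames = max(1, spec.frames_per_tilt)
    strip_width = max(16, spec.image_size // 8)
    doc = MdocDocument(
        global_header={
            "PixelSpacing": f"{spec.pixel_size:.4f}",
            "Voltage": f"{spec.voltage:.0f}",
            "ImageSize": f"{spec.image_size} {spec.image_size}",
        },
        titles=[f"simulated dataset  seed={spec.seed}"],
    )
    t0 = datetime(2024, 1, 1, 12, 0, 0)
    truth_images = []
    defoci = []
    all_shifts = []
    for rank, (angle, image) in enumerate(zip(angles, projections)):
        geom = TiltGeometry(
            tilt_angle=float(angle),
            tilt_axis_angle=spec.tilt_axis_angle,
            handedness=spec.handedness,
        )
        signal = image.astype(float)
        if spec.apply_dose_decay:
            # radiation damage attenuates the specimen's coherent signal ...
            signal = apply_tilt_filter(signal, float(cumulative[rank]), filt_spec)
        if spec.structural_noise_sigma > 0:
            # ... while broadband solvent scattering persists, which is why
            # Thon rings remain fittable even on late, heavily exposed tilts
            signal = signal + rng.normal(
                0.0, spec.structural_noise_sigma, size=signal.shape
            )
        if spec.apply_ctf:
            signal = ctf_modulate(signal, geom, params, strip_width=strip_width)
        frame_dose = spec.dose_per_tilt / n_frames
        sigma = spec.noise_sigma_per_sqrt_dose * np.sqrt(max(frame_dose, 1e-12))
        shifts = (
            rng.uniform(-spec.frame_shift_px, spec.frame_shift_px, size=(n_frames, 2))
            if spec.frame_shift_px > 0
            else np.zeros((n_frames, 2))
        )
        frames = []
        for j in range(n_frames):
            frame = signal / n_frames
            if spec.frame_shift_px > 0:
                frame = _shift_image(frame, shifts[j])
            frame = frame + rng.normal(0.0, sigma, size=frame.shape)
            frames.append(frame)
        movie_name = f"{name}_{rank:03d}.mrc"
        write_mrc(out_dir / movie_name, np.stack(frames),
                  pixel_size=spec.pixel_size)
        sec = MdocSection(z_value=rank)
        sec.keys["TiltAngle"] = f"{angle:.4f}"
        sec.keys["ExposureDose"] = f"{spec.dose_per_tilt:.4f}"
        sec.keys["PriorRecordDose"] = f"{schedule.pre_exposure[rank]:.4f}"
        sec.keys["SubFramePath"] = f"X:\\raw\\{movie_name}"
        sec.keys["NumSubFrames"] = str(n_frames)
        sec.keys["DateTime"] = (t0 + timedelta(minutes=rank)).strftime(
            "%d-%b-%Y %H:%M:%S"
        )
        doc.sections.append(sec)
        defoci.append(spec.defocus)
        all_shifts.append(shifts.tolist())
        truth_images.append(
            {
                "rank": rank,
                "tilt_angle": float(angle),
                "pre_exposure": float(schedule.pre_exposure[rank]),
                "cumulative_exposure": float(cumulative[rank]),
                "defocus_at_axis": spec.defocus,
                "frame_shifts": shifts.tolist(),
            }
        )
    (out_dir / f"{name}.mrc.mdoc").write_text(write_mdoc(doc))
    manifest = {
        "name": name,
        "tomo_num": tomo_num,
        "spec": asdict(spec),
        "angles_acquisition_order": angles.tolist(),
        "images": truth_images,
    }
    (out_dir / f"{name}_truth.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _shift_image(image: np.ndarray, shift) -> np.ndarray:
    ny, nx = image.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.rfftfreq(nx)[None, :]
    phase = np.exp(-2j * np.pi * (fy * shift[0] + fx * shift[1]))
    return np.fft.irfft2(np.fft.rfft2(image) * phase, s=image.shape)


def simulate_ctf_micrograph(
    shape: tuple[int, int],
    params: CtfParams,
    geom: TiltGeometry | None = None,
    seed: int = 0,
    strip_width: int = 32,
    noise_floor: float = 0.1,
) -> np.ndarray:
    """White noise shaped by the (optionally tilted) CTF plus a flat floor.

    The power spectrum of the output is proportional to ``CTF^2`` (locally,
    per strip when tilted), which is what Thon-ring fitting consumes.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(size=shape)
    if geom is None or geom.tilt_angle == 0.0:
        fy = np.fft.fftfreq(shape[0], d=params.pixel_size)[:, None]
        fx = np.fft.rfftfreq(shape[1], d=params.pixel_size)[None, :]
        g = np.hypot(fy, fx)
        signal = np.fft.irfft2(np.fft.rfft2(base) * ctf_value(g, params), s=shape)
    else:
        signal = ctf_modulate(base, geom, params, strip_width=strip_width)
    return signal + noise_floor * rng.normal(size=shape)
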