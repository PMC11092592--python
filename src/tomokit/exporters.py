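"""Export tomolist state to STA ecosystems and convert particle metadata.

Supported targets:

* STOPGAP-style wedge lists (STAR loop, one row per retained tilt);
* RELION-4-style tomogram star + per-tomogram acquisition-order lists;
* Warp-style directories: per-tilt images, a rewritten .mdoc restricted to
  retained sections, and IMOD alignment files;
* STOPGAP "motl" particle tables <-> RELION particle star rows.

Orientation conventions: STOPGAP uses intrinsic zxz Euler triples, RELION
intrinsic zyz; conversion goes through the rotation matrix so the physical
orientation is untouched.  Coordinate origins: STOPGAP positions are 1-based
voxel centers, RELION coordinates 0-based — the difference is the single
offset constant ``STOPGAP_ORIGIN_OFFSET``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import stario
from .alignment import write_alignment
from .mdoc import MdocDocument, MdocSection, parse_mdoc, write_mdoc
from .mrc import read_mrc, write_mrc
from .tomolist import TomoList, TiltSeriesRecord

__all__ = [
    "STOPGAP_ORIGIN_OFFSET",
    "export_wedgelist",
    "export_relion4",
    "export_warp_dir",
    "euler_to_matrix",
    "matrix_to_euler",
    "motl_to_star",
    "star_to_motl",
]

#: positions_relion = positions_stopgap - STOPGAP_ORIGIN_OFFSET
STOPGAP_ORIGIN_OFFSET = 1.0


# ---------------------------------------------------------------------------
# wedge list

WEDGELIST_COLUMNS = [
    "tomo_num", "pixelsize", "tomo_x", "tomo_y", "tomo_z", "tilt_angle",
    "defocus", "exposure", "voltage", "cs", "amp_contrast",
]


def export_wedgelist(
    tomolist: TomoList,
    tomo_dims: tuple[int, int, int] = (0, 0, 0),
    cs: float = 2.7,
    amp_contrast: float = 0.07,
    dose_convention: str = "post",
) -> str:
    """Build a STOPGAP-style wedge list (STAR text) from the tomolist.

    One row per retained tilt of every non-skipped series; the exposure
    column carries the cumulative dose used for exposure filtering.
    """
    rows = []
    for r in tomolist:
        if r.skip:
            continue
        exposures = r.exposure_for_filtering(dose_convention)
        defoci = (
            [c.defocus for c in r.ctf] if r.ctf is not None else [0.0] * r.n_tilts()
        )
        for k in range(r.n_tilts()):
            rows.append(
                {
                    "tomo_num": r.tomo_num,
                    "pixelsize": r.pixel_size,
                    "tomo_x": tomo_dims[0],
                    "tomo_y": tomo_dims[1],
                    "tomo_z": tomo_dims[2],
                    "tilt_angle": r.tilt_angles[k],
                    "defocus": defoci[k],
                    "exposure": exposures[k],
                    "voltage": r.voltage,
                    "cs": cs,
                    "amp_contrast": amp_contrast,
                }
            )
    df = pd.DataFrame(rows, columns=WEDGELIST_COLUMNS)
    return stario.write_star({"wedgelist": df})


# ---------------------------------------------------------------------------
# RELION 4

def acquisition_order_rows(r: TiltSeriesRecord) -> list[tuple[int, float]]:
    """(1-based acquisition rank, tilt angle) rows in acquisition order."""
    idx = np.argsort(r.acquisition_order)
    return [
        (rank + 1, float(r.tilt_angles[i])) for rank, i in enumerate(idx)
    ]


def export_relion4(tomolist: TomoList) -> tuple[str, dict[int, str]]:
    """RELION-4-style export: global tomogram star + per-series order lists.

    Returns the star text and ``{tomo_num: order_csv_text}`` where each CSV
    row is ``rank,angle`` in acquisition order (rank 1-based).
    """
    rows = []
    orders: dict[int, str] = {}
    for r in tomolist:
        if r.skip:
            continue
        if r.alignment is None:
            raise ValueError(
                f"series {r.tomo_num}: RELION-4 export needs an alignment"
            )
        if r.ctf is None:
            raise ValueError(
                f"series {r.tomo_num}: RELION-4 export needs CTF results"
            )
        stack = r.stage_paths.get(
            "curated_stack", r.stage_paths.get("motion_corrected", "")
        )
        rows.append(
            {
                "rlnTomoName": f"ts_{r.tomo_num:03d}",
                "rlnTomoTiltSeriesName": stack,
                "rlnTomoTiltSeriesPixelSize": r.pixel_size,
                "rlnVoltage": r.voltage,
                "rlnTomoImportOrderList": f"order_ts_{r.tomo_num:03d}.csv",
                "rlnTomoImportFractionalDose": (
                    float(np.mean(r.per_image_dose)) if r.n_tilts() else 0.0
                ),
            }
        )
        orders[r.tomo_num] = (
            "\n".join(f"{rank},{angle:.2f}" for rank, angle in
                      acquisition_order_rows(r)) + "\n"
        )
    star = stario.write_star(
        {"global": pd.DataFrame(rows, columns=[
            "rlnTomoName", "rlnTomoTiltSeriesName", "rlnTomoTiltSeriesPixelSize",
            "rlnVoltage", "rlnTomoImportOrderList", "rlnTomoImportFractionalDose",
        ])}
    )
    return star, orders


# ---------------------------------------------------------------------------
# Warp-style directory

def export_warp_dir(tomolist: TomoList, out_dir: str | Path) -> Path:
    """Write per-series retained tilt images, rewritten .mdoc and alignments.

    The rewritten mdoc contains only retained sections with renumbered
    ZValues; the source images are taken from the series' curated (or
    motion-corrected) stack.  Re-exporting overwrites identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for r in tomolist:
        if r.skip:
            continue
        ts_name = f"ts_{r.tomo_num:03d}"
        ts_dir = out_dir / ts_name
        ts_dir.mkdir(exist_ok=True)
        stack_path = r.stage_paths.get(
            "curated_stack", r.stage_paths.get("motion_corrected")
        )
        if stack_path is None:
            raise ValueError(
                f"series {r.tomo_num}: no motion-corrected stack to export"
            )
        stack, pix = read_mrc(stack_path)
        if stack.ndim == 2:
            stack = stack[None]
        if len(stack) != r.n_tilts():
            raise ValueError(
                f"series {r.tomo_num}: stack depth {len(stack)} != "
                f"{r.n_tilts()} retained tilts"
            )
        doc = parse_mdoc(Path(r.mdoc_path).read_text(), require_tilt_angle=False)
        retained = _retained_sections(doc, r)
        new_doc = MdocDocument(
            global_header=dict(doc.global_header), titles=list(doc.titles)
        )
        for new_z, sec in enumerate(retained):
            new_doc.sections.append(
                MdocSection(z_value=new_z, keys=dict(sec.keys),
                            header_name=sec.header_name)
            )
        (ts_dir / f"{ts_name}.mdoc").write_text(write_mdoc(new_doc))
        for k in range(r.n_tilts()):
            write_mrc(
                ts_dir / f"{ts_name}_{k:03d}.mrc", stack[k],
                pixel_size=pix or r.pixel_size,
            )
        if r.alignment is not None:
            tlt, xf = write_alignment(r.alignment)
            (ts_dir / f"{ts_name}.tlt").write_text(tlt)
            (ts_dir / f"{ts_name}.xf").write_text(xf)
    return out_dir


def _retained_sections(doc: MdocDocument, r: TiltSeriesRecord) -> list[MdocSection]:
    """Mdoc sections for the retained tilts, in sorted-angle order."""
    angles = np.array([s.tilt_angle for s in doc.sections])
    order = np.argsort(angles, kind="stable")
    sorted_secs = [doc.sections[i] for i in order]
    retained = [
        sec for i, sec in enumerate(sorted_secs) if i not in set(r.removed_images)
    ]
    if len(retained) != r.n_tilts():
        raise ValueError(
            f"series {r.tomo_num}: mdoc yields {len(retained)} retained "
            f"sections but record has {r.n_tilts()} tilts"
        )
    return retained


# ---------------------------------------------------------------------------
# Euler conventions

def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(triple, convention: str) -> np.ndarray:
    """Intrinsic Euler triple (degrees) -> rotation matrix.

    ``zxz``: R = Rz(a1) Rx(a2) Rz(a3); ``zyz``: R = Rz(a1) Ry(a2) Rz(a3).
    """
    a1, a2, a3 = (math.radians(float(a)) for a in triple)
    if convention == "zxz":
        return _rot_z(a1) @ _rot_x(a2) @ _rot_z(a3)
    if convention == "zyz":
        return _rot_z(a1) @ _rot_y(a2) @ _rot_z(a3)
    raise ValueError(f"unknown Euler convention {convention!r}")


def matrix_to_euler(matrix: np.ndarray, convention: str) -> tuple[float, float, float]:
    """Rotation matrix -> intrinsic Euler triple (degrees).

    At gimbal lock (middle angle 0 or 180 deg) the canonical triple with the
    third angle equal to zero is returned.
    """
    m = np.asarray(matrix, dtype=float)
    if convention == "zxz":
        beta = math.acos(max(-1.0, min(1.0, m[2, 2])))
        if abs(math.sin(beta)) < 1e-8:
            # beta = 0 or 180: only a combination of a1, a3 is determined;
            # canonically a3 = 0, then m = Rz(a1) (Rx(pi) if beta=180)
            alpha = math.atan2(m[1, 0], m[0, 0])
            return (math.degrees(alpha), math.degrees(beta), 0.0)
        alpha = math.atan2(m[0, 2], -m[1, 2])
        gamma = math.atan2(m[2, 0], m[2, 1])
        return (math.degrees(alpha), math.degrees(beta), math.degrees(gamma))
    if convention == "zyz":
        beta = math.acos(max(-1.0, min(1.0, m[2, 2])))
        if abs(math.sin(beta)) < 1e-8:
            if m[2, 2] > 0:
                alpha = math.atan2(m[1, 0], m[0, 0])
            else:  # beta = 180: m = Rz(a1) Ry(pi) with a3 = 0
                alpha = math.atan2(-m[1, 0], -m[0, 0])
            return (math.degrees(alpha), math.degrees(beta), 0.0)
        alpha = math.atan2(m[1, 2], m[0, 2])
        gamma = math.atan2(m[2, 1], -m[2, 0])
        return (math.degrees(alpha), math.degrees(beta), math.degrees(gamma))
    raise ValueError(f"unknown Euler convention {convention!r}")


# ---------------------------------------------------------------------------
# particle tables

MOTL_COLUMNS = [
    "particle_id", "tomo_num", "pos_x", "pos_y", "pos_z",
    "phi", "theta", "psi", "score", "class",
]
STAR_PARTICLE_COLUMNS = [
    "rlnTomoParticleId", "rlnTomoName", "rlnCoordinateX", "rlnCoordinateY",
    "rlnCoordinateZ", "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi",
    "rlnMaxValueProbDistribution", "rlnClassNumber",
]


def motl_to_star(motl: pd.DataFrame) -> pd.DataFrame:
    """STOPGAP particle table (zxz, 1-based centers) -> RELION rows.

    The rotation matrix of each particle is preserved exactly; positions are
    shifted from 1-based voxel centers to 0-based coordinates.
    """
    rows = []
    for _, p in motl.iterrows():
        m = euler_to_matrix((p["phi"], p["theta"], p["psi"]), "zxz")
        rot, tilt, psi = matrix_to_euler(m, "zyz")
        rows.append(
            {
                "rlnTomoParticleId": int(p["particle_id"]),
                "rlnTomoName": f"ts_{int(p['tomo_num']):03d}",
                "rlnCoordinateX": p["pos_x"] - STOPGAP_ORIGIN_OFFSET,
                "rlnCoordinateY": p["pos_y"] - STOPGAP_ORIGIN_OFFSET,
                "rlnCoordinateZ": p["pos_z"] - STOPGAP_ORIGIN_OFFSET,
                "rlnAngleRot": rot,
                "rlnAngleTilt": tilt,
                "rlnAnglePsi": psi,
                "rlnMaxValueProbDistribution": p["score"],
                "rlnClassNumber": int(p["class"]),
            }
        )
    return pd.DataFrame(rows, columns=STAR_PARTICLE_COLUMNS)


def star_to_motl(star: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`motl_to_star`."""
    rows = []
    for _, p in star.iterrows():
        m = euler_to_matrix(
            (p["rlnAngleRot"], p["rlnAngleTilt"], p["rlnAnglePsi"]), "zyz"
        )
        phi, theta, psi = matrix_to_euler(m, "zxz")
        name = str(p["rlnTomoName"])
        tomo_num = int(name.split("_")[-1]) if "_" in name else int(name)
        rows.append(
            {
                "particle_id": int(p["rlnTomoParticleId"]),
                "tomo_num": tomo_num,
                "pos_x": p["rlnCoordinateX"] + STOPGAP_ORIGIN_OFFSET,
                "pos_y": p["rlnCoordinateY"] + STOPGAP_ORIGIN_OFFSET,
                "pos_z": p["rlnCoordinateZ"] + STOPGAP_ORIGIN_OFFSET,
                "phi": phi,
                "theta": theta,
                "psi": psi,
                "score": p["rlnMaxValueProbDistribution"],
                "class": int(p["rlnClassNumber"]),
            }
        )
    return pd.DataFrame(rows, columns=MOTL_COLUMNS)
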