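"""STA interchange: wedge lists, RELION-4 export, Warp directories, Euler
conventions and particle-table conversion."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from tomokit import stario
from tomokit.exporters import (
    MOTL_COLUMNS,
    STOPGAP_ORIGIN_OFFSET,
    acquisition_order_rows,
    euler_to_matrix,
    export_relion4,
    export_warp_dir,
    export_wedgelist,
    matrix_to_euler,
    motl_to_star,
    star_to_motl,
)
from tomokit.mdoc import parse_mdoc
from tomokit.params import ParamFile
from tomokit.pipeline import Pipeline, run_pipeline
from tomokit.tomolist import import_project


@pytest.fixture()
def processed_project(tmp_path, raw_project):
    """Imported + assembled + curated project (2 removed from series 1)."""
    raw, _ = raw_project
    project = tmp_path / "proj"
    import_project(raw, project)
    steps = [
        ParamFile("assemble", {"odd_even": False}),
        ParamFile("clean", {"bad_1": [0, 40]}),
        ParamFile("ctf", {"defocus_min": 15000.0, "defocus_max": 35000.0,
                          "defocus_step": 500.0, "tile": 64}),
    ]
    tomolist, report = run_pipeline(Pipeline(steps), project, seed=0)
    assert report.ok
    return project, tomolist


class TestWedgelist:
    def test_row_counts_and_exposure_column(self, processed_project):
        _, tomolist = processed_project
        star = stario.read_star(export_wedgelist(tomolist))["wedgelist"]
        assert len(star) == 39 + 41
        r1 = tomolist.get(1)
        rows1 = star[star["tomo_num"] == 1]
        assert len(rows1) == 39
        assert np.allclose(
            rows1["exposure"].to_numpy(),
            r1.exposure_for_filtering("post"),
            atol=5e-6,  # star text carries 6 decimals
        )
        assert np.all(np.diff(rows1["tilt_angle"].to_numpy()) > 0)

    def test_skipped_series_excluded(self, processed_project):
        _, tomolist = processed_project
        tomolist.get(2).skip = True
        star = stario.read_star(export_wedgelist(tomolist))["wedgelist"]
        assert set(star["tomo_num"]) == {1}


class TestRelion4:
    def test_order_list_worked_example(self):
        from tomokit.mdoc import MdocDocument, MdocSection
        from tomokit.stack_ops import assemble_tilt_series
        from tomokit.tomolist import TiltSeriesRecord

        angles = [0, 3, -3, 6, -6]
        doc = MdocDocument()
        for z, a in enumerate(angles):
            sec = MdocSection(z_value=z)
            sec.keys["TiltAngle"] = str(a)
            sec.keys["ExposureDose"] = "3.0"
            doc.sections.append(sec)
        series = assemble_tilt_series(np.zeros((5, 2, 2)), doc)
        record = TiltSeriesRecord(
            tomo_num=1,
            tilt_angles=series.tilt_angles,
            acquisition_order=series.acquisition_order,
            per_image_dose=series.per_image_dose,
            pre_exposure=series.pre_exposure,
        )
        assert acquisition_order_rows(record) == [
            (1, 0.0), (2, 3.0), (3, -3.0), (4, 6.0), (5, -6.0)
        ]

    def test_star_round_trips_and_curation_consistency(self, processed_project):
        _, tomolist = processed_project
        star_text, orders = export_relion4(tomolist)
        star = stario.read_star(star_text)["global"]
        assert len(star) == 2
        assert len(orders[1].strip().splitlines()) == 39
        assert len(orders[2].strip().splitlines()) == 41
        assert star["rlnVoltage"].iloc[0] == pytest.approx(300.0)


class TestWarpExport:
    def test_retained_counts_and_mdoc_reparse(self, tmp_path, processed_project):
        project, tomolist = processed_project
        out = export_warp_dir(tomolist, tmp_path / "warp")
        ts1 = out / "ts_001"
        images = sorted(ts1.glob("ts_001_*.mrc"))
        assert len(images) == 39
        doc = parse_mdoc((ts1 / "ts_001.mdoc").read_text())
        assert len(doc.sections) == 39
        assert [s.z_value for s in doc.sections] == list(range(39))
        record = tomolist.get(1)
        assert np.allclose(
            sorted(s.tilt_angle for s in doc.sections), record.tilt_angles
        )
        tlt_lines = (ts1 / "ts_001.tlt").read_text().strip().splitlines()
        assert len(tlt_lines) == 39

    def test_re_export_is_byte_identical(self, tmp_path, processed_project):
        _, tomolist = processed_project
        out = export_warp_dir(tomolist, tmp_path / "warp")
        first = {
            p.relative_to(out): p.read_bytes() for p in out.rglob("*") if p.is_file()
        }
        export_warp_dir(tomolist, out)
        second = {
            p.relative_to(out): p.read_bytes() for p in out.rglob("*") if p.is_file()
        }
        assert first == second


class TestEulerConversions:
    def test_zero_triple_is_identity(self):
        for conv in ("zxz", "zyz"):
            assert np.allclose(euler_to_matrix((0, 0, 0), conv), np.eye(3))

    def test_single_axis_case(self):
        m = euler_to_matrix((90, 0, 0), "zxz")
        assert np.allclose(m @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    @pytest.mark.parametrize("conv,scipy_seq", [("zxz", "ZXZ"), ("zyz", "ZYZ")])
    def test_matches_independent_rotation_composition(self, conv, scipy_seq):
        rng = np.random.default_rng(0)
        for _ in range(50):
            triple = rng.uniform(-180, 180, 3)
            triple[1] = rng.uniform(1, 179)
            ours = euler_to_matrix(triple, conv)
            reference = Rotation.from_euler(
                scipy_seq, triple, degrees=True
            ).as_matrix()
            assert np.abs(ours - reference).max() < 1e-12

    def test_round_trip_1000_random_orientations(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            triple = rng.uniform(-180, 180, 3)
            triple[1] = rng.uniform(0.5, 179.5)
            for conv in ("zxz", "zyz"):
                m = euler_to_matrix(triple, conv)
                back = euler_to_matrix(matrix_to_euler(m, conv), conv)
                worst = max(worst, np.abs(back - m).max())
                assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)
        assert worst < 1e-10

    def test_gimbal_lock_canonical_triple(self):
        for conv in ("zxz", "zyz"):
            for beta in (0.0, 180.0):
                m = euler_to_matrix((30.0, beta, 40.0), conv)
                triple = matrix_to_euler(m, conv)
                assert triple[2] == 0.0
                assert np.abs(euler_to_matrix(triple, conv) - m).max() < 1e-10


class TestParticleConversion:
    def _motl(self, n=20, seed=5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "particle_id": np.arange(n),
                "tomo_num": np.ones(n, int),
                "pos_x": rng.integers(1, 64, n).astype(float),
                "pos_y": rng.integers(1, 64, n).astype(float),
                "pos_z": rng.integers(1, 64, n).astype(float),
                "phi": rng.uniform(-180, 180, n),
                "theta": rng.uniform(1, 179, n),
                "psi": rng.uniform(-180, 180, n),
                "score": rng.uniform(0, 1, n),
                "class": np.ones(n, int),
            }
        )

    def test_identity_orientation_both_dialects(self):
        motl = self._motl(1)
        motl.loc[0, ["phi", "theta", "psi"]] = 0.0
        star = motl_to_star(motl)
        assert star[["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]].iloc[
            0
        ].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_positions_exact_matrices_tight(self):
        motl = self._motl()
        back = star_to_motl(motl_to_star(motl))
        assert list(back.columns) == MOTL_COLUMNS
        for col in ("pos_x", "pos_y", "pos_z", "particle_id", "class"):
            assert np.array_equal(back[col].to_numpy(), motl[col].to_numpy())
        for row_in, row_out in zip(motl.itertuples(), back.itertuples()):
            m_in = euler_to_matrix((row_in.phi, row_in.theta, row_in.psi), "zxz")
            m_out = euler_to_matrix((row_out.phi, row_out.theta, row_out.psi), "zxz")
            assert np.abs(m_in - m_out).max() < 1e-10

    def test_origin_offset_contract(self):
        motl = self._motl(1)
        motl.loc[0, ["pos_x", "pos_y", "pos_z"]] = 1.0
        star = motl_to_star(motl)
        assert star[["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]].iloc[
            0
        ].to_list() == [0.0, 0.0, 0.0]
        assert STOPGAP_ORIGIN_OFFSET == 1.0

    def test_rotation_matrix_preserved_across_dialects(self):
        motl = self._motl(10, seed=9)
        star = motl_to_star(motl)
        for row_in, row_out in zip(motl.itertuples(), star.itertuples()):
            m_zxz = euler_to_matrix((row_in.phi, row_in.theta, row_in.psi), "zxz")
            m_zyz = euler_to_matrix(
                (row_out.rlnAngleRot, row_out.rlnAngleTilt, row_out.rlnAnglePsi),
                "zyz",
            )
            assert np.abs(m_zxz - m_zyz).max() < 1e-10
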