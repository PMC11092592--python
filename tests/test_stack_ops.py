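"""Assembly, dose bookkeeping, curation, frame sums and movie alignment."""

import numpy as np
import pytest

from tomokit.mdoc import MdocDocument, MdocSection
from tomokit.stack_ops import (
    DoseSchedule,
    align_frames,
    assemble_tilt_series,
    clean_stack,
    sum_frames,
)
from tomokit.synthetic import _shift_image


def _mdoc_for(angles, dose=3.0):
    doc = MdocDocument()
    for z, angle in enumerate(angles):
        sec = MdocSection(z_value=z)
        sec.keys["TiltAngle"] = str(angle)
        sec.keys["ExposureDose"] = str(dose)
        doc.sections.append(sec)
    return doc


def _brute_force_pre_exposure(angles, doses):
    """Independent oracle: prefix sums in acquisition order, re-sorted."""
    pre = [sum(doses[:k]) for k in range(len(doses))]
    order = sorted(range(len(angles)), key=lambda i: (angles[i], i))
    return [pre[i] for i in order]


class TestAssembly:
    def test_dose_symmetric_worked_example(self):
        angles = [0, 3, -3, 6, -6]
        series = assemble_tilt_series(np.zeros((5, 4, 4)), _mdoc_for(angles))
        assert list(series.tilt_angles) == [-6, -3, 0, 3, 6]
        assert list(series.pre_exposure) == [12, 6, 0, 3, 9]

    def test_sequential_acquisition(self):
        angles = [-6, -3, 0, 3, 6]
        series = assemble_tilt_series(np.zeros((5, 4, 4)), _mdoc_for(angles))
        assert list(series.pre_exposure) == [0, 3, 6, 9, 12]
        assert list(series.acquisition_order) == [0, 1, 2, 3, 4]

    def test_single_image_identity(self):
        series = assemble_tilt_series(np.ones((1, 4, 4)), _mdoc_for([12.0]))
        assert list(series.pre_exposure) == [0.0]

    def test_slices_follow_their_angles(self, rng):
        angles = [0, 3, -3]
        images = np.stack([np.full((4, 4), a) for a in angles])
        series = assemble_tilt_series(images, _mdoc_for(angles))
        assert [img[0, 0] for img in series.stack] == [-3, 0, 3]

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="images but"):
            assemble_tilt_series(np.zeros((3, 4, 4)), _mdoc_for([0, 3]))

    @pytest.mark.parametrize("trial", range(5))
    def test_pre_exposure_matches_brute_force_over_permutations(self, trial):
        rng = np.random.default_rng(trial)
        for _ in range(20):
            n = int(rng.integers(2, 41))
            angles = rng.permutation(np.arange(n) * 3.0 - 60)
            doses = rng.uniform(1, 5, n)
            doc = _mdoc_for(angles, dose=0)
            for sec, d in zip(doc.sections, doses):
                sec.keys["ExposureDose"] = repr(float(d))
            series = assemble_tilt_series(np.zeros((n, 2, 2)), doc)
            expected = _brute_force_pre_exposure(list(angles), list(doses))
            assert np.allclose(series.pre_exposure, expected)


class TestDoseSchedule:
    def test_prefix_sum_invariant(self, rng):
        doses = rng.uniform(1, 5, 20)
        sched = DoseSchedule.from_doses(doses, initial_dose=2.0)
        assert sched.pre_exposure[0] == 2.0
        assert np.allclose(np.diff(sched.pre_exposure), doses[:-1])

    def test_filtering_conventions(self):
        sched = DoseSchedule.from_doses([3.0, 3.0])
        assert list(sched.exposure_for_filtering("post")) == [3.0, 6.0]
        assert list(sched.exposure_for_filtering("pre")) == [0.0, 3.0]
        assert list(sched.exposure_for_filtering("mid")) == [1.5, 4.5]


class TestCuration:
    def _series(self, n=41):
        angles = np.arange(n) * 3.0 - 60
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)
        doc = _mdoc_for(angles[perm])
        return assemble_tilt_series(np.arange(n * 4 * 4).reshape(n, 4, 4)[perm], doc)

    def test_remove_nothing_is_identity(self):
        series = self._series()
        out = clean_stack(series.stack, series, [])
        assert np.array_equal(out.stack, series.stack)
        assert np.array_equal(out.tilt_angles, series.tilt_angles)

    def test_counts_and_angle_conservation(self):
        series = self._series(41)
        out = clean_stack(series.stack, series, [0, 40])
        assert out.stack.shape[0] == 39
        assert len(out.tilt_angles) == 39
        removed = {series.tilt_angles[0], series.tilt_angles[40]}
        assert set(series.tilt_angles) - set(out.tilt_angles) == removed

    def test_acquisition_order_stays_a_permutation(self):
        series = self._series(10)
        out = clean_stack(series.stack, series, [3, 7])
        assert sorted(out.acquisition_order) == list(range(8))
        # relative acquisition order of survivors preserved
        kept = [i for i in range(10) if i not in (3, 7)]
        old = series.acquisition_order[kept]
        assert np.array_equal(np.argsort(out.acquisition_order), np.argsort(old))

    def test_out_of_range_index_rejected(self):
        series = self._series(5)
        with pytest.raises(IndexError):
            clean_stack(series.stack, series, [5])

    def test_removing_all_requires_skip(self):
        series = self._series(3)
        with pytest.raises(ValueError, match="skip"):
            clean_stack(series.stack, series, [0, 1, 2])


class TestFrameSums:
    def test_parity_split_partitions_sum(self, rng):
        movie = rng.normal(size=(4, 8, 8))
        total = sum_frames(movie, "all")
        odd = sum_frames(movie, "odd")
        even = sum_frames(movie, "even")
        assert np.allclose(total, movie.sum(axis=0), atol=1e-12)
        assert np.array_equal(odd + even, total)  # partition is exact
        # frame 0 is "even" by the 0-based convention
        assert np.array_equal(sum_frames(movie[:1], "even"), movie[0])

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            sum_frames(np.ones((1, 4, 4)), "odd")


class TestFrameAlignment:
    def _texture(self, size=128):
        # periodic smooth random field (Fourier shifts wrap, so the
        # texture must too)
        rng = np.random.default_rng(5)
        noise = rng.normal(size=(size, size))
        fy = np.fft.fftfreq(size)[:, None]
        fx = np.fft.rfftfreq(size)[None, :]
        envelope = np.exp(-((np.hypot(fy, fx) * size / 8.0) ** 2))
        base = np.fft.irfft2(np.fft.rfft2(noise) * envelope, s=noise.shape)
        return base / base.std()

    def test_integer_shifts_recovered_exactly(self):
        base = self._texture()
        true = np.array([[0, 0], [3, -3], [-3, 3], [2, 1]], float)
        movie = np.stack([_shift_image(base, t) for t in true])
        _, shifts = align_frames(movie)
        expected = -(true - true.mean(axis=0))
        assert np.abs(shifts - expected).max() < 1e-3

    def test_zero_shift_movie_stays_put(self):
        base = self._texture(64)
        rng = np.random.default_rng(0)
        movie = np.stack([base + 0.01 * rng.normal(size=base.shape)] * 3)
        _, shifts = align_frames(movie)
        assert np.abs(shifts).max() < 0.1

    def test_subpixel_recovery_at_moderate_noise(self):
        base = self._texture(256)
        rng = np.random.default_rng(11)
        true = np.array([[0, 0], [1.4, -0.7], [-0.6, 0.9], [0.3, 1.1]])
        movie = np.stack(
            [_shift_image(base, t) + 0.5 * rng.normal(size=base.shape) for t in true]
        )
        _, shifts = align_frames(movie)
        expected = -(true - true.mean(axis=0))
        assert np.abs(shifts - expected).max() < 0.25

    def test_all_zero_movie_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            align_frames(np.zeros((3, 8, 8)))
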