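import numpy as np
import pytest

from tomokit.ctf import CtfParams
from tomokit.synthetic import SimSpec, make_phantom, simulate_tilt_series


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def ctf_params():
    """Typical 300 kV optics at 2 A/px."""
    return CtfParams(
        voltage=300.0, cs=2.7, amplitude_contrast=0.07, pixel_size=2.0
    )


@pytest.fixture()
def small_sim_spec():
    """Desk-scale tilt-series: 64 px images, +/-60 deg in 3 deg steps."""
    return SimSpec(image_size=64, thickness=32, seed=7, frames_per_tilt=2,
                   defocus=25000.0)


@pytest.fixture()
def raw_project(tmp_path, small_sim_spec):
    """A two-series raw data directory plus its ground-truth manifests."""
    raw = tmp_path / "raw"
    manifests = {}
    for k in (1, 2):
        spec = SimSpec(**{**small_sim_spec.__dict__, "seed": k})
        volume, _ = make_phantom(spec)
        manifests[k] = simulate_tilt_series(volume, spec, raw, tomo_num=k)
    return raw, manifests
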