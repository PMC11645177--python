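import pytest

import ferromap as fm
from ferromap.pipeline import bundled_table1_path, calibration_points, read_table1


@pytest.fixture(scope="session")
def table1():
    return read_table1(bundled_table1_path())


@pytest.fixture(scope="session")
def table1_points(table1):
    return calibration_points(table1)


@pytest.fixture(scope="session")
def true_calib():
    return fm.CalibrationModel(slope=10.02, intercept=88.028, r_squared=0.98, n_points=11)


@pytest.fixture(scope="session")
def phantom_params():
    return fm.get_preset("phantom-multiecho")


@pytest.fixture(scope="session")
def dual_params():
    return fm.get_preset("dual-echo-dynamic")


@pytest.fixture
def phantom_factory():
    """Factory for small phantoms: phantom_factory(noise_sigma=...) -> (spec, image)."""

    def make(noise_sigma=0.0, seed=0, grid=(64, 64, 1), base_signal=1000.0, **kw):
        spec = fm.default_phantom_spec(
            grid_shape=grid, noise_sigma=noise_sigma, base_signal=base_signal, **kw
        )
        img = fm.generate_phantom_image(spec, fm.get_preset("phantom-multiecho"), seed=seed)
        return spec, img

    return make


@pytest.fixture
def study_factory():
    """Factory for small dynamic studies: (spec, frames)."""

    def make(scenario="group1", noise_sigma=0.0, seed=0, grid=(32, 32, 1), **kw):
        spec = fm.build_group_study(scenario, grid_shape=grid, noise_sigma=noise_sigma, **kw)
        frames = fm.generate_dynamic_study(spec, fm.get_preset("dual-echo-dynamic"), seed=seed)
        return spec, frames

    return make


@pytest.fixture
def tiny_noise():
    """Effectively-noiseless NoiseEstimate so the SNR gate keeps all echoes."""
    return fm.NoiseEstimate(sigma=1e-9, method="provided")
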