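import pytest

from snfsim import field_model as fm
from snfsim.detection import DetectorConfig, SpikeFeatureConfig, compute_baseline
from snfsim.records import IctalParams, SeizureEvent
from snfsim.synthetic import assemble_recording, generate_baseline

FS = 500.0


@pytest.fixture(scope="session")
def baseline_600():
    """10 min of stationary baseline, 4 channels."""
    return generate_baseline(600.0, seed=101)


@pytest.fixture(scope="session")
def detector_config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def spike_config():
    return SpikeFeatureConfig()


@pytest.fixture(scope="session")
def baseline_stats(baseline_600, detector_config):
    return compute_baseline(baseline_600, detector_config)


@pytest.fixture(scope="session")
def event_record():
    """900 s recording with one 30 s bilateral gain-3 event at t = 600 s."""
    return assemble_recording(
        [SeizureEvent(600.0, 630.0, "bilateral")], seed=11, duration_s=900.0,
        ictal_params=IctalParams(band_gain=(3.0, 3.0, 3.0)),
    )


@pytest.fixture(scope="session")
def coarse_geometry():
    return fm.GeometryConfig(resolution=0.5)


@pytest.fixture(scope="session")
def snf_setup(coarse_geometry):
    """Coarse grid + SNF montage + one solved sub-configuration."""
    grid = fm.build_grid(coarse_geometry)
    montage = fm.snf_montage()
    fm.add_electrode_tracks(grid, montage)
    fmap = fm.solve_quasistatic(grid, montage, "L1", 650.0)
    return grid, montage, fmap
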