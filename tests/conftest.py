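import numpy as np
import pytest

import spiralflow as sf


@pytest.fixture(scope="session")
def small_geometry():
    """Odd transverse grid so one voxel sits exactly on the tube axis."""
    return sf.VesselGeometry(grid_shape=(4, 33, 33), radius_mm=3.0, voxel_size=0.8)


@pytest.fixture(scope="session")
def steady_waveform():
    return sf.FlowWaveform(steady=True)  # constant 3 ml/s


@pytest.fixture(scope="session")
def pulsatile_waveform():
    return sf.FlowWaveform()


def full_sampling_schedule(matrix_ky, matrix_kz, repeats=1, tr=8.9):
    """Every (ky, kz) profile once per repeat, in raster order."""
    ky, kz = np.meshgrid(
        np.arange(-matrix_ky // 2, matrix_ky // 2),
        np.arange(-matrix_kz // 2, matrix_kz // 2),
        indexing="ij",
    )
    ky = np.tile(ky.ravel(), repeats)
    kz = np.tile(kz.ravel(), repeats)
    return sf.SamplingSchedule(
        ky=ky, kz=kz, arm_index=np.zeros(len(ky), dtype=np.int64),
        matrix_ky=matrix_ky, matrix_kz=matrix_kz, tr=tr,
    )


@pytest.fixture(scope="session")
def fully_sampled_steady():
    """Noiseless, fully sampled steady-flow acquisition on a small grid.

    Returns (scene, schedule, timeline, raw, bin_config, ktmask, coil_maps).
    """
    geom = sf.VesselGeometry(grid_shape=(2, 16, 16), radius_mm=2.0, voxel_size=1.0)
    scene = sf.PhantomScene(
        geometry=geom,
        waveform=sf.FlowWaveform(steady=True),
        rr=sf.RRGenerator(sd_fraction=0.0, seed=3),
        acq=sf.AcquisitionConfig(n_coils=2, noise_sd=0.0),
    )
    # two full rasters, one per cardiac frame: 256 profiles x 4 segments x 1 ms
    # fills exactly one 1024 ms frame per repeat
    schedule = full_sampling_schedule(16, 16, repeats=2, tr=1.0)
    timeline = sf.CardiacTimeline(
        np.array([0.0, 2048.0, 4096.0]), nominal_rr=2048.0
    )
    raw = sf.encode_kspace(scene, schedule, timeline=timeline)
    bin_config = sf.BinningConfig(n_card=2, frame_duration=1024.0, n_discard=0)
    ktmask = sf.build_kt_mask(schedule, timeline, bin_config)
    return scene, schedule, timeline, raw, bin_config, ktmask, scene.coil_maps()
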