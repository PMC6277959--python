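import numpy as np
import pytest

from platescan.calibration import CornerSet, MachineCoord
from platescan.plate_geometry import builtin_plate
from platescan.scan_planner import ScanConfig
from platescan.synthetic_acquisition import SceneParams, render_scene, simulate_acquisition

# small frames keep simulated acquisitions fast without losing the
# JPEG size signature
SMALL_FRAME = dict(width=160, height=120)


@pytest.fixture(scope="session")
def scene():
    """One deterministic in-focus droplet scene (float, 256x192)."""
    return render_scene(SceneParams(seed=5, width=256, height=192)).astype(float)


@pytest.fixture
def measured_corners():
    """A realistic corner measurement: slight rotation, tilt and warp."""
    return CornerSet(
        c10=MachineCoord(100.15, -1.34, 0.13),
        c01=MachineCoord(0.22, -62.81, -0.05),
        c11=MachineCoord(100.40, -64.10, 0.21),
    )


@pytest.fixture(scope="session")
def sim24(tmp_path_factory):
    """A complete simulated 24-well acquisition (no missing images)."""
    out = tmp_path_factory.mktemp("sim24")
    truth = simulate_acquisition(
        builtin_plate("24"),
        ScanConfig(),
        SceneParams(seed=7, **SMALL_FRAME),
        out,
        missing_prob=0.0,
    )
    return out, truth


def truth_partition(truth):
    """Ground truth as (well, data filenames, sentinel filename) tuples."""
    return truth.stacks()


def manifest_partition(manifest):
    """Recovered manifest in the same shape as truth_partition."""
    from pathlib import Path

    return [
        (
            s.well,
            [Path(r.path).name for r in s.images],
            Path(s.sentinel.path).name if s.sentinel else None,
        )
        for s in manifest.stacks
    ]
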