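from pathlib import Path

import numpy as np
import pytest

from underice.detection import Frame
from underice.geometry import CameraCalib
from underice.pipeline import RunConfig, run_pipeline
from underice.synthetic import RenderParams, TrueAggregate, render_frame

REPO_ROOT = Path(__file__).resolve().parents[1]
REFERENCE_CONFIG = REPO_ROOT / "configs" / "reference_scenario.yaml"


@pytest.fixture(scope="session")
def calib() -> CameraCalib:
    return CameraCalib()


@pytest.fixture(scope="session")
def reference_config() -> RunConfig:
    return RunConfig.from_yaml(REFERENCE_CONFIG)


@pytest.fixture(scope="session")
def reference_report(reference_config):
    """The shipped reference synthetic scenario, run end to end once."""
    return run_pipeline(reference_config)


@pytest.fixture
def render_single(calib):
    """Render one aggregate centred in a noise-free frame; returns Frame."""

    def _render(
        diameter_cm: float,
        eccentricity: float = 0.0,
        standoff: float = 1.0,
        orientation: float = 0.0,
        noise_sd: float = 0.0,
    ) -> Frame:
        geom = Frame(
            frame_id=0, t=0.0, depth=standoff + 1.0, tilt=0.0,
            altimeter=standoff, x=0.0, y=0.0,
        )
        agg = TrueAggregate(
            agg_id=0, x=0.0, y=0.0, diameter=diameter_cm,
            eccentricity=eccentricity, orientation=orientation,
            type_label="rounded",
        )
        return render_frame(
            geom, None, [agg], calib, RenderParams(noise_sd=noise_sd),
            rng=np.random.default_rng(0),
        )

    return _render
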