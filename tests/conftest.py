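"""Shared fixtures: small synthetic plan/log pairs and log-stream builders."""

from __future__ import annotations

import numpy as np
import pytest

from mrlqa import (
    LinacState,
    LogSample,
    NoiseModel,
    PlanSpec,
    default_geometry,
    generate_log,
    generate_plan,
)
from mrlqa.log_io import DEFAULT_DIALECT


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def small_spec():
    """3 beams, 12 segments: big enough to exercise grouping, small enough to be fast."""
    return PlanSpec(n_beams=3, total_segments=12, seed=7)


@pytest.fixture(scope="session")
def small_beams(small_spec):
    beams, _ = generate_plan(small_spec)
    return beams


@pytest.fixture(scope="session")
def zero_noise_pair(small_spec, tmp_path_factory):
    """(plan_path, log_paths, beams) for an error-free delivery of the small plan."""
    d = tmp_path_factory.mktemp("zero_noise")
    beams, plan_path = generate_plan(small_spec, d / "plan.dcm")
    log_paths = generate_log(beams, NoiseModel.none(seed=1), d)
    return plan_path, log_paths, beams


def make_sample(
    time_ms: float,
    state: LinacState = LinacState.RADIATION_ON,
    dose: float = 0.0,
    gantry: float = 0.0,
    y1=None,
    y2=None,
    x1: float = -50.0,
    x2: float = 50.0,
    source_file: int = 0,
) -> LogSample:
    """One log sample with a default 20 mm-open aperture on every pair."""
    return LogSample(
        time_ms=time_ms,
        linac_state=state,
        step_dose_mu=dose,
        gantry_deg=gantry,
        y1_mm=np.full(80, -10.0) if y1 is None else np.asarray(y1, float),
        y2_mm=np.full(80, 10.0) if y2 is None else np.asarray(y2, float),
        x1_mm=x1,
        x2_mm=x2,
        source_file=source_file,
    )


def make_run(start_ms, n, mu, state=LinacState.RADIATION_ON, gantry=0.0, **kw):
    """A contiguous run of n samples with a linear step-dose ramp to mu."""
    return [
        make_sample(start_ms + 40.0 * k, state,
                    dose=mu * (k + 1) / n if state is LinacState.RADIATION_ON else 0.0,
                    gantry=gantry, **kw)
        for k in range(n)
    ]


def write_log_file(path, rows):
    """Write raw rows (lists matching the documented dialect header) as CSV."""
    header = ",".join(DEFAULT_DIALECT.columns())
    lines = [header] + [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def dialect_row(time_ms, state="Radiation On", dose=0.0, gantry=0.0,
                x1=-50.0, x2=50.0, y1_val=-10.0, y2_val=10.0):
    """One CSV row in the documented dialect with constant leaf banks."""
    return [time_ms, state, dose, gantry, x1, x2] + [y1_val] * 80 + [y2_val] * 80
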