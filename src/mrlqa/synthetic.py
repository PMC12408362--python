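"""Synthetic matched plan + delivery-log generator with controllable errors.

This module manufactures the two inputs the QA pipeline consumes — an RT
Plan and its delivery log — so every stage is testable end to end without
clinical data.  The plan generator emulates the shape of step-and-shoot
SBRT plans (11–17 static gantry angles, tens to hundreds of segments,
roughly 10–20 MU per segment, connected MLC-realizable apertures).  The log
generator emulates the documented log semantics: 40 ms samples, the
Intersegment / Move Only / Radiation On state machine, a step dose that
accumulates within each segment and resets at beam-off, and optical leaf
tracking noise.

The error model separates:

* per-sample Gaussian tracking jitter (default sigma 0.08 mm, the scale the
  optical tracking system shows on a held leaf),
* per-segment systematic leaf and jaw offsets (default uniform +-0.3 mm,
  applied to pairs the plan opens — parked pairs are actively held closed),
* per-segment MU errors (default uniform +-0.3 MU),
* an optional constant whole-bank shift for fault-injection studies,
* random delivery interruptions that split the log across files at a
  beam-on sample, exercising the merge-and-resume path.

All randomness flows from the seeds in the spec / noise model; a fixed seed
reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError
from .geometry import MachineGeometry, default_geometry
from .log_io import DEFAULT_DIALECT, LogDialect
from .plan_io import PlannedBeam, PlannedSegment, write_rtplan

__all__ = ["PlanSpec", "NoiseModel", "generate_plan", "generate_log"]


@dataclass
class PlanSpec:
    """Shape parameters of a synthetic step-and-shoot plan."""

    n_beams: int = 15
    gantry_angles_deg: list[float] | None = None  # evenly spaced if None
    segments_per_beam: int | tuple[int, int] = (6, 10)
    total_segments: int | None = None  # overrides segments_per_beam if set
    center_range_mm: float = 15.0  # beam aperture center drawn in +- this
    segment_wobble_mm: float = 8.0  # per-segment center offset around the beam center
    size_x_range_mm: tuple[float, float] = (25.0, 70.0)
    size_y_range_mm: tuple[float, float] = (25.0, 70.0)
    edge_step_mm: float = 5.0  # per-leaf random in-step of the aperture edge
    min_gap_mm: float = 2.0
    mu_per_segment: tuple[float, float] = (8.0, 22.0)
    seed: int = 42


@dataclass
class NoiseModel:
    """Delivery error model; all magnitudes in mm / MU, all sigmas >= 0."""

    leaf_jitter_sd_mm: float = 0.08
    leaf_systematic_mm: float = 0.3
    jaw_systematic_mm: float = 0.3
    mu_error_mu: float = 0.3
    bank_shift_mm: float = 0.0
    bank_shift_bank: str = "y1"
    interruption_prob: float = 0.0
    seed: int = 0

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseModel":
        """An error-free delivery (identity round trip)."""
        return cls(leaf_jitter_sd_mm=0.0, leaf_systematic_mm=0.0,
                   jaw_systematic_mm=0.0, mu_error_mu=0.0, seed=seed)


def _segment_counts(spec: PlanSpec, rng: np.random.Generator) -> list[int]:
    if spec.total_segments is not None:
        q, r = divmod(spec.total_segments, spec.n_beams)
        if q < 1:
            raise GenerationError("fewer segments than beams")
        return [q + 1 if i < r else q for i in range(spec.n_beams)]
    if isinstance(spec.segments_per_beam, int):
        return [spec.segments_per_beam] * spec.n_beams
    lo, hi = spec.segments_per_beam
    return [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_beams)]


def generate_plan(
    spec: PlanSpec,
    rtplan_path: str | Path | None = None,
    geometry: MachineGeometry | None = None,
) -> tuple[list[PlannedBeam], Path | None]:
    """Build a synthetic plan; optionally write it as an RTPLAN file.

    Deterministic for a fixed ``spec.seed``: the same spec produces the same
    beams and, when a path is given, a byte-identical RTPLAN file.
    """
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(spec.seed)
    if spec.gantry_angles_deg is not None:
        if len(spec.gantry_angles_deg) != spec.n_beams:
            raise GenerationError("gantry_angles_deg length must equal n_beams")
        angles = [a % 360.0 for a in spec.gantry_angles_deg]
    else:
        angles = [round(360.0 * i / spec.n_beams, 4) for i in range(spec.n_beams)]

    counts = _segment_counts(spec, rng)
    half_y = geometry.half_y_mm
    edges = geometry.leaf_edges_x_mm

    beams: list[PlannedBeam] = []
    for gantry, n_seg in zip(angles, counts):
        base_cx = rng.uniform(-spec.center_range_mm, spec.center_range_mm)
        base_cy = rng.uniform(-spec.center_range_mm, spec.center_range_mm)
        segments: list[PlannedSegment] = []
        for k in range(n_seg):
            cx = base_cx + rng.uniform(-spec.segment_wobble_mm, spec.segment_wobble_mm)
            cy = base_cy + rng.uniform(-spec.segment_wobble_mm, spec.segment_wobble_mm)
            wx = rng.uniform(*spec.size_x_range_mm)
            wy = rng.uniform(*spec.size_y_range_mm)
            x1 = max(cx - wx / 2.0, -geometry.half_x_mm + 1.0)
            x2 = min(cx + wx / 2.0, geometry.half_x_mm - 1.0)
            ylo = max(cy - wy / 2.0, -half_y + 1.0)
            yhi = min(cy + wy / 2.0, half_y - 1.0)
            if x2 - x1 < 2.0 or yhi - ylo < spec.min_gap_mm:
                raise GenerationError("aperture specification collapses to an empty field")

            open_pairs = (edges[1:] > x1) & (edges[:-1] < x2)
            y1 = np.full(geometry.n_leaf_pairs, round(cy, 3))  # parked closed at center
            y2 = y1.copy()
            step = spec.edge_step_mm
            for p in np.nonzero(open_pairs)[0]:
                lo = ylo + rng.uniform(0.0, step)
                hi = yhi - rng.uniform(0.0, step)
                if hi - lo < spec.min_gap_mm:
                    mid = 0.5 * (lo + hi)
                    lo, hi = mid - spec.min_gap_mm / 2.0, mid + spec.min_gap_mm / 2.0
                y1[p] = round(lo, 3)
                y2[p] = round(hi, 3)
            mu = round(rng.uniform(*spec.mu_per_segment), 3)
            segments.append(PlannedSegment(
                beam_key=gantry, segment_index=k, mu=mu,
                y1_mm=y1, y2_mm=y2,
                x1_mm=round(x1, 3), x2_mm=round(x2, 3),
            ))
        beams.append(PlannedBeam(
            gantry_deg=gantry,
            segments=segments,
            beam_mu=round(sum(s.mu for s in segments), 3),
        ))

    path = None
    if rtplan_path is not None:
        path = write_rtplan(beams, rtplan_path, geometry,
                            entropy=f"mrlqa-seed-{spec.seed}")
    return beams, path


# ---------------------------------------------------------------------------
# Log generation


def generate_log(
    beams: list[PlannedBeam],
    noise: NoiseModel,
    out_dir: str | Path,
    sample_period_ms: float = 40.0,
    mu_per_sample: float = 0.155,
    base_name: str = "delivery",
    dialect: LogDialect = DEFAULT_DIALECT,
    write_manifest: bool = True,
) -> list[Path]:
    """Simulate the delivery of ``beams`` and write log CSV file(s).

    The dose rate is a constant ``mu_per_sample`` MU per 40 ms sample
    (default 0.155, ~17 MU over ~110 samples), so a segment's beam-on run
    length scales with its MU.  Interruptions (probability per segment)
    split the output mid-run into a new file whose step dose resumes from
    zero, as a real resumed delivery does.

    Returns the written log paths in delivery order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(noise.seed)
    n_pairs = len(beams[0].segments[0].y1_mm) if beams and beams[0].segments else 80

    files: list[list[dict]] = [[]]

    def emit(state: str, dose: float, gantry: float, y1, y2, x1, x2) -> None:
        files[-1].append({
            "state": state, "dose": dose, "gantry": gantry,
            "y1": np.asarray(y1, float), "y2": np.asarray(y2, float),
            "x1": float(x1), "x2": float(x2),
        })

    def jitter(n: int) -> np.ndarray:
        if noise.leaf_jitter_sd_mm == 0.0:
            return np.zeros(n)
        return rng.normal(0.0, noise.leaf_jitter_sd_mm, n)

    prev_gantry = beams[0].gantry_deg if beams else 0.0
    first_segment = beams[0].segments[0] if beams and beams[0].segments else None
    for _ in range(2):  # machine settling before the first beam
        if first_segment is not None:
            emit("Move Only", 0.0, prev_gantry,
                 first_segment.y1_mm + jitter(n_pairs),
                 first_segment.y2_mm + jitter(n_pairs),
                 first_segment.x1_mm, first_segment.x2_mm)

    for beam in beams:
        if abs(beam.gantry_deg - prev_gantry) > 1e-9 and beam.segments:
            seg0 = beam.segments[0]
            for frac in (0.33, 0.67, 1.0):  # gantry swing to the next angle
                g = prev_gantry + frac * ((beam.gantry_deg - prev_gantry + 540.0) % 360.0 - 180.0)
                emit("Move Only", 0.0, g % 360.0,
                     seg0.y1_mm + jitter(n_pairs), seg0.y2_mm + jitter(n_pairs),
                     seg0.x1_mm, seg0.x2_mm)
        prev_gantry = beam.gantry_deg

        for seg in beam.segments:
            open_pairs = (seg.y2_mm - seg.y1_mm) >= 0.1
            sys1 = np.zeros(n_pairs)
            sys2 = np.zeros(n_pairs)
            if noise.leaf_systematic_mm > 0.0:
                s = noise.leaf_systematic_mm
                sys1[open_pairs] = rng.uniform(-s, s, int(open_pairs.sum()))
                sys2[open_pairs] = rng.uniform(-s, s, int(open_pairs.sum()))
            if noise.bank_shift_mm != 0.0:
                shift = np.where(open_pairs, noise.bank_shift_mm, 0.0)
                if noise.bank_shift_bank == "y1":
                    sys1 += shift
                else:
                    sys2 += shift
            jaw_sys = (rng.uniform(-noise.jaw_systematic_mm, noise.jaw_systematic_mm, 2)
                       if noise.jaw_systematic_mm > 0.0 else np.zeros(2))
            mu_err = (rng.uniform(-noise.mu_error_mu, noise.mu_error_mu)
                      if noise.mu_error_mu > 0.0 else 0.0)
            mu_actual = max(0.5, seg.mu + mu_err)
            n_on = max(2, int(round(mu_actual / mu_per_sample)))

            interrupt_at = -1
            if noise.interruption_prob > 0.0 and rng.uniform() < noise.interruption_prob:
                interrupt_at = int(rng.integers(1, n_on))

            for _ in range(3):  # beam hold while the aperture settles
                emit("Intersegment", 0.0, beam.gantry_deg,
                     seg.y1_mm + sys1 + jitter(n_pairs),
                     seg.y2_mm + sys2 + jitter(n_pairs),
                     seg.x1_mm + jaw_sys[0], seg.x2_mm + jaw_sys[1])

            resumed_base = 0.0
            for k in range(n_on):
                if k == interrupt_at:
                    files.append([])  # therapist pause: the log restarts in a new file
                    resumed_base = mu_actual * k / n_on
                dose = mu_actual if k == n_on - 1 else mu_actual * (k + 1) / n_on
                emit("Radiation On", dose - resumed_base, beam.gantry_deg,
                     seg.y1_mm + sys1 + jitter(n_pairs),
                     seg.y2_mm + sys2 + jitter(n_pairs),
                     seg.x1_mm + jaw_sys[0], seg.x2_mm + jaw_sys[1])

    paths = []
    for i, rows in enumerate(files):
        if not rows:
            continue
        suffix = f"_{i:02d}" if len(files) > 1 else ""
        path = out_dir / f"{base_name}{suffix}.csv"
        _write_log_csv(rows, path, sample_period_ms, dialect)
        paths.append(path)

    if write_manifest:
        manifest = {
            "noise_model": asdict(noise),
            "sample_period_ms": sample_period_ms,
            "mu_per_sample": mu_per_sample,
            "files": [p.name for p in paths],
            "n_beams": len(beams),
            "n_segments": sum(len(b.segments) for b in beams),
        }
        (out_dir / f"{base_name}_manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths


def _write_log_csv(rows: list[dict], path: Path, period_ms: float,
                   dialect: LogDialect) -> None:
    n_pairs = len(rows[0]["y1"])
    data = {
        dialect.time_col: [period_ms * (i + 1) for i in range(len(rows))],
        dialect.state_col: [r["state"] for r in rows],
        dialect.dose_col: [r["dose"] for r in rows],
        dialect.gantry_col: [r["gantry"] for r in rows],
        dialect.x1_col: [r["x1"] for r in rows],
        dialect.x2_col: [r["x2"] for r in rows],
    }
    y1 = np.array([r["y1"] for r in rows])
    y2 = np.array([r["y2"] for r in rows])
    for i in range(n_pairs):
        data[f"{dialect.y1_prefix}{i:03d}"] = y1[:, i]
    for i in range(n_pairs):
        data[f"{dialect.y2_prefix}{i:03d}"] = y2[:, i]
    frame = pd.DataFrame(data)
    frame.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
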