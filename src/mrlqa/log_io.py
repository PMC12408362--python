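"""Delivery-log reading, merging, and segment extraction.

A delivery log is a CSV file of machine-state samples recorded every 40 ms
during treatment.  The dialect is fixed and documented here:

* header (comma separated, UTF-8, ``.`` decimal):
  ``time_ms,linac_state,step_dose_mu,gantry_deg,x1_mm,x2_mm,
  y1_000..y1_079,y2_000..y2_079``
* ``linac_state`` is one of ``Intersegment``, ``Move Only``, ``Radiation On``;
  radiation is produced only in the latter state.
* ``step_dose_mu`` accumulates MU within the current segment and resets to
  zero at beam deactivation.
* All positions are projected to the isocenter plane, in mm (IEC 61217).

Deliveries split over several files (sub-plans, or manual interruptions by
the therapist) are merged into one timeline by :func:`merge_logs`; segment
extraction then reduces the sample stream to one
:class:`DeliveredSegment` per contiguous beam-on run, with per-segment
averaging of leaf and jaw positions to suppress the optical tracking jitter.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import circmean

from .errors import FormatError, IntegrityError, UsageError
from .geometry import MachineGeometry

__all__ = [
    "LinacState",
    "LogDialect",
    "LogSample",
    "DeliveredSegment",
    "read_log_csv",
    "merge_logs",
    "extract_segments",
    "segments_to_frame",
]

N_LEAVES = 80


class LinacState(enum.Enum):
    INTERSEGMENT = "Intersegment"
    MOVE_ONLY = "Move Only"
    RADIATION_ON = "Radiation On"


@dataclass(frozen=True)
class LogDialect:
    """Column layout of the log CSV.

    The default matches the documented dialect above; a thin adapter for a
    different vendor export only needs to supply its own column names.
    """

    time_col: str = "time_ms"
    state_col: str = "linac_state"
    dose_col: str = "step_dose_mu"
    gantry_col: str = "gantry_deg"
    x1_col: str = "x1_mm"
    x2_col: str = "x2_mm"
    y1_prefix: str = "y1_"
    y2_prefix: str = "y2_"
    n_leaves: int = N_LEAVES

    def columns(self) -> list[str]:
        cols = [self.time_col, self.state_col, self.dose_col, self.gantry_col,
                self.x1_col, self.x2_col]
        cols += [f"{self.y1_prefix}{i:03d}" for i in range(self.n_leaves)]
        cols += [f"{self.y2_prefix}{i:03d}" for i in range(self.n_leaves)]
        return cols


DEFAULT_DIALECT = LogDialect()

_STATE_LOOKUP = {s.value: s for s in LinacState}


@dataclass
class LogSample:
    """One 40 ms machine-state record, positions at the isocenter plane (mm)."""

    time_ms: float
    linac_state: LinacState
    step_dose_mu: float
    gantry_deg: float
    y1_mm: np.ndarray  # (80,) bank Y1 leaf positions
    y2_mm: np.ndarray  # (80,) bank Y2 leaf positions
    x1_mm: float
    x2_mm: float
    source_file: int = 0  # provenance: index into the merged file list


@dataclass
class DeliveredSegment:
    """One delivered step-and-shoot segment recovered from the log.

    Leaf and jaw positions are means over the segment's beam-on samples;
    the standard deviations are kept for diagnostics (tracking jitter scale).
    """

    beam_key: float  # circular-mean gantry angle, degrees
    segment_index: int
    mu: float
    y1_mean_mm: np.ndarray
    y2_mean_mm: np.ndarray
    x1_mean_mm: float
    x2_mean_mm: float
    n_samples: int
    y1_sd_mm: np.ndarray = field(repr=False, default=None)
    y2_sd_mm: np.ndarray = field(repr=False, default=None)
    flags: tuple[str, ...] = ()


def read_log_csv(path: str | Path, dialect: LogDialect = DEFAULT_DIALECT) -> list[LogSample]:
    """Read one delivery-log CSV into an ordered list of samples.

    Raises :class:`FormatError` for a malformed header, empty file, unknown
    state string or unparseable number (with the offending column / row), and
    :class:`IntegrityError` if timestamps are not strictly increasing.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty log file") from None
    expected = dialect.columns()
    got = list(frame.columns)
    missing = [c for c in expected if c not in got]
    extra = [c for c in got if c not in expected]
    if missing or extra:
        raise FormatError(
            f"{path}: header mismatch (missing: {missing or 'none'}, extra: {extra or 'none'})"
        )
    if len(frame) == 0:
        raise FormatError(f"{path}: no samples")
    frame = frame[expected]

    numeric_cols = [c for c in expected if c != dialect.state_col]
    numeric = frame[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        col = bad.columns[int(np.argmax(bad.iloc[row].to_numpy()))]
        raise FormatError(f"{path}: unparseable value in column '{col}' at data row {row}")

    states = []
    for row, raw in enumerate(frame[dialect.state_col]):
        state = _STATE_LOOKUP.get(str(raw).strip())
        if state is None:
            raise FormatError(f"{path}: unknown linac state {raw!r} at data row {row}")
        states.append(state)

    times = numeric[dialect.time_col].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        row = int(np.argmax(np.diff(times) <= 0)) + 1
        raise IntegrityError(f"{path}: timestamps not strictly increasing at data row {row}")

    y1_cols = [f"{dialect.y1_prefix}{i:03d}" for i in range(dialect.n_leaves)]
    y2_cols = [f"{dialect.y2_prefix}{i:03d}" for i in range(dialect.n_leaves)]
    y1 = numeric[y1_cols].to_numpy(float)
    y2 = numeric[y2_cols].to_numpy(float)
    dose = numeric[dialect.dose_col].to_numpy(float)
    gantry = np.mod(numeric[dialect.gantry_col].to_numpy(float), 360.0)
    x1 = numeric[dialect.x1_col].to_numpy(float)
    x2 = numeric[dialect.x2_col].to_numpy(float)

    return [
        LogSample(
            time_ms=float(times[i]),
            linac_state=states[i],
            step_dose_mu=float(dose[i]),
            gantry_deg=float(gantry[i]),
            y1_mm=y1[i],
            y2_mm=y2[i],
            x1_mm=float(x1[i]),
            x2_mm=float(x2[i]),
        )
        for i in range(len(frame))
    ]


def merge_logs(
    paths: Sequence[str | Path],
    dialect: LogDialect = DEFAULT_DIALECT,
    gap_ms: float = 40.0,
) -> list[LogSample]:
    """Concatenate several log files into one strictly increasing timeline.

    Each file keeps its internal sample order; a per-file offset (previous
    end + one sample period) is added to the timestamps.  Every sample
    records the index of its source file so segment extraction can recognise
    interruptions at file boundaries.
    """
    if len(paths) == 0:
        raise UsageError("merge_logs requires at least one log file")
    merged: list[LogSample] = []
    offset = 0.0
    for file_idx, path in enumerate(paths):
        samples = read_log_csv(path, dialect)
        for s in samples:
            s.time_ms += offset
            s.source_file = file_idx
        merged.extend(samples)
        offset = merged[-1].time_ms + gap_ms
    return merged


def _run_bounds(samples: Sequence[LogSample]) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of maximal contiguous beam-on runs.

    A file boundary inside a beam-on stretch splits the run: the step dose
    restarts with the new file, so each side carries its own maximum.
    """
    runs = []
    start = None
    for i, s in enumerate(samples):
        on = s.linac_state is LinacState.RADIATION_ON
        if on and start is not None and s.source_file != samples[i - 1].source_file:
            runs.append((start, i))
            start = i
            continue
        if on and start is None:
            start = i
        elif not on and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(samples)))
    return runs


def _circular_diff_deg(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def extract_segments(
    samples: Sequence[LogSample],
    geometry: MachineGeometry,
    gantry_tol_deg: float = 0.5,
) -> list[DeliveredSegment]:
    """Reduce a sample stream to delivered segments via the linac-state machine.

    Each maximal contiguous beam-on run is one segment: its MU is the maximum
    step dose within the run (the step dose accumulates within a segment and
    resets at beam-off), and leaf/jaw positions are averaged over the run's
    samples only.  Two consecutive runs separated solely by a file boundary
    (no intervening Intersegment state) at the same gantry angle are an
    interrupted segment and are merged, with MU = sum of the per-run maxima.

    Runs that accumulate zero MU are dropped with a warning; runs whose
    gantry spread exceeds ``gantry_tol_deg`` are flagged.
    """
    runs = _run_bounds(samples)

    # Merge interrupted runs: file boundary between them, same gantry,
    # and no Intersegment sample in the gap.
    groups: list[list[tuple[int, int]]] = []
    for run in runs:
        if groups:
            prev = groups[-1][-1]
            gap = samples[prev[1]:run[0]]
            boundary = samples[run[0]].source_file != samples[prev[1] - 1].source_file
            no_interseg = all(s.linac_state is not LinacState.INTERSEGMENT for s in gap)
            g_prev = _run_gantry(samples, prev)
            g_this = _run_gantry(samples, run)
            if boundary and no_interseg and _circular_diff_deg(g_prev, g_this) <= gantry_tol_deg:
                groups[-1].append(run)
                continue
        groups.append([run])

    segments: list[DeliveredSegment] = []
    for group in groups:
        mu = sum(max(s.step_dose_mu for s in samples[a:b]) for a, b in group)
        if mu <= 0.0:
            warnings.warn(
                "beam-on run with zero step dose dropped (integrity anomaly)",
                stacklevel=2,
            )
            continue
        pooled = [s for a, b in group for s in samples[a:b]]
        y1 = np.array([s.y1_mm for s in pooled])
        y2 = np.array([s.y2_mm for s in pooled])
        gantry = np.array([s.gantry_deg for s in pooled])
        beam_key = float(circmean(gantry, high=360.0, low=0.0))
        flags = []
        if len(group) > 1:
            flags.append("merged_interruption")
        spread = max(_circular_diff_deg(float(g), beam_key) for g in gantry)
        if spread > gantry_tol_deg:
            flags.append("gantry_spread")
        segments.append(
            DeliveredSegment(
                beam_key=beam_key,
                segment_index=len(segments),
                mu=float(mu),
                y1_mean_mm=y1.mean(axis=0),
                y2_mean_mm=y2.mean(axis=0),
                x1_mean_mm=float(np.mean([s.x1_mm for s in pooled])),
                x2_mean_mm=float(np.mean([s.x2_mm for s in pooled])),
                n_samples=len(pooled),
                y1_sd_mm=y1.std(axis=0, ddof=0),
                y2_sd_mm=y2.std(axis=0, ddof=0),
                flags=tuple(flags),
            )
        )
    return segments


def _run_gantry(samples: Sequence[LogSample], run: tuple[int, int]) -> float:
    return float(circmean([s.gantry_deg for s in samples[run[0]:run[1]]], high=360.0, low=0.0))


def segments_to_frame(segments: Iterable[DeliveredSegment]) -> pd.DataFrame:
    """Debug dump: one row per segment, mirroring the DeliveredSegment fields."""
    rows = []
    for seg in segments:
        row = {
            "beam_key_deg": seg.beam_key,
            "segment_index": seg.segment_index,
            "mu": seg.mu,
            "x1_mean_mm": seg.x1_mean_mm,
            "x2_mean_mm": seg.x2_mean_mm,
            "n_samples": seg.n_samples,
            "flags": ";".join(seg.flags),
        }
        for i in range(len(seg.y1_mean_mm)):
            row[f"y1_{i:03d}"] = seg.y1_mean_mm[i]
            row[f"y2_{i:03d}"] = seg.y2_mean_mm[i]
        rows.append(row)
    return pd.DataFrame(rows)
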