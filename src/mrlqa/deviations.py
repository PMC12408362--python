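"""Plan-versus-log deviation statistics: MU, jaws, per-leaf max and RMS.

Deviations are signed plan − log (positive means the plan value is larger).
Leaf statistics aggregate over the matched segments of the whole delivery:

    max_dev_i = max_j | Y_log,i,j − Y_plan,i,j |
    rms_i     = sqrt( (1/m) * sum_j ( Y_log,i,j − Y_plan,i,j )^2 )

for leaf i over the m matched segments j.  Leaf pairs that are closed in
both plan and log for a given segment contribute nothing for that segment
(their tracked positions are dosimetrically irrelevant); this exclusion can
be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PairingError
from .log_io import DeliveredSegment
from .plan_io import PlannedBeam, PlannedSegment

__all__ = [
    "SegmentPair",
    "SegmentPairing",
    "DeviationReport",
    "match_segments",
    "mu_and_jaw_deviations",
    "leaf_rms",
    "leaf_max_deviation",
    "compute_deviation_report",
]

CLOSED_GAP_MM = 0.1  # a pair with a smaller open interval counts as closed


def _circ_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


@dataclass
class SegmentPair:
    beam_index: int
    gantry_deg: float
    plan: PlannedSegment
    log: DeliveredSegment


@dataclass
class SegmentPairing:
    pairs: list[SegmentPair]

    @property
    def m(self) -> int:
        return len(self.pairs)

    def by_beam(self) -> dict[int, list[SegmentPair]]:
        out: dict[int, list[SegmentPair]] = {}
        for p in self.pairs:
            out.setdefault(p.beam_index, []).append(p)
        return out


def match_segments(
    plan_beams: list[PlannedBeam],
    delivered: list[DeliveredSegment],
    gantry_tol_deg: float = 0.5,
) -> SegmentPairing:
    """Pair plan and log segments by gantry angle and within-beam order.

    Each delivered segment is assigned to the plan beam whose gantry angle
    is nearest (must be within tolerance); within a beam, segments pair in
    delivery order.  A count mismatch or an unassignable segment raises
    :class:`PairingError` naming the beam — itself a QA failure.
    """
    per_beam_log: dict[int, list[DeliveredSegment]] = {i: [] for i in range(len(plan_beams))}
    orphans = []
    for seg in delivered:
        dists = [_circ_diff(seg.beam_key, b.gantry_deg) for b in plan_beams]
        best = int(np.argmin(dists)) if dists else -1
        if best < 0 or dists[best] > gantry_tol_deg:
            orphans.append(seg)
        else:
            per_beam_log[best].append(seg)
    if orphans:
        angles = sorted({round(s.beam_key, 2) for s in orphans})
        raise PairingError(
            f"{len(orphans)} delivered segment(s) at gantry {angles} match no planned beam"
        )

    pairs: list[SegmentPair] = []
    problems = []
    for i, beam in enumerate(plan_beams):
        logs = per_beam_log[i]
        if len(logs) != len(beam.segments):
            problems.append(
                f"beam at gantry {beam.gantry_deg:g} deg: {len(beam.segments)} planned "
                f"vs {len(logs)} delivered segments"
            )
            continue
        for pseg, lseg in zip(beam.segments, logs):
            pairs.append(SegmentPair(i, beam.gantry_deg, pseg, lseg))
    if problems:
        raise PairingError("segment count mismatch: " + "; ".join(problems))
    return SegmentPairing(pairs=pairs)


def mu_and_jaw_deviations(pairing: SegmentPairing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per matched segment: (plan − log) for MU, X1 and X2 jaws."""
    mu = np.array([p.plan.mu - p.log.mu for p in pairing.pairs])
    x1 = np.array([p.plan.x1_mm - p.log.x1_mean_mm for p in pairing.pairs])
    x2 = np.array([p.plan.x2_mm - p.log.x2_mean_mm for p in pairing.pairs])
    return mu, x1, x2


def _leaf_difference_matrix(
    pairing: SegmentPairing, exclude_closed: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(m, 160) log − plan leaf differences and an (m, 160) inclusion mask.

    Columns 0..79 are bank Y1, 80..159 bank Y2; a pair closed in both plan
    and log yields an excluded entry for both of its leaves.
    """
    m = pairing.m
    n = len(pairing.pairs[0].plan.y1_mm) if m else 0
    diffs = np.zeros((m, 2 * n))
    include = np.ones((m, 2 * n), bool)
    for j, p in enumerate(pairing.pairs):
        diffs[j, :n] = p.log.y1_mean_mm - p.plan.y1_mm
        diffs[j, n:] = p.log.y2_mean_mm - p.plan.y2_mm
        if exclude_closed:
            plan_closed = (p.plan.y2_mm - p.plan.y1_mm) < CLOSED_GAP_MM
            log_closed = (p.log.y2_mean_mm - p.log.y1_mean_mm) < CLOSED_GAP_MM
            closed = plan_closed & log_closed
            include[j, :n] = ~closed
            include[j, n:] = ~closed
    return diffs, include


def leaf_rms(pairing: SegmentPairing, exclude_closed: bool = True) -> np.ndarray:
    """Per-leaf RMS of (log − plan) over matched segments (160 entries).

    The divisor is the number of included segments for that leaf; leaves with
    no included segment report NaN (missing).
    """
    diffs, include = _leaf_difference_matrix(pairing, exclude_closed)
    counts = include.sum(axis=0)
    sq = np.where(include, diffs**2, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(sq / counts)
    out[counts == 0] = np.nan
    return out


def leaf_max_deviation(pairing: SegmentPairing, exclude_closed: bool = True) -> np.ndarray:
    """Per-leaf maximum |log − plan| over matched segments (160 entries)."""
    diffs, include = _leaf_difference_matrix(pairing, exclude_closed)
    mag = np.where(include, np.abs(diffs), -np.inf).max(axis=0)
    mag[~np.isfinite(mag)] = np.nan
    return mag


@dataclass
class DeviationReport:
    """All plan-vs-log deviation tables for one delivery."""

    mu_dev: np.ndarray
    x1_dev: np.ndarray
    x2_dev: np.ndarray
    leaf_max_dev: np.ndarray  # 160 entries: Y1 leaves then Y2 leaves
    leaf_rms: np.ndarray
    n_segments: int
    excluded_closed: bool = True
    segment_gantry: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        finite = np.isfinite(self.leaf_rms) & np.isfinite(self.leaf_max_dev)
        assert np.all(self.leaf_rms[finite] <= self.leaf_max_dev[finite] + 1e-12)

    def summary(self) -> dict:
        finite_rms = self.leaf_rms[np.isfinite(self.leaf_rms)]
        finite_max = self.leaf_max_dev[np.isfinite(self.leaf_max_dev)]
        order = np.argsort(np.nan_to_num(self.leaf_rms, nan=-1.0))[::-1][:5]
        return {
            "max_abs_mu_dev": float(np.abs(self.mu_dev).max()) if self.mu_dev.size else None,
            "max_abs_jaw_dev_mm": float(
                max(np.abs(self.x1_dev).max(), np.abs(self.x2_dev).max())
            ) if self.x1_dev.size else None,
            "max_leaf_dev_mm": float(finite_max.max()) if finite_max.size else None,
            "max_leaf_rms_mm": float(finite_rms.max()) if finite_rms.size else None,
            "top_rms_leaves": [_leaf_name(int(i)) for i in order],
            "n_segments": self.n_segments,
        }

    def segment_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gantry_deg": self.segment_gantry,
            "mu_dev": self.mu_dev,
            "x1_dev_mm": self.x1_dev,
            "x2_dev_mm": self.x2_dev,
        })

    def leaf_frame(self) -> pd.DataFrame:
        names = [_leaf_name(i) for i in range(len(self.leaf_rms))]
        return pd.DataFrame({
            "leaf": names,
            "max_dev_mm": self.leaf_max_dev,
            "rms_mm": self.leaf_rms,
        })


def _leaf_name(i: int) -> str:
    return f"Y1_{i:02d}" if i < 80 else f"Y2_{i - 80:02d}"


def compute_deviation_report(
    pairing: SegmentPairing, exclude_closed: bool = True
) -> DeviationReport:
    mu, x1, x2 = mu_and_jaw_deviations(pairing)
    return DeviationReport(
        mu_dev=mu,
        x1_dev=x1,
        x2_dev=x2,
        leaf_max_dev=leaf_max_deviation(pairing, exclude_closed),
        leaf_rms=leaf_rms(pairing, exclude_closed),
        n_segments=pairing.m,
        excluded_closed=exclude_closed,
        segment_gantry=np.array([p.gantry_deg for p in pairing.pairs]),
    )
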