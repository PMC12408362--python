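"""End-to-end QA pipeline: plan + log in, per-gantry verdicts out.

The pipeline runs read -> merge -> extract -> match -> deviations ->
fluence (plan and log, per gantry angle) -> gamma + Pearson -> report.
Any stage failure is surfaced with the stage name and turns the overall
verdict into FAIL with a reason rather than propagating an exception.

Verdicts per gantry angle:

* gamma PASS iff the passing rate is strictly above 98% (a rate of exactly
  98.0 fails),
* Pearson PASS iff r >= 0.985 (the threshold itself is acceptable),

and the overall verdict is PASS iff every per-gantry verdict passes and
segment pairing raised no error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import QAConfig
from .deviations import DeviationReport, compute_deviation_report, match_segments
from .errors import QAError
from .fluence import FluenceGrid, aperture_of, compute_fluence, grid_for_apertures
from .gamma import gamma_map, pearson_correlation
from .log_io import extract_segments, merge_logs
from .plan_io import read_rtplan

__all__ = ["PerGantryResult", "QAReport", "run_qa", "write_report", "read_report"]

log = logging.getLogger("mrlqa")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PerGantryResult:
    gantry_deg: float
    gamma_passing_rate_percent: float
    gamma_verdict: str
    pearson_r: float
    pearson_verdict: str
    n_evaluated: int
    n_segments: int


@dataclass
class QAReport:
    per_gantry: list[PerGantryResult]
    deviation_summary: dict
    provenance: dict
    overall_verdict: str
    errors: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    schema_version: int = REPORT_SCHEMA_VERSION
    # transient artefacts, not serialized:
    deviation_report: DeviationReport | None = field(default=None, repr=False, compare=False)
    fluence_maps: list[tuple[FluenceGrid, FluenceGrid, np.ndarray]] = field(
        default_factory=list, repr=False, compare=False
    )

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "overall_verdict": self.overall_verdict,
            "per_gantry": [asdict(g) for g in self.per_gantry],
            "deviation_summary": self.deviation_summary,
            "provenance": self.provenance,
            "errors": self.errors,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "QAReport":
        return cls(
            per_gantry=[PerGantryResult(**g) for g in data["per_gantry"]],
            deviation_summary=data["deviation_summary"],
            provenance=data["provenance"],
            overall_verdict=data["overall_verdict"],
            errors=data.get("errors", []),
            notes=data.get("notes", []),
            schema_version=data.get("schema_version", REPORT_SCHEMA_VERSION),
        )


def _config_hash(config: QAConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_qa(
    plan_paths: Sequence[str | Path],
    log_paths: Sequence[str | Path],
    config: QAConfig | None = None,
    keep_maps: bool = False,
) -> QAReport:
    """Run the full log-file QA pipeline and return the report.

    ``keep_maps`` retains the per-gantry (plan, log, gamma) maps on the
    report object for rendering; they are never serialized.
    """
    config = config or QAConfig()
    geometry = config.geometry()
    criteria = config.criteria()
    provenance = {
        "plan_files": [str(p) for p in plan_paths],
        "log_files": [str(p) for p in log_paths],
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "tool_version": __version__,
        "resolution_mm": config.resolution_mm,
    }

    def failed(stage: str, exc: Exception) -> QAReport:
        log.error("stage %s failed: %s", stage, exc)
        return QAReport(
            per_gantry=[],
            deviation_summary={},
            provenance=provenance,
            overall_verdict="FAIL",
            errors=[f"{stage}: {exc}"],
        )

    notes: list[str] = []
    try:
        beams = read_rtplan(list(plan_paths), geometry, swap_banks=config.swap_leaf_banks)
    except QAError as exc:
        return failed("read_rtplan", exc)
    try:
        samples = merge_logs(list(log_paths))
        delivered = extract_segments(samples, geometry, config.gantry_tol_deg)
    except QAError as exc:
        return failed("log_extraction", exc)
    for seg in delivered:
        for flag in seg.flags:
            notes.append(f"log segment {seg.segment_index} "
                         f"(gantry {seg.beam_key:.1f}): {flag}")
            log.info("segment %d flagged: %s", seg.segment_index, flag)

    try:
        pairing = match_segments(beams, delivered, config.gantry_tol_deg)
    except QAError as exc:
        return failed("match_segments", exc)

    deviation_report = compute_deviation_report(pairing, config.exclude_closed_pairs)

    per_gantry: list[PerGantryResult] = []
    maps = []
    pairs_by_beam = pairing.by_beam()
    for i, beam in enumerate(beams):
        pairs = pairs_by_beam.get(i, [])
        plan_aps = [aperture_of(p.plan) for p in pairs]
        log_aps = [aperture_of(p.log) for p in pairs]
        grid = grid_for_apertures(plan_aps + log_aps, geometry, config.resolution_mm,
                                  config.grid_margin_mm, config.full_field)
        f_plan = compute_fluence(plan_aps, geometry, grid=grid, gantry_deg=beam.gantry_deg)
        f_log = compute_fluence(log_aps, geometry, grid=grid, gantry_deg=beam.gantry_deg)
        gres = gamma_map(f_plan, f_log, criteria)
        r = pearson_correlation(f_plan, f_log, config.pearson_mask,
                                criteria.threshold_fraction)
        gamma_ok = gres.passing_rate_percent > config.gamma_pass_percent
        pearson_ok = bool(np.isfinite(r)) and r >= config.pearson_pass_r
        per_gantry.append(PerGantryResult(
            gantry_deg=beam.gantry_deg,
            gamma_passing_rate_percent=gres.passing_rate_percent,
            gamma_verdict="PASS" if gamma_ok else "FAIL",
            pearson_r=float(r),
            pearson_verdict="PASS" if pearson_ok else "FAIL",
            n_evaluated=gres.n_evaluated,
            n_segments=len(pairs),
        ))
        if keep_maps:
            maps.append((f_plan, f_log, gres.gamma_map))

    ok = all(g.gamma_verdict == "PASS" for g in per_gantry)
    if config.combine_pearson_in_verdict:
        ok = ok and all(g.pearson_verdict == "PASS" for g in per_gantry)
    return QAReport(
        per_gantry=per_gantry,
        deviation_summary=deviation_report.summary(),
        provenance=provenance,
        overall_verdict="PASS" if ok else "FAIL",
        notes=notes,
        deviation_report=deviation_report,
        fluence_maps=maps,
    )


def write_report(report: QAReport, out_dir: str | Path, render_png: bool = False) -> Path:
    """Serialize the report: JSON, per-gantry CSV and deviation CSVs.

    Returns the path of the JSON report.  If the report still carries its
    fluence maps and ``render_png`` is set, per-gantry fluence/gamma panels
    are rendered alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=1))

    pd.DataFrame([asdict(g) for g in report.per_gantry]).to_csv(
        out_dir / "per_gantry.csv", index=False
    )
    if report.deviation_report is not None:
        report.deviation_report.segment_frame().to_csv(
            out_dir / "deviations_segments.csv", index=False
        )
        report.deviation_report.leaf_frame().to_csv(
            out_dir / "deviations_leaves.csv", index=False
        )
    if render_png and report.fluence_maps:
        for f_plan, f_log, _ in report.fluence_maps:
            tag = f"g{f_plan.gantry_deg:05.1f}".replace(".", "p")
            f_plan.render_png(out_dir / f"fluence_plan_{tag}.png",
                              f"Plan fluence, gantry {f_plan.gantry_deg:g} deg")
            f_log.render_png(out_dir / f"fluence_log_{tag}.png",
                             f"Log fluence, gantry {f_log.gantry_deg:g} deg")
    return json_path


def read_report(path: str | Path) -> QAReport:
    """Inverse of :func:`write_report` for the JSON part."""
    return QAReport.from_dict(json.loads(Path(path).read_text()))
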