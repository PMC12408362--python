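"""DICOM RT Plan I/O for static-gantry step-and-shoot beams.

The reader accepts plans whose beams each hold a fixed gantry angle and
shape every segment with one X jaw pair plus two opposing banks of 80 leaves
travelling in IEC Y (DICOM beam-limiting device types ``X``/``ASYMX`` and
``MLCY``).  Segment MU follows the DICOM meterset-weight convention:

    mu_k = beam_meterset * (w[k+1] - w[k]) / w_final

with leaf and jaw positions taken from the segment's opening control point
(positions omitted on a control point carry forward, per the standard).

Plans split into several sub-plan files are read as one delivery by passing
the file paths in delivery order; beams and segments concatenate in file
order, mirroring how split delivery logs are merged.

The writer emits a minimal standards-conformant RTPLAN (one control point
per segment plus a closing weight-only point) and is deterministic: fixed
creation dates and UIDs derived from a caller-supplied entropy string, so
identical inputs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, GeometryMismatchError, IntegrityError, UnsupportedPlanError
from .geometry import MachineGeometry

__all__ = ["PlannedSegment", "PlannedBeam", "read_rtplan", "write_rtplan"]

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
_MU_TOL = 1e-3


@dataclass
class PlannedSegment:
    """One planned step-and-shoot segment (positions in mm at the isocenter plane)."""

    beam_key: float  # planned gantry angle, degrees
    segment_index: int
    mu: float
    y1_mm: np.ndarray
    y2_mm: np.ndarray
    x1_mm: float
    x2_mm: float


@dataclass
class PlannedBeam:
    gantry_deg: float
    segments: list[PlannedSegment]
    beam_mu: float


def read_rtplan(
    paths: str | Path | Sequence[str | Path],
    geometry: MachineGeometry,
    swap_banks: bool = False,
) -> list[PlannedBeam]:
    """Read one or more RTPLAN files into planned beams in delivery order.

    ``swap_banks`` exchanges the Y1/Y2 bank assignment for vendors whose
    leaf-position ordering differs from the default (bank 1 -> Y1).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    beams: list[PlannedBeam] = []
    for path in paths:
        beams.extend(_read_single(Path(path), geometry, swap_banks))
    return beams


def _read_single(path: Path, geometry: MachineGeometry, swap_banks: bool) -> list[PlannedBeam]:
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several types for junk input
        raise FormatError(f"{path}: not a readable DICOM file ({exc})") from None
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise FormatError(f"{path}: not an RTPLAN (Modality={getattr(ds, 'Modality', None)!r})")

    metersets = _beam_metersets(ds, path)

    beams = []
    beam_items = sorted(ds.BeamSequence, key=lambda b: int(b.BeamNumber))
    for beam in beam_items:
        number = int(beam.BeamNumber)
        if number not in metersets:
            raise FormatError(f"{path}: beam {number} has no referenced meterset")
        beams.append(_read_beam(beam, metersets[number], geometry, swap_banks, path))
    return beams


def _beam_metersets(ds: Dataset, path: Path) -> dict[int, float]:
    out: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for ref in getattr(fg, "ReferencedBeamSequence", []):
            out[int(ref.ReferencedBeamNumber)] = float(ref.BeamMeterset)
    if not out:
        raise FormatError(f"{path}: no FractionGroup beam metersets")
    return out


def _read_beam(
    beam: Dataset,
    meterset: float,
    geometry: MachineGeometry,
    swap_banks: bool,
    path: Path,
) -> PlannedBeam:
    cps = list(beam.ControlPointSequence)
    if len(cps) < 2:
        raise FormatError(f"{path}: beam {beam.BeamNumber} has fewer than 2 control points")

    gantries = [float(cp.GantryAngle) for cp in cps if hasattr(cp, "GantryAngle")]
    if not gantries:
        raise FormatError(f"{path}: beam {beam.BeamNumber} has no gantry angle")
    if max(gantries) - min(gantries) > 1e-6:
        raise UnsupportedPlanError(
            f"{path}: beam {beam.BeamNumber} has a dynamic gantry; only static-gantry "
            "step-and-shoot plans are supported"
        )
    gantry = gantries[0] % 360.0

    final_weight = float(beam.FinalCumulativeMetersetWeight)
    weights = [float(cp.CumulativeMetersetWeight) for cp in cps]
    if any(np.diff(weights) < 0):
        raise IntegrityError(f"{path}: beam {beam.BeamNumber} meterset weights decrease")
    if final_weight <= 0 or abs(weights[-1] - final_weight) > 1e-6 * max(final_weight, 1.0):
        raise IntegrityError(
            f"{path}: beam {beam.BeamNumber} final cumulative weight {final_weight} "
            f"does not match the last control point ({weights[-1]})"
        )

    n = geometry.n_leaf_pairs
    x_jaws: tuple[float, float] | None = None
    leaves: np.ndarray | None = None
    segments: list[PlannedSegment] = []
    for k in range(len(cps) - 1):
        x_jaws, leaves = _positions_at(cps[k], x_jaws, leaves, n, path, beam.BeamNumber)
        if x_jaws is None or leaves is None:
            raise FormatError(
                f"{path}: beam {beam.BeamNumber} control point {k} lacks jaw or leaf positions"
            )
        y1 = leaves[:n].copy()
        y2 = leaves[n:].copy()
        if swap_banks:
            y1, y2 = y2, y1
        mu = meterset * (weights[k + 1] - weights[k]) / final_weight
        segments.append(
            PlannedSegment(
                beam_key=gantry,
                segment_index=k,
                mu=mu,
                y1_mm=y1,
                y2_mm=y2,
                x1_mm=x_jaws[0],
                x2_mm=x_jaws[1],
            )
        )

    total = sum(s.mu for s in segments)
    if abs(total - meterset) > _MU_TOL:
        raise IntegrityError(
            f"{path}: beam {beam.BeamNumber} segment MUs sum to {total:.4f}, "
            f"meterset is {meterset:.4f}"
        )
    return PlannedBeam(gantry_deg=gantry, segments=segments, beam_mu=meterset)


def _positions_at(cp, x_jaws, leaves, n_pairs, path, beam_number):
    for item in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        kind = item.RTBeamLimitingDeviceType
        vals = [float(v) for v in item.LeafJawPositions]
        if kind in ("X", "ASYMX"):
            if len(vals) != 2:
                raise FormatError(f"{path}: beam {beam_number}: X jaw needs 2 positions")
            x_jaws = (vals[0], vals[1])
        elif kind.startswith("MLC"):
            if len(vals) != 2 * n_pairs:
                raise GeometryMismatchError(
                    f"{path}: beam {beam_number}: {len(vals)} leaf positions, "
                    f"expected {2 * n_pairs}"
                )
            leaves = np.asarray(vals, float)
    return x_jaws, leaves


# ---------------------------------------------------------------------------
# Writer


def write_rtplan(
    beams: Sequence[PlannedBeam],
    path: str | Path,
    geometry: MachineGeometry,
    plan_label: str = "MRLQA-SYN",
    entropy: str = "mrlqa",
) -> Path:
    """Write beams as a minimal RTPLAN file (deterministic for fixed entropy).

    Positions are rounded to 0.001 mm and meterset weights to 1e-6 when
    encoded, so a write/read round trip is lossless to 1e-3 mm / 1e-3 MU.
    """
    path = Path(path)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[entropy, "sop"])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = generate_uid(entropy_srcs=["mrlqa-impl"])

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SYN0000"
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[entropy, "study"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[entropy, "series"])
    ds.FrameOfReferenceUID = generate_uid(entropy_srcs=[entropy, "frame"])
    ds.StudyID = "1"
    ds.SeriesNumber = 1
    ds.StudyDate = "20250101"
    ds.StudyTime = "120000"
    ds.InstanceCreationDate = "20250101"
    ds.InstanceCreationTime = "120000"
    ds.Manufacturer = "mrlqa synthetic delivery generator"
    ds.ReferringPhysicianName = ""
    ds.AccessionNumber = ""
    ds.PositionReferenceIndicator = ""
    ds.RTPlanLabel = plan_label
    ds.RTPlanDate = "20250101"
    ds.RTPlanTime = "120000"
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(beams)
    fg.NumberOfBrachyApplicationSetups = 0
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for bnum, beam in enumerate(beams, start=1):
        beam_ds = _beam_dataset(beam, bnum, geometry)
        ref = Dataset()
        ref.ReferencedBeamNumber = bnum
        ref.BeamMeterset = float(beam_ds.FinalCumulativeMetersetWeight)
        fg.ReferencedBeamSequence.append(ref)
        ds.BeamSequence.append(beam_ds)

    ds.save_as(str(path), enforce_file_format=True)
    return path


def _beam_dataset(beam: PlannedBeam, bnum: int, geometry: MachineGeometry) -> Dataset:
    b = Dataset()
    b.BeamNumber = bnum
    b.BeamName = f"B{bnum:02d}"
    b.BeamType = "STATIC"
    b.RadiationType = "PHOTON"
    b.TreatmentMachineName = "UnitySim"
    b.TreatmentDeliveryType = "TREATMENT"
    b.PrimaryDosimeterUnit = "MU"
    b.SourceAxisDistance = round(geometry.sad_cm * 10.0, 1)  # DICOM uses mm
    b.NumberOfWedges = 0
    b.NumberOfCompensators = 0
    b.NumberOfBoli = 0
    b.NumberOfBlocks = 0

    jaw_dev = Dataset()
    jaw_dev.RTBeamLimitingDeviceType = "ASYMX"
    jaw_dev.NumberOfLeafJawPairs = 1
    mlc_dev = Dataset()
    mlc_dev.RTBeamLimitingDeviceType = "MLCY"
    mlc_dev.NumberOfLeafJawPairs = geometry.n_leaf_pairs
    mlc_dev.LeafPositionBoundaries = [round(float(e), 3) for e in geometry.leaf_edges_x_mm]
    b.BeamLimitingDeviceSequence = [jaw_dev, mlc_dev]

    # Cumulative weights carried in MU (final weight = beam meterset),
    # accumulated in integer milli-MU so every encoded weight is the
    # canonical double of a 3-decimal value: the reader's weight-difference
    # arithmetic then reproduces segment MUs to float round-off instead of
    # a normalisation-rounding error.
    milli = np.concatenate([[0], np.cumsum([int(round(s.mu * 1000)) for s in beam.segments])])
    weights = milli / 1000.0
    total = float(weights[-1])

    cps = []
    for k, seg in enumerate(beam.segments):
        cp = Dataset()
        cp.ControlPointIndex = k
        cp.CumulativeMetersetWeight = float(weights[k])
        if k == 0:
            cp.GantryAngle = round(beam.gantry_deg, 4)
            cp.GantryRotationDirection = "NONE"
            cp.BeamLimitingDeviceAngle = 0.0
            cp.BeamLimitingDeviceRotationDirection = "NONE"
            cp.PatientSupportAngle = 0.0
            cp.PatientSupportRotationDirection = "NONE"
            cp.NominalBeamEnergy = 7.0
            cp.DoseRateSet = 425.0
            cp.IsocenterPosition = [0.0, 0.0, 0.0]
        jaw = Dataset()
        jaw.RTBeamLimitingDeviceType = "ASYMX"
        jaw.LeafJawPositions = [round(float(seg.x1_mm), 3), round(float(seg.x2_mm), 3)]
        mlc = Dataset()
        mlc.RTBeamLimitingDeviceType = "MLCY"
        mlc.LeafJawPositions = [
            round(float(v), 3) for v in np.concatenate([seg.y1_mm, seg.y2_mm])
        ]
        cp.BeamLimitingDevicePositionSequence = [jaw, mlc]
        cps.append(cp)

    closing = Dataset()
    closing.ControlPointIndex = len(beam.segments)
    closing.CumulativeMetersetWeight = total
    cps.append(closing)

    b.NumberOfControlPoints = len(cps)
    b.FinalCumulativeMetersetWeight = total
    b.ControlPointSequence = cps
    return b
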