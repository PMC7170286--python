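"""Vendor-neutral in-memory representation of a radiotherapy treatment plan.

The model is assembled from up to four files:

* a DICOM RT Plan (required) — beams, control points, MLC/jaw positions,
  metersets, tolerance-table labels, bolus references, table-top positions;
* a DICOM RT Dose (optional) — dose-grid resolution;
* a DICOM RT Structure Set (optional) — couch/bolus structures and
  CT density overrides;
* a YAML "sidecar" (required for a full context) — fields that live in the
  treatment-planning-system database rather than in DICOM exports: course
  name and intent, approval status, DRR presence/overlay, calculation model
  names, imager positions for setup fields, reference points and QA-plan
  linkage.  The schema is documented in ``docs/sidecar.md``.

Conventions: positions are millimetres in the DICOM patient coordinate
system, angles are IEC 61217 degrees normalised to [0, 360), doses are Gy
and metersets MU.  Fields a loader cannot see are left ``None`` ("unknown");
downstream checkers treat unknown as "insufficient data" and flag rather
than silently pass.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
import yaml
from pydicom.errors import InvalidDicomError

__all__ = [
    "PlanStatus",
    "CourseIntent",
    "DeliveryKind",
    "BeamRole",
    "QAKind",
    "ControlPoint",
    "Beam",
    "ReferencePoint",
    "QAPlanContext",
    "PlanContext",
    "PlanModelError",
    "PlanFormatError",
    "PlanStructureError",
    "PlanValidationError",
    "SidecarError",
    "LinkageError",
    "load_rtplan",
    "load_sidecar",
    "load_dose_grid",
    "load_structures",
    "assemble_context",
    "validate_context",
]

#: beams whose delivery type does not say SETUP are still classified as setup
#: fields when their name matches this pattern (exports vary between vendors).
DEFAULT_SETUP_NAME_REGEX = r"(?i)^(setup|su[_ -]|su$)"

ISOCENTER_TOLERANCE_MM = 0.01


class PlanModelError(Exception):
    """Base class for loader errors."""


class PlanFormatError(PlanModelError):
    """The file is not the DICOM object the loader expected."""


class PlanStructureError(PlanModelError):
    """A required DICOM element is missing; the message names it."""


class PlanValidationError(PlanModelError):
    """A structural invariant of the plan model is violated."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class SidecarError(PlanModelError):
    """The sidecar file is malformed; the message carries the key."""


class LinkageError(PlanModelError):
    """A file references a different plan than the one being assembled."""


class PlanStatus(str, enum.Enum):
    UNAPPROVED = "UNAPPROVED"
    PLANNING_APPROVED = "PLANNING_APPROVED"
    TREATMENT_APPROVED = "TREATMENT_APPROVED"
    COMPLETED = "COMPLETED"
    REJECTED = "REJECTED"


class CourseIntent(str, enum.Enum):
    CLINICAL = "CLINICAL"
    NON_CLINICAL = "NON_CLINICAL"
    QA = "QA"


class DeliveryKind(str, enum.Enum):
    STATIC = "STATIC"
    IMRT = "IMRT"
    VMAT = "VMAT"


class BeamRole(str, enum.Enum):
    TREATMENT = "TREATMENT"
    SETUP = "SETUP"


class QAKind(str, enum.Enum):
    EPID = "EPID"
    MAPCHECK = "MAPCHECK"


@dataclass
class ControlPoint:
    """One snapshot of machine state in a delivery sequence.

    ``cumulative_meterset_weight`` is stored as the fraction of the beam's
    final cumulative weight, so it runs from 0 to 1 regardless of how the
    planning system scaled the raw weights.
    """

    index: int
    cumulative_meterset_weight: float
    gantry_angle: float
    collimator_angle: float
    couch_angle: float
    jaw_positions: tuple[float, float, float, float]  # x1, x2, y1, y2 (mm)
    mlc_leaf_positions: Optional[np.ndarray] = None  # shape (2, n_pairs), mm
    table_top_vertical: Optional[float] = None
    table_top_longitudinal: Optional[float] = None
    table_top_lateral: Optional[float] = None


@dataclass
class Beam:
    beam_id: str
    beam_name: str
    machine_name: str
    energy_label: str  # e.g. "6X", "15X", "6X-FFF"
    delivery_kind: DeliveryKind
    role: BeamRole
    dose_rate: Optional[float]  # MU/min
    meterset: Optional[float]  # MU
    isocenter: Optional[np.ndarray]  # (3,) mm, DICOM patient coordinates
    control_points: list[ControlPoint] = field(default_factory=list)
    bolus_ids: list[str] = field(default_factory=list)
    tolerance_table_label: str = ""
    drr_present: Optional[bool] = None
    drr_overlay_present: Optional[bool] = None
    imager_position: Optional[np.ndarray] = None  # (vrt, lng, lat) mm

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)


@dataclass
class ReferencePoint:
    """A dose-tracking point accumulating beam contributions against the
    prescription."""

    ref_id: str
    name: str
    total_dose: float  # Gy
    dose_per_fraction: Optional[float]  # Gy
    contributing_beam_ids: list[str] = field(default_factory=list)


@dataclass
class CouchStructure:
    name: str
    density: Optional[float]  # assigned relative electron density


@dataclass
class DensityOverride:
    structure_name: str
    value: float
    unit: str = "rel_electron_density"


@dataclass
class BolusStructure:
    name: str
    hu: Optional[float]  # assigned HU; None when not evaluable


@dataclass
class QAPlanContext:
    """A verification (QA) plan linked to a clinical plan."""

    qa_plan_id: str
    qa_kind: QAKind
    course_id: Optional[str]
    course_intent: Optional[CourseIntent]
    plan_status: Optional[PlanStatus]
    beams: list[Beam]
    reference_sid: Optional[float]  # mm
    linked_clinical_plan_id: str
    tolerance_table_label: Optional[str] = None
    treatment_time_defined: Optional[bool] = None


@dataclass
class PlanContext:
    """A loaded treatment plan: the unit that a check run consumes."""

    plan_id: str
    plan_name: str
    sop_instance_uid: str = ""
    course_id: Optional[str] = None
    plan_status: Optional[PlanStatus] = None
    course_intent: Optional[CourseIntent] = None
    fractions: Optional[int] = None
    prescription_dose: Optional[float] = None  # Gy
    beams: list[Beam] = field(default_factory=list)
    reference_points: list[ReferencePoint] = field(default_factory=list)
    calc_model: Optional[str] = None
    leaf_motion_calculator: Optional[str] = None
    dose_grid_resolution: Optional[float] = None  # mm, max axis pitch
    image_id: Optional[str] = None
    image_name: Optional[str] = None
    structure_set_id: Optional[str] = None
    structure_set_name: Optional[str] = None
    patient_orientation: Optional[str] = None  # HFS, HFP, FFS, FFP, ...
    couch_structures: list[CouchStructure] = field(default_factory=list)
    density_overrides: list[DensityOverride] = field(default_factory=list)
    bolus_structures: list[BolusStructure] = field(default_factory=list)
    qa_plans: list[QAPlanContext] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def treatment_beams(self) -> list[Beam]:
        return [b for b in self.beams if b.role is BeamRole.TREATMENT]

    def setup_beams(self) -> list[Beam]:
        return [b for b in self.beams if b.role is BeamRole.SETUP]


# ---------------------------------------------------------------------------
# RT Plan loading
# ---------------------------------------------------------------------------


def _normalize_angle(value: float) -> float:
    return float(value) % 360.0


def _read_dataset(path, expected_modality: str) -> pydicom.Dataset:
    try:
        ds = pydicom.dcmread(str(path))
    except (InvalidDicomError, Exception) as exc:  # pydicom raises various
        if isinstance(exc, InvalidDicomError) or "DICOM" in str(exc):
            raise PlanFormatError(f"{path}: not a DICOM file ({exc})") from exc
        raise PlanFormatError(f"{path}: cannot read DICOM ({exc})") from exc
    modality = getattr(ds, "Modality", None)
    if modality != expected_modality:
        raise PlanFormatError(
            f"{path}: expected Modality {expected_modality}, found {modality!r}"
        )
    return ds


def _mlc_from_sequence(cp_ds) -> tuple[Optional[np.ndarray], dict]:
    """Extract jaw and MLC positions from one control point item."""
    out: dict = {}
    mlc = None
    for item in cp_ds.get("BeamLimitingDevicePositionSequence", []):
        kind = item.RTBeamLimitingDeviceType
        pos = [float(v) for v in item.LeafJawPositions]
        if kind in ("X", "ASYMX"):
            out["x"] = (pos[0], pos[1])
        elif kind in ("Y", "ASYMY"):
            out["y"] = (pos[0], pos[1])
        elif kind in ("MLCX", "MLCY"):
            half = len(pos) // 2
            mlc = np.array([pos[:half], pos[half:]], dtype=float)
    return mlc, out


def _classify_delivery(beam_ds, control_points: list[ControlPoint]) -> DeliveryKind:
    beam_type = str(beam_ds.get("BeamType", "STATIC")).upper()
    if beam_type == "STATIC":
        return DeliveryKind.STATIC
    gantry = [cp.gantry_angle for cp in control_points]
    if len(gantry) > 1 and (max(gantry) - min(gantry)) > 1e-6:
        return DeliveryKind.VMAT
    return DeliveryKind.IMRT


def _load_beam(
    beam_ds,
    meterset_by_number: dict[int, float],
    tolerance_labels: dict[int, str],
    setup_name_regex: str,
) -> Beam:
    name = str(beam_ds.get("BeamName", ""))
    number = int(beam_ds.BeamNumber)
    delivery_type = str(beam_ds.get("TreatmentDeliveryType", "TREATMENT")).upper()
    if delivery_type == "SETUP" or re.search(setup_name_regex, name):
        role = BeamRole.SETUP
    else:
        role = BeamRole.TREATMENT

    final_weight = float(beam_ds.get("FinalCumulativeMetersetWeight", 1.0)) or 1.0

    energy = None
    dose_rate = None
    isocenter = None
    fff = False
    for item in beam_ds.get("PrimaryFluenceModeSequence", []):
        if str(item.get("FluenceModeID", "")).upper() == "FFF":
            fff = True

    control_points: list[ControlPoint] = []
    jaw = {"x": (0.0, 0.0), "y": (0.0, 0.0)}
    mlc_prev: Optional[np.ndarray] = None
    table = {"v": None, "l": None, "t": None}
    gantry = collimator = couch = 0.0
    for cp_ds in beam_ds.get("ControlPointSequence", []):
        idx = int(cp_ds.ControlPointIndex)
        if "NominalBeamEnergy" in cp_ds:
            energy = float(cp_ds.NominalBeamEnergy)
        if "DoseRateSet" in cp_ds:
            dose_rate = float(cp_ds.DoseRateSet)
        if "IsocenterPosition" in cp_ds:
            isocenter = np.array([float(v) for v in cp_ds.IsocenterPosition])
        if "GantryAngle" in cp_ds:
            gantry = _normalize_angle(cp_ds.GantryAngle)
        if "BeamLimitingDeviceAngle" in cp_ds:
            collimator = _normalize_angle(cp_ds.BeamLimitingDeviceAngle)
        if "PatientSupportAngle" in cp_ds:
            couch = _normalize_angle(cp_ds.PatientSupportAngle)
        if "TableTopVerticalPosition" in cp_ds and cp_ds.TableTopVerticalPosition is not None:
            table["v"] = float(cp_ds.TableTopVerticalPosition)
        if "TableTopLongitudinalPosition" in cp_ds and cp_ds.TableTopLongitudinalPosition is not None:
            table["l"] = float(cp_ds.TableTopLongitudinalPosition)
        if "TableTopLateralPosition" in cp_ds and cp_ds.TableTopLateralPosition is not None:
            table["t"] = float(cp_ds.TableTopLateralPosition)
        mlc, jaws = _mlc_from_sequence(cp_ds)
        jaw.update(jaws)
        if mlc is not None:
            mlc_prev = mlc
        weight = float(cp_ds.CumulativeMetersetWeight) / final_weight
        control_points.append(
            ControlPoint(
                index=idx,
                cumulative_meterset_weight=weight,
                gantry_angle=gantry,
                collimator_angle=collimator,
                couch_angle=couch,
                jaw_positions=(jaw["x"][0], jaw["x"][1], jaw["y"][0], jaw["y"][1]),
                mlc_leaf_positions=None if mlc_prev is None else mlc_prev.copy(),
                table_top_vertical=table["v"],
                table_top_longitudinal=table["l"],
                table_top_lateral=table["t"],
            )
        )

    if energy is not None:
        label = f"{energy:g}X" + ("-FFF" if fff else "")
    else:
        label = ""

    tol_number = beam_ds.get("ReferencedToleranceTableNumber")
    tol_label = tolerance_labels.get(int(tol_number), "") if tol_number is not None else ""

    bolus_ids = [
        str(item.get("BolusID", item.get("ReferencedROINumber", "")))
        for item in beam_ds.get("ReferencedBolusSequence", [])
    ]

    beam = Beam(
        beam_id=str(number),
        beam_name=name,
        machine_name=str(beam_ds.get("TreatmentMachineName", "")),
        energy_label=label,
        delivery_kind=DeliveryKind.STATIC,  # refined below
        role=role,
        dose_rate=dose_rate,
        meterset=meterset_by_number.get(number),
        isocenter=isocenter,
        control_points=control_points,
        bolus_ids=bolus_ids,
        tolerance_table_label=tol_label,
    )
    beam.delivery_kind = _classify_delivery(beam_ds, control_points)
    return beam


def _validate_beam_structure(beam: Beam) -> list[str]:
    problems = []
    prev = -np.inf
    for cp in beam.control_points:
        w = cp.cumulative_meterset_weight
        if w < prev - 1e-9:
            problems.append(
                f"beam {beam.beam_id} ({beam.beam_name}): cumulative meterset "
                f"weight decreases at control point {cp.index} ({w:.6f} < {prev:.6f})"
            )
        prev = max(prev, w)
        for angle, label in (
            (cp.gantry_angle, "gantry"),
            (cp.collimator_angle, "collimator"),
            (cp.couch_angle, "couch"),
        ):
            if not (0.0 <= angle < 360.0):
                problems.append(
                    f"beam {beam.beam_id}: {label} angle {angle} outside [0, 360) "
                    f"at control point {cp.index}"
                )
        if cp.mlc_leaf_positions is not None:
            bank_a, bank_b = cp.mlc_leaf_positions
            bad = np.nonzero(bank_a > bank_b + 1e-9)[0]
            if bad.size:
                problems.append(
                    f"beam {beam.beam_id}: MLC bank A exceeds bank B for leaf "
                    f"pair(s) {bad.tolist()} at control point {cp.index}"
                )
        if beam.meterset is not None and beam.meterset < 0:
            problems.append(f"beam {beam.beam_id}: negative meterset")
    return problems


def load_rtplan(path, *, setup_name_regex: str = DEFAULT_SETUP_NAME_REGEX) -> PlanContext:
    """Load a DICOM RT Plan into a partial :class:`PlanContext`.

    Fields that only exist in the planning-system database (course, statuses,
    DRR presence, calculation models, reference points, QA linkage) are left
    ``None`` pending :func:`load_sidecar`.

    Raises
    ------
    PlanFormatError
        if the file is not a DICOM RT Plan.
    PlanStructureError
        if the RT Plan has no BeamSequence.
    PlanValidationError
        if a structural invariant is violated (non-monotone cumulative
        meterset weights, MLC bank ordering, out-of-range angles).
    """
    ds = _read_dataset(path, "RTPLAN")
    if "BeamSequence" not in ds:
        raise PlanStructureError(f"{path}: RT Plan is missing BeamSequence")

    tolerance_labels = {
        int(t.ToleranceTableNumber): str(t.get("ToleranceTableLabel", ""))
        for t in ds.get("ToleranceTableSequence", [])
    }

    meterset_by_number: dict[int, float] = {}
    fractions = None
    for fg in ds.get("FractionGroupSequence", []):
        if "NumberOfFractionsPlanned" in fg:
            fractions = int(fg.NumberOfFractionsPlanned)
        for rb in fg.get("ReferencedBeamSequence", []):
            if "BeamMeterset" in rb:
                meterset_by_number[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    orientation = None
    for ps in ds.get("PatientSetupSequence", []):
        if "PatientPosition" in ps:
            orientation = str(ps.PatientPosition)

    beams = [
        _load_beam(b, meterset_by_number, tolerance_labels, setup_name_regex)
        for b in ds.BeamSequence
    ]

    problems: list[str] = []
    for beam in beams:
        problems.extend(_validate_beam_structure(beam))
    if problems:
        raise PlanValidationError(problems)

    return PlanContext(
        plan_id=str(ds.get("RTPlanLabel", "")),
        plan_name=str(ds.get("RTPlanName", ds.get("RTPlanLabel", ""))),
        sop_instance_uid=str(ds.get("SOPInstanceUID", "")),
        fractions=fractions,
        beams=beams,
        patient_orientation=orientation,
    )


# ---------------------------------------------------------------------------
# Sidecar
# ---------------------------------------------------------------------------


def _parse_enum(enum_cls, value, key: str):
    if value is None:
        return None
    try:
        return enum_cls(str(value).upper())
    except ValueError as exc:
        allowed = ", ".join(e.value for e in enum_cls)
        raise SidecarError(f"key {key!r}: {value!r} is not one of {allowed}") from exc


def _qa_plan_from_entry(entry: dict, base_dir: Path, ctx: PlanContext, i: int) -> QAPlanContext:
    key = f"qa_plans[{i}]"
    if not isinstance(entry, dict):
        raise SidecarError(f"{key}: expected a mapping")
    for required in ("qa_plan_id", "qa_kind", "linked_clinical_plan_id"):
        if required not in entry:
            raise SidecarError(f"{key}: missing required key {required!r}")
    linked = str(entry["linked_clinical_plan_id"])
    if linked != ctx.plan_id:
        raise LinkageError(
            f"{key}: linked_clinical_plan_id {linked!r} does not match plan "
            f"{ctx.plan_id!r}"
        )
    beams: list[Beam] = []
    if entry.get("rtplan_file"):
        qa_ctx = load_rtplan(base_dir / str(entry["rtplan_file"]))
        beams = qa_ctx.beams
    return QAPlanContext(
        qa_plan_id=str(entry["qa_plan_id"]),
        qa_kind=_parse_enum(QAKind, entry["qa_kind"], f"{key}.qa_kind"),
        course_id=entry.get("course_id"),
        course_intent=_parse_enum(
            CourseIntent, entry.get("course_intent"), f"{key}.course_intent"
        ),
        plan_status=_parse_enum(PlanStatus, entry.get("plan_status"), f"{key}.plan_status"),
        beams=beams,
        reference_sid=(
            float(entry["reference_sid_mm"]) if entry.get("reference_sid_mm") is not None else None
        ),
        linked_clinical_plan_id=linked,
        tolerance_table_label=entry.get("tolerance_table_label"),
        treatment_time_defined=entry.get("treatment_time_defined"),
    )


def load_sidecar(path, ctx: PlanContext) -> PlanContext:
    """Merge planning-database fields from a YAML sidecar into ``ctx``.

    The sidecar must carry the same ``plan_id`` as the loaded RT Plan.
    Optional keys that are absent stay ``None`` ("unknown"), which makes the
    dependent checkers flag with an "insufficient data" message instead of
    passing silently.
    """
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise SidecarError(f"{path}: malformed YAML ({exc})") from exc
    if not isinstance(doc, dict):
        raise SidecarError(f"{path}: sidecar must be a mapping")
    if "plan_id" not in doc:
        raise SidecarError(f"{path}: missing required key 'plan_id'")
    if str(doc["plan_id"]) != ctx.plan_id:
        raise LinkageError(
            f"{path}: sidecar plan_id {doc['plan_id']!r} does not match loaded "
            f"plan {ctx.plan_id!r}"
        )

    ctx = dataclasses.replace(ctx)
    ctx.course_id = doc.get("course_id", ctx.course_id)
    ctx.plan_status = _parse_enum(PlanStatus, doc.get("plan_status"), "plan_status") or ctx.plan_status
    ctx.course_intent = (
        _parse_enum(CourseIntent, doc.get("course_intent"), "course_intent") or ctx.course_intent
    )
    if doc.get("prescription_dose_gy") is not None:
        ctx.prescription_dose = float(doc["prescription_dose_gy"])
    if doc.get("fractions") is not None:
        ctx.fractions = int(doc["fractions"])
    ctx.calc_model = doc.get("calc_model", ctx.calc_model)
    ctx.leaf_motion_calculator = doc.get("leaf_motion_calculator", ctx.leaf_motion_calculator)
    ctx.image_id = doc.get("image_id", ctx.image_id)
    ctx.image_name = doc.get("image_name", ctx.image_name)
    ctx.structure_set_id = doc.get("structure_set_id", ctx.structure_set_id)
    ctx.structure_set_name = doc.get("structure_set_name", ctx.structure_set_name)
    if doc.get("warnings") is not None:
        ctx.warnings = [str(w) for w in doc["warnings"]]

    drr = doc.get("drr", {})
    if not isinstance(drr, dict):
        raise SidecarError(f"{path}: 'drr' must map beam names to present/overlay")
    imagers = doc.get("imager_positions", {})
    if not isinstance(imagers, dict):
        raise SidecarError(f"{path}: 'imager_positions' must be a mapping")
    for beam in ctx.beams:
        entry = drr.get(beam.beam_name)
        if entry is not None:
            beam.drr_present = entry.get("present")
            beam.drr_overlay_present = entry.get("overlay")
        imager = imagers.get(beam.beam_name)
        if imager is not None:
            beam.imager_position = np.array(
                [float(imager["vrt"]), float(imager["lng"]), float(imager["lat"])]
            )

    rps = []
    for i, entry in enumerate(doc.get("reference_points", []) or []):
        key = f"reference_points[{i}]"
        if not isinstance(entry, dict) or "name" not in entry:
            raise SidecarError(f"{key}: expected a mapping with a 'name'")
        rps.append(
            ReferencePoint(
                ref_id=str(entry.get("ref_id", entry["name"])),
                name=str(entry["name"]),
                total_dose=float(entry.get("total_dose_gy", 0.0)),
                dose_per_fraction=(
                    float(entry["dose_per_fraction_gy"])
                    if entry.get("dose_per_fraction_gy") is not None
                    else None
                ),
                contributing_beam_ids=[str(b) for b in entry.get("contributing_beam_ids", [])],
            )
        )
    if rps:
        ctx.reference_points = rps

    qa_entries = doc.get("qa_plans", []) or []
    ctx.qa_plans = [
        _qa_plan_from_entry(entry, path.parent, ctx, i) for i, entry in enumerate(qa_entries)
    ]
    return ctx


# ---------------------------------------------------------------------------
# RT Dose / RT Structure Set
# ---------------------------------------------------------------------------


def load_dose_grid(path, ctx: PlanContext) -> PlanContext:
    """Set ``dose_grid_resolution`` from a DICOM RT Dose file.

    The resolution is the *maximum* voxel pitch across the three axes — a
    conservative convention: if any axis is coarser than policy, the plan is
    out of policy.
    """
    ds = _read_dataset(path, "RTDOSE")
    refs = [
        str(item.get("ReferencedSOPInstanceUID", ""))
        for item in ds.get("ReferencedRTPlanSequence", [])
    ]
    if ctx.sop_instance_uid and refs and ctx.sop_instance_uid not in refs:
        raise LinkageError(
            f"{path}: RT Dose references plan {refs}, not {ctx.sop_instance_uid}"
        )
    pitches = [float(v) for v in ds.get("PixelSpacing", [])]
    offsets = [float(v) for v in ds.get("GridFrameOffsetVector", [])]
    if len(offsets) > 1:
        pitches.append(float(np.max(np.abs(np.diff(offsets)))))
    if not pitches:
        raise PlanStructureError(f"{path}: RT Dose has no grid spacing information")
    ctx = dataclasses.replace(ctx)
    ctx.dose_grid_resolution = max(pitches)
    return ctx


_HU_PROPERTY_NAMES = {"HU", "HOUNSFIELD", "EFFECTIVE_HU"}


def load_structures(path, ctx: PlanContext) -> PlanContext:
    """Read couch/bolus structures and density overrides from an RT
    Structure Set.

    Couch parts are ROIs with interpreted type SUPPORT; their assigned
    relative electron density comes from the ROI physical properties.  Bolus
    ROIs carry an HU-valued property in this package's synthetic exports
    (vendor exports vary; a bolus without one is reported "not evaluable").
    """
    ds = _read_dataset(path, "RTSTRUCT")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.get("StructureSetROISequence", [])}
    couch: list[CouchStructure] = []
    boluses: list[BolusStructure] = []
    overrides: list[DensityOverride] = []
    for obs in ds.get("RTROIObservationsSequence", []):
        roi_number = int(obs.ReferencedROINumber)
        name = names.get(roi_number, str(roi_number))
        kind = str(obs.get("RTROIInterpretedType", "")).upper()
        props = {
            str(p.ROIPhysicalProperty).upper(): float(p.ROIPhysicalPropertyValue)
            for p in obs.get("ROIPhysicalPropertiesSequence", [])
        }
        red = props.get("REL_ELEC_DENSITY")
        hu = next((props[k] for k in _HU_PROPERTY_NAMES if k in props), None)
        if kind == "SUPPORT":
            couch.append(CouchStructure(name=name, density=red))
        if kind == "BOLUS":
            boluses.append(BolusStructure(name=name, hu=hu))
        for prop, value in props.items():
            unit = "HU" if prop in _HU_PROPERTY_NAMES else prop.lower()
            overrides.append(DensityOverride(structure_name=name, value=value, unit=unit))
    ctx = dataclasses.replace(ctx)
    ctx.couch_structures = couch
    ctx.bolus_structures = boluses
    ctx.density_overrides = overrides
    return ctx


# ---------------------------------------------------------------------------
# Context-level validation and assembly
# ---------------------------------------------------------------------------


def validate_context(ctx: PlanContext, *, rp_consistency_rel_tol: float = 0.01) -> list[str]:
    """Run cross-field consistency checks; returns soft warnings.

    Hard structural invariants were already enforced at load time.  Findings
    here (e.g. a reference point whose per-fraction dose times the fraction
    count disagrees with its total) are appended to ``ctx.warnings`` so that
    the warning-listing checker can surface them.
    """
    notes: list[str] = []
    bolus_names = {b.name for b in ctx.bolus_structures}
    for beam in ctx.beams:
        for bolus_id in beam.bolus_ids:
            if bolus_names and bolus_id not in bolus_names:
                notes.append(
                    f"beam {beam.beam_name}: bolus reference {bolus_id!r} does not "
                    f"resolve to a bolus structure"
                )
    if ctx.fractions is not None:
        for rp in ctx.reference_points:
            if rp.dose_per_fraction is None:
                continue
            expected = rp.dose_per_fraction * ctx.fractions
            if rp.total_dose > 0 and abs(expected - rp.total_dose) > rp_consistency_rel_tol * rp.total_dose:
                notes.append(
                    f"reference point {rp.name}: dose/fraction x fractions = "
                    f"{expected:.3f} Gy disagrees with total {rp.total_dose:.3f} Gy"
                )
    ctx.warnings.extend(notes)
    return notes


def assemble_context(
    plan_path,
    sidecar_path,
    dose_path=None,
    struct_path=None,
    *,
    setup_name_regex: str = DEFAULT_SETUP_NAME_REGEX,
) -> PlanContext:
    """Compose the loaders into a full, validated :class:`PlanContext`.

    Errors raised by each loader are re-raised with the offending file in the
    message, so a multi-file assembly failure always names its source.
    """
    ctx = load_rtplan(plan_path, setup_name_regex=setup_name_regex)
    if struct_path is not None:
        ctx = load_structures(struct_path, ctx)
    if dose_path is not None:
        ctx = load_dose_grid(dose_path, ctx)
    ctx = load_sidecar(sidecar_path, ctx)
    validate_context(ctx)
    return ctx
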