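"""Synthetic DICOM-RT fixtures, defect injection and audit-log simulation.

This module makes the whole checking system testable without any clinical
data.  It generates minimal-but-valid DICOM RT Plan / RT Dose / RT
Structure Set files plus a sidecar for five plan templates (conventional
static, sliding-window IMRT, two-arc VMAT, and two single-fraction
stereotactic templates with EPID / MapCheck verification plans); every
template is constructed to pass all checks of the default profile for any
seed — the module's defining contract.  A catalog of named defects then
mutates one aspect of a clean fixture at a time, each mapped to the
checker expected to flag it, giving a defect → checker detection matrix.

The plans are checker inputs, not dosimetric truth: apertures, metersets
and couch values are drawn from clinically plausible ranges, but no dose
is computed and no anatomy exists.  Seeded generation is byte-reproducible
(fixed dates, seed-derived UIDs).
"""

from __future__ import annotations

import math
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pydicom
import yaml
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import datasets
from .audit import ALL_CATEGORIES
from .framework import ComplianceStatus, RunConfig, default_config, run_checks
from .plan_model import PlanContext, assemble_context

__all__ = [
    "TEMPLATES",
    "FixtureSet",
    "DefectSpec",
    "DEFECTS",
    "generate_clean_context",
    "build_context",
    "inject_defect",
    "evaluate_detection",
    "AuditSimConfig",
    "simulate_audit_logs",
]

TEMPLATES = (
    "STATIC_2FIELD",
    "IMRT_5FIELD",
    "VMAT_2ARC",
    "ONE_FX_VMAT_WITH_EPID_QA",
    "ONE_FX_FFF_WITH_MAPCHECK_QA",
)

_SOP_RTPLAN = "1.2.840.10008.5.1.4.1.1.481.5"
_SOP_RTDOSE = "1.2.840.10008.5.1.4.1.1.481.2"
_SOP_RTSTRUCT = "1.2.840.10008.5.1.4.1.1.481.3"
_DATE = "20160414"
_MACHINE = "TB1"
_N_PAIRS = 40  # MLC leaf pairs; 10 mm leaves spanning x = -200..200 mm


@dataclass
class FixtureSet:
    """Paths of one generated plan fixture."""

    template: str
    seed: int
    directory: Path
    plan_path: Path
    dose_path: Path
    struct_path: Path
    sidecar_path: Path
    qa_plan_paths: dict[str, Path] = field(default_factory=dict)


@dataclass(frozen=True)
class DefectSpec:
    """A named, seeded mutation of a clean fixture, mapped to the checker
    expected to flag it."""

    defect_id: str
    mutation: str  # human-readable description of the altered field(s)
    expected_checker: str
    template: str
    seed: int = 0


def _uid(template: str, seed: int, role: str) -> str:
    return generate_uid(entropy_srcs=[f"plancheck/{template}/{seed}/{role}"])


# ---------------------------------------------------------------------------
# Plan description builders (plain dicts, written to DICOM afterwards)
# ---------------------------------------------------------------------------


def _parked_banks() -> tuple[np.ndarray, np.ndarray]:
    a = np.full(_N_PAIRS, -70.0)  # parked behind the x1 jaw (jaws open to -60 at most)
    return a.copy(), a.copy()


def _static_aperture(half_x: float, jitter: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bank_a, bank_b = _parked_banks()
    open_pairs = slice(10, 30)
    bank_a[open_pairs] = -half_x + jitter
    bank_b[open_pairs] = half_x + jitter
    return bank_a, bank_b


def _beam(
    number: int,
    name: str,
    *,
    beam_type: str,
    delivery_type: str,
    energy: float,
    fff: bool,
    dose_rate: Optional[float],
    meterset: float,
    isocenter: Sequence[float],
    cps: list[dict],
    bolus_ids: Sequence[str] = (),
) -> dict:
    return {
        "number": number,
        "name": name,
        "machine": _MACHINE,
        "beam_type": beam_type,
        "delivery_type": delivery_type,
        "energy": energy,
        "fff": fff,
        "dose_rate": dose_rate,
        "meterset": meterset,
        "isocenter": [round(float(v), 2) for v in isocenter],
        "bolus_ids": list(bolus_ids),
        "cps": cps,
    }


def _cp(
    weight: float,
    gantry: float,
    *,
    collimator: float = 0.0,
    couch: float = 0.0,
    jaw_x: tuple[float, float] = (-50.0, 50.0),
    jaw_y: tuple[float, float] = (-50.0, 50.0),
    mlc: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> dict:
    return {
        "weight": round(float(weight), 6),
        "gantry": round(float(gantry) % 360.0, 2),
        "collimator": round(float(collimator) % 360.0, 2),
        "couch": round(float(couch) % 360.0, 2),
        "jaw_x": jaw_x,
        "jaw_y": jaw_y,
        "mlc": None
        if mlc is None
        else (np.round(mlc[0], 2), np.round(mlc[1], 2)),
    }


def _couch_values(rng: np.random.Generator) -> tuple[float, float, float]:
    return (
        round(float(rng.uniform(-180.0, -80.0)), 1),
        round(float(rng.uniform(600.0, 1000.0)), 1),
        round(float(rng.uniform(-20.0, 20.0)), 1),
    )


def _setup_beams(start_number: int, isocenter, energy: float = 6.0) -> list[dict]:
    beams = []
    for i, (name, gantry) in enumerate((("SU_AP", 0.0), ("SU_LAT", 270.0))):
        cps = [
            _cp(w, gantry, jaw_x=(-100.0, 100.0), jaw_y=(-100.0, 100.0))
            for w in (0.0, 1.0)
        ]
        beams.append(
            _beam(
                start_number + i,
                name,
                beam_type="STATIC",
                delivery_type="SETUP",
                energy=energy,
                fff=False,
                dose_rate=None,
                meterset=0.0,
                isocenter=isocenter,
                cps=cps,
            )
        )
    return beams


def _static_plan(rng: np.random.Generator) -> dict:
    iso = rng.uniform(-20.0, 20.0, size=3)
    half_x = float(rng.uniform(30.0, 55.0))
    jitter = np.round(rng.uniform(-2.0, 2.0, size=20), 1)
    beams = []
    for i, (name, gantry) in enumerate((("AP", 0.0), ("PA", 180.0))):
        mlc = _static_aperture(half_x, jitter)
        cps = [
            _cp(w, gantry, jaw_x=(-60.0, 60.0), jaw_y=(-55.0, 55.0), mlc=mlc)
            for w in (0.0, 1.0)
        ]
        beams.append(
            _beam(
                i + 1,
                name,
                beam_type="STATIC",
                delivery_type="TREATMENT",
                energy=6.0,
                fff=False,
                dose_rate=600.0,
                meterset=round(float(rng.uniform(90.0, 110.0)), 1),
                isocenter=iso,
                cps=cps,
            )
        )
    beams += _setup_beams(3, iso)
    return {
        "plan_name": "PELV_STAT",
        "fractions": 25,
        "prescription_gy": 50.0,
        "beams": beams,
        "bolus": None,
        "needs_lmc": False,
        "couch": _couch_values(rng),
    }


def _imrt_plan(rng: np.random.Generator) -> dict:
    iso = rng.uniform(-20.0, 20.0, size=3)
    n_cp = 15
    beams = []
    gantries = (200.0, 280.0, 0.0, 80.0, 160.0)
    pair_jitter = np.round(rng.uniform(-1.5, 1.5, size=16), 1)
    for i, gantry in enumerate(gantries):
        cps = []
        for k in range(n_cp):
            offset = -30.0 + 60.0 * k / (n_cp - 1)
            bank_a, bank_b = _parked_banks()
            bank_a[12:28] = offset - 10.0 + pair_jitter
            bank_b[12:28] = offset + 10.0 + pair_jitter
            cps.append(
                _cp(
                    k / (n_cp - 1),
                    gantry,
                    jaw_x=(-60.0, 60.0),
                    jaw_y=(-45.0, 45.0),
                    mlc=(bank_a, bank_b),
                )
            )
        beams.append(
            _beam(
                i + 1,
                f"IMRT_{int(gantry):03d}",
                beam_type="DYNAMIC",
                delivery_type="TREATMENT",
                energy=6.0,
                fff=False,
                dose_rate=400.0,
                meterset=round(float(rng.uniform(90.0, 120.0)), 1),
                isocenter=iso,
                cps=cps,
                bolus_ids=("Bolus5mm",),
            )
        )
    beams += _setup_beams(6, iso)
    return {
        "plan_name": "HN_IMRT",
        "fractions": 28,
        "prescription_gy": 50.4,
        "beams": beams,
        "bolus": {"name": "Bolus5mm", "hu": 0.0},
        "needs_lmc": True,
        "couch": _couch_values(rng),
    }


def _arc_cps(rng: np.random.Generator, n_cp: int, clockwise: bool, collimator: float) -> list[dict]:
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    cps = []
    for k in range(n_cp):
        frac = k / (n_cp - 1)
        gantry = (181.0 + 358.0 * frac) if clockwise else (179.0 - 358.0 * frac)
        center = 15.0 * math.sin(2.0 * math.pi * k / 20.0 + phase)
        half_gap = 15.0 + 5.0 * math.sin(2.0 * math.pi * k / 13.0)
        bank_a, bank_b = _parked_banks()
        bank_a[12:28] = center - half_gap
        bank_b[12:28] = center + half_gap
        cps.append(
            _cp(
                frac,
                gantry,
                collimator=collimator,
                jaw_x=(-60.0, 60.0),
                jaw_y=(-45.0, 45.0),
                mlc=(bank_a, bank_b),
            )
        )
    return cps


def _vmat_plan(
    rng: np.random.Generator,
    *,
    plan_name: str,
    fractions: int,
    prescription: float,
    fff: bool,
    meterset_range: tuple[float, float],
) -> dict:
    iso = rng.uniform(-20.0, 20.0, size=3)
    beams = []
    for i, (clockwise, coll) in enumerate(((True, 30.0), (False, 330.0))):
        cps = _arc_cps(rng, 60, clockwise, coll)
        beams.append(
            _beam(
                i + 1,
                f"ARC{i + 1}",
                beam_type="DYNAMIC",
                delivery_type="TREATMENT",
                energy=6.0,
                fff=fff,
                dose_rate=1400.0 if fff else 600.0,
                meterset=round(float(rng.uniform(*meterset_range)), 1),
                isocenter=iso,
                cps=cps,
            )
        )
    beams += _setup_beams(3, iso)
    return {
        "plan_name": plan_name,
        "fractions": fractions,
        "prescription_gy": prescription,
        "beams": beams,
        "bolus": None,
        "needs_lmc": False,
        "couch": _couch_values(rng),
    }


def _qa_copy(plan: dict, qa_plan_name: str, *, gantry_zero: bool) -> dict:
    """Verification-plan copy of a clinical plan: same treatment beams,
    metersets and control-point weights; optionally all beams at gantry 0
    (diode-array measurements are made with the beam pointing down)."""
    qa = {
        "plan_name": qa_plan_name,
        "fractions": 1,
        "prescription_gy": plan["prescription_gy"],
        "beams": [],
        "bolus": None,
        "needs_lmc": False,
        "couch": plan["couch"],
    }
    for beam in plan["beams"]:
        if beam["delivery_type"] != "TREATMENT":
            continue
        copy = {**beam, "cps": [dict(cp) for cp in beam["cps"]], "bolus_ids": []}
        if gantry_zero:
            for cp in copy["cps"]:
                cp["gantry"] = 0.0
        qa["beams"].append(copy)
    return qa


_TEMPLATE_BUILDERS: dict[str, Callable[[np.random.Generator], dict]] = {
    "STATIC_2FIELD": _static_plan,
    "IMRT_5FIELD": _imrt_plan,
    "VMAT_2ARC": lambda rng: _vmat_plan(
        rng, plan_name="PROS_VMAT", fractions=5, prescription=40.0, fff=False,
        meterset_range=(450.0, 550.0),
    ),
    "ONE_FX_VMAT_WITH_EPID_QA": lambda rng: _vmat_plan(
        rng, plan_name="SBRT_V1", fractions=1, prescription=8.0, fff=False,
        meterset_range=(800.0, 900.0),
    ),
    "ONE_FX_FFF_WITH_MAPCHECK_QA": lambda rng: _vmat_plan(
        rng, plan_name="SBRT_F1", fractions=1, prescription=8.0, fff=True,
        meterset_range=(1900.0, 2100.0),
    ),
}


# ---------------------------------------------------------------------------
# DICOM writers
# ---------------------------------------------------------------------------


def _file_dataset(sop_class: str, sop_uid: str, modality: str, study_uid: str, series_uid: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.Modality = modality
    ds.PatientName = "SYNTHETIC^PLANCHECK"
    ds.PatientID = "SYN000"
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.StudyID = "1"
    ds.SeriesNumber = 1
    ds.StudyDate = _DATE
    ds.StudyTime = "120000"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.Manufacturer = "plancheck-synth"
    return ds


def _write_rtplan(plan: dict, path: Path, *, template: str, seed: int, role: str) -> str:
    study_uid = _uid(template, seed, "study")
    sop_uid = _uid(template, seed, f"{role}-sop")
    ds = _file_dataset(_SOP_RTPLAN, sop_uid, "RTPLAN", study_uid, _uid(template, seed, f"{role}-series"))
    ds.RTPlanLabel = plan["plan_name"]
    ds.RTPlanName = plan["plan_name"]
    ds.RTPlanDate = _DATE
    ds.RTPlanTime = "120000"
    ds.RTPlanGeometry = "PATIENT"

    tol = Dataset()
    tol.ToleranceTableNumber = 1
    tol.ToleranceTableLabel = plan.get("tolerance_label", "CLINICAL")
    ds.ToleranceTableSequence = [tol]

    setup = Dataset()
    setup.PatientSetupNumber = 1
    setup.PatientPosition = plan.get("orientation", "HFS")
    ds.PatientSetupSequence = [setup]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = plan["fractions"]
    fg.NumberOfBeams = len(plan["beams"])
    fg.NumberOfBrachyApplicationSetups = 0
    refs = []
    for beam in plan["beams"]:
        rb = Dataset()
        rb.ReferencedBeamNumber = beam["number"]
        rb.BeamMeterset = beam["meterset"]
        refs.append(rb)
    fg.ReferencedBeamSequence = refs
    ds.FractionGroupSequence = [fg]

    beam_items = []
    couch = plan["couch"]
    boundaries = [round(-200.0 + 400.0 * i / _N_PAIRS, 1) for i in range(_N_PAIRS + 1)]
    for beam in plan["beams"]:
        b = Dataset()
        b.BeamNumber = beam["number"]
        b.BeamName = beam["name"]
        b.TreatmentMachineName = beam["machine"]
        b.PrimaryDosimeterUnit = "MU"
        b.SourceAxisDistance = 1000.0
        b.BeamType = beam["beam_type"]
        b.RadiationType = "PHOTON"
        b.TreatmentDeliveryType = beam["delivery_type"]
        b.ReferencedPatientSetupNumber = 1
        b.ReferencedToleranceTableNumber = 1
        b.NumberOfWedges = 0
        b.NumberOfCompensators = 0
        b.NumberOfBoli = len(beam["bolus_ids"])
        b.NumberOfBlocks = 0
        b.FinalCumulativeMetersetWeight = 1.0
        b.NumberOfControlPoints = len(beam["cps"])
        if beam["fff"]:
            mode = Dataset()
            mode.FluenceMode = "NON_STANDARD"
            mode.FluenceModeID = "FFF"
            b.PrimaryFluenceModeSequence = [mode]
        if beam["bolus_ids"]:
            boli = []
            for bolus_id in beam["bolus_ids"]:
                item = Dataset()
                item.ReferencedROINumber = 4
                item.BolusID = bolus_id
                boli.append(item)
            b.ReferencedBolusSequence = boli

        limits = []
        for kind, n in (("ASYMX", 1), ("ASYMY", 1), ("MLCX", _N_PAIRS)):
            if kind == "MLCX" and beam["cps"][0]["mlc"] is None:
                continue
            item = Dataset()
            item.RTBeamLimitingDeviceType = kind
            item.NumberOfLeafJawPairs = n
            if kind == "MLCX":
                item.LeafPositionBoundaries = boundaries
            limits.append(item)
        b.BeamLimitingDeviceSequence = limits

        cp_items = []
        for k, cp in enumerate(beam["cps"]):
            c = Dataset()
            c.ControlPointIndex = k
            c.CumulativeMetersetWeight = cp["weight"]
            c.GantryAngle = cp["gantry"]
            c.GantryRotationDirection = "NONE"
            c.BeamLimitingDeviceAngle = cp["collimator"]
            c.PatientSupportAngle = cp["couch"]
            if k == 0:
                c.NominalBeamEnergy = beam["energy"]
                if beam["dose_rate"] is not None:
                    c.DoseRateSet = beam["dose_rate"]
                c.IsocenterPosition = beam["isocenter"]
                c.TableTopVerticalPosition = couch[0]
                c.TableTopLongitudinalPosition = couch[1]
                c.TableTopLateralPosition = couch[2]
                c.TableTopEccentricAngle = 0.0
                c.TableTopPitchAngle = 0.0
                c.TableTopRollAngle = 0.0
            positions = []
            for kind, values in (
                ("ASYMX", list(cp["jaw_x"])),
                ("ASYMY", list(cp["jaw_y"])),
            ):
                item = Dataset()
                item.RTBeamLimitingDeviceType = kind
                item.LeafJawPositions = values
                positions.append(item)
            if cp["mlc"] is not None:
                item = Dataset()
                item.RTBeamLimitingDeviceType = "MLCX"
                item.LeafJawPositions = [float(v) for v in cp["mlc"][0]] + [
                    float(v) for v in cp["mlc"][1]
                ]
                positions.append(item)
            c.BeamLimitingDevicePositionSequence = positions
            cp_items.append(c)
        b.ControlPointSequence = cp_items
        beam_items.append(b)
    ds.BeamSequence = beam_items
    ds.save_as(str(path), enforce_file_format=True)
    return sop_uid


def _write_rtdose(path: Path, plan_sop_uid: str, *, template: str, seed: int, pitch=(2.5, 2.5, 2.5)) -> None:
    ds = _file_dataset(
        _SOP_RTDOSE,
        _uid(template, seed, "dose-sop"),
        "RTDOSE",
        _uid(template, seed, "study"),
        _uid(template, seed, "dose-series"),
    )
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.PixelSpacing = [pitch[0], pitch[1]]
    ds.GridFrameOffsetVector = [round(i * pitch[2], 3) for i in range(10)]
    ds.FrameOfReferenceUID = _uid(template, seed, "frame")
    ref = Dataset()
    ref.ReferencedSOPClassUID = _SOP_RTPLAN
    ref.ReferencedSOPInstanceUID = plan_sop_uid
    ds.ReferencedRTPlanSequence = [ref]
    ds.save_as(str(path), enforce_file_format=True)


def _write_rtstruct(path: Path, plan: dict, *, template: str, seed: int) -> None:
    ds = _file_dataset(
        _SOP_RTSTRUCT,
        _uid(template, seed, "struct-sop"),
        "RTSTRUCT",
        _uid(template, seed, "study"),
        _uid(template, seed, "struct-series"),
    )
    ds.StructureSetLabel = "SS_SYNTH"
    ds.StructureSetDate = _DATE
    ds.StructureSetTime = "120000"
    rois = [
        (1, "BODY", "EXTERNAL", None),
        (2, "CouchSurface", "SUPPORT", ("REL_ELEC_DENSITY", 0.7)),
        (3, "CouchInterior", "SUPPORT", ("REL_ELEC_DENSITY", 0.2)),
    ]
    if plan["bolus"]:
        rois.append((4, plan["bolus"]["name"], "BOLUS", ("HU", plan["bolus"]["hu"])))
    roi_seq = []
    obs_seq = []
    for number, name, kind, prop in rois:
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = _uid(template, seed, "frame")
        roi.ROIGenerationAlgorithm = "MANUAL"
        roi_seq.append(roi)
        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = kind
        obs.ROIInterpreter = ""
        if prop is not None:
            item = Dataset()
            item.ROIPhysicalProperty = prop[0]
            item.ROIPhysicalPropertyValue = prop[1]
            obs.ROIPhysicalPropertiesSequence = [item]
        obs_seq.append(obs)
    ds.StructureSetROISequence = roi_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(str(path), enforce_file_format=True)


def _sidecar_doc(plan: dict, template: str, qa_entries: list[dict]) -> dict:
    doc = {
        "plan_id": plan["plan_name"],
        "course_id": "C1",
        "course_intent": "CLINICAL",
        "plan_status": "TREATMENT_APPROVED",
        "fractions": plan["fractions"],
        "prescription_dose_gy": plan["prescription_gy"],
        "calc_model": "AAA_15606",
        "image_id": "IMG1",
        "image_name": f"CT_{_DATE}",
        "structure_set_id": "SS1",
        "structure_set_name": f"SS_{_DATE}",
        "warnings": [],
    }
    if plan["needs_lmc"]:
        doc["leaf_motion_calculator"] = "LMC_15606"
    doc["drr"] = {
        beam["name"]: {"present": True, "overlay": True} for beam in plan["beams"]
    }
    doc["imager_positions"] = {
        beam["name"]: {"vrt": -500.0, "lng": 0.0, "lat": 0.0}
        for beam in plan["beams"]
        if beam["delivery_type"] == "SETUP"
    }
    treatment_names = [b["name"] for b in plan["beams"] if b["delivery_type"] == "TREATMENT"]
    doc["reference_points"] = [
        {
            "ref_id": "RP1",
            "name": "PRESC_PT",
            "total_dose_gy": plan["prescription_gy"],
            "dose_per_fraction_gy": round(plan["prescription_gy"] / plan["fractions"], 4),
            "contributing_beam_ids": treatment_names,
        }
    ]
    doc["qa_plans"] = qa_entries
    return doc


def generate_clean_context(template: str, seed: int, out_dir) -> FixtureSet:
    """Write a clean synthetic fixture (RT Plan, RT Dose, RT Structure Set,
    sidecar, plus a verification plan for the QA templates) to ``out_dir``.

    The outputs are constructed to produce zero FLAG results under the
    default profile for every seed; identical (template, seed) pairs yield
    byte-identical files.
    """
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}; expected one of {TEMPLATES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    plan = _TEMPLATE_BUILDERS[template](rng)

    plan_path = out_dir / "rtplan.dcm"
    dose_path = out_dir / "rtdose.dcm"
    struct_path = out_dir / "rtstruct.dcm"
    sidecar_path = out_dir / "sidecar.yaml"
    qa_paths: dict[str, Path] = {}
    qa_entries: list[dict] = []

    plan_sop = _write_rtplan(plan, plan_path, template=template, seed=seed, role="plan")
    _write_rtdose(dose_path, plan_sop, template=template, seed=seed)
    _write_rtstruct(struct_path, plan, template=template, seed=seed)

    if template == "ONE_FX_VMAT_WITH_EPID_QA":
        qa_name = f"QA_{plan['plan_name']}"
        qa_plan = _qa_copy(plan, qa_name, gantry_zero=False)
        qa_path = out_dir / "qa_epid.dcm"
        _write_rtplan(qa_plan, qa_path, template=template, seed=seed, role="qa-epid")
        qa_paths["EPID"] = qa_path
        qa_entries.append(
            {
                "qa_plan_id": qa_name,
                "qa_kind": "EPID",
                "course_id": "QA1",
                "course_intent": "QA",
                "plan_status": "TREATMENT_APPROVED",
                "linked_clinical_plan_id": plan["plan_name"],
                "reference_sid_mm": 1000.0,
                "tolerance_table_label": "QA",
                "treatment_time_defined": True,
                "rtplan_file": qa_path.name,
            }
        )
    elif template == "ONE_FX_FFF_WITH_MAPCHECK_QA":
        qa_name = f"QA_{plan['plan_name']}"
        qa_plan = _qa_copy(plan, qa_name, gantry_zero=True)
        qa_path = out_dir / "qa_mapcheck.dcm"
        _write_rtplan(qa_plan, qa_path, template=template, seed=seed, role="qa-mapcheck")
        qa_paths["MAPCHECK"] = qa_path
        qa_entries.append(
            {
                "qa_plan_id": qa_name,
                "qa_kind": "MAPCHECK",
                "course_id": "QA1",
                "course_intent": "QA",
                "plan_status": "TREATMENT_APPROVED",
                "linked_clinical_plan_id": plan["plan_name"],
                "tolerance_table_label": "QA",
                "treatment_time_defined": True,
                "rtplan_file": qa_path.name,
            }
        )

    doc = _sidecar_doc(plan, template, qa_entries)
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)

    return FixtureSet(
        template=template,
        seed=seed,
        directory=out_dir,
        plan_path=plan_path,
        dose_path=dose_path,
        struct_path=struct_path,
        sidecar_path=sidecar_path,
        qa_plan_paths=qa_paths,
    )


def build_context(fixture: FixtureSet) -> PlanContext:
    """Assemble the full plan context from a fixture's files."""
    return assemble_context(
        fixture.plan_path,
        fixture.sidecar_path,
        dose_path=fixture.dose_path,
        struct_path=fixture.struct_path,
    )


# ---------------------------------------------------------------------------
# Defect catalog
# ---------------------------------------------------------------------------


def _edit_dicom(path: Path, fn: Callable[[pydicom.Dataset], None]) -> None:
    ds = pydicom.dcmread(str(path))
    fn(ds)
    ds.save_as(str(path), enforce_file_format=True)


def _edit_sidecar(path: Path, fn: Callable[[dict], None]) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    fn(doc)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _first_treatment_beam(ds: pydicom.Dataset):
    for beam in ds.BeamSequence:
        if str(beam.TreatmentDeliveryType).upper() == "TREATMENT":
            return beam
    raise ValueError("plan has no treatment beams")


def _mut_isocenter(fix: FixtureSet) -> None:
    def fn(ds):
        beam = _first_treatment_beam(ds)
        iso = [float(v) for v in beam.ControlPointSequence[0].IsocenterPosition]
        iso[0] += 1.0
        beam.ControlPointSequence[0].IsocenterPosition = iso

    _edit_dicom(fix.plan_path, fn)


def _mut_plan_name_bad(fix: FixtureSet) -> None:
    # lowercase violates the convention regex; a trailing space would not
    # survive the DICOM round trip (LO values are space-stripped on read)
    _edit_dicom(
        fix.plan_path, lambda ds: setattr(ds, "RTPlanName", str(ds.RTPlanName).lower())
    )


def _mut_course_name(fix: FixtureSet) -> None:
    _edit_sidecar(fix.sidecar_path, lambda doc: doc.update(course_id="XRAY"))


def _mut_image_name(fix: FixtureSet) -> None:
    _edit_sidecar(fix.sidecar_path, lambda doc: doc.update(image_name="ct scan (final)"))


def _mut_beam_name_char(fix: FixtureSet) -> None:
    old_name = str(_first_treatment_beam(pydicom.dcmread(str(fix.plan_path))).BeamName)
    new_name = old_name + "#"

    def fn(ds):
        _first_treatment_beam(ds).BeamName = new_name

    def sidecar_rename(doc):
        # keep DRR and reference-point linkage consistent with the rename so
        # only the invalid character is the finding
        drr = doc.get("drr", {})
        if old_name in drr:
            drr[new_name] = drr.pop(old_name)
        for rp in doc.get("reference_points", []):
            rp["contributing_beam_ids"] = [
                new_name if b == old_name else b for b in rp["contributing_beam_ids"]
            ]

    _edit_dicom(fix.plan_path, fn)
    _edit_sidecar(fix.sidecar_path, sidecar_rename)


def _mut_refpoint_over(fix: FixtureSet) -> None:
    def fn(doc):
        rp = doc["reference_points"][0]
        rp["total_dose_gy"] = round(1.10 * doc["prescription_dose_gy"], 4)
        rp["dose_per_fraction_gy"] = round(rp["total_dose_gy"] / doc["fractions"], 4)

    _edit_sidecar(fix.sidecar_path, fn)


def _mut_refpoint_contrib(fix: FixtureSet) -> None:
    _edit_sidecar(
        fix.sidecar_path,
        lambda doc: doc["reference_points"][0]["contributing_beam_ids"].pop(0),
    )


def _mut_bolus_unlinked(fix: FixtureSet) -> None:
    def fn(ds):
        beam = _first_treatment_beam(ds)
        if "ReferencedBolusSequence" in beam:
            del beam.ReferencedBolusSequence
        beam.NumberOfBoli = 0

    _edit_dicom(fix.plan_path, fn)


def _mut_drr_missing(fix: FixtureSet) -> None:
    def fn(doc):
        name = next(iter(doc["drr"]))
        doc["drr"][name]["present"] = False

    _edit_sidecar(fix.sidecar_path, fn)


def _mut_drr_overlay(fix: FixtureSet) -> None:
    def fn(doc):
        name = next(iter(doc["drr"]))
        doc["drr"][name]["overlay"] = False

    _edit_sidecar(fix.sidecar_path, fn)


def _mut_dose_rate(fix: FixtureSet) -> None:
    def fn(ds):
        beam = _first_treatment_beam(ds)
        beam.ControlPointSequence[0].DoseRateSet = 500.0

    _edit_dicom(fix.plan_path, fn)


def _mut_plan_status(fix: FixtureSet) -> None:
    _edit_sidecar(fix.sidecar_path, lambda doc: doc.update(plan_status="PLANNING_APPROVED"))


def _mut_nonclinical(fix: FixtureSet) -> None:
    _edit_sidecar(fix.sidecar_path, lambda doc: doc.update(course_intent="NON_CLINICAL"))


def _mut_calc_model(fix: FixtureSet) -> None:
    _edit_sidecar(fix.sidecar_path, lambda doc: doc.update(calc_model="PBC_OLD"))


def _mut_grid(fix: FixtureSet) -> None:
    _edit_dicom(fix.dose_path, lambda ds: setattr(ds, "PixelSpacing", [3.5, 3.5]))


def _mut_lmc(fix: FixtureSet) -> None:
    _edit_sidecar(fix.sidecar_path, lambda doc: doc.update(leaf_motion_calculator="LMC_OLD"))


def _mut_couch_struct(fix: FixtureSet) -> None:
    def fn(ds):
        ds.StructureSetROISequence = [
            r for r in ds.StructureSetROISequence if str(r.ROIName) != "CouchInterior"
        ]
        ds.RTROIObservationsSequence = [
            o
            for o in ds.RTROIObservationsSequence
            if int(o.ReferencedROINumber) != 3
        ]

    _edit_dicom(fix.struct_path, fn)


def _mut_couch_position(fix: FixtureSet) -> None:
    def fn(ds):
        for beam in ds.BeamSequence:
            if str(beam.TreatmentDeliveryType).upper() != "TREATMENT":
                continue
            beam.ControlPointSequence[0].TableTopVerticalPosition = -300.0

    _edit_dicom(fix.plan_path, fn)


def _mut_imager(fix: FixtureSet) -> None:
    def fn(doc):
        name = next(iter(doc["imager_positions"]))
        doc["imager_positions"][name]["lng"] += 50.0

    _edit_sidecar(fix.sidecar_path, fn)


def _mut_static_extra_cp(fix: FixtureSet) -> None:
    def fn(ds):
        beam = _first_treatment_beam(ds)
        import copy as _copy

        extra = _copy.deepcopy(beam.ControlPointSequence[-1])
        extra.ControlPointIndex = len(beam.ControlPointSequence)
        beam.ControlPointSequence.append(extra)
        beam.NumberOfControlPoints = len(beam.ControlPointSequence)

    _edit_dicom(fix.plan_path, fn)


def _mut_vmat_truncate(fix: FixtureSet) -> None:
    def fn(ds):
        beam = _first_treatment_beam(ds)
        cps = list(beam.ControlPointSequence)
        kept = cps[::6]
        if kept[-1] is not cps[-1]:
            kept.append(cps[-1])
        for i, cp in enumerate(kept):
            cp.ControlPointIndex = i
        beam.ControlPointSequence = kept
        beam.NumberOfControlPoints = len(kept)

    _edit_dicom(fix.plan_path, fn)


def _set_mlc_pair(cp, pair: int, a: float, b: float) -> None:
    for item in cp.BeamLimitingDevicePositionSequence:
        if item.RTBeamLimitingDeviceType == "MLCX":
            pos = [float(v) for v in item.LeafJawPositions]
            half = len(pos) // 2
            pos[pair] = a
            pos[half + pair] = b
            item.LeafJawPositions = pos


def _mut_leaf_gap(fix: FixtureSet) -> None:
    def fn(ds):
        beam = _first_treatment_beam(ds)
        cp = beam.ControlPointSequence[5]
        for item in cp.BeamLimitingDevicePositionSequence:
            if item.RTBeamLimitingDeviceType == "MLCX":
                pos = [float(v) for v in item.LeafJawPositions]
                half = len(pos) // 2
                center = 0.5 * (pos[15] + pos[half + 15])
                _set_mlc_pair(cp, 15, center - 0.1, center + 0.1)

    _edit_dicom(fix.plan_path, fn)


def _mut_leaf_speed(fix: FixtureSet) -> None:
    def fn(ds):
        beam = _first_treatment_beam(ds)
        cp = beam.ControlPointSequence[6]
        for item in cp.BeamLimitingDevicePositionSequence:
            if item.RTBeamLimitingDeviceType == "MLCX":
                pos = [float(v) for v in item.LeafJawPositions]
                half = len(pos) // 2
                _set_mlc_pair(cp, 15, pos[15], pos[half + 15] + 40.0)

    _edit_dicom(fix.plan_path, fn)


def _mut_tol_test(fix: FixtureSet) -> None:
    _edit_dicom(
        fix.plan_path,
        lambda ds: setattr(ds.ToleranceTableSequence[0], "ToleranceTableLabel", "TEST"),
    )


def _mut_tol_missing(fix: FixtureSet) -> None:
    _edit_dicom(
        fix.plan_path,
        lambda ds: setattr(ds.ToleranceTableSequence[0], "ToleranceTableLabel", ""),
    )


def _qa_path(fix: FixtureSet) -> Path:
    return next(iter(fix.qa_plan_paths.values()))


def _mut_qa_mu(fix: FixtureSet) -> None:
    def fn(ds):
        rb = ds.FractionGroupSequence[0].ReferencedBeamSequence[0]
        rb.BeamMeterset = float(rb.BeamMeterset) + 5.0

    _edit_dicom(_qa_path(fix), fn)


def _mut_qa_sid(fix: FixtureSet) -> None:
    _edit_sidecar(
        fix.sidecar_path, lambda doc: doc["qa_plans"][0].update(reference_sid_mm=1500.0)
    )


def _mut_qa_gantry(fix: FixtureSet) -> None:
    def fn(ds):
        beam = _first_treatment_beam(ds)
        for cp in beam.ControlPointSequence:
            cp.GantryAngle = 30.0

    _edit_dicom(_qa_path(fix), fn)


def _mut_qa_missing(fix: FixtureSet) -> None:
    _edit_sidecar(fix.sidecar_path, lambda doc: doc.update(qa_plans=[]))


def _mut_qa_status(fix: FixtureSet) -> None:
    _edit_sidecar(
        fix.sidecar_path, lambda doc: doc["qa_plans"][0].update(plan_status="PLANNING_APPROVED")
    )


@dataclass(frozen=True)
class _DefectDef:
    description: str
    expected_checker: str
    template: str
    apply: Callable[[FixtureSet], None]


DEFECTS: dict[str, _DefectDef] = {
    "isocenter_shift": _DefectDef(
        "first treatment beam isocenter shifted 1 mm in x",
        "isocenter_consistency", "STATIC_2FIELD", _mut_isocenter),
    "plan_name_bad_convention": _DefectDef(
        "plan display name renamed outside the naming convention",
        "plan_names", "STATIC_2FIELD", _mut_plan_name_bad),
    "course_name_bad": _DefectDef(
        "course renamed outside the course naming convention",
        "course_names", "STATIC_2FIELD", _mut_course_name),
    "image_name_bad": _DefectDef(
        "image display name outside the naming convention",
        "image_structset_names", "STATIC_2FIELD", _mut_image_name),
    "beam_name_invalid_char": _DefectDef(
        "non-whitelisted character appended to a beam name",
        "invalid_characters", "STATIC_2FIELD", _mut_beam_name_char),
    "refpoint_over_limit": _DefectDef(
        "reference point raised to 110% of prescription",
        "reference_point_limits", "STATIC_2FIELD", _mut_refpoint_over),
    "refpoint_missing_contribution": _DefectDef(
        "one treatment beam removed from all reference-point contributions",
        "reference_point_limits", "STATIC_2FIELD", _mut_refpoint_contrib),
    "bolus_unlinked": _DefectDef(
        "bolus reference removed from one treatment beam",
        "bolus_attached", "IMRT_5FIELD", _mut_bolus_unlinked),
    "drr_missing": _DefectDef(
        "DRR marked absent for one beam",
        "drr_created", "STATIC_2FIELD", _mut_drr_missing),
    "drr_overlay_missing": _DefectDef(
        "DRR overlay marked absent for one beam",
        "drr_overlay", "STATIC_2FIELD", _mut_drr_overlay),
    "dose_rate_wrong": _DefectDef(
        "treatment beam dose rate set to a non-commissioned value",
        "dose_rate", "STATIC_2FIELD", _mut_dose_rate),
    "plan_not_approved": _DefectDef(
        "clinical plan left in PLANNING_APPROVED",
        "plan_status", "STATIC_2FIELD", _mut_plan_status),
    "nonclinical_not_complete": _DefectDef(
        "course marked non-clinical while the plan is not COMPLETED",
        "nonclinical_complete", "STATIC_2FIELD", _mut_nonclinical),
    "calc_model_wrong": _DefectDef(
        "dose calculation model replaced by an outdated one",
        "calc_settings_grid", "STATIC_2FIELD", _mut_calc_model),
    "grid_too_coarse": _DefectDef(
        "dose grid coarsened from 2.5 to 3.5 mm",
        "calc_settings_grid", "STATIC_2FIELD", _mut_grid),
    "lmc_wrong": _DefectDef(
        "leaf motion calculator replaced by an outdated one",
        "leaf_motion_calculator", "IMRT_5FIELD", _mut_lmc),
    "couch_structure_missing": _DefectDef(
        "couch interior structure removed from the structure set",
        "couch_structures", "STATIC_2FIELD", _mut_couch_struct),
    "couch_position_out": _DefectDef(
        "table-top vertical start position moved outside the machine window",
        "default_couch_position", "STATIC_2FIELD", _mut_couch_position),
    "imager_position_out": _DefectDef(
        "setup-field imager longitudinal position off by 50 mm",
        "setup_imager_position", "STATIC_2FIELD", _mut_imager),
    "static_extra_cp": _DefectDef(
        "third control point appended to a static beam",
        "control_point_count", "STATIC_2FIELD", _mut_static_extra_cp),
    "vmat_cp_truncated": _DefectDef(
        "VMAT arc decimated below the minimum control-point count",
        "control_point_count", "VMAT_2ARC", _mut_vmat_truncate),
    "leaf_gap_narrow": _DefectDef(
        "one in-field leaf pair closed to a 0.2 mm gap",
        "imrt_leaf_delivery", "IMRT_5FIELD", _mut_leaf_gap),
    "leaf_speed_excess": _DefectDef(
        "one leaf jumps 40 mm between adjacent control points",
        "imrt_leaf_delivery", "IMRT_5FIELD", _mut_leaf_speed),
    "tolerance_table_test": _DefectDef(
        "tolerance table relabelled TEST",
        "tolerance_tables", "STATIC_2FIELD", _mut_tol_test),
    "tolerance_table_missing": _DefectDef(
        "tolerance table label cleared",
        "tolerance_tables", "STATIC_2FIELD", _mut_tol_missing),
    "qa_mu_mismatch": _DefectDef(
        "EPID verification beam meterset off by 5 MU",
        "qa_plans", "ONE_FX_VMAT_WITH_EPID_QA", _mut_qa_mu),
    "qa_sid_wrong": _DefectDef(
        "EPID reference images at 1500 mm SID instead of 1000 mm",
        "qa_plans", "ONE_FX_VMAT_WITH_EPID_QA", _mut_qa_sid),
    "qa_missing": _DefectDef(
        "required EPID verification plan deleted",
        "qa_plans", "ONE_FX_VMAT_WITH_EPID_QA", _mut_qa_missing),
    "qa_status_wrong_epid": _DefectDef(
        "EPID verification plan left unapproved",
        "qa_plans", "ONE_FX_VMAT_WITH_EPID_QA", _mut_qa_status),
    "qa_gantry_nonzero": _DefectDef(
        "MapCheck verification beam at gantry 30 degrees",
        "qa_plans", "ONE_FX_FFF_WITH_MAPCHECK_QA", _mut_qa_gantry),
    "qa_status_wrong_mapcheck": _DefectDef(
        "MapCheck verification plan left unapproved",
        "qa_plans", "ONE_FX_FFF_WITH_MAPCHECK_QA", _mut_qa_status),
}


def defect_spec(defect_id: str, seed: int = 0) -> DefectSpec:
    d = DEFECTS[defect_id]
    return DefectSpec(
        defect_id=defect_id,
        mutation=d.description,
        expected_checker=d.expected_checker,
        template=d.template,
        seed=seed,
    )


def inject_defect(fixture: FixtureSet, defect: str | DefectSpec, out_dir) -> FixtureSet:
    """Copy a fixture to ``out_dir`` and apply one named defect.

    The mutation touches exactly the fields named in the defect's
    description and always leaves the plan loadable.
    """
    defect_id = defect if isinstance(defect, str) else defect.defect_id
    if defect_id not in DEFECTS:
        raise ValueError(f"unknown defect {defect_id!r}")
    d = DEFECTS[defect_id]
    if d.template != fixture.template:
        raise ValueError(
            f"defect {defect_id!r} applies to template {d.template}, "
            f"fixture is {fixture.template}"
        )
    out_dir = Path(out_dir)
    if out_dir.resolve() != fixture.directory.resolve():
        if out_dir.exists():
            shutil.rmtree(out_dir)
        shutil.copytree(fixture.directory, out_dir)
    mutated = FixtureSet(
        template=fixture.template,
        seed=fixture.seed,
        directory=out_dir,
        plan_path=out_dir / fixture.plan_path.name,
        dose_path=out_dir / fixture.dose_path.name,
        struct_path=out_dir / fixture.struct_path.name,
        sidecar_path=out_dir / fixture.sidecar_path.name,
        qa_plan_paths={k: out_dir / p.name for k, p in fixture.qa_plan_paths.items()},
    )
    d.apply(mutated)
    return mutated


# ---------------------------------------------------------------------------
# Detection matrix
# ---------------------------------------------------------------------------


def evaluate_detection(
    defect_ids: Optional[Iterable[str]] = None,
    seeds: Iterable[int] = range(10),
    config: Optional[RunConfig] = None,
    workdir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the defect corpus and measure per-checker detection.

    For every (defect, seed): generate the defect's clean template fixture,
    inject the defect, assemble and run all checks, and record whether the
    mapped checker FLAGged (sensitivity) and whether any *other* checker
    changed status relative to the clean baseline (collateral).  Clean
    fixtures themselves are scored for plan-level specificity (zero FLAGs).

    Returns ``(defect_matrix, clean_table)``: the first indexed by defect id
    with columns ``expected_checker, template, n, detected, sensitivity,
    collateral``; the second indexed by (template, seed) with the FLAG count.
    """
    cfg = config or default_config()
    defect_ids = list(defect_ids) if defect_ids is not None else list(DEFECTS)
    seeds = list(seeds)

    tmp_ctx = tempfile.TemporaryDirectory(prefix="plancheck-detect-") if workdir is None else None
    base = Path(workdir) if workdir is not None else Path(tmp_ctx.name)
    try:
        templates_needed = sorted({DEFECTS[d].template for d in defect_ids} | set(TEMPLATES))
        clean_rows = []
        baselines: dict[tuple[str, int], dict[str, str]] = {}
        fixtures: dict[tuple[str, int], FixtureSet] = {}
        for template in templates_needed:
            for seed in seeds:
                fix = generate_clean_context(template, seed, base / "clean" / template / str(seed))
                report = run_checks(build_context(fix), cfg)
                fixtures[(template, seed)] = fix
                baselines[(template, seed)] = {r.checker_id: r.status.value for r in report.results}
                clean_rows.append(
                    {"template": template, "seed": seed, "flags": len(report.flagged())}
                )
        clean_df = pd.DataFrame(clean_rows).set_index(["template", "seed"])

        rows = []
        mut_dir = base / "mut"
        for defect_id in defect_ids:
            d = DEFECTS[defect_id]
            detected = 0
            collateral = 0
            for seed in seeds:
                fix = fixtures[(d.template, seed)]
                mutated = inject_defect(fix, defect_id, mut_dir)
                report = run_checks(build_context(mutated), cfg)
                statuses = {r.checker_id: r.status.value for r in report.results}
                if statuses.get(d.expected_checker) == ComplianceStatus.FLAG.value:
                    detected += 1
                baseline = baselines[(d.template, seed)]
                collateral += sum(
                    1
                    for cid, status in statuses.items()
                    if cid != d.expected_checker and status != baseline[cid]
                )
            rows.append(
                {
                    "defect_id": defect_id,
                    "expected_checker": d.expected_checker,
                    "template": d.template,
                    "n": len(seeds),
                    "detected": detected,
                    "sensitivity": detected / len(seeds) if seeds else float("nan"),
                    "collateral": collateral,
                }
            )
        return pd.DataFrame(rows).set_index("defect_id"), clean_df
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()


# ---------------------------------------------------------------------------
# Audit-log simulation
# ---------------------------------------------------------------------------


def _default_issue_rates() -> dict[str, dict[str, float]]:
    counts = datasets.load_issue_counts()
    n = {"PRE": datasets.PRE_CHECKS, "WITH": datasets.WITH_CHECKS}
    rates: dict[str, dict[str, float]] = {"PRE": {}, "WITH": {}}
    for _, row in counts.iterrows():
        rates["PRE"][row["category"]] = row["pre_count"] / n["PRE"]
        rates["WITH"][row["category"]] = row["with_count"] / n["WITH"]
    return rates


def _default_time_model() -> dict[str, dict[str, tuple[float, float, int]]]:
    """Per-person log-normal parameters (mu, sigma, n-checks) fitted to the
    bundled timing summaries: the median fixes mu = ln(median) and the
    mean/median ratio fixes sigma = sqrt(2 ln(mean/median))."""
    summary = datasets.load_timing_summary()
    model: dict[str, dict[str, tuple[float, float, int]]] = {"PRE": {}, "WITH": {}}
    for person, row in summary.iterrows():
        if person == "Overall":
            continue
        for period, tag in (("PRE", "pre"), ("WITH", "with")):
            n = int(row[f"{tag}_n"]) if not math.isnan(float(row[f"{tag}_n"] or 0)) else 0
            if n == 0 or math.isnan(float(row[f"{tag}_mean"])):
                continue
            mean = float(row[f"{tag}_mean"])
            median = float(row[f"{tag}_median"])
            mu = math.log(median)
            sigma = math.sqrt(max(2.0 * math.log(mean / median), 1e-4))
            model[period][person] = (mu, sigma, n)
    return model


@dataclass
class AuditSimConfig:
    """Conditions of the simulated two-period audit.

    Defaults reproduce the bundled study conditions: 187 / 186 chart checks
    per period, per-category issue rates equal to the empirical proportions,
    and per-person log-normal timing models fitted to the published
    mean/median summaries.
    """

    n_checks: dict[str, int] = field(
        default_factory=lambda: {"PRE": datasets.PRE_CHECKS, "WITH": datasets.WITH_CHECKS}
    )
    issue_rates: dict[str, dict[str, float]] = field(default_factory=_default_issue_rates)
    time_model: dict[str, dict[str, tuple[float, float, int]]] = field(
        default_factory=_default_time_model
    )
    seed: int = 0

    def __post_init__(self):
        for period, rates in self.issue_rates.items():
            for cat, rate in rates.items():
                if cat not in ALL_CATEGORIES:
                    raise ValueError(f"unknown category {cat!r}")
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"rate for {cat!r} ({period}) outside [0, 1]")
        for period, persons in self.time_model.items():
            for person, (mu, sigma, n) in persons.items():
                if sigma <= 0:
                    raise ValueError(f"sigma must be positive for {person!r} ({period})")


def simulate_audit_logs(cfg: AuditSimConfig, out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate seeded issue and timing logs; writes ``issues.csv`` and
    ``times.csv`` under ``out_dir`` and returns the two DataFrames.

    Issue counts per category are Binomial(n_checks, rate); per-check times
    are log-normal per person, with persons drawn in proportion to their
    recorded check counts.
    """
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    issue_rows = []
    for period in ("PRE", "WITH"):
        n = cfg.n_checks[period]
        for cat in ALL_CATEGORIES:
            rate = cfg.issue_rates.get(period, {}).get(cat, 0.0)
            count = int(rng.binomial(n, rate)) if rate > 0 else 0
            issue_rows.extend({"period": period, "category": cat} for _ in range(count))
    issues = pd.DataFrame(issue_rows, columns=["period", "category"])

    time_rows = []
    for period in ("PRE", "WITH"):
        persons = cfg.time_model.get(period, {})
        if not persons:
            continue
        ids = sorted(persons)
        weights = np.array([persons[p][2] for p in ids], dtype=float)
        weights = weights / weights.sum()
        for _ in range(cfg.n_checks[period]):
            person = ids[int(rng.choice(len(ids), p=weights))]
            mu, sigma, _n = persons[person]
            minutes = float(rng.lognormal(mean=mu, sigma=sigma))
            time_rows.append(
                {"period": period, "person": person, "minutes": round(minutes, 2)}
            )
    times = pd.DataFrame(time_rows, columns=["period", "person", "minutes"])

    issues.to_csv(out_dir / "issues.csv", index=False)
    times.to_csv(out_dir / "times.csv", index=False)
    return issues, times
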