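"""Shared fixtures: generated plan files (session-scoped, one per template)
and an in-memory plan-context builder for fast checker unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from plancheck.framework import default_config
from plancheck.plan_model import (
    Beam,
    BeamRole,
    ControlPoint,
    CouchStructure,
    CourseIntent,
    DeliveryKind,
    PlanContext,
    PlanStatus,
    ReferencePoint,
)
from plancheck.synth import TEMPLATES, build_context, generate_clean_context


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def fixtures(tmp_path_factory):
    """One clean generated fixture per template, seed 0."""
    base = tmp_path_factory.mktemp("clean")
    return {
        template: generate_clean_context(template, 0, base / template)
        for template in TEMPLATES
    }


@pytest.fixture(scope="session")
def contexts(fixtures):
    return {template: build_context(fix) for template, fix in fixtures.items()}


def _simple_beam(
    name: str,
    beam_id: str,
    *,
    role: BeamRole = BeamRole.TREATMENT,
    kind: DeliveryKind = DeliveryKind.STATIC,
    gantry: float = 0.0,
    iso=(0.0, 0.0, 0.0),
    dose_rate: float = 600.0,
    meterset: float = 100.0,
    energy: str = "6X",
    tolerance: str = "CLINICAL",
    n_cp: int = 2,
    mlc=None,
) -> Beam:
    cps = [
        ControlPoint(
            index=k,
            cumulative_meterset_weight=k / (n_cp - 1),
            gantry_angle=gantry,
            collimator_angle=0.0,
            couch_angle=0.0,
            jaw_positions=(-50.0, 50.0, -50.0, 50.0),
            mlc_leaf_positions=None if mlc is None else np.array(mlc[k], dtype=float),
            table_top_vertical=-120.0,
            table_top_longitudinal=800.0,
            table_top_lateral=0.0,
        )
        for k in range(n_cp)
    ]
    return Beam(
        beam_id=beam_id,
        beam_name=name,
        machine_name="TB1",
        energy_label=energy,
        delivery_kind=kind,
        role=role,
        dose_rate=dose_rate if role is BeamRole.TREATMENT else None,
        meterset=meterset if role is BeamRole.TREATMENT else 0.0,
        isocenter=np.array(iso, dtype=float),
        control_points=cps,
        tolerance_table_label=tolerance,
        drr_present=True,
        drr_overlay_present=True,
        imager_position=None if role is BeamRole.TREATMENT else np.array([-500.0, 0.0, 0.0]),
    )


def make_ctx(**overrides) -> PlanContext:
    """A small in-memory context that passes every default checker."""
    beams = overrides.pop("beams", None)
    if beams is None:
        beams = [
            _simple_beam("AP", "1"),
            _simple_beam("PA", "2", gantry=180.0),
            _simple_beam("SU_AP", "3", role=BeamRole.SETUP),
        ]
    ctx = PlanContext(
        plan_id="PELV_AP",
        plan_name="PELV_AP",
        course_id="C1",
        plan_status=PlanStatus.TREATMENT_APPROVED,
        course_intent=CourseIntent.CLINICAL,
        fractions=25,
        prescription_dose=50.0,
        beams=beams,
        reference_points=[
            ReferencePoint(
                ref_id="RP1",
                name="PRESC_PT",
                total_dose=50.0,
                dose_per_fraction=2.0,
                contributing_beam_ids=["AP", "PA"],
            )
        ],
        calc_model="AAA_15606",
        leaf_motion_calculator="LMC_15606",
        dose_grid_resolution=2.5,
        image_id="IMG1",
        image_name="CT_20160414",
        structure_set_id="SS1",
        structure_set_name="SS_20160414",
        patient_orientation="HFS",
        couch_structures=[
            CouchStructure("CouchSurface", 0.7),
            CouchStructure("CouchInterior", 0.2),
        ],
        bolus_structures=[],
    )
    for key, value in overrides.items():
        setattr(ctx, key, value)
    return ctx


@pytest.fixture
def ctx_factory():
    return make_ctx


@pytest.fixture
def simple_beam_factory():
    return _simple_beam
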