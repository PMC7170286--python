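"""The individual plan-integrity checkers.

Each checker is a function ``(PlanContext, RunConfig) -> CheckResult`` and
is registered under a stable id in :data:`REGISTRY`.  The default profile
(``data/default_config.yaml``) enables 25 checkers — one per row of the
shipped rule table, where the QA-plan row is a composite of 10 constituent
sub-checks, for 34 checks in total.

Conventions shared by all checkers:

* a checker that cannot see the data it needs (a sidecar field that was
  never exported) FLAGs with an "insufficient data" message — it never
  certifies what it cannot see;
* tolerance comparisons use ``<=`` at the boundary: a value exactly at
  tolerance passes;
* a checker whose preconditions do not apply to the plan at hand (e.g. the
  leaf-motion-calculator check on a plan with no IMRT beams) PASSes with a
  "not applicable" message, keeping the flag count meaningful.

Thresholds shipped in the default configuration (naming regexes, machine
lists, dose-rate tables, couch windows) are illustrative; every one of them
is intended to be replaced by institution policy.  See ``docs/checkers.md``.
"""

from __future__ import annotations

import re
from typing import Optional

import numpy as np

from .framework import CheckResult, ComplianceStatus, RunConfig
from .plan_model import (
    Beam,
    BeamRole,
    CourseIntent,
    DeliveryKind,
    PlanContext,
    PlanStatus,
    QAKind,
)

__all__ = [
    "REGISTRY",
    "DEFAULT_PARAMS",
    "TABLE_ROWS",
    "QA_SUBCHECKS",
    "check_isocenter_consistency",
    "check_naming_conventions",
    "check_invalid_characters",
    "check_reference_point_limits",
    "check_bolus",
    "check_drr",
    "check_dose_rate",
    "check_plan_status",
    "check_calc_settings",
    "check_couch",
    "check_setup_fields",
    "check_control_points",
    "check_imrt_leaf_delivery",
    "report_patient_orientation",
    "check_tolerance_tables",
    "report_overrides_and_warnings",
    "check_qa_plans",
]

PASS = ComplianceStatus.PASS
FLAG = ComplianceStatus.FLAG
REPORT = ComplianceStatus.REPORT


def _pass(cid: str, messages: Optional[list[str]] = None, **details) -> CheckResult:
    return CheckResult(cid, PASS, messages or [], details)


def _flag(cid: str, messages: list[str], **details) -> CheckResult:
    return CheckResult(cid, FLAG, messages, details)


def _report(cid: str, messages: list[str], **details) -> CheckResult:
    return CheckResult(cid, REPORT, messages, details)


def _insufficient(cid: str, what: str) -> CheckResult:
    return _flag(cid, [f"insufficient data: {what}"])


# ---------------------------------------------------------------------------
# Geometry / machine-state checkers
# ---------------------------------------------------------------------------


def check_isocenter_consistency(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """All fields must share a single isocenter (within tolerance)."""
    cid = "isocenter_consistency"
    p = cfg.params_for(cid)
    tol = float(p["tolerance_mm"])
    known = [(b, b.isocenter) for b in ctx.beams if b.isocenter is not None]
    if not known:
        return _insufficient(cid, "no beam carries an isocenter position")
    ref_beam, ref = known[0]
    offenders = []
    for beam, iso in known[1:]:
        dev = float(np.max(np.abs(iso - ref)))
        if dev > tol:
            offenders.append(f"{beam.beam_name} deviates {dev:.3f} mm from {ref_beam.beam_name}")
    if offenders:
        return _flag(cid, offenders)
    return _pass(cid, [f"all {len(known)} fields share the isocenter (tolerance {tol} mm)"])


def check_naming_conventions(ctx: PlanContext, cfg: RunConfig, scope: str = "plan") -> CheckResult:
    """Course / plan / image & structure-set display names match policy.

    ``scope`` selects which convention this registry entry enforces.  Each
    naming rule carries a ``severity`` switch (``flag`` or ``report``) so an
    institution can soften a convention without disabling it.
    """
    cid = {"course": "course_names", "plan": "plan_names", "image_structset": "image_structset_names"}[scope]
    p = cfg.params_for(cid)
    severity = str(p.get("severity", "flag")).lower()

    targets: list[tuple[str, Optional[str], str]] = []
    if scope == "course":
        targets.append(("course name", ctx.course_id, p["regex"]))
    elif scope == "plan":
        targets.append(("plan name", ctx.plan_name, p["regex"]))
    else:
        targets.append(("image name", ctx.image_name, p["image_regex"]))
        targets.append(("structure set name", ctx.structure_set_name, p["structset_regex"]))

    problems = []
    for label, value, pattern in targets:
        if value is None:
            return _insufficient(cid, f"{label} not available")
        if value == "":
            problems.append(f"{label} is empty")
        elif not re.fullmatch(pattern, value):
            problems.append(f"{label} {value!r} does not match convention {pattern!r}")
    if problems:
        if severity == "report":
            return _report(cid, problems)
        return _flag(cid, problems)
    return _pass(cid)


def check_invalid_characters(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """Names contain only whitelisted characters (non-ASCII and control
    characters break downstream export chains)."""
    cid = "invalid_characters"
    p = cfg.params_for(cid)
    allowed = set(str(p["whitelist"]))
    fields: list[tuple[str, Optional[str]]] = [
        ("plan name", ctx.plan_name),
        ("course name", ctx.course_id),
        ("image name", ctx.image_name),
        ("structure set name", ctx.structure_set_name),
    ]
    fields += [(f"beam name ({b.beam_id})", b.beam_name) for b in ctx.beams]
    problems = []
    for label, value in fields:
        if value is None:
            continue  # absence is the naming checker's finding
        bad = sorted({ch for ch in value if ch not in allowed})
        if bad:
            listing = ", ".join(repr(ch) for ch in bad)
            problems.append(f"{label} {value!r} contains invalid character(s) {listing}")
    if problems:
        return _flag(cid, problems)
    return _pass(cid)


def check_reference_point_limits(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """Reference-point doses stay within prescription limits and every
    treatment beam contributes to at least one reference point."""
    cid = "reference_point_limits"
    p = cfg.params_for(cid)
    if ctx.prescription_dose is None:
        return _insufficient(cid, "prescription dose not available")
    if ctx.fractions is None:
        return _insufficient(cid, "fraction count not available")
    if not ctx.reference_points:
        return _flag(cid, ["plan has no reference points"])
    limit = float(p["limit_multiplier"]) * ctx.prescription_dose
    rel_tol = float(p["consistency_rel_tol"])
    problems = []
    covered: set[str] = set()
    for rp in ctx.reference_points:
        covered.update(rp.contributing_beam_ids)
        if rp.total_dose > limit + 1e-9:
            problems.append(
                f"reference point {rp.name}: total dose {rp.total_dose:.2f} Gy exceeds "
                f"{p['limit_multiplier']} x prescription ({limit:.2f} Gy)"
            )
        if rp.dose_per_fraction is not None and rp.total_dose > 0:
            expected = rp.dose_per_fraction * ctx.fractions
            if abs(expected - rp.total_dose) > rel_tol * rp.total_dose:
                problems.append(
                    f"reference point {rp.name}: dose/fx x fractions = {expected:.2f} Gy "
                    f"disagrees with total dose {rp.total_dose:.2f} Gy"
                )
    for beam in ctx.treatment_beams():
        if beam.beam_id not in covered and beam.beam_name not in covered:
            problems.append(f"beam {beam.beam_name} contributes to no reference point")
    if problems:
        return _flag(cid, problems)
    return _pass(cid)


def check_bolus(ctx: PlanContext, cfg: RunConfig, scope: str = "attached") -> CheckResult:
    """Bolus linkage (``attached``) and non-water bolus overrides (``hu``).

    If any bolus structure exists, every treatment beam must reference it —
    a bolus missing from one field silently changes that field's dose.  The
    ``hu`` scope reports each bolus whose assigned value differs from water.
    """
    if scope == "attached":
        cid = "bolus_attached"
        p = cfg.params_for(cid)
        if not ctx.bolus_structures:
            return _pass(cid, ["no bolus structures in plan"])
        per_bolus = p.get("per_bolus_beams") or {}
        problems = []
        for bolus in ctx.bolus_structures:
            wanted = per_bolus.get(bolus.name)
            beams = ctx.treatment_beams()
            if wanted is not None:
                beams = [b for b in beams if b.beam_name in wanted or b.beam_id in wanted]
            for beam in beams:
                if bolus.name not in beam.bolus_ids:
                    problems.append(
                        f"bolus {bolus.name!r} is not attached to beam {beam.beam_name}"
                    )
        if problems:
            return _flag(cid, problems)
        return _pass(cid)

    cid = "bolus_hu"
    p = cfg.params_for(cid)
    if not ctx.bolus_structures:
        return _pass(cid, ["no bolus structures in plan"])
    water = float(p["water_hu"])
    tol = float(p["tolerance_hu"])
    notes = []
    for bolus in ctx.bolus_structures:
        if bolus.hu is None:
            notes.append(f"bolus {bolus.name!r}: assigned HU not evaluable")
        elif abs(bolus.hu - water) > tol:
            notes.append(f"bolus {bolus.name!r}: assigned {bolus.hu:+.0f} HU (non-water)")
    if notes:
        return _report(cid, notes)
    return _pass(cid, ["all bolus structures at water-equivalent HU"])


def check_drr(ctx: PlanContext, cfg: RunConfig, scope: str = "created") -> CheckResult:
    """DRRs exist for every field (``created``) and carry graticule/field
    overlays (``overlay``).

    A beam with no DRR at all is the ``created`` checker's finding; the
    ``overlay`` checker treats such beams as not applicable so one defect
    maps to one checker.
    """
    cid = "drr_created" if scope == "created" else "drr_overlay"
    problems = []
    insufficient = []
    applicable = 0
    for beam in ctx.beams:
        if scope == "created":
            value = beam.drr_present
        else:
            if beam.drr_present is False:
                continue
            value = beam.drr_overlay_present
        applicable += 1
        if value is None:
            insufficient.append(beam.beam_name)
        elif value is False:
            what = "no DRR" if scope == "created" else "no overlay on DRR"
            problems.append(f"beam {beam.beam_name}: {what}")
    if insufficient:
        return _insufficient(cid, f"DRR metadata missing for beam(s) {', '.join(insufficient)}")
    if problems:
        return _flag(cid, problems)
    if applicable == 0:
        return _pass(cid, ["not applicable: no beams with DRRs to evaluate"])
    return _pass(cid)


def check_dose_rate(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """Each treatment beam's dose rate is an allowed value for its machine
    and energy."""
    cid = "dose_rate"
    p = cfg.params_for(cid)
    allowed_map = p["allowed"]
    problems = []
    for beam in ctx.treatment_beams():
        if beam.dose_rate is None:
            return _insufficient(cid, f"beam {beam.beam_name} has no dose rate")
        machine = allowed_map.get(beam.machine_name)
        if machine is None:
            problems.append(f"beam {beam.beam_name}: machine {beam.machine_name!r} not in configuration")
            continue
        allowed = machine.get(beam.energy_label)
        if allowed is None:
            problems.append(
                f"beam {beam.beam_name}: energy {beam.energy_label!r} not configured "
                f"for machine {beam.machine_name!r}"
            )
            continue
        if not any(abs(beam.dose_rate - float(a)) <= 1e-6 for a in allowed):
            problems.append(
                f"beam {beam.beam_name}: dose rate {beam.dose_rate:g} MU/min not in "
                f"allowed set {sorted(float(a) for a in allowed)} for {beam.energy_label}"
            )
    if problems:
        return _flag(cid, problems)
    return _pass(cid)


# ---------------------------------------------------------------------------
# Status / settings checkers
# ---------------------------------------------------------------------------


def check_plan_status(ctx: PlanContext, cfg: RunConfig, scope: str = "clinical") -> CheckResult:
    """Clinical plans carry the required approval status; plans in
    non-clinical courses are set to completed."""
    cid = "plan_status" if scope == "clinical" else "nonclinical_complete"
    p = cfg.params_for(cid)
    if ctx.course_intent is None:
        return _insufficient(cid, "course intent not available")
    if scope == "clinical":
        if ctx.course_intent is not CourseIntent.CLINICAL:
            return _pass(cid, ["not applicable: plan is not in a clinical course"])
        required = PlanStatus(str(p["required_status"]).upper())
        if ctx.plan_status is None:
            return _insufficient(cid, "plan approval status not available")
        if ctx.plan_status is not required:
            return _flag(
                cid,
                [f"plan status is {ctx.plan_status.value}, required {required.value}"],
            )
        return _pass(cid)
    # non-clinical scope
    if ctx.course_intent is not CourseIntent.NON_CLINICAL:
        return _pass(cid, ["not applicable: course is not non-clinical"])
    if ctx.plan_status is None:
        return _insufficient(cid, "plan approval status not available")
    if ctx.plan_status is not PlanStatus.COMPLETED:
        return _flag(
            cid,
            [
                f"plan in non-clinical course has status {ctx.plan_status.value}; "
                f"non-clinical courses must be set to COMPLETED"
            ],
        )
    return _pass(cid)


def check_calc_settings(ctx: PlanContext, cfg: RunConfig, scope: str = "model_grid") -> CheckResult:
    """Dose algorithm and grid size match policy (``model_grid``); IMRT
    plans used the configured leaf-motion calculator (``lmc``)."""
    if scope == "model_grid":
        cid = "calc_settings_grid"
        p = cfg.params_for(cid)
        problems = []
        if ctx.calc_model is None:
            return _insufficient(cid, "calculation model not available")
        if ctx.calc_model != str(p["model"]):
            problems.append(
                f"calculation model {ctx.calc_model!r} differs from configured {p['model']!r}"
            )
        if ctx.dose_grid_resolution is None:
            return _insufficient(cid, "dose grid resolution not available")
        grid_limit = float(p["default_grid_mm"])
        if ctx.dose_grid_resolution > grid_limit + 1e-9:
            problems.append(
                f"dose grid {ctx.dose_grid_resolution:g} mm coarser than default "
                f"{grid_limit:g} mm"
            )
        if problems:
            return _flag(cid, problems)
        return _pass(cid)

    cid = "leaf_motion_calculator"
    p = cfg.params_for(cid)
    imrt = [b for b in ctx.treatment_beams() if b.delivery_kind is DeliveryKind.IMRT]
    if not imrt:
        return _pass(cid, ["not applicable: no IMRT beams"])
    if ctx.leaf_motion_calculator is None:
        return _insufficient(cid, "leaf motion calculator not available")
    if ctx.leaf_motion_calculator != str(p["model"]):
        return _flag(
            cid,
            [
                f"leaf motion calculator {ctx.leaf_motion_calculator!r} differs from "
                f"configured {p['model']!r}"
            ],
        )
    return _pass(cid)


def check_couch(ctx: PlanContext, cfg: RunConfig, scope: str = "structures") -> CheckResult:
    """Machine-appropriate couch model inserted with the right density
    overrides (``structures``); table-top start position inside the
    per-machine window (``position``)."""
    machines = sorted({b.machine_name for b in ctx.treatment_beams()})
    if scope == "structures":
        cid = "couch_structures"
        p = cfg.params_for(cid)
        tol = float(p.get("density_tolerance", 0.01))
        present = {c.name: c.density for c in ctx.couch_structures}
        problems = []
        for machine in machines:
            required = p["required"].get(machine)
            if required is None:
                problems.append(f"machine {machine!r} not in couch configuration")
                continue
            for name, density in required.items():
                if name not in present:
                    problems.append(f"couch structure {name!r} (machine {machine}) not found")
                elif present[name] is None:
                    problems.append(f"couch structure {name!r} has no density assignment")
                elif abs(present[name] - float(density)) > tol:
                    problems.append(
                        f"couch structure {name!r}: density {present[name]:g} differs from "
                        f"required {float(density):g}"
                    )
        if problems:
            return _flag(cid, problems)
        return _pass(cid)

    cid = "default_couch_position"
    p = cfg.params_for(cid)
    problems = []
    for beam in ctx.treatment_beams():
        windows = p["windows"].get(beam.machine_name)
        if windows is None:
            problems.append(f"machine {beam.machine_name!r} not in couch-position configuration")
            continue
        cp = beam.control_points[0] if beam.control_points else None
        values = {
            "vertical": None if cp is None else cp.table_top_vertical,
            "longitudinal": None if cp is None else cp.table_top_longitudinal,
            "lateral": None if cp is None else cp.table_top_lateral,
        }
        for axis, value in values.items():
            lo, hi = (float(v) for v in windows[axis])
            if value is None:
                return _insufficient(cid, f"beam {beam.beam_name} has no table-top {axis} position")
            if not (lo - 1e-9 <= value <= hi + 1e-9):
                problems.append(
                    f"beam {beam.beam_name}: table-top {axis} {value:g} mm outside "
                    f"window [{lo:g}, {hi:g}] mm"
                )
    if problems:
        return _flag(cid, problems)
    return _pass(cid)


def check_setup_fields(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """Setup fields exist and their imagers sit at the expected position."""
    cid = "setup_imager_position"
    p = cfg.params_for(cid)
    setups = ctx.setup_beams()
    if not setups:
        if p.get("require_setup_fields", True):
            return _flag(cid, ["no setup fields found"])
        return _pass(cid, ["not applicable: plan has no setup fields"])
    expected = np.array([float(p["expected"][k]) for k in ("vrt", "lng", "lat")])
    tol = float(p["tolerance_mm"])
    problems = []
    for beam in setups:
        if beam.imager_position is None:
            return _insufficient(cid, f"imager position unknown for setup field {beam.beam_name}")
        dev = np.abs(beam.imager_position - expected)
        if np.any(dev > tol + 1e-9):
            axis = ("vrt", "lng", "lat")[int(np.argmax(dev))]
            problems.append(
                f"setup field {beam.beam_name}: imager {axis} off by {float(np.max(dev)):.1f} mm "
                f"(tolerance {tol:g} mm)"
            )
    if problems:
        return _flag(cid, problems)
    return _pass(cid)


# ---------------------------------------------------------------------------
# Delivery-sequence checkers
# ---------------------------------------------------------------------------


def check_control_points(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """Control-point counts are valid for each delivery technique."""
    cid = "control_point_count"
    p = cfg.params_for(cid)
    problems = []
    for beam in ctx.beams:
        n = beam.n_control_points
        if beam.delivery_kind is DeliveryKind.STATIC:
            if n != 2:
                problems.append(f"static beam {beam.beam_name}: {n} control points (expected 2)")
        elif beam.delivery_kind is DeliveryKind.IMRT:
            if not (2 <= n <= int(p["max_imrt"])):
                problems.append(
                    f"IMRT beam {beam.beam_name}: {n} control points outside "
                    f"[2, {p['max_imrt']}]"
                )
        else:  # VMAT
            if not (int(p["min_vmat"]) <= n <= int(p["max_vmat"])):
                problems.append(
                    f"VMAT beam {beam.beam_name}: {n} control points outside "
                    f"[{p['min_vmat']}, {p['max_vmat']}]"
                )
    if problems:
        return _flag(cid, problems)
    return _pass(cid)


def check_imrt_leaf_delivery(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """Dynamic deliveries are mechanically feasible.

    Two failure modes are screened: a leaf pair open by less than the
    minimum dynamic gap while inside the field (small gaps are undeliverable
    and dosimetrically unstable — a closed pair parked behind a jaw is
    fine), and a leaf whose required speed between two control points —
    ``|Δposition| · dose_rate / (ΔMU · 60)`` mm/s — exceeds the machine's
    maximum.
    """
    cid = "imrt_leaf_delivery"
    p = cfg.params_for(cid)
    min_gap = float(p["min_gap_mm"])
    closed_gap = float(p["closed_gap_mm"])
    max_speed = float(p["max_leaf_speed_mm_s"])
    dynamic = [
        b
        for b in ctx.treatment_beams()
        if b.delivery_kind in (DeliveryKind.IMRT, DeliveryKind.VMAT)
        and any(cp.mlc_leaf_positions is not None for cp in b.control_points)
    ]
    if not dynamic:
        return _pass(cid, ["not applicable: no dynamic MLC beams"])
    problems = []
    for beam in dynamic:
        if beam.dose_rate is None or beam.meterset is None:
            return _insufficient(cid, f"beam {beam.beam_name} lacks dose rate or meterset")
        mlc = np.array([cp.mlc_leaf_positions for cp in beam.control_points])  # (ncp, 2, npairs)
        weights = np.array([cp.cumulative_meterset_weight for cp in beam.control_points])
        gaps = mlc[:, 1, :] - mlc[:, 0, :]
        for k, cp in enumerate(beam.control_points):
            x1, x2 = cp.jaw_positions[0], cp.jaw_positions[1]
            behind_jaw = (mlc[k, 1, :] <= x1 + 1e-9) | (mlc[k, 0, :] >= x2 - 1e-9)
            closed = gaps[k] <= closed_gap + 1e-9
            narrow = gaps[k] < min_gap - 1e-9
            bad = np.nonzero(narrow & ~(closed & behind_jaw))[0]
            for pair in bad.tolist():
                problems.append(
                    f"beam {beam.beam_name}, CP {cp.index}, leaf pair {pair}: gap "
                    f"{gaps[k, pair]:.2f} mm < minimum {min_gap:g} mm in field"
                )
        d_mu = np.diff(weights) * beam.meterset
        d_pos = np.max(np.abs(np.diff(mlc, axis=0)), axis=(1, 2))  # per segment
        for k in range(len(d_mu)):
            if d_mu[k] <= 0:
                if d_pos[k] > 1e-6:
                    problems.append(
                        f"beam {beam.beam_name}, CP {k}->{k + 1}: leaf motion "
                        f"{d_pos[k]:.1f} mm with no meterset delivered"
                    )
                continue
            speed = d_pos[k] * beam.dose_rate / (d_mu[k] * 60.0)
            if speed > max_speed + 1e-9:
                problems.append(
                    f"beam {beam.beam_name}, CP {k}->{k + 1}: required leaf speed "
                    f"{speed:.1f} mm/s exceeds maximum {max_speed:g} mm/s"
                )
    if problems:
        return _flag(cid, problems)
    return _pass(cid)


# ---------------------------------------------------------------------------
# Report-only checkers
# ---------------------------------------------------------------------------


def report_patient_orientation(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    cid = "patient_orientation"
    if ctx.patient_orientation is None:
        return _insufficient(cid, "patient orientation not available")
    return _report(cid, [f"patient orientation: {ctx.patient_orientation}"])


def check_tolerance_tables(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """Flag non-clinical tolerance tables; otherwise report what is in use.

    A label on the forbidden list (e.g. ``TEST``) can never be clinical and
    flags outright.  Any clinically plausible label is reported for the
    reviewer to judge — the desired table depends on the treatment site, so
    this check cannot be made fully pass/fail.
    """
    cid = "tolerance_tables"
    p = cfg.params_for(cid)
    forbidden = {str(x).upper() for x in p["forbidden_labels"]}
    problems = []
    labels = set()
    for beam in ctx.treatment_beams():
        label = beam.tolerance_table_label
        if not label:
            problems.append(f"beam {beam.beam_name}: no tolerance table assigned")
        elif label.upper() in forbidden:
            problems.append(f"beam {beam.beam_name}: non-clinical tolerance table {label!r}")
        else:
            labels.add(label)
    for beam in ctx.setup_beams():
        if beam.tolerance_table_label:
            labels.add(beam.tolerance_table_label)
    if problems:
        return _flag(cid, problems)
    return _report(cid, [f"tolerance tables in use: {', '.join(sorted(labels)) or 'none'}"])


def report_overrides_and_warnings(
    ctx: PlanContext, cfg: RunConfig, scope: str = "overrides"
) -> CheckResult:
    """List CT density overrides (``overrides``) and unusual calculation
    warnings (``warnings``); nothing to report is a PASS."""
    if scope == "overrides":
        cid = "ct_density_overrides"
        if not ctx.density_overrides:
            return _pass(cid, ["no density overrides"])
        notes = [
            f"override: {o.structure_name} = {o.value:g} ({o.unit})" for o in ctx.density_overrides
        ]
        return _report(cid, notes)

    cid = "unusual_warnings"
    p = cfg.params_for(cid)
    patterns = [re.compile(pat) for pat in p["patterns"]]
    hits = [w for w in ctx.warnings if any(pat.search(w) for pat in patterns)]
    if hits:
        return _report(cid, [f"warning: {w}" for w in hits])
    return _pass(cid, ["no unusual warnings"])


# ---------------------------------------------------------------------------
# QA-plan composite checker
# ---------------------------------------------------------------------------

QA_SUBCHECKS = [
    "verification_plan_in_qa_course",
    "epid_naming_convention",
    "epid_reference_sid",
    "epid_mu_cp_match",
    "mapcheck_plan_created",
    "mapcheck_gantry_zero",
    "qa_tolerance_tables_defined",
    "qa_treatment_time_defined",
    "epid_plan_status",
    "mapcheck_plan_status",
]


def _qa_gates(ctx: PlanContext) -> dict[str, bool]:
    one_fx = ctx.fractions == 1
    modulated = [
        b
        for b in ctx.treatment_beams()
        if b.delivery_kind in (DeliveryKind.IMRT, DeliveryKind.VMAT)
    ]
    energies = {b.energy_label for b in modulated}
    return {
        "epid_compare": one_fx and bool(modulated) and bool(energies & {"6X", "15X"}),
        "mapcheck_required": one_fx and bool(modulated) and "6X-FFF" in energies,
    }


def check_qa_plans(ctx: PlanContext, cfg: RunConfig) -> CheckResult:
    """Composite QA-plan checker: 10 constituent sub-checks, flagging if any
    one fails.  Sub-checks whose applicability gate is closed (e.g. the EPID
    MU/CP comparison on a multi-fraction plan) count as not applicable."""
    cid = "qa_plans"
    p = cfg.params_for(cid)
    gates = _qa_gates(ctx)
    epid = [q for q in ctx.qa_plans if q.qa_kind is QAKind.EPID]
    mapcheck = [q for q in ctx.qa_plans if q.qa_kind is QAKind.MAPCHECK]
    outcomes: list[tuple[str, Optional[bool], str]] = []  # (sub_id, ok/None=n-a, message)

    # 1. every verification plan lives in a QA course
    if ctx.qa_plans:
        bad = [
            q.qa_plan_id
            for q in ctx.qa_plans
            if not (
                q.course_intent is CourseIntent.QA
                or (q.course_id and re.search(p["qa_course_regex"], q.course_id))
            )
        ]
        outcomes.append(
            ("verification_plan_in_qa_course", not bad, f"not in QA course: {', '.join(bad)}" if bad else "ok")
        )
    else:
        outcomes.append(("verification_plan_in_qa_course", None, "no QA plans"))

    # 2. EPID naming convention
    if epid:
        bad = [q.qa_plan_id for q in epid if not re.fullmatch(p["epid_name_regex"], q.qa_plan_id)]
        outcomes.append(("epid_naming_convention", not bad, f"bad name(s): {', '.join(bad)}" if bad else "ok"))
    else:
        outcomes.append(("epid_naming_convention", None, "no EPID plans"))

    # 3. EPID reference images at the correct SID
    if epid:
        msgs = []
        ok = True
        for q in epid:
            if q.reference_sid is None:
                ok = False
                msgs.append(f"{q.qa_plan_id}: SID unknown (insufficient data)")
            elif abs(q.reference_sid - float(p["epid_sid_mm"])) > float(p["sid_tolerance_mm"]) + 1e-9:
                ok = False
                msgs.append(f"{q.qa_plan_id}: SID {q.reference_sid:g} mm != {p['epid_sid_mm']:g} mm")
        outcomes.append(("epid_reference_sid", ok, "; ".join(msgs) or "ok"))
    else:
        outcomes.append(("epid_reference_sid", None, "no EPID plans"))

    # 4. EPID dosimetry comparison, gated on 1 fx, IMRT/VMAT, 6X/15X
    if gates["epid_compare"]:
        if not epid:
            outcomes.append(("epid_mu_cp_match", False, "EPID verification plan required but absent"))
        else:
            msgs = []
            ok = True
            qa_beams = {b.beam_name: b for q in epid for b in q.beams if b.role is BeamRole.TREATMENT}
            for beam in ctx.treatment_beams():
                qa_beam = qa_beams.get(beam.beam_name)
                if qa_beam is None:
                    ok = False
                    msgs.append(f"no QA beam matches {beam.beam_name}")
                    continue
                if (
                    beam.meterset is not None
                    and qa_beam.meterset is not None
                    and abs(beam.meterset - qa_beam.meterset) > float(p["mu_tolerance"]) + 1e-9
                ):
                    ok = False
                    msgs.append(
                        f"{beam.beam_name}: MU {qa_beam.meterset:g} differs from clinical "
                        f"{beam.meterset:g} (tolerance {p['mu_tolerance']} MU)"
                    )
                if qa_beam.n_control_points != beam.n_control_points:
                    ok = False
                    msgs.append(
                        f"{beam.beam_name}: {qa_beam.n_control_points} CPs vs clinical "
                        f"{beam.n_control_points}"
                    )
                else:
                    w_clin = np.array([cp.cumulative_meterset_weight for cp in beam.control_points])
                    w_qa = np.array([cp.cumulative_meterset_weight for cp in qa_beam.control_points])
                    dev = float(np.max(np.abs(w_clin - w_qa))) if len(w_clin) else 0.0
                    if dev > float(p["weight_tolerance"]) + 1e-12:
                        ok = False
                        msgs.append(f"{beam.beam_name}: cumulative weights deviate by {dev:.2e}")
            outcomes.append(("epid_mu_cp_match", ok, "; ".join(msgs) or "MU and control points match"))
    else:
        outcomes.append(("epid_mu_cp_match", None, "gate closed (needs 1 fx, IMRT/VMAT, 6X or 15X)"))

    # 5. MapCheck plan created, gated on 1 fx, IMRT/VMAT, 6X-FFF
    if gates["mapcheck_required"]:
        outcomes.append(
            (
                "mapcheck_plan_created",
                bool(mapcheck),
                "ok" if mapcheck else "MapCheck plan required for 1-fx IMRT/VMAT 6X-FFF but absent",
            )
        )
    else:
        outcomes.append(("mapcheck_plan_created", None, "gate closed (needs 1 fx, IMRT/VMAT, 6X-FFF)"))

    # 6. MapCheck beams all at gantry 0
    if mapcheck:
        msgs = []
        ok = True
        tol = float(p["gantry_tolerance_deg"])
        for q in mapcheck:
            for beam in q.beams:
                if beam.role is not BeamRole.TREATMENT:
                    continue
                angles = np.array([cp.gantry_angle for cp in beam.control_points])
                dev = np.minimum(angles, 360.0 - angles)  # distance to 0 on the circle
                if np.any(dev > tol + 1e-9):
                    ok = False
                    msgs.append(
                        f"{q.qa_plan_id}/{beam.beam_name}: gantry {float(angles[np.argmax(dev)]):g} deg != 0"
                    )
        outcomes.append(("mapcheck_gantry_zero", ok, "; ".join(msgs) or "ok"))
    else:
        outcomes.append(("mapcheck_gantry_zero", None, "no MapCheck plans"))

    # 7 & 8. tolerance tables and treatment time defined on all QA plans
    if ctx.qa_plans:
        bad_tol = [q.qa_plan_id for q in ctx.qa_plans if not q.tolerance_table_label]
        outcomes.append(
            (
                "qa_tolerance_tables_defined",
                not bad_tol,
                f"no tolerance table: {', '.join(bad_tol)}" if bad_tol else "ok",
            )
        )
        bad_time = [q.qa_plan_id for q in ctx.qa_plans if q.treatment_time_defined is not True]
        outcomes.append(
            (
                "qa_treatment_time_defined",
                not bad_time,
                f"treatment time not defined: {', '.join(bad_time)}" if bad_time else "ok",
            )
        )
    else:
        outcomes.append(("qa_tolerance_tables_defined", None, "no QA plans"))
        outcomes.append(("qa_treatment_time_defined", None, "no QA plans"))

    # 9 & 10. QA plan approval statuses
    required = PlanStatus(str(p["required_status"]).upper())
    for sub_id, plans in (("epid_plan_status", epid), ("mapcheck_plan_status", mapcheck)):
        if plans:
            bad = [
                f"{q.qa_plan_id} ({q.plan_status.value if q.plan_status else 'unknown'})"
                for q in plans
                if q.plan_status is not required
            ]
            outcomes.append((sub_id, not bad, f"wrong status: {', '.join(bad)}" if bad else "ok"))
        else:
            outcomes.append((sub_id, None, f"no {'EPID' if 'epid' in sub_id else 'MapCheck'} plans"))

    assert [o[0] for o in outcomes] == QA_SUBCHECKS
    messages = []
    any_fail = False
    details = {}
    for sub_id, ok, msg in outcomes:
        state = "n/a" if ok is None else ("pass" if ok else "FAIL")
        details[sub_id] = state
        messages.append(f"[{state}] {sub_id}: {msg}")
        if ok is False:
            any_fail = True
    status = FLAG if any_fail else PASS
    return CheckResult(cid, status, messages, details)


# ---------------------------------------------------------------------------
# Registry, defaults and the rule-table map
# ---------------------------------------------------------------------------

REGISTRY = {
    # imported without modification from the originating institution
    "isocenter_consistency": check_isocenter_consistency,
    "tolerance_tables": check_tolerance_tables,
    "drr_created": lambda ctx, cfg: check_drr(ctx, cfg, scope="created"),
    # adapted checkers
    "patient_orientation": report_patient_orientation,
    "image_structset_names": lambda ctx, cfg: check_naming_conventions(ctx, cfg, scope="image_structset"),
    "course_names": lambda ctx, cfg: check_naming_conventions(ctx, cfg, scope="course"),
    "plan_names": lambda ctx, cfg: check_naming_conventions(ctx, cfg, scope="plan"),
    "reference_point_limits": check_reference_point_limits,
    "bolus_attached": lambda ctx, cfg: check_bolus(ctx, cfg, scope="attached"),
    "drr_overlay": lambda ctx, cfg: check_drr(ctx, cfg, scope="overlay"),
    "dose_rate": check_dose_rate,
    "plan_status": lambda ctx, cfg: check_plan_status(ctx, cfg, scope="clinical"),
    "calc_settings_grid": lambda ctx, cfg: check_calc_settings(ctx, cfg, scope="model_grid"),
    # locally developed checkers
    "couch_structures": lambda ctx, cfg: check_couch(ctx, cfg, scope="structures"),
    "unusual_warnings": lambda ctx, cfg: report_overrides_and_warnings(ctx, cfg, scope="warnings"),
    "invalid_characters": check_invalid_characters,
    "control_point_count": check_control_points,
    "imrt_leaf_delivery": check_imrt_leaf_delivery,
    "leaf_motion_calculator": lambda ctx, cfg: check_calc_settings(ctx, cfg, scope="lmc"),
    "ct_density_overrides": lambda ctx, cfg: report_overrides_and_warnings(ctx, cfg, scope="overrides"),
    "bolus_hu": lambda ctx, cfg: check_bolus(ctx, cfg, scope="hu"),
    "nonclinical_complete": lambda ctx, cfg: check_plan_status(ctx, cfg, scope="nonclinical"),
    "default_couch_position": lambda ctx, cfg: check_couch(ctx, cfg, scope="position"),
    "setup_imager_position": check_setup_fields,
    "qa_plans": check_qa_plans,
}

#: Row-level metadata for the shipped rule table: id -> (kind, title).
#: ``kind`` is "P/F" for pass/flag rules and "R" for report-only rules.  The
#: QA row is a composite of the 10 sub-checks in :data:`QA_SUBCHECKS`.
TABLE_ROWS = {
    "isocenter_consistency": ("P/F", "Isocenter the same for all fields"),
    "tolerance_tables": ("R", "Report tolerance tables"),
    "drr_created": ("P/F", "Verify DRRs created"),
    "patient_orientation": ("R", "Report patient orientation"),
    "image_structset_names": ("P/F", "Image and structure set names follow convention"),
    "course_names": ("P/F", "Course names follow convention"),
    "plan_names": ("P/F", "Plan names follow convention"),
    "reference_point_limits": ("P/F", "Reference point dose limits"),
    "bolus_attached": ("P/F", "Bolus attached to all fields"),
    "drr_overlay": ("P/F", "Overlay on DRRs"),
    "dose_rate": ("P/F", "Dose rate"),
    "plan_status": ("P/F", "Plan status"),
    "calc_settings_grid": ("P/F", "Default calculation settings and grid size"),
    "couch_structures": ("P/F", "Couch structures properly applied"),
    "unusual_warnings": ("R", "List unusual warnings"),
    "invalid_characters": ("P/F", "Invalid characters"),
    "control_point_count": ("P/F", "Valid number of control points"),
    "imrt_leaf_delivery": ("P/F", "IMRT leaf delivery"),
    "leaf_motion_calculator": ("P/F", "Correct leaf motion calculator algorithm"),
    "ct_density_overrides": ("R", "Report CT density overrides"),
    "bolus_hu": ("R", "Report bolus with non-zero HU values"),
    "nonclinical_complete": ("P/F", "Non-clinical courses are set to complete"),
    "default_couch_position": ("P/F", "Default couch position"),
    "setup_imager_position": ("P/F", "Setup fields correct imager position"),
    "qa_plans": ("P/F", "QA plan checkers (10 constituent checks)"),
}


def total_check_count(enabled: list[str]) -> int:
    """Number of constituent checks in a profile, counting the QA composite
    as its 10 sub-checks."""
    return sum(len(QA_SUBCHECKS) if cid == "qa_plans" else 1 for cid in enabled)


DEFAULT_PARAMS: dict[str, dict] = {
    "isocenter_consistency": {"tolerance_mm": 0.01},
    "tolerance_tables": {"forbidden_labels": ["TEST"]},
    "drr_created": {},
    "patient_orientation": {},
    "image_structset_names": {
        "image_regex": r"[A-Z0-9][A-Z0-9_]*",
        "structset_regex": r"[A-Z0-9][A-Z0-9_]*",
        "severity": "flag",
    },
    "course_names": {"regex": r"C\d+", "severity": "flag"},
    "plan_names": {"regex": r"[A-Z0-9][A-Z0-9_\-]{0,12}", "severity": "flag"},
    "reference_point_limits": {"limit_multiplier": 1.07, "consistency_rel_tol": 0.01},
    "bolus_attached": {"per_bolus_beams": {}},
    "drr_overlay": {},
    "dose_rate": {
        "allowed": {"TB1": {"6X": [400, 600], "15X": [400, 600], "6X-FFF": [1400]}}
    },
    "plan_status": {"required_status": "TREATMENT_APPROVED"},
    "calc_settings_grid": {"model": "AAA_15606", "default_grid_mm": 2.5},
    "couch_structures": {
        "required": {"TB1": {"CouchSurface": 0.7, "CouchInterior": 0.2}},
        "density_tolerance": 0.01,
    },
    "unusual_warnings": {"patterns": ["(?i)unable", "(?i)exceed", "(?i)overlap"]},
    "invalid_characters": {
        "whitelist": (
            "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
            "0123456789 _-.()+"
        )
    },
    "control_point_count": {"max_imrt": 300, "min_vmat": 30, "max_vmat": 400},
    "imrt_leaf_delivery": {"min_gap_mm": 0.5, "closed_gap_mm": 0.1, "max_leaf_speed_mm_s": 25.0},
    "leaf_motion_calculator": {"model": "LMC_15606"},
    "ct_density_overrides": {},
    "bolus_hu": {"water_hu": 0.0, "tolerance_hu": 20.0},
    "nonclinical_complete": {},
    "default_couch_position": {
        "windows": {
            "TB1": {
                "vertical": [-250.0, -50.0],
                "longitudinal": [500.0, 1100.0],
                "lateral": [-50.0, 50.0],
            }
        }
    },
    "setup_imager_position": {
        "expected": {"vrt": -500.0, "lng": 0.0, "lat": 0.0},
        "tolerance_mm": 20.0,
        "require_setup_fields": True,
    },
    "qa_plans": {
        "qa_course_regex": "(?i)^QA",
        "epid_name_regex": r"QA[_A-Z0-9\-]*",
        "epid_sid_mm": 1000.0,
        "sid_tolerance_mm": 1.0,
        "mu_tolerance": 0.1,
        "weight_tolerance": 1e-4,
        "gantry_tolerance_deg": 0.1,
        "required_status": "TREATMENT_APPROVED",
    },
}
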