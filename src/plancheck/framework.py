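"""The check engine: configuration, execution and rendering.

A run takes a :class:`~plancheck.plan_model.PlanContext` and a
:class:`RunConfig` listing the enabled checkers in display order, executes
each checker in isolation, and collects one :class:`CheckResult` per
checker.  Four compliance states are supported:

``PASS``
    the automated criteria in the configuration were met;
``FLAG``
    the criteria were not met — the item needs review and possibly
    correction;
``REPORT``
    the desired outcome is not rigidly defined; the checker lists
    information for the user to review;
``MANUAL``
    a placeholder reminding the user to perform the check by hand.

Checkers are independent of one another: an exception inside one checker
produces a FLAG result carrying the diagnostic for that checker only and
never aborts the run (a QA tool must fail safe).  Display order is purely
presentational; results are identical for any execution order.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import html as _html
import json
import re
from dataclasses import dataclass, field
from typing import Callable, Optional

import yaml

from .plan_model import PlanContext

__all__ = [
    "ComplianceStatus",
    "CheckResult",
    "RunConfig",
    "RunReport",
    "ConfigError",
    "load_config",
    "default_config",
    "run_checks",
    "render_report",
    "report_from_json",
    "exit_code",
]


class ConfigError(Exception):
    """The run configuration is invalid; the message names the key."""


class ComplianceStatus(str, enum.Enum):
    PASS = "pass"
    FLAG = "flag"
    REPORT = "report"
    MANUAL = "manual"


@dataclass
class CheckResult:
    """One checker's outcome."""

    checker_id: str
    status: ComplianceStatus
    messages: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.status in (ComplianceStatus.FLAG, ComplianceStatus.REPORT) and not self.messages:
            raise ValueError(
                f"{self.checker_id}: a {self.status.value} result must carry at "
                f"least one message"
            )


@dataclass
class RunConfig:
    """Enabled checkers (in display order) and their parameters.

    ``params`` maps a checker id to its parameter overrides; values omitted
    there fall back to the registry defaults.  ``notes`` records defaults
    applied and unknown keys encountered while loading.
    """

    enabled_checkers: list[str]
    params: dict[str, dict] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def params_for(self, checker_id: str) -> dict:
        from .checkers import DEFAULT_PARAMS

        merged = dict(DEFAULT_PARAMS.get(checker_id, {}))
        merged.update(self.params.get(checker_id, {}))
        return merged

    def subset(self, checker_ids: list[str]) -> "RunConfig":
        missing = [c for c in checker_ids if c not in self.enabled_checkers]
        if missing:
            raise ConfigError(f"cannot subset to unknown checkers: {missing}")
        return RunConfig(
            enabled_checkers=list(checker_ids),
            params={k: dict(v) for k, v in self.params.items()},
        )


@dataclass
class RunReport:
    plan_id: str
    timestamp: str
    results: list[CheckResult]

    def summary(self) -> dict[str, int]:
        counts = {s.value: 0 for s in ComplianceStatus}
        for r in self.results:
            counts[r.status.value] += 1
        return counts

    def flagged(self) -> list[CheckResult]:
        return [r for r in self.results if r.status is ComplianceStatus.FLAG]


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------

_KNOWN_TOP_KEYS = {"enabled_checkers", "checkers"}


def _validate_params(checker_id: str, params: dict, notes: list[str]) -> None:
    for key, value in params.items():
        if key.endswith("_regex") or key == "regex":
            try:
                re.compile(str(value))
            except re.error as exc:
                raise ConfigError(
                    f"checker {checker_id!r}, key {key!r}: malformed regex ({exc})"
                ) from exc
        if ("tolerance" in key or key.endswith("_tol")) and isinstance(value, (int, float)):
            if value < 0:
                raise ConfigError(
                    f"checker {checker_id!r}, key {key!r}: tolerance must be >= 0"
                )
    if checker_id == "invalid_characters" and "whitelist" in params:
        if not str(params["whitelist"]):
            raise ConfigError("checker 'invalid_characters': whitelist must not be empty")
    if "required_status" in params:
        from .plan_model import PlanStatus

        try:
            PlanStatus(str(params["required_status"]).upper())
        except ValueError as exc:
            allowed = ", ".join(s.value for s in PlanStatus)
            raise ConfigError(
                f"checker {checker_id!r}: required_status "
                f"{params['required_status']!r} is not one of {allowed}"
            ) from exc


def _build_config(doc: dict, registry: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    notes: list[str] = []
    for key in doc:
        if key not in _KNOWN_TOP_KEYS:
            notes.append(f"unknown top-level key {key!r} ignored")
    enabled = doc.get("enabled_checkers")
    if not isinstance(enabled, list) or not enabled:
        raise ConfigError("'enabled_checkers' must be a non-empty list")
    enabled = [str(c) for c in enabled]
    seen = set()
    for cid in enabled:
        if cid in seen:
            raise ConfigError(f"duplicate checker id {cid!r} in enabled_checkers")
        seen.add(cid)
        if cid not in registry:
            raise ConfigError(f"unknown checker id {cid!r}")
    params = {}
    for cid, p in (doc.get("checkers") or {}).items():
        if cid not in registry:
            raise ConfigError(f"unknown checker id {cid!r} under 'checkers'")
        if p is None:
            p = {}
        if not isinstance(p, dict):
            raise ConfigError(f"checker {cid!r}: parameters must be a mapping")
        _validate_params(cid, p, notes)
        params[cid] = p
    for cid in enabled:
        if cid not in params:
            notes.append(f"checker {cid!r}: using registry defaults")
    return RunConfig(enabled_checkers=enabled, params=params, notes=notes)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown checker ids, duplicates, malformed regexes and negative
    tolerances raise :class:`ConfigError`; unknown keys only produce notes.
    """
    from .checkers import REGISTRY

    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML ({exc})") from exc
    return _build_config(doc, REGISTRY)


def default_config() -> RunConfig:
    """The shipped default profile: one checker per rule-table row."""
    from importlib.resources import files

    from .checkers import REGISTRY

    text = files("plancheck").joinpath("data/default_config.yaml").read_text(encoding="utf-8")
    return _build_config(yaml.safe_load(text), REGISTRY)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def run_checks(
    ctx: PlanContext,
    cfg: RunConfig,
    *,
    registry: Optional[dict[str, Callable]] = None,
    timestamp: Optional[str] = None,
) -> RunReport:
    """Run every enabled checker over ``ctx`` and collect the results.

    Checker isolation: an exception inside a checker yields a FLAG result
    with the diagnostic for that checker and the run continues.
    """
    if registry is None:
        from .checkers import REGISTRY as registry  # type: ignore[no-redef]
    results: list[CheckResult] = []
    for cid in cfg.enabled_checkers:
        fn = registry[cid]
        try:
            result = fn(ctx, cfg)
            if result.checker_id != cid:
                result = dataclasses.replace(result, checker_id=cid)
        except Exception as exc:  # fail safe, never abort the run
            result = CheckResult(
                checker_id=cid,
                status=ComplianceStatus.FLAG,
                messages=[f"checker error: {exc.__class__.__name__}: {exc}"],
            )
        results.append(result)
    if timestamp is None:
        timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    return RunReport(plan_id=ctx.plan_id, timestamp=timestamp, results=results)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_STATUS_MARK = {
    ComplianceStatus.PASS: "PASS  ✓",
    ComplianceStatus.FLAG: "FLAG  ⚑",
    ComplianceStatus.REPORT: "REPORT ☰",
    ComplianceStatus.MANUAL: "MANUAL ✎",
}


def _render_text(report: RunReport) -> str:
    rows = [("Item", "Status", "Results")]
    for r in report.results:
        rows.append((r.checker_id, _STATUS_MARK[r.status], "; ".join(r.messages)))
    w0 = max(len(r[0]) for r in rows)
    w1 = max(len(r[1]) for r in rows)
    lines = [f"Plan: {report.plan_id}    checked {report.timestamp}"]
    lines.append("-" * (w0 + w1 + 40))
    for r in rows:
        lines.append(f"{r[0]:<{w0}}  {r[1]:<{w1}}  {r[2]}")
    counts = report.summary()
    lines.append("-" * (w0 + w1 + 40))
    lines.append(
        f"{counts['pass']} pass, {counts['flag']} flag, "
        f"{counts['report']} report, {counts['manual']} manual"
    )
    return "\n".join(lines) + "\n"


def _render_json(report: RunReport) -> str:
    payload = {
        "plan_id": report.plan_id,
        "timestamp": report.timestamp,
        "results": [
            {
                "checker_id": r.checker_id,
                "status": r.status.value,
                "messages": list(r.messages),
                "details": r.details,
            }
            for r in report.results
        ],
        "summary": report.summary(),
    }
    return json.dumps(payload, indent=2, sort_keys=False, ensure_ascii=False) + "\n"


def _render_html(report: RunReport) -> str:
    esc = _html.escape
    rows = []
    for r in report.results:
        rows.append(
            f'  <tr class="{r.status.value}"><td>{esc(r.checker_id)}</td>'
            f"<td>{esc(r.status.value)}</td>"
            f'<td>{esc("; ".join(r.messages))}</td></tr>'
        )
    counts = report.summary()
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>Plan check: {esc(report.plan_id)}</title>"
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:4px 8px}tr.pass td{background:#e7f6e7}tr.flag td"
        "{background:#fbe3e3}tr.report td{background:#fdf6dd}</style>"
        "</head><body>"
        f"<h1>Plan check: {esc(report.plan_id)}</h1>"
        f"<p>Checked {esc(report.timestamp)} — "
        f"{counts['pass']} pass, {counts['flag']} flag, {counts['report']} report, "
        f"{counts['manual']} manual</p>"
        "<table>\n  <tr><th>Item</th><th>Status</th><th>Results</th></tr>\n"
        + "\n".join(rows)
        + "\n</table></body></html>\n"
    )


def render_report(report: RunReport, fmt: str = "text") -> str:
    """Render a run report as ``text``, ``json`` or ``html``.

    The JSON form is lossless: :func:`report_from_json` parses it back to an
    equal :class:`RunReport`.
    """
    if fmt == "text":
        return _render_text(report)
    if fmt == "json":
        return _render_json(report)
    if fmt == "html":
        return _render_html(report)
    raise ValueError(f"unknown report format {fmt!r} (expected text, json or html)")


def report_from_json(text: str) -> RunReport:
    payload = json.loads(text)
    return RunReport(
        plan_id=payload["plan_id"],
        timestamp=payload["timestamp"],
        results=[
            CheckResult(
                checker_id=r["checker_id"],
                status=ComplianceStatus(r["status"]),
                messages=list(r["messages"]),
                details=dict(r.get("details", {})),
            )
            for r in payload["results"]
        ],
    )


def exit_code(report: RunReport) -> int:
    """0 when no checker flagged, 1 otherwise (2 is reserved for load or
    configuration errors and is produced by the CLI, not by a report)."""
    return 1 if report.flagged() else 0
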