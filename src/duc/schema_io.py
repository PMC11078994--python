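"""Read, write and validate DUC profile documents (JSON, UTF-8).

Document layout
---------------
Top level: the header keys ``profileId, profileVersion, profileName,
ducVersion, creationDate, lastUpdated, assets, permissionMode, language``
(all optional) plus the required ``statements`` array of::

    {"conditionTerm": {"label"?, "uri"?},
     "rule": "...", "scope": "...",
     "conditionParameters"?: [{"label"?, "uri"?, "value"?}, ...]}

A JSON Schema 2020-12 rendering of this layout ships in
``duc/data/duc-profile.schema.json``; :func:`validate_document` implements
the same constraints directly so every violation can carry a stable
machine-readable code and a JSON-pointer path (schema validators report
first-failure positions, not governance-oriented codes).

Reading is tolerant where the model documents tolerance: scope may be
omitted (defaults to whole-of-asset), a single parameter object is accepted
in place of a one-element array, dates may be full ISO 8601 date-times
(truncated to dates), and unknown top-level keys are preserved and
re-emitted.  Writing is canonical: fixed key order, 2-space indent, dates
emitted date-only, language lower-cased, parameters always in array form —
so equal profiles dump to identical bytes.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Any

from .model import (
    AssetRef,
    ConditionParameter,
    ConditionStatement,
    DUCError,
    DUCProfile,
    PermissionMode,
    Rule,
    SEMVER_RE,
    Scope,
    TermRef,
    is_valid_uri,
)
from .model import _LANGUAGE_RE  # 3 ASCII letters

__all__ = [
    "Violation",
    "ValidationReport",
    "SchemaViolationError",
    "ParseError",
    "validate_document",
    "load_profile",
    "dump_profile",
    "profile_to_dict",
    "profile_from_dict",
    "schema_path",
]

HEADER_KEYS = (
    "profileId",
    "profileVersion",
    "profileName",
    "ducVersion",
    "creationDate",
    "lastUpdated",
    "assets",
    "permissionMode",
    "language",
)

#: Closed set of violation codes emitted by :func:`validate_document`.
VIOLATION_CODES = frozenset(
    {
        "parse",
        "root-type",
        "statements-min",
        "statements-type",
        "statement-type",
        "term-missing",
        "term-type",
        "term-empty",
        "uri-format",
        "rule-missing",
        "rule-enum",
        "scope-enum",
        "parameters-type",
        "parameter-type",
        "parameter-empty",
        "parameter-value",
        "profile-version-format",
        "date-format",
        "permission-mode-enum",
        "language-format",
        "assets-type",
        "asset-type",
        "asset-empty",
        "string-type",
        "normalized",
    }
)


@dataclass(frozen=True)
class Violation:
    code: str
    path: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of structural validation: every violation, not first-failure.

    ``warnings`` holds non-fatal notes (currently only the ``normalized``
    records written by the lenient reading path); ``ok`` depends on
    ``violations`` alone.
    """

    violations: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, code: str, path: str, message: str) -> None:
        self.violations.append(Violation(code, path, message))

    def warn(self, code: str, path: str, message: str) -> None:
        self.warnings.append(Violation(code, path, message))

    def to_dict(self) -> dict[str, Any]:
        return {
            "ok": self.ok,
            "violations": [v.__dict__ for v in self.violations],
            "warnings": [v.__dict__ for v in self.warnings],
        }


class ParseError(DUCError):
    """The document is not well-formed JSON."""


class SchemaViolationError(DUCError):
    """The document is well-formed JSON but violates the DUC layout."""

    def __init__(self, report: ValidationReport):
        self.report = report
        lines = "; ".join(
            f"{v.code} at {v.path or '/'}: {v.message}" for v in report.violations
        )
        super().__init__(f"invalid DUC document: {lines}")


def schema_path():
    """Filesystem path of the bundled JSON Schema 2020-12 file."""
    from importlib.resources import files

    return files("duc.data") / "duc-profile.schema.json"


_ENUMS = {
    "rule": ("rule-enum", {m.value for m in Rule}),
    "scope": ("scope-enum", {m.value for m in Scope}),
    "permissionMode": ("permission-mode-enum", {m.value for m in PermissionMode}),
}

_NORMALIZABLE = {"rule", "scope", "permissionMode"}


def _canon_enum(key: str, raw: Any) -> str | None:
    """Map a case/whitespace variant onto the printed enum form, if any."""
    if not isinstance(raw, str):
        return None
    folded = " ".join(raw.split()).casefold()
    for value in _ENUMS[key][1]:
        if folded == value.casefold():
            return value
    return None


def _is_scalar(v: Any) -> bool:
    return isinstance(v, (str, int, float)) and not isinstance(v, bool)


def _check_term(obj: Any, path: str, report: ValidationReport) -> None:
    if not isinstance(obj, dict):
        report.add("term-type", path, "conditionTerm must be an object")
        return
    label, uri = obj.get("label"), obj.get("uri")
    if label is not None and not isinstance(label, str):
        report.add("string-type", f"{path}/label", "label must be a string")
    if uri is not None:
        if not isinstance(uri, str) or not is_valid_uri(uri):
            report.add("uri-format", f"{path}/uri", f"{uri!r} is not a valid URI")
    if not label and not uri:
        report.add(
            "term-empty", path, "conditionTerm needs a non-empty label and/or uri"
        )


def _check_parameter(obj: Any, path: str, report: ValidationReport) -> None:
    if not isinstance(obj, dict):
        report.add("parameter-type", path, "conditionParameter must be an object")
        return
    label, uri, value = obj.get("label"), obj.get("uri"), obj.get("value")
    if label is not None and not isinstance(label, str):
        report.add("string-type", f"{path}/label", "label must be a string")
    if uri is not None and (not isinstance(uri, str) or not is_valid_uri(uri)):
        report.add("uri-format", f"{path}/uri", f"{uri!r} is not a valid URI")
    if value is not None and not _is_scalar(value):
        report.add(
            "parameter-value",
            f"{path}/value",
            "value must be a finite number or a string",
        )
    elif isinstance(value, float):
        import math

        if not math.isfinite(value):
            report.add(
                "parameter-value", f"{path}/value", "numeric value must be finite"
            )
    if label is None and uri is None and value is None:
        report.add(
            "parameter-empty", path, "parameter needs a label, uri or value"
        )


def _check_statement(obj: Any, path: str, report: ValidationReport) -> None:
    if not isinstance(obj, dict):
        report.add("statement-type", path, "statement must be an object")
        return
    if "conditionTerm" not in obj:
        report.add("term-missing", path, "statement lacks conditionTerm")
    else:
        _check_term(obj["conditionTerm"], f"{path}/conditionTerm", report)
    if "rule" not in obj:
        report.add("rule-missing", path, "statement lacks rule")
    elif obj["rule"] not in _ENUMS["rule"][1]:
        report.add(
            "rule-enum",
            f"{path}/rule",
            f"{obj['rule']!r} is not one of {sorted(_ENUMS['rule'][1])}",
        )
    if "scope" in obj and obj["scope"] not in _ENUMS["scope"][1]:
        report.add(
            "scope-enum",
            f"{path}/scope",
            f"{obj['scope']!r} is not one of {sorted(_ENUMS['scope'][1])}",
        )
    params = obj.get("conditionParameters")
    if params is None:
        return
    if isinstance(params, dict):  # single-parameter document form
        params = [params]
    if not isinstance(params, list):
        report.add(
            "parameters-type",
            f"{path}/conditionParameters",
            "conditionParameters must be an array (or a single object)",
        )
        return
    for i, p in enumerate(params):
        _check_parameter(p, f"{path}/conditionParameters/{i}", report)


def _check_asset(obj: Any, path: str, report: ValidationReport) -> None:
    if not isinstance(obj, dict):
        report.add("asset-type", path, "asset must be an object")
        return
    known = ("assetName", "assetDescription", "assetReferences", "assetURI")
    if not any(obj.get(k) for k in known):
        report.add("asset-empty", path, "asset needs at least one populated field")
    uri = obj.get("assetURI")
    if uri is not None and (not isinstance(uri, str) or not is_valid_uri(uri)):
        report.add("uri-format", f"{path}/assetURI", f"{uri!r} is not a valid URI")
    refs = obj.get("assetReferences")
    if refs is not None and (
        not isinstance(refs, list) or any(not isinstance(r, str) for r in refs)
    ):
        report.add(
            "string-type",
            f"{path}/assetReferences",
            "assetReferences must be an array of strings",
        )


def _parse_date_ok(raw: Any) -> bool:
    if not isinstance(raw, str):
        return False
    for parser in (_dt.date.fromisoformat, _dt.datetime.fromisoformat):
        try:
            parser(raw)
            return True
        except ValueError:
            continue
    return False


def _validate_obj(doc: Any, report: ValidationReport) -> None:
    if not isinstance(doc, dict):
        report.add("root-type", "", "document root must be a JSON object")
        return
    stmts = doc.get("statements")
    if stmts is None or (isinstance(stmts, list) and len(stmts) == 0):
        report.add(
            "statements-min", "/statements", "profile requires at least one statement"
        )
    elif not isinstance(stmts, list):
        report.add("statements-type", "/statements", "statements must be an array")
    else:
        for i, s in enumerate(stmts):
            _check_statement(s, f"/statements/{i}", report)

    for key in ("profileName", "ducVersion"):
        v = doc.get(key)
        if v is not None and not isinstance(v, str):
            report.add("string-type", f"/{key}", f"{key} must be a string")
    pid = doc.get("profileId")
    if pid is not None and (not isinstance(pid, str) or not is_valid_uri(pid)):
        report.add("uri-format", "/profileId", f"{pid!r} is not a valid URI")
    ver = doc.get("profileVersion")
    if ver is not None and (
        not isinstance(ver, str) or not SEMVER_RE.match(ver)
    ):
        report.add(
            "profile-version-format",
            "/profileVersion",
            f"{ver!r} is not a semantic version (e.g. 1.0.1)",
        )
    for key in ("creationDate", "lastUpdated"):
        raw = doc.get(key)
        if raw is not None and not _parse_date_ok(raw):
            report.add(
                "date-format", f"/{key}", f"{raw!r} is not an ISO 8601 date"
            )
    mode = doc.get("permissionMode")
    if mode is not None and mode not in _ENUMS["permissionMode"][1]:
        report.add(
            "permission-mode-enum",
            "/permissionMode",
            f"{mode!r} is not one of {sorted(_ENUMS['permissionMode'][1])}",
        )
    lang = doc.get("language")
    if lang is not None and (
        not isinstance(lang, str) or not _LANGUAGE_RE.match(lang)
    ):
        report.add(
            "language-format",
            "/language",
            f"{lang!r} is not a 3-letter ISO 639-3 code",
        )
    assets = doc.get("assets")
    if assets is not None:
        if not isinstance(assets, list):
            report.add("assets-type", "/assets", "assets must be an array")
        else:
            for i, a in enumerate(assets):
                _check_asset(a, f"/assets/{i}", report)


def validate_document(document: str) -> ValidationReport:
    """Validate JSON text against the DUC profile layout.

    Returns a report listing *every* violation with a machine-readable code
    and a JSON-pointer path.  Malformed JSON yields a single ``parse``
    violation carrying the line/column of the failure.
    """
    report = ValidationReport()
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        report.add(
            "parse", "", f"line {exc.lineno}, column {exc.colno}: {exc.msg}"
        )
        return report
    _validate_obj(doc, report)
    return report


def _normalize_inplace(doc: Any, report: ValidationReport) -> None:
    """Lenient pass: fold case/whitespace variants of enum fields."""
    if not isinstance(doc, dict):
        return
    mode = doc.get("permissionMode")
    if mode is not None and mode not in _ENUMS["permissionMode"][1]:
        canon = _canon_enum("permissionMode", mode)
        if canon is not None:
            doc["permissionMode"] = canon
            report.warn(
                "normalized", "/permissionMode", f"{mode!r} read as {canon!r}"
            )
    stmts = doc.get("statements")
    if not isinstance(stmts, list):
        return
    for i, s in enumerate(stmts):
        if not isinstance(s, dict):
            continue
        for key in ("rule", "scope"):
            raw = s.get(key)
            if raw is not None and raw not in _ENUMS[key][1]:
                canon = _canon_enum(key, raw)
                if canon is not None:
                    s[key] = canon
                    report.warn(
                        "normalized",
                        f"/statements/{i}/{key}",
                        f"{raw!r} read as {canon!r}",
                    )


def profile_from_dict(doc: dict[str, Any]) -> DUCProfile:
    """Build a :class:`DUCProfile` from an already-validated document dict."""
    statements = []
    for s in doc["statements"]:
        term = TermRef(
            label=s["conditionTerm"].get("label"),
            uri=s["conditionTerm"].get("uri"),
        )
        raw_params = s.get("conditionParameters") or []
        if isinstance(raw_params, dict):
            raw_params = [raw_params]
        params = tuple(
            ConditionParameter(
                label=p.get("label"), uri=p.get("uri"), value=p.get("value")
            )
            for p in raw_params
        )
        statements.append(
            ConditionStatement(
                conditionTerm=term,
                rule=Rule.parse(s["rule"]),
                scope=Scope.parse(s.get("scope", Scope.WHOLE.value)),
                conditionParameters=params,
            )
        )
    assets = None
    if doc.get("assets") is not None:
        assets = tuple(
            AssetRef(
                assetName=a.get("assetName"),
                assetDescription=a.get("assetDescription"),
                assetReferences=(
                    tuple(a["assetReferences"])
                    if a.get("assetReferences") is not None
                    else None
                ),
                assetURI=a.get("assetURI"),
            )
            for a in doc["assets"]
        )
    extensions = {
        k: v
        for k, v in doc.items()
        if k not in HEADER_KEYS and k != "statements"
    }
    return DUCProfile(
        statements=tuple(statements),
        profileId=doc.get("profileId"),
        profileVersion=doc.get("profileVersion"),
        profileName=doc.get("profileName"),
        ducVersion=doc.get("ducVersion"),
        creationDate=doc.get("creationDate"),
        lastUpdated=doc.get("lastUpdated"),
        assets=assets,
        permissionMode=(
            PermissionMode.parse(doc["permissionMode"])
            if doc.get("permissionMode") is not None
            else None
        ),
        language=doc.get("language"),
        extensions=extensions,
    )


def load_profile(document: str, lenient: bool = False) -> DUCProfile:
    """Parse and validate JSON text into a :class:`DUCProfile`.

    With ``lenient=True``, case/whitespace variants of the enumerated
    fields (rule, scope, permissionMode) are folded onto their printed
    forms before validation; each fold is recorded as a ``normalized``
    warning on the report attached to any subsequent error.

    Raises
    ------
    ParseError
        For malformed JSON (message carries line/column).
    SchemaViolationError
        For structural violations; ``exc.report`` holds the full report.
    """
    report = ValidationReport()
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if lenient:
        _normalize_inplace(doc, report)
    _validate_obj(doc, report)
    if not report.ok:
        raise SchemaViolationError(report)
    return profile_from_dict(doc)


def _term_dict(term: TermRef) -> dict[str, Any]:
    out: dict[str, Any] = {}
    if term.label is not None:
        out["label"] = term.label
    if term.uri is not None:
        out["uri"] = term.uri
    return out


def _param_dict(p: ConditionParameter) -> dict[str, Any]:
    out: dict[str, Any] = {}
    if p.label is not None:
        out["label"] = p.label
    if p.uri is not None:
        out["uri"] = p.uri
    if p.value is not None:
        out["value"] = p.value
    return out


def profile_to_dict(profile: DUCProfile) -> dict[str, Any]:
    """Canonical document dict: header keys in fixed order, then statements."""
    out: dict[str, Any] = {}
    if profile.profileId is not None:
        out["profileId"] = profile.profileId
    if profile.profileVersion is not None:
        out["profileVersion"] = profile.profileVersion
    if profile.profileName is not None:
        out["profileName"] = profile.profileName
    if profile.ducVersion is not None:
        out["ducVersion"] = profile.ducVersion
    if profile.creationDate is not None:
        out["creationDate"] = profile.creationDate.isoformat()
    if profile.lastUpdated is not None:
        out["lastUpdated"] = profile.lastUpdated.isoformat()
    if profile.assets is not None:
        assets = []
        for a in profile.assets:
            ad: dict[str, Any] = {}
            if a.assetName is not None:
                ad["assetName"] = a.assetName
            if a.assetDescription is not None:
                ad["assetDescription"] = a.assetDescription
            if a.assetReferences is not None:
                ad["assetReferences"] = list(a.assetReferences)
            if a.assetURI is not None:
                ad["assetURI"] = a.assetURI
            assets.append(ad)
        out["assets"] = assets
    if profile.permissionMode is not None:
        out["permissionMode"] = profile.permissionMode.value
    if profile.language is not None:
        out["language"] = profile.language.lower()
    out["statements"] = []
    for s in profile.statements:
        sd: dict[str, Any] = {
            "conditionTerm": _term_dict(s.conditionTerm),
            "rule": s.rule.value,
            "scope": s.scope.value,
        }
        if s.conditionParameters:
            sd["conditionParameters"] = [
                _param_dict(p) for p in s.conditionParameters
            ]
        out["statements"].append(sd)
    for k in sorted(profile.extensions):
        out[k] = profile.extensions[k]
    return out


def dump_profile(profile: DUCProfile) -> str:
    """Serialize a profile to canonical JSON text.

    Deterministic: fixed key order, 2-space indent, UTF-8-safe output with
    non-ASCII characters left unescaped, trailing newline.  Equal profiles
    produce byte-identical text.
    """
    return json.dumps(profile_to_dict(profile), indent=2, ensure_ascii=False) + "\n"
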