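"""Deterministic human-readable rendering of statements and profiles.

Two sentence styles plus a markdown report:

``template``
    The canonical skeleton — "Regarding [conditionTerm], this form of use
    is [rule], and applies to the [scope], for which the details are
    [conditionParameter]." — with the final clause omitted when a statement
    has no parameters.

``narrative``
    Natural prose keyed on the statement's shape: "General research use is
    permitted for the whole of asset.", "The country of the United Kingdom
    is permitted for the whole of asset.", "The time limit on use is 12
    months and is obligatory for the whole of asset."

``markdown``
    A header block (name, versions, dates, permission mode, assets)
    followed by the template sentences as a numbered list.

Rendering is pure: output depends only on the statement/profile (and, for
URI-only terms, the registry used to look up a display label).
"""

from __future__ import annotations

from enum import Enum

from .model import (
    ConditionParameter,
    ConditionStatement,
    DUCProfile,
    Rule,
    Scope,
    TermRef,
)
from .vocab import Registry, contract_uri, default_registry

__all__ = ["RenderStyle", "render_statement", "render_profile"]


class RenderStyle(str, Enum):
    TEMPLATE = "template"
    NARRATIVE = "narrative"
    MARKDOWN = "markdown"


_RULE_PHRASES = {
    Rule.PERMITTED: "permitted",
    Rule.FORBIDDEN: "forbidden",
    Rule.OBLIGATORY: "obligatory",
    Rule.NO_REQUIREMENT: "not subject to any requirement",
}

_SCOPE_PHRASES = {
    Scope.WHOLE: "whole of asset",
    Scope.PART: "part of asset",
}


def _term_display(term: TermRef, registry: Registry) -> str:
    """Display label for a term: its label, else the registry's, else CURIE."""
    if term.label:
        return term.label
    entry = registry.by_uri.get(term.uri) if term.uri else None
    if entry is not None:
        return entry.preferredLabel
    return contract_uri(term.uri, registry)


def _param_display(p: ConditionParameter, registry: Registry) -> str:
    if p.value is not None and p.label:
        return f"{p.value} {p.label}"
    if p.label:
        return p.label
    if p.value is not None:
        return str(p.value)
    entry = registry.by_uri.get(p.uri) if p.uri else None
    if entry is not None:
        return entry.preferredLabel
    return contract_uri(p.uri, registry)


def _join_and(parts: list[str]) -> str:
    if len(parts) <= 1:
        return "".join(parts)
    return ", ".join(parts[:-1]) + " and " + parts[-1]


def _narrative(stmt: ConditionStatement, registry: Registry) -> str:
    label = _term_display(stmt.conditionTerm, registry)
    rule = _RULE_PHRASES[stmt.rule]
    scope = _SCOPE_PHRASES[stmt.scope]
    params = stmt.conditionParameters
    if not params:
        return f"{label} is {rule} for the {scope}."
    if any(p.value is not None for p in params):
        amounts = _join_and(
            [_param_display(p, registry) for p in params]
        )
        return f"The {label.lower()} is {amounts} and is {rule} for the {scope}."
    details = _join_and([_param_display(p, registry) for p in params])
    return f"The {label.lower()} of {details} is {rule} for the {scope}."


def _template(stmt: ConditionStatement, registry: Registry) -> str:
    label = _term_display(stmt.conditionTerm, registry)
    head = (
        f"Regarding {label}, this form of use is {stmt.rule.value}, "
        f"and applies to the {stmt.scope.value}"
    )
    if not stmt.conditionParameters:
        return head + "."
    details = "; ".join(
        _param_display(p, registry) for p in stmt.conditionParameters
    )
    return head + f", for which the details are {details}."


def render_statement(
    stmt: ConditionStatement,
    style: RenderStyle | str = RenderStyle.NARRATIVE,
    registry: Registry | None = None,
) -> str:
    """Render one condition statement as a sentence."""
    style = RenderStyle(style)
    registry = registry if registry is not None else default_registry()
    if style is RenderStyle.NARRATIVE:
        return _narrative(stmt, registry)
    # markdown has no per-statement form of its own; it lists template lines
    return _template(stmt, registry)


def _markdown(profile: DUCProfile, registry: Registry) -> str:
    lines = [f"# {profile.profileName or 'DUC Profile'}", ""]
    meta = [
        ("Profile ID", profile.profileId),
        ("Profile version", profile.profileVersion),
        ("DUC version", profile.ducVersion),
        ("Created", profile.creationDate.isoformat() if profile.creationDate else None),
        ("Last updated", profile.lastUpdated.isoformat() if profile.lastUpdated else None),
        ("Permission mode", profile.permissionMode.value if profile.permissionMode else None),
        ("Language", profile.language),
    ]
    for key, val in meta:
        if val is not None:
            lines.append(f"- **{key}**: {val}")
    if profile.assets:
        names = [
            a.assetName or a.assetURI or a.assetDescription or "unnamed asset"
            for a in profile.assets
        ]
        lines.append(f"- **Assets**: {'; '.join(names)}")
    lines += ["", "## Condition statements", ""]
    for i, stmt in enumerate(profile.statements, start=1):
        lines.append(f"{i}. {_template(stmt, registry)}")
    return "\n".join(lines) + "\n"


def render_profile(
    profile: DUCProfile,
    style: RenderStyle | str = RenderStyle.NARRATIVE,
    registry: Registry | None = None,
) -> str:
    """Render a whole profile.

    Narrative and template styles join the statement sentences, in document
    order, with single spaces; markdown produces a header block plus a
    numbered statement list.
    """
    style = RenderStyle(style)
    registry = registry if registry is not None else default_registry()
    if style is RenderStyle.MARKDOWN:
        return _markdown(profile, registry)
    return " ".join(
        render_statement(s, style, registry) for s in profile.statements
    )
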