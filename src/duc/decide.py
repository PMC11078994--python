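"""Evaluate requested uses against DUC profiles.

The engine answers the Data Access Committee triage question: given one or
more profiles governing an asset and a request (a list of use-condition
terms, optionally parameterised), is the requested use covered?

Per-term semantics
------------------
A statement *matches* a request item when their terms denote the same
concept (:func:`duc.vocab.terms_match`) and the parameters are compatible:
a statement with no parameters covers any item; a parameterised statement
covers only an item whose parameter equals one of the statement's (URI
equality after CURIE expansion, else normalised-label equality, else value
equality).

If no statement matches, the profile's ``permissionMode`` decides:
forbidden-by-default, permitted-by-default, or — with no declared mode —
``Unknown`` (never a silent default).  Among matched statements any
contradictory rule pair (Forbidden vs any of Permitted/Obligatory/No
Requirement, or Obligatory vs No Requirement) yields ``Conflict``;
otherwise the strongest rule wins under the conservative precedence
Forbidden > Obligatory > Permitted > No Requirement.  Scope never changes
an outcome: a verdict is flagged ``partial`` when every decisive statement
covers only part of the asset.

Across profiles aggregation is OR: any single profile may grant a request
(the intended way to express alternative condition sets, e.g. one profile
per country group).  A granting profile's ``Obligatory`` statements travel
with the grant as obligations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .model import (
    ConditionParameter,
    ConditionStatement,
    DUCProfile,
    PermissionMode,
    Rule,
    TermRef,
)
from .vocab import Registry, default_registry, expand_curie, normalize_label, terms_match

__all__ = [
    "Outcome",
    "Verdict",
    "RequestItem",
    "UseRequest",
    "ProfileDecision",
    "Decision",
    "evaluate_term",
    "evaluate_request",
    "collect_obligations",
    "detect_conflicts",
    "parameters_equal",
    "CONTRADICTORY_PAIRS",
    "RULE_PRECEDENCE",
    "GRANTING_OUTCOMES",
]


class Outcome(str, Enum):
    PERMITTED = "Permitted"
    FORBIDDEN = "Forbidden"
    OBLIGATORY = "Obligatory"
    NO_REQUIREMENT = "NoRequirement"
    PERMITTED_BY_DEFAULT = "PermittedByDefault"
    FORBIDDEN_BY_DEFAULT = "ForbiddenByDefault"
    UNKNOWN = "Unknown"
    CONFLICT = "Conflict"


#: Rule pairs that cannot be reconciled when they match the same use.
CONTRADICTORY_PAIRS = frozenset(
    {
        frozenset({Rule.FORBIDDEN, Rule.PERMITTED}),
        frozenset({Rule.FORBIDDEN, Rule.OBLIGATORY}),
        frozenset({Rule.FORBIDDEN, Rule.NO_REQUIREMENT}),
        frozenset({Rule.OBLIGATORY, Rule.NO_REQUIREMENT}),
    }
)

#: Strongest first; applied only to non-contradictory matched rule sets.
RULE_PRECEDENCE = (Rule.FORBIDDEN, Rule.OBLIGATORY, Rule.PERMITTED, Rule.NO_REQUIREMENT)

_RULE_OUTCOME = {
    Rule.FORBIDDEN: Outcome.FORBIDDEN,
    Rule.OBLIGATORY: Outcome.OBLIGATORY,
    Rule.PERMITTED: Outcome.PERMITTED,
    Rule.NO_REQUIREMENT: Outcome.NO_REQUIREMENT,
}

#: Outcomes under which a request item does not block a grant.
GRANTING_OUTCOMES = frozenset(
    {
        Outcome.PERMITTED,
        Outcome.OBLIGATORY,
        Outcome.NO_REQUIREMENT,
        Outcome.PERMITTED_BY_DEFAULT,
    }
)


@dataclass(frozen=True)
class Verdict:
    """Per-term outcome with provenance.

    ``decisiveStatements`` holds indices (document order) of the matched
    statements that produced the outcome; it is empty exactly for the
    default/unknown outcomes.  ``partial`` is true when every decisive
    statement has part-of-asset scope.
    """

    outcome: Outcome
    partial: bool = False
    decisiveStatements: tuple[int, ...] = ()
    note: str = ""


@dataclass(frozen=True)
class RequestItem:
    term: TermRef
    parameter: ConditionParameter | None = None


@dataclass(frozen=True)
class UseRequest:
    items: tuple[RequestItem, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise ValueError("a use request needs at least one item")

    @classmethod
    def from_dict(cls, doc: dict) -> "UseRequest":
        """Build from the JSON request layout ``{"items": [...]}``."""
        items = []
        for it in doc.get("items", []):
            t = it["term"]
            p = it.get("parameter")
            items.append(
                RequestItem(
                    term=TermRef(label=t.get("label"), uri=t.get("uri")),
                    parameter=(
                        ConditionParameter(
                            label=p.get("label"),
                            uri=p.get("uri"),
                            value=p.get("value"),
                        )
                        if p is not None
                        else None
                    ),
                )
            )
        return cls(items=tuple(items))


@dataclass(frozen=True)
class ProfileDecision:
    profileId: str | None
    verdicts: tuple[Verdict, ...]
    granted: bool
    obligations: tuple[ConditionStatement, ...]
    note: str = ""


@dataclass(frozen=True)
class Decision:
    perProfile: tuple[ProfileDecision, ...]
    granted: bool


def parameters_equal(
    a: ConditionParameter,
    b: ConditionParameter,
    registry: Registry | None = None,
) -> bool:
    """Parameter identity: URI first, else label, else scalar value."""
    registry = registry if registry is not None else default_registry()
    if a.uri is not None and b.uri is not None:
        return expand_curie(a.uri, registry) == expand_curie(b.uri, registry)
    if a.label is not None and b.label is not None:
        return normalize_label(a.label) == normalize_label(b.label)
    if a.value is not None and b.value is not None:
        return a.value == b.value
    return False


def _statement_matches(
    stmt: ConditionStatement,
    term: TermRef,
    parameter: ConditionParameter | None,
    registry: Registry,
) -> bool:
    if not terms_match(stmt.conditionTerm, term, registry):
        return False
    if not stmt.conditionParameters:
        return True
    if parameter is None:
        return False
    return any(
        parameters_equal(p, parameter, registry) for p in stmt.conditionParameters
    )


def evaluate_term(
    profile: DUCProfile,
    term: TermRef,
    parameter: ConditionParameter | None = None,
    registry: Registry | None = None,
) -> Verdict:
    """Evaluate one requested term (optionally parameterised) on a profile.

    Total and deterministic; statement order affects only the ordering of
    ``decisiveStatements``, never the outcome.
    """
    registry = registry if registry is not None else default_registry()
    matched = tuple(
        i
        for i, s in enumerate(profile.statements)
        if _statement_matches(s, term, parameter, registry)
    )
    if not matched:
        if profile.permissionMode is PermissionMode.UNSTATED_FORBIDDEN:
            return Verdict(
                Outcome.FORBIDDEN_BY_DEFAULT,
                note="no matching statement; unstated conditions are forbidden",
            )
        if profile.permissionMode is PermissionMode.UNSTATED_PERMITTED:
            return Verdict(
                Outcome.PERMITTED_BY_DEFAULT,
                note="no matching statement; unstated conditions are permitted",
            )
        return Verdict(
            Outcome.UNKNOWN,
            note="no matching statement and no permissionMode declared",
        )
    rules = {profile.statements[i].rule for i in matched}
    partial = all(
        profile.statements[i].scope.value == "Part of asset" for i in matched
    )
    for pair in CONTRADICTORY_PAIRS:
        if pair <= rules:
            names = " vs ".join(sorted(r.value for r in pair))
            return Verdict(
                Outcome.CONFLICT,
                partial=partial,
                decisiveStatements=matched,
                note=f"contradictory matched rules: {names}",
            )
    for rule in RULE_PRECEDENCE:
        if rule in rules:
            decisive = tuple(
                i for i in matched if profile.statements[i].rule is rule
            )
            partial = all(
                profile.statements[i].scope.value == "Part of asset"
                for i in decisive
            )
            return Verdict(
                _RULE_OUTCOME[rule],
                partial=partial,
                decisiveStatements=decisive,
            )
    raise AssertionError("unreachable: matched rules exhausted")


def collect_obligations(profile: DUCProfile) -> list[ConditionStatement]:
    """The profile's ``Obligatory`` statements, in document order."""
    return [s for s in profile.statements if s.rule is Rule.OBLIGATORY]


def evaluate_request(
    profiles: Sequence[DUCProfile],
    request: UseRequest,
    registry: Registry | None = None,
) -> Decision:
    """Evaluate a request against each profile and OR the grants.

    A profile grants the request when no item's verdict blocks it (blocking
    outcomes: Forbidden, ForbiddenByDefault, Unknown, Conflict).  The
    granting profile's obligatory statements are reported as obligations.
    """
    if not profiles:
        raise ValueError("evaluate_request needs at least one profile")
    registry = registry if registry is not None else default_registry()
    per_profile = []
    for profile in profiles:
        verdicts = tuple(
            evaluate_term(profile, item.term, item.parameter, registry)
            for item in request.items
        )
        blockers = [
            (i, v)
            for i, v in enumerate(verdicts)
            if v.outcome not in GRANTING_OUTCOMES
        ]
        granted = not blockers
        note = "" if granted else "; ".join(
            f"item {i}: {v.outcome.value}" + (f" ({v.note})" if v.note else "")
            for i, v in blockers
        )
        per_profile.append(
            ProfileDecision(
                profileId=profile.profileId,
                verdicts=verdicts,
                granted=granted,
                obligations=tuple(collect_obligations(profile)) if granted else (),
                note=note,
            )
        )
    return Decision(
        perProfile=tuple(per_profile),
        granted=any(p.granted for p in per_profile),
    )


def _parameter_sets_compatible(
    a: ConditionStatement, b: ConditionStatement, registry: Registry
) -> bool:
    if not a.conditionParameters and not b.conditionParameters:
        return True
    if not a.conditionParameters or not b.conditionParameters:
        return False
    return any(
        parameters_equal(pa, pb, registry)
        for pa in a.conditionParameters
        for pb in b.conditionParameters
    )


def detect_conflicts(
    profile: DUCProfile, registry: Registry | None = None
) -> list[tuple[tuple[int, int], str]]:
    """Statement pairs that contradict each other on the same use.

    Two statements conflict when their terms match, their parameter sets
    are compatible (both empty, or overlapping under parameter equality),
    and their rules form a contradictory pair.  Statements about the same
    term with disjoint parameters — per-country variation, say — do not
    conflict.
    """
    registry = registry if registry is not None else default_registry()
    out: list[tuple[tuple[int, int], str]] = []
    stmts = profile.statements
    for i in range(len(stmts)):
        for j in range(i + 1, len(stmts)):
            a, b = stmts[i], stmts[j]
            if frozenset({a.rule, b.rule}) not in CONTRADICTORY_PAIRS:
                continue
            if not terms_match(a.conditionTerm, b.conditionTerm, registry):
                continue
            if not _parameter_sets_compatible(a, b, registry):
                continue
            out.append(
                ((i, j), f"{a.rule.value} vs {b.rule.value} on the same term")
            )
    return out
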