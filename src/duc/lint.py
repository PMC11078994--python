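"""Non-fatal quality checks for DUC profiles.

These encode recommendations and field observations as warnings, never
errors: a profile that validates structurally is always accepted, and any
flagged construction may be a deliberate authoring choice.

Warning codes (closed set)
--------------------------
``label-only-term``
    A condition term carries no URI; free-text labels invite variable
    spellings across custodians and hurt interoperability.
``no-uuid-profile-id``
    The profile identifier is missing or carries no UUID; UUID-bearing
    identifiers keep profile references unambiguous.
``implausible-category-rule``
    A procedural ("how") or motivational ("why") concept paired with a
    ``Forbidden`` rule — e.g. forbidding "ethical approval" — is rarely
    what the author meant.  The pairing matrix ships as data
    (``duc/data/implausible_rules.tsv``) so adopters can extend it.
``conflicting-statements``
    Two statements contradict each other on the same use (see
    :func:`duc.decide.detect_conflicts`).
``no-permission-mode``
    Without a declared permission mode, unstated conditions cannot be
    decided and evaluate to ``Unknown``.
``dates-reversed``
    ``lastUpdated`` precedes ``creationDate``.
``unknown-duc-version``
    ``ducVersion`` is not a known release of the model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .decide import detect_conflicts
from .model import DUCProfile, Rule, TermRef
from .vocab import Registry, default_registry

__all__ = [
    "LINT_CODES",
    "KNOWN_DUC_VERSIONS",
    "LintWarning",
    "LintReport",
    "categorize_term",
    "lint_profile",
    "load_implausibility_matrix",
]

LINT_CODES = frozenset(
    {
        "label-only-term",
        "no-uuid-profile-id",
        "implausible-category-rule",
        "conflicting-statements",
        "no-permission-mode",
        "dates-reversed",
        "unknown-duc-version",
    }
)

KNOWN_DUC_VERSIONS = frozenset({"1.0.0"})

_UUID_RE = re.compile(
    r"[0-9a-fA-F]{8}-[0-9a-fA-F]{4}-[0-9a-fA-F]{4}-[0-9a-fA-F]{4}-[0-9a-fA-F]{12}"
)


@dataclass(frozen=True)
class LintWarning:
    code: str
    path: str
    message: str


@dataclass
class LintReport:
    warnings: list[LintWarning] = field(default_factory=list)

    @property
    def codes(self) -> list[str]:
        return [w.code for w in self.warnings]

    def to_dict(self) -> dict:
        return {"warnings": [w.__dict__ for w in self.warnings]}


def load_implausibility_matrix(
    path: "str | Path | None" = None,
) -> set[tuple[str, Rule]]:
    """Read the (wCategory, rule) pairs the linter flags as implausible."""
    if path is None:
        from importlib.resources import as_file, files

        with as_file(files("duc.data") / "implausible_rules.tsv") as p:
            return load_implausibility_matrix(p)
    pairs: set[tuple[str, Rule]] = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        category, rule = line.split("\t")
        pairs.add((category.strip(), Rule.parse(rule.strip())))
    return pairs


def categorize_term(term: TermRef, registry: Registry | None = None) -> str:
    """The who/what/when/where/why/how category of a term, else ``unknown``.

    Every condition of use can be read as one of these six interrogative
    forms; the category comes from the registry entry the term resolves to.
    """
    registry = registry if registry is not None else default_registry()
    try:
        entry = registry.lookup(term)
    except Exception:
        entry = None
    return entry.wCategory if entry is not None else "unknown"


def lint_profile(
    profile: DUCProfile,
    registry: Registry | None = None,
    implausible: "set[tuple[str, Rule]] | None" = None,
) -> LintReport:
    """Run all lint checks; never mutates the profile, never fails it."""
    registry = registry if registry is not None else default_registry()
    if implausible is None:
        implausible = load_implausibility_matrix()
    report = LintReport()

    if profile.profileId is None or not _UUID_RE.search(profile.profileId):
        report.warnings.append(
            LintWarning(
                "no-uuid-profile-id",
                "/profileId",
                "profileId is missing or carries no UUID; a UUID-bearing URI "
                "avoids ambiguous profile identifiers",
            )
        )
    if profile.permissionMode is None:
        report.warnings.append(
            LintWarning(
                "no-permission-mode",
                "/permissionMode",
                "no permissionMode declared; unstated conditions will "
                "evaluate to Unknown",
            )
        )
    if (
        profile.creationDate is not None
        and profile.lastUpdated is not None
        and profile.lastUpdated < profile.creationDate
    ):
        report.warnings.append(
            LintWarning(
                "dates-reversed",
                "/lastUpdated",
                f"lastUpdated {profile.lastUpdated} precedes creationDate "
                f"{profile.creationDate}",
            )
        )
    if (
        profile.ducVersion is not None
        and profile.ducVersion not in KNOWN_DUC_VERSIONS
    ):
        report.warnings.append(
            LintWarning(
                "unknown-duc-version",
                "/ducVersion",
                f"ducVersion {profile.ducVersion!r} is not a known release "
                f"({', '.join(sorted(KNOWN_DUC_VERSIONS))})",
            )
        )
    for i, stmt in enumerate(profile.statements):
        if stmt.conditionTerm.uri is None:
            report.warnings.append(
                LintWarning(
                    "label-only-term",
                    f"/statements/{i}/conditionTerm",
                    f"term {stmt.conditionTerm.label!r} has no uri; free-text "
                    "labels reduce interoperability",
                )
            )
        category = categorize_term(stmt.conditionTerm, registry)
        if (category, stmt.rule) in implausible:
            report.warnings.append(
                LintWarning(
                    "implausible-category-rule",
                    f"/statements/{i}",
                    f"a {category!r} concept under rule {stmt.rule.value!r} "
                    "is rarely meaningful (kept: such pairings are warned "
                    "about, never disallowed)",
                )
            )
    for (i, j), reason in detect_conflicts(profile, registry):
        report.warnings.append(
            LintWarning(
                "conflicting-statements",
                f"/statements/{i}",
                f"statements {i} and {j} conflict: {reason}",
            )
        )
    return report
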