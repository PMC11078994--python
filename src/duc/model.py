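"""Typed in-memory representation of Digital Use Conditions (DUC) profiles.

A DUC profile expresses the conditions under which a biomedical asset (a
record, biosample, dataset, registry, or whole biobank) may be used.  It is
an ordered collection of *condition statements* of equal standing, each a
four-part unit assembled in a fixed order:

1. ``conditionTerm`` — an atomic, non-directional concept of use, given as a
   free-text label and/or an ontology URI (e.g. a GA4GH Data Use Ontology
   term);
2. ``rule`` — the directionality applied to the term: ``Obligatory``,
   ``Permitted``, ``Forbidden`` or ``No Requirement``;
3. ``scope`` — whether term+rule covers the ``Whole of asset`` or only
   ``Part of asset`` (defaults to the whole);
4. optional ``conditionParameters`` — refinements such as a country code, a
   disease term, or a numeric value with its unit in the label.

Statements are independent: no statement refers to, or conditions on, any
other statement.  Header fields (identifier, versions, dates, assets,
permission mode, language) contextualise the statements and are all
optional.

Enumerated fields are stored byte-exact: ``"permitted"`` is *not* a valid
rule at this layer.  Lenient normalisation is available only on the document
reading path (see :mod:`duc.schema_io`).
"""

from __future__ import annotations

import datetime as _dt
import math
import re
import uuid as _uuid
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping, Sequence, Union

__all__ = [
    "DUCError",
    "ModelError",
    "Rule",
    "Scope",
    "PermissionMode",
    "TermRef",
    "ConditionParameter",
    "ConditionStatement",
    "AssetRef",
    "DUCProfile",
    "make_statement",
    "make_profile",
    "is_valid_uri",
    "parse_iso_date",
    "SEMVER_RE",
]

ParamValue = Union[int, float, str]


class DUCError(Exception):
    """Base class for all errors raised by this package."""


class ModelError(DUCError):
    """An invariant of the DUC model was violated."""


def _enum_parse(cls, value):
    """Parse ``value`` into enum ``cls``, byte-exact, with a helpful error."""
    if isinstance(value, cls):
        return value
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(repr(m.value) for m in cls)
        raise ModelError(
            f"{value!r} is not a valid {cls.__name__}; allowed values: {allowed}"
        ) from None


class Rule(str, Enum):
    """Directionality of a condition term."""

    OBLIGATORY = "Obligatory"
    PERMITTED = "Permitted"
    FORBIDDEN = "Forbidden"
    NO_REQUIREMENT = "No Requirement"

    @classmethod
    def parse(cls, value: "Rule | str") -> "Rule":
        return _enum_parse(cls, value)


class Scope(str, Enum):
    """Coverage of a term+rule combination over the asset."""

    WHOLE = "Whole of asset"
    PART = "Part of asset"

    @classmethod
    def parse(cls, value: "Scope | str") -> "Scope":
        return _enum_parse(cls, value)


class PermissionMode(str, Enum):
    """Profile-level declaration of how unstated conditions are read."""

    UNSTATED_FORBIDDEN = "All unstated conditions are Forbidden"
    UNSTATED_PERMITTED = "All unstated conditions are Permitted"

    @classmethod
    def parse(cls, value: "PermissionMode | str") -> "PermissionMode":
        return _enum_parse(cls, value)


# Scheme per RFC 3986: ALPHA *( ALPHA / DIGIT / "+" / "-" / "." )
_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:\S+$")

SEMVER_RE = re.compile(
    r"^(0|[1-9]\d*)\.(0|[1-9]\d*)\.(0|[1-9]\d*)"
    r"(?:-[0-9A-Za-z][0-9A-Za-z.\-]*)?(?:\+[0-9A-Za-z][0-9A-Za-z.\-]*)?$"
)

_LANGUAGE_RE = re.compile(r"^[A-Za-z]{3}$")


def is_valid_uri(text: str) -> bool:
    """Syntactic URI check: a scheme, a colon, and no whitespace.

    The scheme is deliberately unrestricted — ``urn:``, ``doi:`` and other
    non-locator identifiers are as acceptable as ``http(s)``.
    """
    return isinstance(text, str) and bool(_URI_RE.match(text))


def parse_iso_date(value: "str | _dt.date") -> _dt.date:
    """Parse an ISO 8601 date or date-time into a date.

    Accepts :class:`datetime.date`/`datetime.datetime` objects as-is
    (datetimes are truncated to their date).
    """
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    if not isinstance(value, str):
        raise ModelError(f"cannot interpret {value!r} as an ISO 8601 date")
    try:
        return _dt.date.fromisoformat(value)
    except ValueError:
        pass
    try:
        return _dt.datetime.fromisoformat(value).date()
    except ValueError:
        raise ModelError(f"{value!r} is not an ISO 8601 date") from None


@dataclass(frozen=True)
class TermRef:
    """A concept reference: free-text label and/or resource identifier.

    At least one of ``label``/``uri`` must be present and non-empty.  The
    URI is checked syntactically only; no network resolution ever happens.
    """

    label: str | None = None
    uri: str | None = None

    def __post_init__(self) -> None:
        if not (self.label or self.uri):
            raise ModelError(
                "a term reference needs a non-empty label and/or uri"
            )
        if self.uri is not None and not is_valid_uri(self.uri):
            raise ModelError(f"{self.uri!r} is not a syntactically valid URI")


@dataclass(frozen=True)
class ConditionParameter:
    """A refinement of a statement: label, ontology URI and/or scalar value.

    Units travel in the label (value ``12``, label ``"months"``); there is
    no dedicated units field in this version of the model.
    """

    label: str | None = None
    uri: str | None = None
    value: ParamValue | None = None

    def __post_init__(self) -> None:
        if self.label is None and self.uri is None and self.value is None:
            raise ModelError(
                "a condition parameter needs a label, uri or value"
            )
        if self.uri is not None and not is_valid_uri(self.uri):
            raise ModelError(f"{self.uri!r} is not a syntactically valid URI")
        if isinstance(self.value, (int, float)) and not isinstance(self.value, bool):
            if not math.isfinite(self.value):
                raise ModelError("numeric parameter values must be finite")


@dataclass(frozen=True)
class ConditionStatement:
    """The four-part condition unit: term + rule + scope + parameters.

    Reads as the sentence "Regarding [conditionTerm], this form of use is
    [rule], and applies to the [scope], for which the details are
    [conditionParameter]".  Statements never reference other statements.
    """

    conditionTerm: TermRef
    rule: Rule
    scope: Scope = Scope.WHOLE
    conditionParameters: tuple[ConditionParameter, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.conditionTerm, TermRef):
            raise ModelError("conditionTerm must be a TermRef")
        object.__setattr__(self, "rule", Rule.parse(self.rule))
        object.__setattr__(self, "scope", Scope.parse(self.scope))
        object.__setattr__(
            self, "conditionParameters", tuple(self.conditionParameters)
        )
        for p in self.conditionParameters:
            if not isinstance(p, ConditionParameter):
                raise ModelError(
                    "conditionParameters must contain ConditionParameter objects"
                )


@dataclass(frozen=True)
class AssetRef:
    """A pointer to an asset the profile governs. At least one field set."""

    assetName: str | None = None
    assetDescription: str | None = None
    assetReferences: tuple[str, ...] | None = None
    assetURI: str | None = None

    def __post_init__(self) -> None:
        if self.assetReferences is not None:
            object.__setattr__(
                self, "assetReferences", tuple(self.assetReferences)
            )
        if (
            self.assetName is None
            and self.assetDescription is None
            and self.assetReferences is None
            and self.assetURI is None
        ):
            raise ModelError("an asset reference needs at least one field")
        if self.assetURI is not None and not is_valid_uri(self.assetURI):
            raise ModelError(
                f"{self.assetURI!r} is not a syntactically valid URI"
            )


@dataclass(frozen=True)
class DUCProfile:
    """A DUC profile: optional contextual header + >=1 condition statements.

    ``extensions`` preserves unknown top-level document keys so that
    documents written by later model versions survive a read/write cycle.
    Whether ``lastUpdated`` precedes ``creationDate`` is a lint-level
    concern, not a constructor error.
    """

    statements: tuple[ConditionStatement, ...]
    profileId: str | None = None
    profileVersion: str | None = None
    profileName: str | None = None
    ducVersion: str | None = None
    creationDate: _dt.date | None = None
    lastUpdated: _dt.date | None = None
    assets: tuple[AssetRef, ...] | None = None
    permissionMode: PermissionMode | None = None
    language: str | None = None
    extensions: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "statements", tuple(self.statements))
        if not self.statements:
            raise ModelError("profile requires at least one statement")
        for s in self.statements:
            if not isinstance(s, ConditionStatement):
                raise ModelError("statements must be ConditionStatement objects")
        if self.profileId is not None and not is_valid_uri(self.profileId):
            raise ModelError(
                f"profileId {self.profileId!r} is not a syntactically valid URI"
            )
        if self.profileVersion is not None and not SEMVER_RE.match(
            self.profileVersion
        ):
            raise ModelError(
                f"profileVersion {self.profileVersion!r} is not a semantic version"
            )
        if self.creationDate is not None:
            object.__setattr__(
                self, "creationDate", parse_iso_date(self.creationDate)
            )
        if self.lastUpdated is not None:
            object.__setattr__(
                self, "lastUpdated", parse_iso_date(self.lastUpdated)
            )
        if self.assets is not None:
            object.__setattr__(self, "assets", tuple(self.assets))
            for a in self.assets:
                if not isinstance(a, AssetRef):
                    raise ModelError("assets must contain AssetRef objects")
        if self.permissionMode is not None:
            object.__setattr__(
                self, "permissionMode", PermissionMode.parse(self.permissionMode)
            )
        if self.language is not None and not _LANGUAGE_RE.match(self.language):
            raise ModelError(
                f"language {self.language!r} is not a 3-letter ISO 639-3 code"
            )
        object.__setattr__(self, "extensions", dict(self.extensions))


def make_statement(
    term: TermRef,
    rule: Rule | str,
    scope: Scope | str | None = None,
    parameters: Iterable[ConditionParameter] | None = None,
) -> ConditionStatement:
    """Assemble a condition statement, defaulting scope to the whole asset.

    Parameters
    ----------
    term:
        The atomic, non-directional concept of use.
    rule:
        Directionality — one of the four exact rule strings or a :class:`Rule`.
    scope:
        Coverage; ``None`` means ``"Whole of asset"``.
    parameters:
        Optional refinements; ``None`` means no parameters.

    Raises
    ------
    ModelError
        If the rule or scope string is outside its printed value set, or the
        term is invalid.
    """
    return ConditionStatement(
        conditionTerm=term,
        rule=Rule.parse(rule),
        scope=Scope.WHOLE if scope is None else Scope.parse(scope),
        conditionParameters=tuple(parameters) if parameters else (),
    )


def make_profile(
    statements: Sequence[ConditionStatement],
    *,
    profileId: str | None = None,
    profileVersion: str | None = None,
    profileName: str | None = None,
    ducVersion: str | None = None,
    creationDate: "str | _dt.date | None" = None,
    lastUpdated: "str | _dt.date | None" = None,
    assets: Sequence[AssetRef] | None = None,
    permissionMode: PermissionMode | str | None = None,
    language: str | None = None,
    auto_id: bool = False,
    auto_dates: bool = False,
) -> DUCProfile:
    """Assemble a DUC profile from statements and optional header fields.

    With ``auto_id`` a fresh ``urn:uuid:...`` profile identifier is minted
    (a UUID in the identifier keeps profile references unambiguous).  With
    ``auto_dates`` both creation and last-update dates are set to today.
    """
    if not statements:
        raise ModelError("profile requires at least one statement")
    if auto_id:
        if profileId is not None:
            raise ModelError("auto_id conflicts with an explicit profileId")
        profileId = f"urn:uuid:{_uuid.uuid4()}"
    if auto_dates:
        today = _dt.date.today()
        creationDate = creationDate or today
        lastUpdated = lastUpdated or today
    return DUCProfile(
        statements=tuple(statements),
        profileId=profileId,
        profileVersion=profileVersion,
        profileName=profileName,
        ducVersion=ducVersion,
        creationDate=creationDate,
        lastUpdated=lastUpdated,
        assets=tuple(assets) if assets is not None else None,
        permissionMode=(
            PermissionMode.parse(permissionMode)
            if permissionMode is not None
            else None
        ),
        language=language,
    )
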