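"""Term identity: CURIEs, labels, matching, and the DUO-tag converter.

Condition terms may be referenced by ontology URI (ideally a persistent
purl, e.g. ``http://purl.obolibrary.org/obo/DUO_0000007`` for "Disease
specific research"), by compact CURIE (``DUO:0000007``), or by free-text
label.  URIs resolve term identity unambiguously; labels only match after a
conservative normalisation (case fold, whitespace collapse) — no fuzzy or
semantic matching is attempted here, that job belongs to an intermediary
terminology service.

A small file-backed :class:`Registry` mediates between the three forms and
carries the who/what/when/where/why/how category used by the linter and the
default directionality used when converting plain DUO-style tag lists into
profiles.  Everything is offline: no ontology is ever fetched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

from .model import (
    DUCError,
    DUCProfile,
    Rule,
    TermRef,
    is_valid_uri,
    make_profile,
    make_statement,
)

__all__ = [
    "VocabEntry",
    "Registry",
    "UnknownPrefixError",
    "ConversionError",
    "default_registry",
    "expand_curie",
    "contract_uri",
    "normalize_label",
    "terms_match",
    "duo_tags_to_profile",
    "DEFAULT_PREFIXES",
    "W_CATEGORIES",
]

#: OBO purl convention as printed in DUO/DOID identifiers (underscore form).
DEFAULT_PREFIXES: dict[str, str] = {
    "DUO": "http://purl.obolibrary.org/obo/DUO_",
    "DOID": "http://purl.obolibrary.org/obo/DOID_",
}

W_CATEGORIES = frozenset({"who", "what", "when", "where", "why", "how", "unknown"})

_CURIE_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_.\-]*):(\S+)$")


class UnknownPrefixError(DUCError):
    """A CURIE used a prefix absent from the registry's prefix map."""


class ConversionError(DUCError):
    """A tag list could not be converted into a profile."""


def normalize_label(label: str) -> str:
    """Case-fold, trim, and collapse internal whitespace runs.

    This is the *only* label transformation applied anywhere: two labels
    denote the same concept exactly when their normalisations are equal.
    Idempotent by construction.
    """
    return " ".join(label.split()).casefold()


@dataclass(frozen=True)
class VocabEntry:
    """One registry row: a concept URI with labels and lint/convert hints."""

    uri: str
    preferredLabel: str
    synonyms: tuple[str, ...] = ()
    wCategory: str = "unknown"
    defaultRule: Rule | None = None

    def __post_init__(self) -> None:
        if self.wCategory not in W_CATEGORIES:
            raise DUCError(
                f"wCategory {self.wCategory!r} not in {sorted(W_CATEGORIES)}"
            )


@dataclass(frozen=True)
class Registry:
    """A closed, file-backed vocabulary with a CURIE prefix map."""

    entries: tuple[VocabEntry, ...] = ()
    prefixes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PREFIXES))

    def __post_init__(self) -> None:
        bases = list(self.prefixes.values())
        if len(set(bases)) != len(bases):
            raise DUCError("prefix expansion must be injective: duplicate base URIs")
        seen: set[str] = set()
        for e in self.entries:
            if e.uri in seen:
                raise DUCError(f"duplicate registry uri {e.uri!r}")
            seen.add(e.uri)

    # -- lookup tables (built lazily, cached on the instance dict) --------
    @property
    def by_uri(self) -> dict[str, VocabEntry]:
        cache = self.__dict__.get("_by_uri")
        if cache is None:
            cache = {e.uri: e for e in self.entries}
            self.__dict__["_by_uri"] = cache
        return cache

    @property
    def by_label(self) -> dict[str, VocabEntry]:
        """Normalised preferred label or synonym -> entry."""
        cache = self.__dict__.get("_by_label")
        if cache is None:
            cache = {}
            for e in self.entries:
                for lab in (e.preferredLabel, *e.synonyms):
                    cache.setdefault(normalize_label(lab), e)
            self.__dict__["_by_label"] = cache
        return cache

    def lookup(self, ref: TermRef) -> VocabEntry | None:
        """Resolve a term reference to a registry entry, URI first."""
        if ref.uri is not None:
            return self.by_uri.get(expand_curie(ref.uri, self))
        if ref.label is not None:
            return self.by_label.get(normalize_label(ref.label))
        return None

    @classmethod
    def from_file(
        cls,
        path: "str | Path",
        prefixes: dict[str, str] | None = None,
    ) -> "Registry":
        """Read a tab-separated registry file.

        Columns: uri, preferredLabel, synonyms (pipe-joined, may be empty),
        wCategory, defaultRule (optional).  Lines starting with ``#`` are
        comments.
        """
        entries = []
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise DUCError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            uri, label = cols[0].strip(), cols[1].strip()
            synonyms = tuple(
                s.strip() for s in (cols[2].split("|") if len(cols) > 2 and cols[2].strip() else [])
            )
            category = cols[3].strip() if len(cols) > 3 and cols[3].strip() else "unknown"
            rule = (
                Rule.parse(cols[4].strip())
                if len(cols) > 4 and cols[4].strip()
                else None
            )
            entries.append(
                VocabEntry(
                    uri=uri,
                    preferredLabel=label,
                    synonyms=synonyms,
                    wCategory=category,
                    defaultRule=rule,
                )
            )
        return cls(
            entries=tuple(entries),
            prefixes=dict(prefixes) if prefixes is not None else dict(DEFAULT_PREFIXES),
        )


@lru_cache(maxsize=1)
def default_registry() -> Registry:
    """The small illustrative registry bundled with the package."""
    from importlib.resources import as_file, files

    with as_file(files("duc.data") / "registry.tsv") as p:
        return Registry.from_file(p)


def expand_curie(curie: str, registry: Registry | None = None) -> str:
    """Expand ``prefix:localId`` to a full URI via the registry prefix map.

    Inputs that are already URIs (``://`` present, or a ``urn:``/``doi:``
    identifier) pass through unchanged.  An unregistered CURIE prefix is an
    error, so typos do not silently become opaque identifiers.
    """
    registry = registry if registry is not None else default_registry()
    if "://" in curie:
        return curie
    m = _CURIE_RE.match(curie)
    if m:
        prefix, local = m.group(1), m.group(2)
        if prefix in registry.prefixes:
            return registry.prefixes[prefix] + local
        if is_valid_uri(curie) and prefix.lower() in {"urn", "doi", "mailto", "file"}:
            return curie
        raise UnknownPrefixError(
            f"unknown CURIE prefix {prefix!r}; registered: "
            f"{sorted(registry.prefixes)}"
        )
    raise UnknownPrefixError(f"{curie!r} is neither a CURIE nor a URI")


def contract_uri(uri: str, registry: Registry | None = None) -> str:
    """Contract a URI to CURIE form using the longest matching base.

    URIs under no registered base are returned unchanged.
    """
    registry = registry if registry is not None else default_registry()
    best: tuple[int, str] | None = None
    for prefix, base in registry.prefixes.items():
        if uri.startswith(base) and len(uri) > len(base):
            if best is None or len(base) > best[0]:
                best = (len(base), f"{prefix}:{uri[len(base):]}")
    return best[1] if best is not None else uri


def terms_match(a: TermRef, b: TermRef, registry: Registry | None = None) -> bool:
    """Decide whether two term references denote the same concept.

    Symmetric.  URI-vs-URI comparison is authoritative (after CURIE
    expansion); a label-only reference matches a URI-bearing one only when
    the registry maps that label (or a synonym) to the same URI; label-only
    pairs match exactly after :func:`normalize_label` — never fuzzily.
    """
    registry = registry if registry is not None else default_registry()
    if a.uri is not None and b.uri is not None:
        return expand_curie(a.uri, registry) == expand_curie(b.uri, registry)
    if a.uri is None and b.uri is None:
        # both necessarily carry labels (TermRef invariant)
        return normalize_label(a.label) == normalize_label(b.label)
    with_uri, label_only = (a, b) if a.uri is not None else (b, a)
    if label_only.label is None:
        return False
    entry = registry.by_label.get(normalize_label(label_only.label))
    if entry is None:
        return False
    return entry.uri == expand_curie(with_uri.uri, registry)


def duo_tags_to_profile(
    tags: Iterable[str], registry: Registry | None = None
) -> DUCProfile:
    """Decompose a flat list of DUO-style tags into a DUC profile.

    Tag systems attach directional codes to datasets; the DUC model instead
    separates each concept (atomic, non-directional) from its rule.  Each
    tag becomes one independent statement whose term is the registry's
    URI + preferred label and whose rule is the registry's default
    directionality — so a negated modifier tag ("No X use") yields its
    atomic root X under rule ``Forbidden``.

    Raises
    ------
    ConversionError
        If the tag list is empty, or any tag lacks a registry entry with a
        default rule (all offenders listed).
    """
    registry = registry if registry is not None else default_registry()
    tags = list(tags)
    if not tags:
        raise ConversionError(
            "cannot convert an empty tag list: profiles need at least one statement"
        )
    unmapped: list[str] = []
    statements = []
    for tag in tags:
        try:
            uri = expand_curie(tag, registry)
        except UnknownPrefixError:
            unmapped.append(tag)
            continue
        entry = registry.by_uri.get(uri)
        if entry is None or entry.defaultRule is None:
            unmapped.append(tag)
            continue
        statements.append(
            make_statement(
                TermRef(label=entry.preferredLabel, uri=entry.uri),
                entry.defaultRule,
            )
        )
    if unmapped:
        raise ConversionError(
            "tags without a registry mapping (uri + defaultRule): "
            + ", ".join(repr(t) for t in unmapped)
        )
    return make_profile(statements)
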