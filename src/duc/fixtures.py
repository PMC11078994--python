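"""Packaged worked examples and a seeded synthetic profile generator.

Worked examples
---------------
``fig2``
    The canonical three-statement profile: general research use permitted,
    country restricted to the United Kingdom, and a 12-month time limit on
    use as an obligation.  Its narrative rendering is the reference
    paragraph reproduced byte-exactly in the golden tests.
``fig3``
    The same three statements under a fully populated contextual header.
    The header values are this package's invention (valid, but not part of
    any golden byte comparison).
``duo_discussion``
    A single fully URI-qualified statement: disease-specific research
    (DUO_0000007) permitted for the whole asset, parameterised by epilepsy
    (DOID_1826).

Generator
---------
:func:`generate_profiles` draws schema-valid profiles from the bundled
registry vocabulary under configurable inclusion probabilities, entirely
driven by one integer seed.  :func:`generate_corpus` additionally returns
per-profile bookkeeping (planted obligatory/parameterised statement counts,
header fields used) so tests can check module outputs against what was
planted rather than against the module under test.
"""

from __future__ import annotations

import datetime as _dt
import random
import uuid as _uuid
from dataclasses import dataclass

from .model import (
    AssetRef,
    ConditionParameter,
    ConditionStatement,
    DUCError,
    DUCProfile,
    PermissionMode,
    Rule,
    Scope,
    TermRef,
    make_profile,
    make_statement,
)
from .vocab import Registry, default_registry

__all__ = [
    "WORKED_EXAMPLES",
    "worked_example",
    "GeneratorConfig",
    "GeneratedProfile",
    "generate_corpus",
    "generate_profiles",
]

WORKED_EXAMPLES = ("fig2", "fig3", "duo_discussion")

_OBO = "http://purl.obolibrary.org/obo/"


def _fig2_statements() -> tuple[ConditionStatement, ...]:
    return (
        make_statement(TermRef(label="General research use"), Rule.PERMITTED),
        make_statement(
            TermRef(label="Country"),
            Rule.PERMITTED,
            parameters=[ConditionParameter(label="the United Kingdom")],
        ),
        make_statement(
            TermRef(label="Time limit on use"),
            Rule.OBLIGATORY,
            parameters=[ConditionParameter(label="months", value=12)],
        ),
    )


def worked_example(name: str) -> DUCProfile:
    """Return one of the packaged worked-example profiles by name."""
    if name == "fig2":
        return make_profile(_fig2_statements())
    if name == "fig3":
        return make_profile(
            _fig2_statements(),
            profileId="urn:uuid:550e8400-e29b-41d4-a716-446655440000",
            profileVersion="1.0.1",
            profileName="Example registry use conditions",
            ducVersion="1.0.0",
            creationDate=_dt.date(2023, 3, 1),
            lastUpdated=_dt.date(2023, 6, 15),
            assets=[
                AssetRef(
                    assetName="Example rare disease patient registry",
                    assetDescription=(
                        "A fictional national patient registry used to "
                        "illustrate contextual header fields."
                    ),
                    assetReferences=["https://example.org/registry-docs"],
                    assetURI="https://example.org/assets/registry-42",
                )
            ],
            permissionMode=PermissionMode.UNSTATED_FORBIDDEN,
            language="eng",
        )
    if name == "duo_discussion":
        return make_profile(
            [
                make_statement(
                    TermRef(
                        label="Disease specific research",
                        uri=f"{_OBO}DUO_0000007",
                    ),
                    Rule.PERMITTED,
                    Scope.WHOLE,
                    parameters=[
                        ConditionParameter(
                            label="epilepsy", uri=f"{_OBO}DOID_1826"
                        )
                    ],
                )
            ]
        )
    raise KeyError(
        f"unknown worked example {name!r}; available: {', '.join(WORKED_EXAMPLES)}"
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic profile generator.

    Probabilities are per-statement (``p_parameter``, ``p_uri``,
    ``p_obligatory``, ``p_forbidden``) or per-header-field
    (``p_header_field``).  Rules are drawn independently per statement:
    Obligatory with ``p_obligatory``, Forbidden with ``p_forbidden``, and
    the remainder split 4:1 between Permitted and No Requirement —
    permissive statements dominate real profiles, which mostly describe
    what a custodian allows.
    """

    n_profiles: int = 100
    statements_min: int = 1
    statements_max: int = 6
    p_parameter: float = 0.5
    p_uri: float = 0.6
    p_header_field: float = 0.5
    p_obligatory: float = 0.15
    p_forbidden: float = 0.15
    seed: int = 0
    vocabulary: Registry | None = None

    def __post_init__(self) -> None:
        for name in (
            "p_parameter",
            "p_uri",
            "p_header_field",
            "p_obligatory",
            "p_forbidden",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DUCError(f"{name}={v} is not a probability")
        if self.statements_min < 1 or self.statements_max < self.statements_min:
            raise DUCError("statement count range must satisfy 1 <= min <= max")
        if self.p_obligatory + self.p_forbidden > 1.0:
            raise DUCError("p_obligatory + p_forbidden must not exceed 1")
        if self.n_profiles < 0:
            raise DUCError("n_profiles must be non-negative")


@dataclass(frozen=True)
class GeneratedProfile:
    """A generated profile plus the bookkeeping of what was planted."""

    profile: DUCProfile
    n_statements: int
    n_obligatory: int
    n_forbidden: int
    n_parameterized: int
    header_fields: tuple[str, ...]


_PARAM_LABELS = (
    "the United Kingdom",
    "France",
    "Germany",
    "Canada",
    "epilepsy",
    "type 2 diabetes",
)
_VALUE_PARAMS = ((12, "months"), (2, "years"), (5, "years"), (36, "months"))
_PROFILE_NAMES = (
    "Biobank use conditions",
    "Registry access profile",
    "Cohort sharing terms",
    "Imaging collection terms",
)
_LANGUAGES = ("eng", "fra", "deu", "spa")
_VERSIONS = ("1.0.0", "1.0.1", "1.1.0", "2.0.0")


def _draw_rule(rng: random.Random, cfg: GeneratorConfig) -> Rule:
    u = rng.random()
    if u < cfg.p_obligatory:
        return Rule.OBLIGATORY
    if u < cfg.p_obligatory + cfg.p_forbidden:
        return Rule.FORBIDDEN
    rest = 1.0 - cfg.p_obligatory - cfg.p_forbidden
    if rest <= 0.0 or (u - cfg.p_obligatory - cfg.p_forbidden) < 0.8 * rest:
        return Rule.PERMITTED
    return Rule.NO_REQUIREMENT


def _draw_statement(
    rng: random.Random, cfg: GeneratorConfig, registry: Registry
) -> ConditionStatement:
    entry = rng.choice(registry.entries)
    use_uri = rng.random() < cfg.p_uri
    if use_uri:
        term = TermRef(
            label=entry.preferredLabel if rng.random() < 0.5 else None,
            uri=entry.uri,
        )
    else:
        term = TermRef(label=entry.preferredLabel)
    params: list[ConditionParameter] = []
    if rng.random() < cfg.p_parameter:
        if rng.random() < 0.3:
            value, unit = rng.choice(_VALUE_PARAMS)
            params.append(ConditionParameter(label=unit, value=value))
        else:
            for lab in rng.sample(_PARAM_LABELS, k=rng.choice((1, 1, 2))):
                params.append(ConditionParameter(label=lab))
    return make_statement(
        term,
        _draw_rule(rng, cfg),
        Scope.PART if rng.random() < 0.15 else Scope.WHOLE,
        parameters=params,
    )


def _draw_header(rng: random.Random, cfg: GeneratorConfig) -> dict:
    fields: dict = {}
    if rng.random() < cfg.p_header_field:
        fields["profileId"] = (
            f"urn:uuid:{_uuid.UUID(int=rng.getrandbits(128), version=4)}"
        )
    if rng.random() < cfg.p_header_field:
        fields["profileVersion"] = rng.choice(_VERSIONS)
    if rng.random() < cfg.p_header_field:
        fields["profileName"] = rng.choice(_PROFILE_NAMES)
    if rng.random() < cfg.p_header_field:
        fields["ducVersion"] = "1.0.0"
    if rng.random() < cfg.p_header_field:
        created = _dt.date(2020, 1, 1) + _dt.timedelta(days=rng.randrange(1500))
        fields["creationDate"] = created
        fields["lastUpdated"] = created + _dt.timedelta(days=rng.randrange(400))
    if rng.random() < cfg.p_header_field:
        fields["permissionMode"] = rng.choice(tuple(PermissionMode))
    if rng.random() < cfg.p_header_field:
        fields["language"] = rng.choice(_LANGUAGES)
    if rng.random() < cfg.p_header_field:
        fields["assets"] = [
            AssetRef(
                assetName=f"Asset {rng.randrange(1000)}",
                assetURI=f"https://example.org/assets/{rng.randrange(1000)}",
            )
        ]
    return fields


def generate_corpus(config: GeneratorConfig) -> list[GeneratedProfile]:
    """Generate profiles with bookkeeping; deterministic for a fixed seed."""
    registry = (
        config.vocabulary if config.vocabulary is not None else default_registry()
    )
    if not registry.entries:
        raise DUCError("generator needs a non-empty vocabulary")
    rng = random.Random(config.seed)
    out: list[GeneratedProfile] = []
    for _ in range(config.n_profiles):
        n = rng.randint(config.statements_min, config.statements_max)
        statements = [_draw_statement(rng, config, registry) for _ in range(n)]
        header = _draw_header(rng, config)
        profile = make_profile(statements, **header)
        out.append(
            GeneratedProfile(
                profile=profile,
                n_statements=n,
                n_obligatory=sum(
                    1 for s in statements if s.rule is Rule.OBLIGATORY
                ),
                n_forbidden=sum(
                    1 for s in statements if s.rule is Rule.FORBIDDEN
                ),
                n_parameterized=sum(
                    1 for s in statements if s.conditionParameters
                ),
                header_fields=tuple(sorted(header)),
            )
        )
    return out


def generate_profiles(config: GeneratorConfig) -> list[DUCProfile]:
    """Generate schema-valid profiles; deterministic for a fixed seed."""
    return [g.profile for g in generate_corpus(config)]
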