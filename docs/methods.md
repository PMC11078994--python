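# Methods

This note documents the semantics this package implements, the choices
made where the underlying model leaves behaviour open, and what the test
fixtures do and do not establish.

## The statement model

A condition statement is the ordered four-part unit
`conditionTerm → rule → scope → conditionParameters`.  Terms are atomic
and non-directional; all directionality lives in the rule, one of exactly
four byte-exact strings (`Obligatory`, `Permitted`, `Forbidden`,
`No Requirement`).  Scope defaults to `Whole of asset` and expresses
*coverage*, never permission strength.  Parameters refine a statement to
any degree (a country, a disease URI, a numeric value); units ride in the
parameter label (`value: 12, label: "months"`) because the model has no
dedicated units field.  `conditionParameters` is a list — profiles
commonly need "one or more country codes" — and a single-parameter object
in a document is accepted on read and normalised to a one-element list.

Statements are independent: nothing in one statement conditions on
another, and no Boolean inter-statement logic exists in this model
version.  Alternative condition sets are expressed as multiple profiles
per asset.

Enumerated fields are never case-folded at the model layer
(`"permitted"` is invalid).  A *lenient* reading mode — off by default —
folds case/whitespace variants of `rule`/`scope`/`permissionMode` onto
their printed forms and records each fold as a `normalized` warning.

## Serialization and validation

`dump_profile` is canonical: header keys in a fixed order, two-space
indent, dates emitted date-only (full ISO 8601 date-times are accepted on
read and truncated), `language` lower-cased on write, parameters always
in list form, unknown top-level keys preserved in an `extensions` map and
re-emitted after the known keys (sorted).  Consequently `load∘dump` is
the identity on the model and `dump∘load∘dump = dump` on documents.  The
identity holds for profiles whose language is already lower-case and
whose dates are date-valued — i.e. for everything the package itself
writes; the lower-casing and truncation are the two documented
normalisations.

`validate_document` reports *all* violations, each with a stable code
(`rule-enum`, `statements-min`, `language-format`, ...) and a
JSON-pointer path.  It is implemented as an explicit structural walker;
the bundled JSON Schema 2020-12 file (`duc/data/duc-profile.schema.json`)
renders the same constraints for interoperating tools, and a test pins
the schema's enumerations and minimum-statements bound to the model
constants.  Two deliberately light checks: `language` is validated as
exactly three ASCII letters rather than against the full ISO 639-3
registry (no registry is bundled), and `ducVersion` accepts any string,
with unknown release values flagged by the linter instead.

## Term identity

Term matching is deliberately conservative, in three tiers:

1. both references carry URIs → equality after CURIE expansion
   (authoritative);
2. exactly one carries a URI → match only if the registry maps the
   other's normalised label or synonym to that same URI;
3. neither carries a URI → equality of normalised labels.

Normalisation is case-fold + whitespace collapse, nothing else: "Research
specific" never matches "Disease specific research".  Fuzzy or semantic
matching is out of scope by design — it belongs to a terminology
intermediary, not a conditions-of-use engine.  The bundled registry
(12 rows, tab-separated) is illustrative: apart from `DUO_0000007`
(disease specific research) its DUO-prefixed identifiers are fixtures,
not assertions about DUO releases.  The prefix map ships with `DUO` and
`DOID` under the OBO underscore-purl convention and is user-extensible.

The DUO-tag converter gives each tag one statement: the registry row's
URI + preferred label under the row's default rule.  A directional source
tag (a "No ..." modifier) is decomposed by the row itself, whose
preferred label is the atomic root and whose default rule is `Forbidden`.

## Rendering

The narrative style is keyed on statement shape: no parameter →
"`<Term>` is `<rule-phrase>` for the `<scope-phrase>`."; label-only
parameters → "The `<term, lower-cased>` of `<labels>` is ... ";
value-bearing parameters → "The `<term, lower-cased>` is `<value>
<label>` and is ...".  Rule phrases are permitted / forbidden /
obligatory / "not subject to any requirement" (the last is this package's
coinage; the model names no narrative phrase for `No Requirement`).
URI-only terms render through the registry's preferred label, else the
contracted CURIE.  Rendering is pure; the worked example reproduces its
reference paragraph byte-exactly and is pinned by a golden test.

## Decision semantics

`evaluate_term` is total and deterministic:

1. **Match.** A statement matches a requested (term, parameter) when the
   terms match and parameters are compatible: an unparameterised
   statement covers any request parameter; a parameterised statement
   covers only a request whose parameter equals one of its own (URI
   equality after expansion, else normalised-label equality, else value
   equality).  A request item *without* a parameter does not match a
   parameterised statement — the statement is narrower than the ask.
2. **Defaults.** No match → `permissionMode` decides
   (`ForbiddenByDefault` / `PermittedByDefault`); with no declared mode
   the verdict is `Unknown`, never a silent default.  Any matched
   statement pre-empts the mode, including `No Requirement`.
3. **Resolution.** Among matched rules, any contradictory pair —
   Forbidden against any of Permitted/Obligatory/No Requirement, or
   Obligatory against No Requirement — yields `Conflict` (surfaced, not
   resolved).  Otherwise the strongest rule wins under
   Forbidden > Obligatory > Permitted > No Requirement.  The model itself
   asserts statement independence and no precedence; this conservative
   ordering plus explicit conflict surfacing is this package's policy,
   checked against an independent decision-table oracle over an
   exhaustive 120-case enumeration.
4. **Partiality.** `partial` is set when every decisive statement covers
   only part of the asset; scope never alters the outcome itself.

A profile grants a request when no item's verdict blocks it; blocking
outcomes are `Forbidden`, `ForbiddenByDefault`, `Unknown` and `Conflict`
(so permitted-by-default grants, making the all-permitted mode the limit
case in which any request without forbidden/conflicting matches is
granted).  A granting profile's `Obligatory` statements are returned as
obligations.  Aggregation across profiles is OR; there is no cross-profile
conflict notion.  Quantitative parameter reasoning (whether a 6-month
request satisfies a 12-month limit) is explicitly out of scope.

`detect_conflicts` flags statement pairs with matching terms, compatible
parameter sets (both empty, or overlapping under parameter equality) and
contradictory rules.  A pair where exactly one statement is
parameterised is *not* flagged — the parameterised one is read as a
narrower carve-out — a known limitation of the literal compatibility
rule.

## Linting

Seven warning codes, never errors: `label-only-term`,
`no-uuid-profile-id` (missing identifier or identifier without a UUID),
`implausible-category-rule`, `conflicting-statements`,
`no-permission-mode`, `dates-reversed`, `unknown-duc-version`.  Every
term is classifiable as a who/what/when/where/why/how form of use; the
implausibility matrix pairing {how, why} with `Forbidden` ships as data
(`duc/data/implausible_rules.tsv`) so adopters can extend it, and flagged
pairings are always kept — tools may warn, the model forbids nothing.

## Synthetic generator

`generate_profiles` draws schema-valid profiles from the bundled
registry under per-statement probabilities (defaults: 1–6 statements,
parameter 0.5, URI 0.6, header field 0.5, obligatory 0.15, forbidden
0.15, remainder split 4:1 permitted : no-requirement — real profiles are
dominated by statements about what a custodian allows).  All randomness
flows from one integer seed through a single `random.Random`; UUIDs are
drawn from the same stream, so corpora are byte-reproducible.
`generate_corpus` returns planted counts per profile so tests check
module outputs against bookkeeping rather than against the modules
themselves.

What the generator emulates: structural variety (statement counts,
label/URI mixtures, parameter shapes, header sparsity) over a closed
vocabulary.  What it does not: realistic institutional policy text, open
vocabularies, cross-field correlations, or adversarially malformed
documents.  Passing the round-trip and statistical suites therefore
establishes the *mechanics* — serialization, validation, decision
algebra — not fitness of any particular vocabulary for a real governance
setting.

## Problem sizes and numerics

The standard suites use corpora of 200–2,000 generated profiles
(round-trip identity over 1,000 profiles at seed 1; the obligatory-rate
check over 2,000 profiles at p = 0.3, asserted within three binomial
standard errors); the decision oracle is exhaustive at 120 cases.  These
sizes exercise every code path while keeping the whole suite in seconds.
There is no floating-point numerics to speak of: values are compared
exactly, and the only tolerance anywhere is the binomial band above.
Dates compare as calendar dates; numeric parameter values compare with
Python scalar equality (so `12 == 12.0`).

## Known limitations

* Registry membership of ISO 639-3 codes is not checked (format only).
* Label matching across languages, synonym mining and fuzzy matching are
  out of scope.
* The one-parameterised/one-bare conflict pattern described above is not
  flagged.
* Statement-level extension keys are not preserved (only top-level
  unknown keys are).
* Obligations attach to a grant as whole statements; no machinery
  interprets their parameters (time spans, amounts).
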