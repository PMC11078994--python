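# duc-toolkit

A Python library and `duc` command-line tool for **Digital Use Conditions
(DUC)**: machine-readable profiles describing the conditions under which
biomedical assets — records, biosamples, datasets, registries, whole
biobanks — may be used.

It is written for the people who sit between data and its reuse: resource
custodians who must document sharing conditions, catalogue builders who
want those conditions queryable, and Data Access Committees who triage
requests against them.

## The model

A **DUC profile** is an ordered list of *at least one* independent
condition statement plus optional contextual header fields.  Each
statement is a four-part unit, assembled in a fixed order so that it reads
as a natural sentence:

| part | meaning | values |
|---|---|---|
| `conditionTerm` | atomic, *non-directional* concept of use | free-text `label` and/or ontology `uri` (e.g. `http://purl.obolibrary.org/obo/DUO_0000007` = disease specific research) |
| `rule` | directionality applied to the term | `Obligatory`, `Permitted`, `Forbidden`, `No Requirement` |
| `scope` | coverage over the asset | `Whole of asset` (default), `Part of asset` |
| `conditionParameters` | optional refinements | `label` / `uri` / scalar `value` (units in the label) |

giving the canonical sentence *"Regarding [conditionTerm], this form of
use is [rule], and applies to the [scope], for which the details are
[conditionParameter]."*

Statements are of equal standing and never reference one another; the
header's `permissionMode` declares how unstated conditions are read
(`All unstated conditions are Forbidden` / `... Permitted`).  Alternative
condition sets are expressed as *multiple profiles* for one asset, with
OR semantics across profiles.

On top of the model the package provides:

* **schema_io** — canonical JSON read/write plus a validator that reports
  *every* violation with a machine code and JSON-pointer path (a JSON
  Schema 2020-12 file ships alongside);
* **vocab** — CURIE⇄URI handling, conservative label normalisation,
  registry-mediated term matching, and a converter that decomposes flat
  DUO-style tag lists into atomic statement + rule form;
* **decide** — a per-term decision engine (match → permissionMode defaults
  → conflict detection → Forbidden > Obligatory > Permitted >
  No Requirement precedence) with obligations and multi-profile OR
  aggregation;
* **lint** — non-fatal quality warnings (label-only terms, missing UUID
  identifiers, implausible category/rule pairings, conflicting statements,
  ...);
* **fixtures** — packaged worked examples and a seeded synthetic profile
  generator with planted-count bookkeeping.

## Worked example

```python
from duc import (ConditionParameter, Rule, TermRef,
                 make_statement, make_profile, render_profile)

profile = make_profile([
    make_statement(TermRef(label="General research use"), Rule.PERMITTED),
    make_statement(TermRef(label="Country"), Rule.PERMITTED,
                   parameters=[ConditionParameter(label="the United Kingdom")]),
    make_statement(TermRef(label="Time limit on use"), Rule.OBLIGATORY,
                   parameters=[ConditionParameter(label="months", value=12)]),
])
print(render_profile(profile, "narrative"))
```

prints

```
General research use is permitted for the whole of asset. The country of the United Kingdom is permitted for the whole of asset. The time limit on use is 12 months and is obligatory for the whole of asset.
```

— one sentence per independent statement: any research use is allowed, use
is tied to the United Kingdom, and a 12-month time limit is an obligation
that travels with any grant (`collect_obligations` returns exactly that
statement).  The same profile is available as
`worked_example("fig2")`, and `examples/` contains runnable scripts for
every capability (rendering, validation + linting, request evaluation,
tag-list conversion, corpus generation).

From the shell:

```bash
duc validate profile.json          # exit 0 iff structurally valid
duc render profile.json --style narrative
duc decide --profile p1.json --profile p2.json --request request.json
duc lint profile.json              # warnings, exit 0
duc convert --from duo-tags tags.txt
duc generate --n 100 --seed 1 --out corpus/
```

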