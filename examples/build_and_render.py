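"""Build a three-statement use-conditions profile and render it.

Each statement is the four-part unit term + rule + scope + parameters; the
renderer turns the profile into the natural-language paragraph a Data
Access Committee member would read.
"""

from duc import (
    ConditionParameter,
    Rule,
    TermRef,
    dump_profile,
    make_profile,
    make_statement,
    render_profile,
)

profile = make_profile(
    [
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
    ],
    auto_id=True,
    auto_dates=True,
)

print("# Narrative — one sentence per independent statement:")
print(render_profile(profile, "narrative"))
print()
print("# Canonical template form (the model's sentence skeleton):")
print(render_profile(profile, "template"))
print()
print("# Canonical JSON document (what `duc validate` checks):")
print(dump_profile(profile))
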