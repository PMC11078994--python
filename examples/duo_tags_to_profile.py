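"""Decompose a flat DUO-style tag list into a use-conditions profile.

Tag vocabularies bake directionality into their codes ("no general methods
use"); the profile model keeps concepts atomic and non-directional and puts
the directionality in each statement's rule.  The bundled registry supplies
each tag's atomic root and default rule.
"""

from duc import duo_tags_to_profile, render_profile

tags = ["DUO:0000042", "DUO:0000007", "DUO:0000025", "DUO:0000015"]
profile = duo_tags_to_profile(tags)

print(f"{len(tags)} tags -> {len(profile.statements)} independent statements\n")
for tag, stmt in zip(tags, profile.statements):
    print(f"  {tag:14s} -> {stmt.conditionTerm.label!r}: {stmt.rule.value}")
print()
print(render_profile(profile, "narrative"))
print()
print("Note the negated modifier DUO:0000015 ('no general methods use')")
print("became its atomic root 'General methods use' under rule Forbidden.")
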