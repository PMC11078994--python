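"""Validate a profile document and lint it for quality warnings.

Validation is structural and fatal (wrong enum values, missing statements);
linting encodes recommendations — a term without an ontology URI, a missing
permission mode, an implausible category/rule pairing — as warnings that
never fail a valid document.
"""

import json

from duc import dump_profile, lint_profile, validate_document, worked_example

profile = worked_example("fig2")
document = dump_profile(profile)

report = validate_document(document)
print(f"valid: {report.ok} ({len(report.violations)} violation(s))")

# corrupt one field: a rule outside the four printed values
doc = json.loads(document)
doc["statements"][0]["rule"] = "Allowed"
bad = validate_document(json.dumps(doc))
for v in bad.violations:
    print(f"after corruption -> {v.code} at {v.path}: {v.message}")

lint = lint_profile(profile)
print(f"\n{len(lint.warnings)} lint warning(s) on the valid profile:")
for w in lint.warnings:
    print(f"  {w.code} at {w.path}")
print("\nlabel-only-term flags free-text terms: without an ontology URI two")
print("custodians may spell the same concept differently and queries miss.")
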