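"""Evaluate an access request against alternative profiles.

One asset carries two profiles: use permitted in countries A-C with
profit-based research allowed, or in countries D-F with profit-based
research forbidden.  Aggregation across profiles is OR — any one profile
may grant — which is how mutually exclusive condition sets are expressed
without inter-statement logic.
"""

from duc import (
    ConditionParameter,
    PermissionMode,
    RequestItem,
    Rule,
    TermRef,
    UseRequest,
    evaluate_request,
    make_profile,
    make_statement,
)

region = TermRef(label="Use in a geographic region")
profit = TermRef(label="Use for profit purposes")

profile_1 = make_profile(
    [
        make_statement(
            region,
            Rule.PERMITTED,
            parameters=[ConditionParameter(label=c) for c in ("Country A", "Country B", "Country C")],
        ),
        make_statement(profit, Rule.PERMITTED),
    ],
    permissionMode=PermissionMode.UNSTATED_FORBIDDEN,
    profileName="Profile 1 (countries A-C, profit allowed)",
)
profile_2 = make_profile(
    [
        make_statement(
            region,
            Rule.PERMITTED,
            parameters=[ConditionParameter(label=c) for c in ("Country D", "Country E", "Country F")],
        ),
        make_statement(profit, Rule.FORBIDDEN),
    ],
    permissionMode=PermissionMode.UNSTATED_FORBIDDEN,
    profileName="Profile 2 (countries D-F, no profit)",
)

for country in ("Country A", "Country D"):
    request = UseRequest(
        items=(
            RequestItem(region, ConditionParameter(label=country)),
            RequestItem(profit),
        )
    )
    decision = evaluate_request([profile_1, profile_2], request)
    print(f"profit-based use in {country}: "
          f"{'GRANTED' if decision.granted else 'DENIED'}")
    for profile, d in zip((profile_1, profile_2), decision.perProfile):
        outcomes = ", ".join(v.outcome.value for v in d.verdicts)
        print(f"  {profile.profileName}: granted={d.granted} [{outcomes}]")
print()
print("A request is granted when at least one profile leaves no item")
print("Forbidden / forbidden-by-default / Unknown / in Conflict.")
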