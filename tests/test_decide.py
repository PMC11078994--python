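"""Decision engine: matching, defaults, precedence, conflicts, OR-aggregation."""

import itertools
import random

import pytest

from duc import (
    ConditionParameter,
    GeneratorConfig,
    Outcome,
    PermissionMode,
    RequestItem,
    Rule,
    Scope,
    TermRef,
    UseRequest,
    collect_obligations,
    detect_conflicts,
    evaluate_request,
    evaluate_term,
    generate_corpus,
    make_profile,
    make_statement,
    worked_example,
)
from duc.decide import CONTRADICTORY_PAIRS, GRANTING_OUTCOMES, RULE_PRECEDENCE

MODES = (PermissionMode.UNSTATED_FORBIDDEN, PermissionMode.UNSTATED_PERMITTED, None)


def oracle_outcome(matched_rules, mode):
    """Independent re-derivation of the per-term policy, written against the
    documented decision table rather than the engine's code path."""
    if not matched_rules:
        return {
            PermissionMode.UNSTATED_FORBIDDEN: Outcome.FORBIDDEN_BY_DEFAULT,
            PermissionMode.UNSTATED_PERMITTED: Outcome.PERMITTED_BY_DEFAULT,
            None: Outcome.UNKNOWN,
        }[mode]
    rules = set(matched_rules)
    contradictions = [
        {Rule.FORBIDDEN, Rule.PERMITTED},
        {Rule.FORBIDDEN, Rule.OBLIGATORY},
        {Rule.FORBIDDEN, Rule.NO_REQUIREMENT},
        {Rule.OBLIGATORY, Rule.NO_REQUIREMENT},
    ]
    if any(c <= rules for c in contradictions):
        return Outcome.CONFLICT
    for rule, outcome in [
        (Rule.FORBIDDEN, Outcome.FORBIDDEN),
        (Rule.OBLIGATORY, Outcome.OBLIGATORY),
        (Rule.PERMITTED, Outcome.PERMITTED),
        (Rule.NO_REQUIREMENT, Outcome.NO_REQUIREMENT),
    ]:
        if rule in rules:
            return outcome
    raise AssertionError


def truth_table_cases():
    """The exhaustive 120-case enumeration on a 3-term toy vocabulary:
    3 permission-mode states x (2 unmatched shapes + 4 rules x 2 scopes
    matched singly + 10 rule multisets x 3 scope combos matched doubly)."""
    query = TermRef(label="term under test")
    other = TermRef(label="an unrelated term")
    third = TermRef(label="a background term")
    cases = []
    for mode in MODES:
        # no statement matches; profile shape varies (1 or 2 unrelated stmts)
        for extra in (False, True):
            stmts = [make_statement(other, Rule.PERMITTED)]
            if extra:
                stmts.append(make_statement(third, Rule.OBLIGATORY))
            cases.append((stmts, query, mode, ()))
        # exactly one statement matches
        for rule in Rule:
            for scope in Scope:
                stmts = [
                    make_statement(query, rule, scope),
                    make_statement(other, Rule.FORBIDDEN),
                ]
                cases.append((stmts, query, mode, (rule,)))
        # exactly two statements match
        for r1, r2 in itertools.combinations_with_replacement(list(Rule), 2):
            for s1, s2 in [
                (Scope.WHOLE, Scope.WHOLE),
                (Scope.WHOLE, Scope.PART),
                (Scope.PART, Scope.PART),
            ]:
                stmts = [
                    make_statement(query, r1, s1),
                    make_statement(other, Rule.PERMITTED),
                    make_statement(query, r2, s2),
                ]
                cases.append((stmts, query, mode, (r1, r2)))
    return cases


class TestEvaluateTermOracle:
    def test_enumeration_size_is_120(self):
        assert len(truth_table_cases()) == 120

    def test_exhaustive_truth_table_agreement(self, registry):
        disagreements = []
        for stmts, query, mode, matched in truth_table_cases():
            profile = make_profile(stmts, permissionMode=mode)
            got = evaluate_term(profile, query, registry=registry)
            want = oracle_outcome(matched, mode)
            if got.outcome is not want:
                disagreements.append((matched, mode, got.outcome, want))
        assert disagreements == []

    def test_decisive_statements_empty_iff_default_or_unknown(self, registry):
        for stmts, query, mode, matched in truth_table_cases():
            profile = make_profile(stmts, permissionMode=mode)
            v = evaluate_term(profile, query, registry=registry)
            is_default = v.outcome in {
                Outcome.PERMITTED_BY_DEFAULT,
                Outcome.FORBIDDEN_BY_DEFAULT,
                Outcome.UNKNOWN,
            }
            assert is_default == (v.decisiveStatements == ())
            if v.outcome is Outcome.CONFLICT:
                assert len(v.decisiveStatements) >= 2


class TestEvaluateTermSemantics:
    def test_fig2_general_research_use_permitted(self, fig2_profile, registry):
        v = evaluate_term(
            fig2_profile, TermRef(label="General research use"), registry=registry
        )
        assert v.outcome is Outcome.PERMITTED and v.partial is False

    def test_unstated_term_forbidden_by_default(self, registry):
        profile = make_profile(
            [make_statement(TermRef(label="X"), Rule.PERMITTED)],
            permissionMode=PermissionMode.UNSTATED_FORBIDDEN,
        )
        v = evaluate_term(profile, TermRef(label="Y"), registry=registry)
        assert v.outcome is Outcome.FORBIDDEN_BY_DEFAULT

    def test_absent_mode_yields_unknown_never_a_default(self, registry):
        profile = make_profile([make_statement(TermRef(label="X"), Rule.PERMITTED)])
        v = evaluate_term(profile, TermRef(label="Y"), registry=registry)
        assert v.outcome is Outcome.UNKNOWN

    def test_unparameterized_statement_covers_any_parameter(self, registry):
        profile = make_profile(
            [make_statement(TermRef(label="Country"), Rule.PERMITTED)]
        )
        v = evaluate_term(
            profile,
            TermRef(label="Country"),
            ConditionParameter(label="France"),
            registry,
        )
        assert v.outcome is Outcome.PERMITTED

    def test_parameterized_statement_needs_equal_parameter(self, registry):
        profile = make_profile(
            [
                make_statement(
                    TermRef(label="Country"),
                    Rule.PERMITTED,
                    parameters=[ConditionParameter(label="the United Kingdom")],
                )
            ],
            permissionMode=PermissionMode.UNSTATED_FORBIDDEN,
        )
        hit = evaluate_term(
            profile,
            TermRef(label="Country"),
            ConditionParameter(label="The  UNITED kingdom"),
            registry,
        )
        miss = evaluate_term(
            profile,
            TermRef(label="Country"),
            ConditionParameter(label="France"),
            registry,
        )
        assert hit.outcome is Outcome.PERMITTED
        assert miss.outcome is Outcome.FORBIDDEN_BY_DEFAULT

    def test_partial_flag_tracks_part_of_asset_scope(self, registry):
        profile = make_profile(
            [make_statement(TermRef(label="X"), Rule.PERMITTED, Scope.PART)]
        )
        assert evaluate_term(profile, TermRef(label="X"), registry=registry).partial

    def test_statement_order_never_changes_outcome(self, registry):
        rng = random.Random(7)
        for g in generate_corpus(GeneratorConfig(n_profiles=25, seed=5)):
            profile = g.profile
            query = rng.choice(profile.statements).conditionTerm
            base = evaluate_term(profile, query, registry=registry)
            shuffled = list(profile.statements)
            rng.shuffle(shuffled)
            permuted = make_profile(shuffled, permissionMode=profile.permissionMode)
            again = evaluate_term(permuted, query, registry=registry)
            assert again.outcome is base.outcome
            assert again.partial == base.partial

    def test_locality_unrelated_statement_never_changes_verdict(self, registry):
        for stmts, query, mode, _ in truth_table_cases()[:40]:
            profile = make_profile(stmts, permissionMode=mode)
            grown = make_profile(
                list(stmts)
                + [make_statement(TermRef(label="something else entirely"), Rule.FORBIDDEN)],
                permissionMode=mode,
            )
            assert (
                evaluate_term(profile, query, registry=registry).outcome
                is evaluate_term(grown, query, registry=registry).outcome
            )


def country_profiles():
    """Two alternative condition sets for one asset: use permitted in
    countries A-C with profit-based research allowed, or in countries D-F
    with profit-based research not allowed."""
    region = TermRef(label="Use in a geographic region")
    profit = TermRef(label="Use for profit purposes")
    p1 = make_profile(
        [
            make_statement(
                region,
                Rule.PERMITTED,
                parameters=[
                    ConditionParameter(label=c) for c in ("Country A", "Country B", "Country C")
                ],
            ),
            make_statement(profit, Rule.PERMITTED),
        ],
        profileId="urn:example:profile-1",
        permissionMode=PermissionMode.UNSTATED_FORBIDDEN,
    )
    p2 = make_profile(
        [
            make_statement(
                region,
                Rule.PERMITTED,
                parameters=[
                    ConditionParameter(label=c) for c in ("Country D", "Country E", "Country F")
                ],
            ),
            make_statement(profit, Rule.FORBIDDEN),
        ],
        profileId="urn:example:profile-2",
        permissionMode=PermissionMode.UNSTATED_FORBIDDEN,
    )
    return p1, p2


class TestEvaluateRequest:
    def request(self, country):
        return UseRequest(
            items=(
                RequestItem(
                    TermRef(label="Use in a geographic region"),
                    ConditionParameter(label=country),
                ),
                RequestItem(TermRef(label="Use for profit purposes")),
            )
        )

    def test_multi_profile_or_semantics(self, registry):
        p1, p2 = country_profiles()
        granted = evaluate_request([p1, p2], self.request("Country A"), registry)
        assert granted.granted
        assert [d.granted for d in granted.perProfile] == [True, False]
        denied = evaluate_request([p1, p2], self.request("Country D"), registry)
        assert not denied.granted
        assert [d.granted for d in denied.perProfile] == [False, False]

    def test_grant_carries_obligations(self, fig2_profile, registry):
        request = UseRequest(
            items=(RequestItem(TermRef(label="General research use")),)
        )
        # the fixture has no permissionMode: make the grant decidable
        profile = make_profile(
            fig2_profile.statements,
            permissionMode=PermissionMode.UNSTATED_PERMITTED,
        )
        decision = evaluate_request([profile], request, registry)
        assert decision.granted
        obligations = decision.perProfile[0].obligations
        assert [s.conditionTerm.label for s in obligations] == ["Time limit on use"]

    def test_unknown_blocks_and_is_surfaced(self, fig2_profile, registry):
        request = UseRequest(items=(RequestItem(TermRef(label="cloning")),))
        decision = evaluate_request([fig2_profile], request, registry)
        assert not decision.granted
        assert "Unknown" in decision.perProfile[0].note

    def test_permissive_mode_limit_case(self, registry):
        """All-permitted mode with no Forbidden statements grants everything."""
        cfg = GeneratorConfig(n_profiles=40, seed=6, p_forbidden=0.0)
        request = UseRequest(
            items=(RequestItem(TermRef(label="an arbitrary request term")),)
        )
        for g in generate_corpus(cfg):
            profile = make_profile(
                g.profile.statements,
                permissionMode=PermissionMode.UNSTATED_PERMITTED,
            )
            if detect_conflicts(profile, registry):
                continue
            assert evaluate_request([profile], request, registry).granted

    def test_aggregate_is_or_of_per_profile(self, registry):
        """Definitional property over generated (profiles, request) pairs."""
        rng = random.Random(2)
        profiles = [
            make_profile(
                g.profile.statements,
                permissionMode=rng.choice(MODES),
            )
            for g in generate_corpus(GeneratorConfig(n_profiles=60, seed=2))
        ]
        vocab_terms = [
            s.conditionTerm for p in profiles for s in p.statements
        ]
        checked = 0
        for _ in range(500):
            chosen = rng.sample(profiles, k=rng.randint(1, 3))
            request = UseRequest(
                items=tuple(
                    RequestItem(rng.choice(vocab_terms))
                    for _ in range(rng.randint(1, 3))
                )
            )
            decision = evaluate_request(chosen, request, registry)
            assert decision.granted == any(
                d.granted for d in decision.perProfile
            )
            for d in decision.perProfile:
                assert d.granted == all(
                    v.outcome in GRANTING_OUTCOMES for v in d.verdicts
                )
            checked += 1
        assert checked == 500


class TestCollectObligations:
    def test_fig2_single_time_limit_obligation(self, fig2_profile):
        obligations = collect_obligations(fig2_profile)
        assert [s.conditionTerm.label for s in obligations] == ["Time limit on use"]

    def test_no_obligations(self):
        p = make_profile([make_statement(TermRef(label="x"), Rule.PERMITTED)])
        assert collect_obligations(p) == []

    def test_count_matches_generator_bookkeeping(self):
        for seed in (1, 2, 3):
            for g in generate_corpus(GeneratorConfig(n_profiles=40, seed=seed)):
                assert len(collect_obligations(g.profile)) == g.n_obligatory


class TestDetectConflicts:
    def test_direct_contradiction(self, registry):
        p = make_profile(
            [
                make_statement(TermRef(label="X"), Rule.PERMITTED),
                make_statement(TermRef(label="X"), Rule.FORBIDDEN),
            ]
        )
        [(pair, reason)] = detect_conflicts(p, registry)
        assert pair == (0, 1) and "Forbidden" in reason

    def test_disjoint_parameters_do_not_conflict(self, registry):
        p = make_profile(
            [
                make_statement(
                    TermRef(label="Use in a geographic region"),
                    Rule.PERMITTED,
                    parameters=[ConditionParameter(label="the United Kingdom")],
                ),
                make_statement(
                    TermRef(label="Use in a geographic region"),
                    Rule.FORBIDDEN,
                    parameters=[ConditionParameter(label="France")],
                ),
            ]
        )
        assert detect_conflicts(p, registry) == []

    def test_agrees_with_bruteforce_pairwise_oracle(self, registry):
        from duc.decide import parameters_equal
        from duc.vocab import terms_match

        def oracle(profile):
            found = []
            n = len(profile.statements)
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = profile.statements[i], profile.statements[j]
                    if {a.rule, b.rule} not in [set(p) for p in CONTRADICTORY_PAIRS]:
                        continue
                    if not terms_match(a.conditionTerm, b.conditionTerm, registry):
                        continue
                    pa, pb = a.conditionParameters, b.conditionParameters
                    if pa and pb:
                        if not any(
                            parameters_equal(x, y, registry) for x in pa for y in pb
                        ):
                            continue
                    elif pa or pb:
                        continue
                    found.append((i, j))
            return found

        cfg = GeneratorConfig(
            n_profiles=60, seed=3, p_forbidden=0.4, statements_max=8
        )
        for g in generate_corpus(cfg):
            got = [pair for pair, _ in detect_conflicts(g.profile, registry)]
            assert got == oracle(g.profile)


def test_precedence_constants_are_consistent():
    assert set(RULE_PRECEDENCE) == set(Rule)
    for pair in CONTRADICTORY_PAIRS:
        assert len(pair) == 2
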