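"""Scoring engine: matching, weighting, the cascade, and its invariants."""

import dataclasses

import pytest

from conftest import BREAST, LUNG, PAN, alt, build_kb, mta, oracle_score, profile, rule, target

from dda.kb import TumorContext
from dda.scoring import (
    DriverScore,
    MatchLevel,
    TargetScore,
    Tier,
    TierThresholds,
    WeightConfig,
    alteration_match_level,
    classify_tier,
    driver_ael,
    driver_mta_association,
    mta_ael,
    rule_weight,
    score_profile,
    select_potential_drivers,
    target_ael,
)
from dda.synthetic import KBGenParams, generate_kb, generate_profiles

CFG = WeightConfig()


class TestAlterationMatch:
    @pytest.mark.parametrize(
        "observed, subject, expected",
        [
            (alt("KRAS", "snv", "G12V"), alt("KRAS", "snv", "G12V"), MatchLevel.EXACT_VARIANT),
            (alt("KRAS", "snv", "A146T"), alt("KRAS", "snv", "G12D"),
             MatchLevel.DIFFERENT_VARIANT_SAME_GENE),
            (alt("PTEN", "cnv_loss"), alt("BRAF", "snv", "V600E"), MatchLevel.NONE),
            (alt("KRAS", "snv", "G12V"), alt("KRAS", "snv"), MatchLevel.SAME_CLASS),
            (alt("KRAS", "cnv_amplification"), alt("KRAS", "snv"), MatchLevel.GENE_ONLY),
            (alt("KRAS", "snv"), alt("KRAS", "snv", "G12V"), MatchLevel.GENE_ONLY),
            (alt("KRAS", "indel", "G12del"), alt("KRAS", "snv", "G12V"),
             MatchLevel.DIFFERENT_VARIANT_SAME_GENE),
        ],
    )
    def test_match_levels(self, observed, subject, expected):
        assert alteration_match_level(observed, subject) is expected


class TestRuleWeight:
    @pytest.mark.parametrize(
        "evidence_class, source, context, subject, observed, direction, expected",
        [
            # clinical, all factors unity
            ("clinical", 1.0, BREAST, alt("KRAS", "snv", "G12V"),
             alt("KRAS", "snv", "G12V"), "positive", 10.0),
            # preclinical x pan-cancer x gene-only, negative
            ("preclinical", 1.0, PAN, alt("KRAS", "snv", "G12V"),
             alt("KRAS", "cnv_amplification"), "negative", -5 * 0.75 * 0.5),
            # clinical x top source x other tumor x different variant
            ("clinical", 2.0, LUNG, alt("KRAS", "snv", "G12D"),
             alt("KRAS", "snv", "A146T"), "positive", 10 * 2 * 0.5 * 0.25),
        ],
    )
    def test_weight_products(self, evidence_class, source, context, subject, observed,
                             direction, expected):
        r = rule("driver_function", subject, evidence_class=evidence_class,
                 source_weight=source, context=context, direction=direction)
        assert rule_weight(r, observed, BREAST, CFG) == pytest.approx(expected, abs=1e-12)

    def test_non_matching_gene_refused(self):
        r = rule("driver_function", alt("BRAF", "snv", "V600E"))
        with pytest.raises(ValueError, match="filter"):
            rule_weight(r, alt("KRAS", "snv", "G12V"), BREAST, CFG)

    def test_histology_mismatch_is_other_tumor(self):
        r = rule("driver_function", alt("KRAS", "snv"),
                 context=TumorContext("lung", "adenocarcinoma"))
        w = rule_weight(r, alt("KRAS", "snv"), TumorContext("lung", "squamous"), CFG)
        assert w == pytest.approx(10 * 0.5 * 0.75)


class TestDriverCalculation:
    def test_two_positive_function_rules_sum(self):
        rules = [rule("driver_function", alt("KRAS", "snv", "G12V")) for _ in range(2)]
        kb = build_kb(rules)
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        score = driver_ael("KRAS", p, kb, CFG)
        assert score.ael == pytest.approx(20.0)
        assert score.ael == sum(c for _, c in score.contributions)

    def test_resistance_evidence_still_counts_positively(self):
        # a negative drug association is still evidence of driverhood
        m = mta("cetuximab", {target("EGFR")})
        r = rule("driver_mta", alt("KRAS", "snv", "G12V"), object_mta="cetuximab",
                 direction="negative")
        kb = build_kb([r], [m])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        assert driver_ael("KRAS", p, kb, CFG).ael == pytest.approx(+10.0)

    def test_no_matching_rules_gives_zero(self):
        kb = build_kb([rule("driver_function", alt("BRAF", "snv", "V600E"))])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V"), alt("BRAF", "snv", "V600E")])
        assert driver_ael("KRAS", p, kb, CFG).ael == 0.0

    def test_gene_absent_from_profile_errors(self):
        kb = build_kb([rule("driver_function", alt("KRAS", "snv"))])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        with pytest.raises(ValueError, match="TP53"):
            driver_ael("TP53", p, kb, CFG)

    def test_negative_function_evidence_deducts(self):
        rules = [
            rule("driver_function", alt("KRAS", "snv")),
            rule("driver_function", alt("KRAS", "snv"), direction="negative",
                 source_weight=2.0),
        ]
        kb = build_kb(rules)
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        # +10*0.75 (same class) - 20*0.75 = -7.5
        assert driver_ael("KRAS", p, kb, CFG).ael == pytest.approx(-7.5)

    def test_best_match_used_once_per_rule(self):
        # two observed KRAS alterations; the rule matches both at different
        # levels but contributes only once, at the better level
        r = rule("driver_function", alt("KRAS", "snv", "G12V"))
        kb = build_kb([r])
        p = profile("p1", BREAST,
                    [alt("KRAS", "snv", "G12V"), alt("KRAS", "cnv_amplification")])
        score = driver_ael("KRAS", p, kb, CFG)
        assert len(score.contributions) == 1
        assert score.ael == pytest.approx(10.0)


class TestPotentialDrivers:
    def test_strictly_positive_threshold(self):
        rules = [
            rule("driver_function", alt("AAA", "snv")),                       # +7.5
            rule("driver_function", alt("CCC", "snv"), direction="negative"),  # -7.5
        ]
        kb = build_kb(rules)
        kb.genes.add("BBB")
        p = profile("p1", BREAST,
                    [alt("AAA", "snv", "X1Y"), alt("BBB", "snv", "X2Y"), alt("CCC", "snv", "X3Y")])
        drivers = select_potential_drivers(p, kb, CFG)
        assert [d.gene for d in drivers] == ["AAA"]

    def test_no_matches_gives_empty(self):
        kb = build_kb([rule("driver_function", alt("ZZZ", "snv"))])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        assert select_potential_drivers(p, kb, CFG) == []

    def test_synthetic_all_positive_profile(self):
        kb = generate_kb(KBGenParams(seed=11, p_negative=0.0))
        p = generate_profiles(kb, 1, alterations_per_patient_mean=5.0, seed=4)[0]
        drivers = select_potential_drivers(p, kb, CFG)
        # every mutated gene with any matching rule scores positive
        genes_with_rules = {
            r.subject.gene for r in kb.rules
        } & set(p.mutant_genes())
        assert {d.gene for d in drivers} == genes_with_rules


class TestTargetCalculation:
    def _driver(self, gene="KRAS", ael=10.0):
        return DriverScore(gene, ael, [("x", ael)])

    def test_single_positive_rule(self):
        t = target("EGFR")
        r = rule("driver_target", alt("KRAS", "snv", "G12V"), object_target=t)
        kb = build_kb([r])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        assert target_ael(t, [self._driver()], p, kb, CFG).ael == pytest.approx(10.0)

    def test_signed_sum_across_drivers(self):
        t = target("EGFR")
        rules = [
            rule("driver_target", alt("KRAS", "snv", "G12V"), object_target=t),
            rule("driver_target", alt("TP53", "snv", "R175H"), object_target=t,
                 direction="negative", source_weight=1.25),
        ]
        kb = build_kb(rules)
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V"), alt("TP53", "snv", "R175H")])
        drivers = [self._driver("KRAS"), self._driver("TP53")]
        score = target_ael(t, drivers, p, kb, CFG)
        assert score.ael == pytest.approx(10.0 - 12.5)
        assert score.ael == sum(c for _, _, c in score.contributions)

    def test_no_rules_gives_zero(self):
        t = target("EGFR")
        kb = build_kb([], extra_targets=[t])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        assert target_ael(t, [self._driver()], p, kb, CFG).ael == 0.0

    def test_non_driver_rules_ignored(self):
        t = target("EGFR")
        r = rule("driver_target", alt("TP53", "snv"), object_target=t)
        kb = build_kb([r])
        p = profile("p1", BREAST, [alt("TP53", "snv", "R175H")])
        # TP53 is not among the potential drivers passed in
        assert target_ael(t, [self._driver("KRAS")], p, kb, CFG).ael == 0.0


class TestMTACalculation:
    def test_direct_association_sums(self):
        m = mta("drugx", {target("EGFR")})
        r = rule("driver_mta", alt("KRAS", "snv", "G12V"), object_mta="drugx")
        kb = build_kb([r], [m])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        d = DriverScore("KRAS", 20.0, [])
        assert driver_mta_association(d, kb.mta("drugx"), p, kb, CFG) == pytest.approx(10.0)

    def test_exact_cancellation_inherits_nothing(self):
        m = mta("drugx", {target("EGFR")})
        rules = [
            rule("driver_mta", alt("KRAS", "snv", "G12V"), object_mta="drugx"),
            rule("driver_mta", alt("KRAS", "snv", "G12V"), object_mta="drugx",
                 direction="negative"),
        ]
        kb = build_kb(rules, [m])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        d = DriverScore("KRAS", 20.0, [])
        assert driver_mta_association(d, kb.mta("drugx"), p, kb, CFG) == 0.0
        score = mta_ael(kb.mta("drugx"), [d], {}, p, kb, CFG)
        # S = 0: no direct term, and sign(0)=0 blocks driver-AEL inheritance
        assert score.ael == 0.0
        assert score.inherited_driver_component == 0.0

    def test_decomposed_sum(self):
        # one driver (AEL 20), S(d,m)=+10, targets contribute +5 -> 35
        t = target("EGFR")
        m = mta("drugx", {t})
        r = rule("driver_mta", alt("KRAS", "snv", "G12V"), object_mta="drugx")
        kb = build_kb([r], [m])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        d = DriverScore("KRAS", 20.0, [])
        targets = {t: TargetScore(t, 5.0, [])}
        score = mta_ael(kb.mta("drugx"), [d], targets, p, kb, CFG)
        assert score.ael == pytest.approx(35.0)
        assert score.direct_component == pytest.approx(10.0)
        assert score.inherited_driver_component == pytest.approx(20.0)
        assert score.inherited_target_component == pytest.approx(5.0)
        assert score.ael == (
            score.direct_component
            + score.inherited_driver_component
            + score.inherited_target_component
        )

    def test_inhibitor_of_negatively_scored_target_goes_negative(self):
        # anti-EGFR pattern: the agent's only link to a KRAS-mutant profile
        # is a target whose AEL is negative
        t = target("EGFR")
        m = mta("panitumumab-like", {t})
        rules = [
            rule("driver_function", alt("KRAS", "snv", "G12V")),
            rule("driver_target", alt("KRAS", "snv", "G12V"), object_target=t,
                 direction="negative", source_weight=1.5),
        ]
        kb = build_kb(rules, [m])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        res = score_profile(p, kb, CFG)
        assert res.mta_score("panitumumab-like").ael < 0


class TestScoreProfile:
    def test_no_matches_all_zero(self):
        m = mta("drugx", {target("EGFR")})
        kb = build_kb([rule("driver_function", alt("ZZZ", "snv"))], [m])
        p = profile("p1", BREAST, [alt("KRAS", "snv", "G12V")])
        res = score_profile(p, kb, CFG, all_mtas=True)
        assert res.drivers == []
        assert all(t.ael == 0.0 for t in res.targets)
        assert [m_.ael for m_ in res.mtas] == [0.0]
        assert score_profile(p, kb, CFG).mtas == []  # filtered by default

    def test_opposite_sign_target_links_rank(self):
        t_pos, t_neg = target("MTOR"), target("EGFR")
        m_pos, m_neg = mta("goodrug", {t_pos}), mta("badrug", {t_neg})
        rules = [
            rule("driver_function", alt("PIK3CA", "snv", "E545K")),
            rule("driver_function", alt("KRAS", "snv", "A146T")),
            rule("driver_function", alt("PTEN", "cnv_loss")),
            rule("driver_function", alt("ESR1", "expression_over")),
            rule("driver_function", alt("PGR", "expression_over")),
            rule("driver_target", alt("PIK3CA", "snv", "E545K"), object_target=t_pos),
            rule("driver_target", alt("KRAS", "snv", "A146T"), object_target=t_neg,
                 direction="negative"),
        ]
        kb = build_kb(rules, [m_pos, m_neg])
        p = profile("example5-like", BREAST, [
            alt("PIK3CA", "snv", "E545K"), alt("KRAS", "snv", "A146T"),
            alt("PTEN", "cnv_loss"), alt("ESR1", "expression_over"),
            alt("PGR", "expression_over"),
        ])
        res = score_profile(p, kb, CFG)
        names = [m_.mta for m_ in res.mtas]
        assert names.index("goodrug") < names.index("badrug")
        assert res.mta_score("goodrug").ael > 0 > res.mta_score("badrug").ael

    def test_deterministic(self):
        kb = generate_kb(KBGenParams(seed=5))
        p = generate_profiles(kb, 1, seed=6)[0]
        a = score_profile(p, kb, CFG).to_json()
        b = score_profile(p, kb, CFG).to_json()
        assert a == b


class TestTierClassification:
    @pytest.mark.parametrize(
        "ael, tier",
        [
            (-1291.37, Tier.LOW),
            (191.61, Tier.INTERMEDIATE),
            (266.93, Tier.INTERMEDIATE),
            (315.04, Tier.INTERMEDIATE),
            (4165.0, Tier.HIGH),
            (4604.32, Tier.HIGH),
            (-1487.93, Tier.LOW),
            (0.0, Tier.INTERMEDIATE),
            (1000.0, Tier.INTERMEDIATE),
            (-1e-9, Tier.LOW),
            (1000.0000001, Tier.HIGH),
        ],
    )
    def test_boundaries_and_printed_values(self, ael, tier):
        assert classify_tier(ael, TierThresholds()) is tier

    def test_custom_thresholds(self):
        th = TierThresholds(low_upper=100.0, high_lower=500.0)
        assert classify_tier(99.9, th) is Tier.LOW
        assert classify_tier(300.0, th) is Tier.INTERMEDIATE
        assert classify_tier(500.1, th) is Tier.HIGH


# ---------------------------------------------------------------------------
# invariants on random instances


def _random_instance(seed):
    kb = generate_kb(
        KBGenParams(seed=seed, n_genes=6, n_targets=8, n_mtas=8,
                    rules_per_gene=2, rules_per_target=2, rules_per_mta=2)
    )
    assert len(kb.rules) <= 50
    p = generate_profiles(kb, 1, alterations_per_patient_mean=4.0, seed=seed + 1000)[0]
    return kb, p


@pytest.mark.parametrize("seed", range(8))
class TestEngineInvariants:
    def test_oracle_equivalence(self, seed):
        kb, p = _random_instance(seed)
        driver, potential, target_s, mta_s = oracle_score(p, kb, CFG)
        res = score_profile(p, kb, CFG, all_mtas=True)
        assert {d.gene for d in res.drivers} == set(potential)
        for d in res.drivers:
            assert d.ael == pytest.approx(potential[d.gene], abs=1e-9)
        for t in res.targets:
            assert t.ael == pytest.approx(target_s.get(t.node, 0.0), abs=1e-9)
        for m in res.mtas:
            assert m.ael == pytest.approx(mta_s[m.mta], abs=1e-9)

    def test_decompositions_sum_exactly(self, seed):
        kb, p = _random_instance(seed)
        res = score_profile(p, kb, CFG, all_mtas=True)
        for d in res.drivers:
            assert d.ael == sum(c for _, c in d.contributions)
        for t in res.targets:
            assert t.ael == sum(c for _, _, c in t.contributions)
        for m in res.mtas:
            assert m.ael == (
                m.direct_component
                + m.inherited_driver_component
                + m.inherited_target_component
            )

    def test_linearity_under_rule_duplication(self, seed):
        kb, p = _random_instance(seed)
        base = score_profile(p, kb, CFG, all_mtas=True)
        # duplicate one rule that actually fired for a potential driver
        fired = {rid for d in base.drivers for rid, _ in d.contributions}
        if not fired:
            pytest.skip("no driver evidence fired on this instance")
        rid = sorted(fired)[0]
        orig = next(r for r in kb.rules if r.rule_id == rid)
        dup = dataclasses.replace(orig, rule_id="DUP00001")
        kb.rules.append(dup)
        doubled = score_profile(p, kb, CFG, all_mtas=True)
        for d in doubled.drivers:
            contribs = dict(d.contributions)
            if rid in contribs:
                assert contribs["DUP00001"] == contribs[rid]
        kb.rules.remove(dup)
        assert score_profile(p, kb, CFG, all_mtas=True).to_json() == base.to_json()

    def test_gating_non_drivers_contribute_nothing(self, seed):
        # resistance-heavy KB so that some mutated genes score <= 0
        kb = generate_kb(
            KBGenParams(seed=seed, n_genes=6, n_targets=8, n_mtas=8,
                        rules_per_gene=4, rules_per_target=2, rules_per_mta=2,
                        p_negative=0.75)
        )
        p = generate_profiles(kb, 1, alterations_per_patient_mean=4.0, seed=seed + 1000)[0]
        res = score_profile(p, kb, CFG, all_mtas=True)
        driver_genes = {d.gene for d in res.drivers}
        if driver_genes == set(p.mutant_genes()):
            pytest.skip("every mutated gene is a potential driver here")
        kept = [a for a in p.alterations if a.gene in driver_genes]
        if not kept:
            pytest.skip("no potential drivers at all")
        ablated = dataclasses.replace(p, alterations=tuple(kept))
        res2 = score_profile(ablated, kb, CFG, all_mtas=True)
        assert {t.node: t.ael for t in res.targets} == {t.node: t.ael for t in res2.targets}
        assert {m.mta: m.ael for m in res.mtas} == {m.mta: m.ael for m in res2.mtas}

    def test_scale_covariance(self, seed):
        kb, p = _random_instance(seed)
        c = 3.0
        base = score_profile(p, kb, CFG, all_mtas=True)
        scaled = score_profile(p, kb, CFG.scaled(c), all_mtas=True)
        assert {d.gene for d in scaled.drivers} == {d.gene for d in base.drivers}
        for a, b in zip(base.mtas, scaled.mtas):
            assert b.ael == pytest.approx(c * a.ael, rel=1e-12, abs=1e-12)

    def test_monotonicity_of_positive_evidence(self, seed):
        kb, p = _random_instance(seed)
        res = score_profile(p, kb, CFG, all_mtas=True)
        if not res.drivers:
            pytest.skip("no potential drivers")
        d = res.drivers[0]
        obs = p.alterations_of(d.gene)[0]
        # driver->MTA clause: requires S(d,m) >= 0
        m_name = next(
            (m.mta for m in res.mtas if m.per_driver_S.get(d.gene, 0.0) >= 0), None
        )
        if m_name is not None:
            before = res.mta_score(m_name).ael
            kb.rules.append(rule("driver_mta", obs, object_mta=m_name, rule_id="MONO1"))
            after = score_profile(p, kb, CFG, all_mtas=True).mta_score(m_name).ael
            assert after > before
            kb.rules.pop()
        # driver->target clause, likewise with non-negative net association
        m2 = next(
            (m for m in res.mtas if m.per_driver_S.get(d.gene, 0.0) >= 0), None
        )
        if m2 is not None:
            tgt = sorted(kb.mta(m2.mta).targets)[0]
            before = res.mta_score(m2.mta).ael
            kb.rules.append(
                rule("driver_target", obs, object_target=tgt, rule_id="MONO2")
            )
            after = score_profile(p, kb, CFG, all_mtas=True).mta_score(m2.mta).ael
            assert after > before
            kb.rules.pop()
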