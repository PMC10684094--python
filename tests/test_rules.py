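"""Knowledge initialization, rule extraction/ensembling and rendering."""

import numpy as np
import pytest

from tgfnn.network import Feature, FeatureSchema, StandardizationStats
from tgfnn.rules import (
    Rule,
    RuleSet,
    RuleTerm,
    ensemble_rules,
    extract_rules,
    init_from_rules,
    render_rules,
)


@pytest.fixture
def clinical_schema():
    return FeatureSchema(
        [
            Feature("lvef", "continuous"),
            Feature("sbp", "continuous"),
            Feature("sodium", "continuous"),
            Feature("bnp_delta_pct", "continuous"),
            Feature("mitral_regurg", "continuous"),
            Feature("diabetes", "categorical", n_levels=2, levels=("absent", "present")),
        ]
    )


@pytest.fixture
def four_expert_rules():
    pos = [0.0, 1.0]
    return RuleSet(
        [
            Rule([RuleTerm("lvef", "low"), RuleTerm("sbp", "low")], list(pos)),
            Rule([RuleTerm("lvef", "low"), RuleTerm("mitral_regurg", "high")], list(pos)),
            Rule([RuleTerm("lvef", "low"), RuleTerm("bnp_delta_pct", "high")], list(pos)),
            Rule([RuleTerm("lvef", "low"), RuleTerm("sodium", "low")], list(pos)),
        ]
    )


class TestRuleTypes:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Rule([])  # needs a term
        with pytest.raises(ValueError):
            Rule([RuleTerm("a", "low"), RuleTerm("a", "high")])  # duplicate feature
        with pytest.raises(ValueError):
            RuleTerm("a", "low", importance=1.5)

    def test_json_roundtrip(self, four_expert_rules, tmp_path):
        path = tmp_path / "rules.json"
        four_expert_rules.to_json(path)
        loaded = RuleSet.from_json(path)
        assert len(loaded) == 4
        assert loaded.rules[0].terms == four_expert_rules.rules[0].terms
        assert loaded.rules[0].class_weights == [0.0, 1.0]


class TestInitFromRules:
    def test_structured_columns_argmax_on_specified_slots(
        self, clinical_schema, four_expert_rules
    ):
        params = init_from_rules(four_expert_rules, clinical_schema, K=10, seed=0)
        A, M = params.attention, params.connection
        for k, rule in enumerate(four_expert_rules):
            for t in rule.terms:
                i = clinical_schema.index(t.feature)
                d = clinical_schema.concept_index(t.feature, t.concept)
                assert np.unravel_index(np.argmax(A[:, :, k]), A[:, :, k].shape) in [
                    (clinical_schema.index(tt.feature),
                     clinical_schema.concept_index(tt.feature, tt.concept))
                    for tt in rule.terms
                ]
                assert A[i, d, k] == pytest.approx(0.9, abs=1e-9)
                assert M[i, k] == pytest.approx(0.9, abs=1e-9)
            assert params.inference[k, 1] > params.inference[k, 0]

    def test_single_rule_single_term_concentration(self):
        schema = FeatureSchema([Feature("x"), Feature("y")])
        rs = RuleSet([Rule([RuleTerm("x", "high")])])
        params = init_from_rules(rs, schema, K=1, seed=0)
        A = params.attention[:, :, 0]
        assert np.unravel_index(np.argmax(A), A.shape) == (0, 2)

    def test_empty_ruleset_matches_default_fit_init(self, clinical_schema):
        a = init_from_rules(RuleSet([]), clinical_schema, K=5, seed=3)
        b = init_from_rules(RuleSet([]), clinical_schema, K=5, seed=3)
        assert np.array_equal(a.attention_raw, b.attention_raw)
        assert np.array_equal(a.cutoff_raw, b.cutoff_raw)

    def test_errors(self, clinical_schema, four_expert_rules):
        with pytest.raises(ValueError):
            init_from_rules(four_expert_rules, clinical_schema, K=2, seed=0)
        bad = RuleSet([Rule([RuleTerm("unknown_feature", "low")])])
        with pytest.raises(KeyError, match="unknown_feature"):
            init_from_rules(bad, clinical_schema, K=2, seed=0)
        bad2 = RuleSet([Rule([RuleTerm("diabetes", "low")])])
        with pytest.raises(KeyError, match="diabetes"):
            init_from_rules(bad2, clinical_schema, K=2, seed=0)

    def test_cutoffs_at_data_quantiles(self, clinical_schema):
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 3.0, size=(500, 6))
        params = init_from_rules(RuleSet([]), clinical_schema, K=3, seed=0, data=X)
        expected = np.quantile(X[:, 0], [0.2, 0.4, 0.6, 0.8])
        assert np.allclose(params.cutoffs[0], expected, atol=1e-6)


class TestExtractRules:
    def _handbuilt(self, clinical_schema, strong=0.95, weak=0.01):
        """Two rule columns: rule 0 fires strongly, rule 1 barely."""
        rs = RuleSet(
            [
                Rule([RuleTerm("lvef", "low"), RuleTerm("sbp", "low")]),
                Rule([RuleTerm("sodium", "high")]),
            ]
        )
        params = init_from_rules(rs, clinical_schema, K=2, seed=0)
        # rows on the low plateau of lvef/sbp and low sodium: rule 0 fires
        X = np.full((20, 6), 0.0)
        X[:, [0, 1, 2]] = -3.0
        X[:, 5] = 0.0
        params.smoothness.eps = 0.05
        return params, X

    def test_strength_filter_forced_by_construction(self, clinical_schema):
        params, X = self._handbuilt(clinical_schema)
        rs = extract_rules(params, X, strength_threshold=0.1,
                           importance_threshold=0.2)
        origins = [r.origin for r in rs]
        assert 0 in origins and 1 not in origins

    def test_identical_columns_collapse(self, clinical_schema):
        rule = Rule([RuleTerm("lvef", "low"), RuleTerm("sbp", "low")])
        rs_in = RuleSet([rule, Rule(list(rule.terms))])
        params = init_from_rules(rs_in, clinical_schema, K=2, seed=0)
        params.smoothness.eps = 0.05
        X = np.full((10, 6), -3.0)
        X[:, 5] = 0.0
        out = extract_rules(params, X, strength_threshold=0.05, corr_threshold=0.9)
        assert len(out) == 1

    def test_all_filtered_warns_not_raises(self, clinical_schema):
        params, X = self._handbuilt(clinical_schema)
        with pytest.warns(UserWarning, match="filtered out"):
            out = extract_rules(params, X, strength_threshold=2.0)
        assert len(out) == 0

    def test_roundtrip_recovers_injected_terms(self, clinical_schema, four_expert_rules):
        """extract(init(R)) with zero thresholds recovers every term of R."""
        params = init_from_rules(four_expert_rules, clinical_schema, K=4, seed=0)
        X = np.zeros((10, 6))
        out = extract_rules(params, X, strength_threshold=0.0,
                            corr_threshold=0.999, importance_threshold=0.5)
        by_origin = {r.origin: r for r in out}
        for k, rule in enumerate(four_expert_rules):
            got = {(t.feature, t.concept) for t in by_origin[k].terms}
            assert got == {(t.feature, t.concept) for t in rule.terms}

    def test_nonempty_firing_data_required(self, clinical_schema, four_expert_rules):
        params = init_from_rules(four_expert_rules, clinical_schema, K=4, seed=0)
        with pytest.raises(ValueError):
            extract_rules(params, np.zeros((0, 6)))


class TestEnsembleRules:
    def _rule(self, feats, strength):
        return Rule([RuleTerm(f, c) for f, c in feats], strength=strength)

    def test_single_fold_top_subset(self):
        fold = RuleSet([self._rule([("a", "low")], 0.9),
                        self._rule([("b", "low")], 0.5),
                        self._rule([("c", "high")], 0.3)])
        out = ensemble_rules([fold], max_rules=2)
        assert [r.strength for r in out] == [0.9, 0.5]

    def test_identical_folds_collapse(self):
        fold = RuleSet([self._rule([("a", "low")], 0.9),
                        self._rule([("b", "high")], 0.4)])
        out = ensemble_rules([fold] * 5)
        assert len(out) == 2
        assert {tuple(t.feature for t in r.terms) for r in out} == {("a",), ("b",)}

    def test_disjoint_strong_rules_union_matches_bruteforce(self):
        f1 = RuleSet([self._rule([("a", "low")], 0.9), self._rule([("b", "low")], 0.7)])
        f2 = RuleSet([self._rule([("c", "high")], 0.8), self._rule([("d", "low")], 0.6)])
        out = ensemble_rules([f1, f2], max_rules=4)
        # brute force: all rules are pairwise orthogonal, so the best
        # selection is simply the top-4 by strength
        pooled = sorted(f1.rules + f2.rules, key=lambda r: -r.strength)
        assert [r.strength for r in out] == [r.strength for r in pooled[:4]]

    def test_idempotent(self):
        f1 = RuleSet([self._rule([("a", "low"), ("b", "low")], 0.8),
                      self._rule([("a", "low")], 0.6),
                      self._rule([("c", "high")], 0.5)])
        once = ensemble_rules([f1], corr_threshold=0.6, max_rules=10)
        twice = ensemble_rules([once], corr_threshold=0.6, max_rules=10)
        assert [r.terms for r in twice] == [r.terms for r in once]

    def test_no_surviving_pair_exceeds_threshold(self):
        rng = np.random.default_rng(0)
        feats = [f"f{i}" for i in range(6)]
        rules = []
        for _ in range(12):
            chosen = rng.choice(6, size=2, replace=False)
            rules.append(Rule(
                [RuleTerm(feats[c], "low", float(rng.uniform(0.3, 1))) for c in chosen],
                strength=float(rng.uniform(0, 1)),
            ))
        out = ensemble_rules([RuleSet(rules)], corr_threshold=0.7)
        from tgfnn.rules import _cosine, _term_matrix

        V, _ = _term_matrix(out.rules)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert _cosine(V[i], V[j]) <= 0.7 + 1e-12

    def test_requires_at_least_one_fold(self):
        with pytest.raises(ValueError):
            ensemble_rules([])


class TestRenderRules:
    def test_exact_sentence_form(self):
        rs = RuleSet([Rule([RuleTerm("sbp", "low", 0.9), RuleTerm("lvef", "low", 0.9)],
                           class_weights=[0.0, 1.0])])
        report, heatmap = render_rules(
            rs,
            display_names={"sbp": "Systolic Blood Pressure",
                           "lvef": "Left Ventricular Ejection Fraction"},
        )
        assert ("IF Systolic Blood Pressure is low AND "
                "Left Ventricular Ejection Fraction is low, "
                "THEN refer for heart transplantation/ LVAD") in report

    def test_empty_ruleset(self):
        report, heatmap = render_rules(RuleSet([]))
        assert report == ""
        assert heatmap.empty

    def test_heatmap_shape_for_seven_rules(self):
        rng = np.random.default_rng(1)
        feats = [f"f{i}" for i in range(5)]
        rules = []
        for _ in range(7):
            chosen = rng.choice(5, size=2, replace=False)
            rules.append(Rule([RuleTerm(feats[c], "low") for c in chosen]))
        report, heatmap = render_rules(RuleSet(rules))
        assert heatmap.shape[1] == 7
        used = {(t.feature, "low") for r in rules for t in r.terms}
        assert heatmap.shape[0] == len(used)
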