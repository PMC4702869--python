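"""Truncation strategies and machine-learning relative reasoning."""

import json
import logging

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from biotrans import (
    MetaRule,
    PredictionSettings,
    Store,
    apply_meta_rules,
    apply_rule,
    build_training_set,
    canonicalize,
    likelihood_filter,
    parse_rule,
    predict,
    train,
    triggers,
)
from biotrans.chem import Likelihood
from biotrans.datamodel import Reaction
from biotrans.errors import TrainingError, ValidationError
from biotrans.evaluation import recovery_experiment
from biotrans.fixtures import toy_rule_library
from biotrans.reasoning import (
    MLTruncation,
    RelativeReasoningModel,
    TrainingInstance,
    featurize,
)

CATEGORIES = [m.value for m in Likelihood]


def _fake_candidates(categories):
    """Candidate list with one dummy rule per requested likelihood."""
    out = []
    for i, cat in enumerate(categories):
        rule = parse_rule(
            "[CH2:1][OH:2]>>[CH1:1]=[O:2]", f"dummy-{i}", cat, rule_id=f"d{i:02d}"
        )
        ps = next(iter(apply_rule(rule, canonicalize("CCO"))))
        out.append((rule, ps))
    return out


class TestLikelihoodFilter:
    def test_weakest_threshold_is_identity(self):
        candidates = _fake_candidates(CATEGORIES)
        assert likelihood_filter(candidates, "Very Unlikely") == candidates

    def test_neutral_keeps_likely_drops_unlikely(self):
        candidates = _fake_candidates(["Likely", "Unlikely"])
        kept = likelihood_filter(candidates, "Neutral")
        assert [rule.likelihood.value for rule, _ in kept] == ["Likely"]

    def test_strictest_threshold_empties_neutral_candidates(self):
        candidates = _fake_candidates(["Neutral", "Neutral"])
        assert likelihood_filter(candidates, "Very Likely") == []

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError):
            likelihood_filter([], "Plausible")

    @hsettings(max_examples=50, derandomize=True)
    @given(
        cats=st.lists(st.sampled_from(CATEGORIES), max_size=6),
        strict=st.sampled_from(CATEGORIES),
        loose=st.sampled_from(CATEGORIES),
    )
    def test_monotone_in_threshold(self, cats, strict, loose):
        if Likelihood.from_string(strict) < Likelihood.from_string(loose):
            strict, loose = loose, strict
        candidates = _fake_candidates(cats)
        kept_strict = likelihood_filter(candidates, strict)
        kept_loose = likelihood_filter(candidates, loose)
        assert set(id(r) for r, _ in kept_strict) <= set(id(r) for r, _ in kept_loose)


class TestMetaRules:
    def test_direct_suppression(self):
        candidates = _fake_candidates(["Neutral", "Neutral"])
        meta = [MetaRule(winner="d00", losers=("d01",))]
        kept = apply_meta_rules(candidates, meta)
        assert [r.rule_id for r, _ in kept] == ["d00"]

    def test_absent_winner_means_no_suppression(self):
        candidates = _fake_candidates(["Neutral"])  # only d00
        meta = [MetaRule(winner="d99", losers=("d00",))]
        assert apply_meta_rules(candidates, meta) == candidates

    def test_chain_collapses_to_fixed_point(self):
        candidates = _fake_candidates(["Neutral"] * 3)  # d00, d01, d02
        meta = [
            MetaRule(winner="d00", losers=("d01",)),
            MetaRule(winner="d01", losers=("d02",)),
        ]
        kept = apply_meta_rules(candidates, meta)
        assert [r.rule_id for r, _ in kept] == ["d00"]

    def test_cycle_retains_both_with_warning(self, caplog):
        candidates = _fake_candidates(["Neutral", "Neutral"])
        meta = [
            MetaRule(winner="d00", losers=("d01",)),
            MetaRule(winner="d01", losers=("d00",)),
        ]
        with caplog.at_level(logging.WARNING):
            kept = apply_meta_rules(candidates, meta)
        assert [r.rule_id for r, _ in kept] == ["d00", "d01"]
        assert "cyclic suppression" in caplog.text

    def test_winner_cannot_be_its_own_loser(self):
        with pytest.raises(ValidationError):
            MetaRule(winner="a", losers=("a", "b"))

    @hsettings(max_examples=40, derandomize=True, deadline=None)
    @given(
        n=st.integers(1, 5),
        edges=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)).filter(lambda e: e[0] != e[1]),
            max_size=8,
        ),
    )
    def test_idempotent_at_fixed_point(self, n, edges):
        candidates = _fake_candidates(["Neutral"] * n)
        meta = [MetaRule(winner=f"d{a:02d}", losers=(f"d{b:02d}",)) for a, b in edges]
        once = apply_meta_rules(candidates, meta)
        twice = apply_meta_rules(once, meta)
        assert [r.rule_id for r, _ in twice] == [r.rule_id for r, _ in once]


class TestBuildTrainingSet:
    @pytest.fixture()
    def ethanol_package(self, store):
        pkg = store.create_package("ground-truth", owner="alice")
        educt = store.add_entity(pkg.package_id, canonicalize("CCO"))
        product = store.add_entity(pkg.package_id, canonicalize("CC=O"))
        store.add_entity(pkg.package_id, Reaction(educts=[educt], products=[product]))
        return pkg

    def test_observed_rule_labeled_positive(self, ethanol_package, toy_rules_by_id):
        rules = [toy_rules_by_id["bt0001"], toy_rules_by_id["bt0003"]]
        instances = build_training_set([ethanol_package], rules)
        assert len(instances) == 1
        assert instances[0].triggered == ["bt0001"]
        assert instances[0].observed == ["bt0001"]

    def test_triggered_but_unobserved_is_negative(self, ethanol_package, toy_rules_by_id):
        chlorination = parse_rule(
            "[CX4:1][OH:2]>>[CX4:1]Cl", "alcohol to alkyl chloride", "Unlikely",
            rule_id="chl",
        )
        rules = [toy_rules_by_id["bt0001"], chlorination]
        (instance,) = build_training_set([ethanol_package], rules)
        assert set(instance.triggered) == {"bt0001", "chl"}
        assert instance.observed == ["bt0001"]

    def test_untriggered_educts_excluded(self, store, toy_rules_by_id):
        pkg = store.create_package("p", owner="alice")
        educt = store.add_entity(pkg.package_id, canonicalize("C"))  # methane
        product = store.add_entity(pkg.package_id, canonicalize("CO"))
        store.add_entity(pkg.package_id, Reaction(educts=[educt], products=[product]))
        assert build_training_set([pkg], [toy_rules_by_id["bt0001"]]) == []

    def test_empty_package_warns(self, store, toy_rules_by_id, caplog):
        pkg = store.create_package("empty", owner="alice")
        with caplog.at_level(logging.WARNING):
            out = build_training_set([pkg], [toy_rules_by_id["bt0001"]])
        assert out == []
        assert "empty training set" in caplog.text


class TestTrain:
    def test_always_observed_rule_scores_at_least_half(self, synthetic_pkg):
        library = toy_rule_library()
        instances = build_training_set([synthetic_pkg], library)
        model = train(instances, mode="single_label", seed=0)
        # bt0002 (aldehyde -> acid) is active and essentially always observed
        scores = model.score(canonicalize("CC=O"), ["bt0002"])
        assert scores["bt0002"] >= 0.5

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValidationError):
            train([object()], mode="both")

    def test_empty_training_set_rejected(self):
        with pytest.raises(TrainingError):
            train([], mode="single_label")

    def test_observed_must_be_subset_of_triggered(self):
        with pytest.raises(ValidationError):
            TrainingInstance(
                compound=canonicalize("CCO"),
                triggered=["a"],
                observed=["b"],
                features=np.zeros(3),
            )

    def test_nontriggered_slots_carry_no_loss(self, synthetic_pkg):
        """Relabeling rules on instances that do not trigger a target rule
        leaves the target rule's fitted scorer unchanged."""
        library = toy_rule_library()
        instances = build_training_set([synthetic_pkg], library)
        target = "bt0001"
        baseline = train(instances, mode="single_label", seed=0).scorers[target]

        perturbed = []
        for inst in instances:
            if target in inst.triggered:
                perturbed.append(inst)
            else:
                flipped = list(inst.triggered) if inst.observed != inst.triggered else []
                perturbed.append(
                    TrainingInstance(
                        compound=inst.compound,
                        triggered=inst.triggered,
                        observed=flipped,
                        features=inst.features,
                        rule_ids=inst.rule_ids,
                    )
                )
        retrained = train(perturbed, mode="single_label", seed=0).scorers[target]
        assert baseline["kind"] == retrained["kind"]
        if baseline["kind"] == "constant":
            assert baseline["p"] == retrained["p"]
        else:
            assert np.allclose(baseline["coef"], retrained["coef"])
            assert baseline["intercept"] == pytest.approx(retrained["intercept"])


@pytest.fixture(scope="module")
def fitted_model(synthetic_pkg):
    instances = build_training_set([synthetic_pkg], toy_rule_library())
    return train(instances, mode="multi_label", seed=0)


class TestScore:
    @pytest.fixture()
    def model(self, fitted_model):
        return fitted_model

    def test_empty_triggered_rules_empty_map(self, model):
        assert model.score(canonicalize("CCO"), []) == {}

    def test_probabilities_in_unit_interval(self, model, synthetic_pkg):
        library = toy_rule_library()
        for compound in list(synthetic_pkg.compounds.values())[:10]:
            triggered = [r.rule_id for r in library if triggers(r, compound)]
            for p in model.score(compound, triggered).values():
                assert 0.0 <= p <= 1.0

    def test_unknown_rule_scored_with_global_prior(self, model, caplog):
        with caplog.at_level(logging.WARNING):
            scores = model.score(canonicalize("CCO"), ["bt0001", "mystery"])
        assert scores["mystery"] == pytest.approx(model.global_prior)
        assert "unknown to model" in caplog.text

    def test_json_roundtrip_preserves_scores(self, model):
        restored = RelativeReasoningModel.from_json(
            json.loads(json.dumps(model.to_json()))
        )
        compound = canonicalize("COc1ccccc1")
        triggered = ["bt0005", "bt0007"]
        assert restored.score(compound, triggered) == pytest.approx(
            model.score(compound, triggered)
        )


class TestMLTruncation:
    def test_cutoff_validation(self, synthetic_pkg):
        instances = build_training_set([synthetic_pkg], toy_rule_library())
        model = train(instances, mode="single_label", seed=0)
        with pytest.raises(ValidationError):
            MLTruncation(model, probability_cutoff=1.5)

    def test_cutoff_zero_keeps_untruncated_node_set(self, synthetic_pkg):
        library = toy_rule_library()
        instances = build_training_set([synthetic_pkg], library)
        model = train(instances, mode="multi_label", seed=0)
        plain = predict(
            "COC(C)=O", PredictionSettings(max_levels=3), Store(), rules=library
        )
        truncated = predict(
            "COC(C)=O",
            PredictionSettings(max_levels=3, truncation=MLTruncation(model, 0.0)),
            Store(),
            rules=library,
        )
        assert set(truncated.nodes) <= set(plain.nodes)

    def test_high_cutoff_prunes(self, synthetic_pkg):
        library = toy_rule_library()
        instances = build_training_set([synthetic_pkg], library)
        model = train(instances, mode="multi_label", seed=0)
        plain = predict(
            "COc1ccc(C)cc1", PredictionSettings(max_levels=2), Store(), rules=library
        )
        truncated = predict(
            "COc1ccc(C)cc1",
            PredictionSettings(max_levels=2, truncation=MLTruncation(model, 0.99)),
            Store(),
            rules=library,
        )
        assert set(truncated.nodes) < set(plain.nodes)


def test_recovery_single_seed_both_modes():
    """Models trained on a synthetic package rank the generating rules
    above the inactive ones on held-out compounds (full sweep in the
    acceptance suite)."""
    for mode in ("single_label", "multi_label"):
        result = recovery_experiment(seed=0, mode=mode)
        assert result.separated, (mode, result.mean_scores)


def test_featurize_layout(toy_rules_by_id):
    rule_ids = sorted(toy_rules_by_id)
    x = featurize(canonicalize("CCO"), ["bt0001"], rule_ids)
    assert len(x) == len(rule_ids) + 1024
    assert x[: len(rule_ids)].sum() == 1.0
    assert x[rule_ids.index("bt0001")] == 1.0
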