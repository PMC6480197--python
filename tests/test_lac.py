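"""Entropy, information gain, projection, partition and lazy classification."""

import math
import random

import pytest
from sklearn.metrics import mutual_info_score

from caawd.car_miner import CAR, CARStore, itemize, mine_cars
from caawd.cdea import ABNORMAL, NORMAL
from caawd.lac import (LazyClassifier, classify, entropy, information_gain,
                       partition_rules, project)
from caawd.worked_examples import (oversleep_test_instance,
                                   sleeping_routine_training)

from conftest import random_itemized_dataset
from oracles import brute_classify, table_ig


class TestEntropy:
    @pytest.mark.parametrize("counts,expected", [
        ({"Normal": 1, "Abnormal": 1}, 1.0),
        ({"Normal": 5, "Abnormal": 0}, 0.0),
        ({"Normal": 3, "Abnormal": 1}, 0.8113),  # −(.75·log2 .75 + .25·log2 .25)
        ([2, 2, 2, 2], 2.0),
    ])
    def test_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-4)

    def test_invalid_distributions(self):
        with pytest.raises(ValueError):
            entropy([0, 0])
        with pytest.raises(ValueError):
            entropy([-1, 2])


class TestInformationGain:
    def test_perfect_predictor_on_balanced_data(self):
        data = ([(frozenset({("m", "1")}), NORMAL)] * 4
                + [(frozenset({("m", "0")}), ABNORMAL)] * 4)
        assert information_gain({("m", "1")}, data) == pytest.approx(1.0)

    def test_class_independent_antecedent(self):
        data = [(frozenset({("m", "1")}), NORMAL),
                (frozenset({("m", "0")}), NORMAL),
                (frozenset({("m", "1")}), ABNORMAL),
                (frozenset({("m", "0")}), ABNORMAL)]
        assert information_gain({("m", "1")}, data) == pytest.approx(0.0)

    def test_no_match_defined_as_zero(self, caplog):
        data = [(frozenset({("m", "1")}), NORMAL)] * 3
        with caplog.at_level("WARNING"):
            assert information_gain({("q", "9")}, data) == 0.0
        assert any("matches no training" in r.message for r in caplog.records)

    def test_hand_dataset_against_contingency_table(self):
        """Eight-instance dataset: IG equals the direct contingency-table
        computation and sklearn's mutual information (nats→bits)."""
        rng = random.Random(5)
        data = random_itemized_dataset(rng, 8, n_attrs=3)
        for ant in [{("a0", "v0")}, {("a1", "v1")}, {("a0", "v0"), ("a1", "v0")}]:
            got = information_gain(ant, data)
            assert got == pytest.approx(table_ig(ant, data), abs=1e-12)
            match = [1 if frozenset(ant) <= t else 0 for t, _ in data]
            labels = [lab for _, lab in data]
            if 0 < sum(match) < len(match):
                mi_bits = mutual_info_score(match, labels) / math.log(2)
                assert got == pytest.approx(mi_bits, abs=1e-9)


def _store_from(data, min_sup=0.01, min_conf=0.0):
    return mine_cars(data, min_sup, min_conf)


class TestProjection:
    def test_disjoint_test_gives_empty_projection(self):
        data = [(frozenset({("a", "1")}), NORMAL),
                (frozenset({("a", "2")}), ABNORMAL)]
        store = _store_from(data)
        proj = project(store, frozenset({("z", "9")}))
        assert proj.rules == []

    def test_training_instance_projects_all_its_subset_rules(self):
        """A test identical to a training instance retains exactly the
        rules whose antecedents are subsets of its items."""
        rng = random.Random(2)
        data = random_itemized_dataset(rng, 12, n_attrs=4)
        store = _store_from(data)
        test = data[0][0]
        proj = project(store, test)
        got = {r.key() for r in proj.rules}
        expected = {r.key() for r in store.rules if r.antecedent <= test}
        assert got == expected
        assert all(r.antecedent <= test for r in proj.rules)

    def test_routine_rules_project_onto_deviant_test(self, scheme):
        """The daytime-oversleep test shares object/location/activity with
        the nightly routine, so those rules project; rules mentioning the
        routine's 23:00 time bin do not."""
        train = [itemize(i, scheme) for i in sleeping_routine_training(scheme)]
        store = mine_cars(train, 0.01, 0.5)
        test_items, _ = itemize(
            oversleep_test_instance(scheme).with_label(NORMAL), scheme)
        proj = project(store, test_items, training=train)
        ants = [r.antecedent for r in proj.rules]
        assert frozenset({("object", "Bed")}) in ants
        assert not any(("time_bin", "[23:00,00:00)") in a for a in ants)


class TestPartition:
    def test_pure_confidence_rule_never_wrong(self):
        data = ([(frozenset({("a", "1")}), NORMAL)] * 5
                + [(frozenset({("a", "2")}), ABNORMAL)] * 5)
        store = _store_from(data)
        clf = LazyClassifier(store, data)
        part = clf.partition(clf.project(frozenset({("a", "1")})))
        assert all(r.confidence < 1.0 for r in part.wrong)

    def test_minority_consequent_rule_is_pruned(self):
        """A rule agreeing with 1 of 5 matching training instances
        contradicts the majority and lands in the wrong set."""
        data = ([(frozenset({("a", "1")}), NORMAL)] * 4
                + [(frozenset({("a", "1")}), ABNORMAL)])
        store = _store_from(data, min_sup=0.2, min_conf=0.0)
        clf = LazyClassifier(store, data)
        part = clf.partition(clf.project(frozenset({("a", "1")})))
        assert [r.consequent for r in part.wrong] == [ABNORMAL]
        assert [r.consequent for r in part.used] == [NORMAL]

    def test_dominated_rule_is_sparse(self):
        """When one rule outranks another on every training projection the
        runner-up is sparse, never used."""
        # m=1 predicts the class perfectly; b=1 occurs only alongside m=1,
        # so the b rule is never anyone's best applicable rule
        data = [(frozenset({("m", "1"), ("b", "1")}), NORMAL),
                (frozenset({("m", "1"), ("b", "0")}), NORMAL),
                (frozenset({("m", "0"), ("b", "0")}), ABNORMAL),
                (frozenset({("m", "0"), ("b", "0")}), ABNORMAL)]
        rules = [CAR(frozenset({("m", "1")}), NORMAL, 0.5, 1.0),
                 CAR(frozenset({("b", "1")}), NORMAL, 0.25, 1.0)]
        clf = LazyClassifier(CARStore(rules), data)
        proj = clf.project(frozenset({("m", "1"), ("b", "1")}))
        part = clf.partition(proj)
        assert [r.antecedent for r in part.used] == [frozenset({("m", "1")})]
        assert [r.antecedent for r in part.sparse] == [frozenset({("b", "1")})]

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_is_exact(self, seed):
        """used ∪ sparse ∪ wrong equals the projection, pairwise disjoint."""
        rng = random.Random(seed)
        data = random_itemized_dataset(rng, 20)
        store = _store_from(data)
        clf = LazyClassifier(store, data)
        test = data[rng.randrange(len(data))][0]
        proj = clf.project(test)
        part = partition_rules(proj, data)
        keys = lambda rs: {r.key() for r in rs}
        assert keys(part.used) | keys(part.sparse) | keys(part.wrong) == \
            keys(proj.rules)
        assert not keys(part.used) & keys(part.sparse)
        assert not keys(part.used) & keys(part.wrong)
        assert not keys(part.sparse) & keys(part.wrong)


class TestClassify:
    def test_memorized_pattern_is_normal(self):
        items = frozenset({("a", "1"), ("b", "2")})
        data = [(items, NORMAL)] * 10 + [(frozenset({("a", "9")}), ABNORMAL)] * 2
        res = classify(items, _store_from(data), data)
        assert res.label == NORMAL

    def test_empty_projection_falls_back_to_abnormal(self):
        data = [(frozenset({("a", "1")}), NORMAL),
                (frozenset({("a", "2")}), ABNORMAL)]
        res = classify(frozenset({("z", "1")}), _store_from(data), data)
        assert res.label == ABNORMAL
        assert res.reason == "no matching routine pattern"
        assert res.rule is None

    def test_fallback_class_is_configurable(self):
        data = [(frozenset({("a", "1")}), NORMAL),
                (frozenset({("a", "2")}), ABNORMAL)]
        res = classify(frozenset({("z", "1")}), _store_from(data), data,
                       fallback_class=NORMAL)
        assert res.label == NORMAL

    def test_daytime_oversleep_flagged_abnormal(self, scheme):
        """Trained on the nightly routine plus labeled deviations, the
        9:30/11.5 h test instance is classified Abnormal."""
        train = [itemize(i, scheme) for i in sleeping_routine_training(scheme)]
        store = mine_cars(train, 0.01, 0.5)
        test_items, _ = itemize(
            oversleep_test_instance(scheme).with_label(NORMAL), scheme)
        res = classify(test_items, store, train)
        assert res.label == ABNORMAL
        assert res.information_gain > 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """Classification agrees with the plain rule-scoring oracle on
        every test instance of random small problems."""
        rng = random.Random(seed)
        train = random_itemized_dataset(rng, 25)
        tests = [t for t, _ in random_itemized_dataset(rng, 15)]
        store = _store_from(train, min_sup=0.04, min_conf=0.5)
        clf = LazyClassifier(store, train)
        for t in tests:
            assert clf.classify(t).label == brute_classify(t, store.rules, train)

    def test_projection_soundness_on_every_classification(self):
        rng = random.Random(4)
        train = random_itemized_dataset(rng, 20)
        store = _store_from(train)
        clf = LazyClassifier(store, train)
        for t, _ in train:
            res = clf.classify(t)
            if res.rule is not None:
                assert res.rule.antecedent <= t
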