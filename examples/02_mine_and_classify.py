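"""Mine class association rules and classify a deviant test instance.

Uses the worked night-sleeper scenario: fourteen nights of a 23:30 /
7 h 45 m routine plus four labeled daytime-oversleep deviations.  The
rule base is mined at low minimum support, and an unseen 9:30 / 11.5 h
instance is classified by projecting the rules onto its items and
taking the highest information-gain rule.
"""

from caawd import LazyClassifier, mine_cars
from caawd.car_miner import ItemizationScheme, itemize
from caawd.worked_examples import (oversleep_test_instance,
                                   sleeping_routine_training)

scheme = ItemizationScheme()
training = [itemize(i, scheme) for i in sleeping_routine_training(scheme)]
store = mine_cars(training, min_support=0.01, min_confidence=0.5)
print(f"{len(store)} class association rules mined from "
      f"{len(training)} training instances")

clf = LazyClassifier(store, training)
test = oversleep_test_instance(scheme)
itemset, _ = itemize(test.with_label("Normal"), scheme)
result = clf.classify(itemset)

print(f"test instance: Sleeping at {test.start_time:%H:%M} for "
      f"{test.duration_minutes} min")
print(f"classified:    {result.label}")
print(f"winning rule:  {sorted(f'{a}={v}' for a, v in result.rule.antecedent)}"
      f" -> {result.rule.consequent}")
print(f"information gain {result.information_gain:.4f} bits, "
      f"confidence {result.rule.confidence:.2f}")
print(f"projected rules: {result.partition.sizes()}")

# The winner is a rule over the deviant time/duration bins: daytime
# oversleeping was seen (and labeled) in training, so its items carry
# maximal information about the class, beating every routine rule.
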