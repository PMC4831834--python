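"""K2 structure learning, checked against exhaustive search.

K2 walks a fixed causal ordering (grade first, so grade can only be a
parent) and greedily adds the parent that most improves the BIC score.
On a small node set the exact optimum over all order-consistent DAGs is
computable, so the two can be compared directly.
"""

from gliobayes import K2Config, exhaustive_best_dag, k2_search
from gliobayes import default_cohort_spec, generate_cohort
from gliobayes.structure import node_specs_for, total_score

table = generate_cohort(default_cohort_spec(seed=7))
order = ("grade", "t1wc", "nrCBV", "nMTT", "nrCBF")
complete = table.dropna(subset=list(order))
specs = node_specs_for(order)

greedy = k2_search(complete, K2Config(order, max_parents=3))
exact = exhaustive_best_dag(complete, order, max_parents=3)

print("K2 edges:        ", sorted(greedy.edges))
print("exhaustive edges:", sorted(exact.edges))
print(f"K2 score:         {total_score(greedy, complete, specs):.3f}")
print(f"exhaustive score: {total_score(exact, complete, specs):.3f}")
print()
print("Identical scores mean the greedy search found the global optimum")
print("over all DAGs consistent with this ordering.")
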