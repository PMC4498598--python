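"""Simulate one coalescent genealogy and place causative mutations on it.

Builds a Kingman genealogy for a small haploid sample, prints its shape
statistics against the coalescent's closed-form expectations, and drops
mutations on branches in proportion to branch length.
"""

import numpy as np

from coalor import place_mutations, simulate_tree, total_branch_length

rng = np.random.default_rng(1)
n = 10

tree = simulate_tree(n, rng)
print("newick:", tree.to_newick(3))
print("TMRCA          = %.3f  (expectation 2(1-1/n) = %.3f)"
      % (tree.tmrca, 2 * (1 - 1 / n)))
print("total length L = %.3f  (expectation 2*sum 1/i = %.3f)"
      % (total_branch_length(tree), 2 * sum(1 / i for i in range(1, n))))

mutations = place_mutations(tree, mutation_rate=1.0, rng=rng)
print("\n%d mutations at rate 1.0 per unit branch length:" % len(mutations))
for m in mutations:
    print("  branch above node %2d -> carriers %s (frequency %.2f)"
          % (m.branch_child_node, sorted(m.carrier_leaves), m.frequency))
print("\nCarriers are the leaves below the mutated branch: one early branch "
      "can make a mutation common, while tip branches give singletons.")
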