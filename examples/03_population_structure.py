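"""Pairwise F_ST, hierarchical AMOVA, and the bootstrapped NJ dendrogram."""

import numpy as np

import stockscan as ss

ds, truth = ss.simulate_metapopulation(ss.default_scenario(seed=3))
single = ss.select_one_snp_per_tag(ds)

theta, _ = ss.pairwise_fst(single)
print("pairwise Weir-Cockerham theta:")
print(theta.round(3).to_string())
# Between-lineage pairs sit near 0.07 and within-lineage pairs near 0.04,
# the calibration targets of the generator.

grouping = {pop: truth.lineage_of_pop[pop] for pop in single.populations()}
am = ss.amova(single, grouping)
print("\nAMOVA (groups = lineages):")
print(am.table.round(3).to_string(index=False))
# Most variation is within populations, a few percent between lineages -
# the same shape as hierarchical AMOVAs of real walleye surveys.

tree = ss.nj_bootstrap(single, n_boot=200, seed=3)
print("\nNJ dendrogram (bootstrap support on internal nodes):")
print(tree.newick)
sig = ss.fst_permutation_test(single, "wisconsin_pop1", "minnesota_pop1",
                              n_perm=999, seed=3)
print(f"\npermutation test wisconsin_pop1 vs minnesota_pop1: "
      f"theta={sig.theta:.3f}, p={sig.p_value:.4f} ({sig.n_permutations} permutations)")
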