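"""Simulate a stocked two-lineage metapopulation and run the filter chain.

Builds the default scenario (8 walleye-like populations in two postglacial
lineages, 1,200 RAD tags on 24 chromosomes, one Red-Lake-style stocking
pulse), simulates read depths, and applies the quality filters:
missingness -> minor-allele count -> HDplot paralog screen -> one SNP per
tag + F_IS (single-SNP branch) and microhaplotypes (multiallelic branch).
"""

import stockscan as ss

cfg = ss.default_scenario(seed=1)
ds, truth = ss.simulate_metapopulation(cfg)
counts = ss.simulate_read_counts(ds, truth)
print(f"simulated {ds.n_individuals} individuals x {ds.n_snps} SNPs "
      f"({ds.snps['tag'].nunique()} RAD tags)")

res = ss.run_filter_chain(ds, counts)
print("filter report:", res.report)
print(f"single-SNP dataset: {res.single_snp.n_snps} SNPs")
print(f"microhaplotype dataset: {res.microhaps.n_tags} tags")

# The report counts what each step removed: low-MAC SNPs dominate because
# the simulated site-frequency spectrum is skewed to rare alleles, as in
# real RAD data; HDplot flags only collapsed-paralog tags (none here,
# paralog_fraction defaults to 0 in the clean scenario).
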