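"""Nest floral mutations into the two deep cell lineages.

Mutations subfixed in the same layer ride the same cell-abundance
signal, so their VAFs correlate positively across samples; opposite
layers anticorrelate (their cell fractions are complementary).
Candidates are nested against deep branch anchor mutations with a
permutation-standardised correlation Z.
"""

import floralineage as fl

cfg = fl.default_two_flower_config(seed=5, depth_mean=300.0)
truth, table = fl.simulate_dataset(cfg)
vaf = fl.vaf_matrix(table.alt, table.total)
meta = truth.samples

anchors = fl.AnchorSet(group1=("ANCHOR-L1-main", "ANCHOR-L1-sub"),
                       group2=("ANCHOR-L2-main", "ANCHOR-L2-sub"))

# the two deep anchors of a lineage correlate strongly with each other
res = fl.permutation_z(vaf.loc["ANCHOR-L2-main"], vaf.loc["ANCHOR-L2-sub"],
                       n_perm=10_000, seed=5)
print(f"anchor pair L2 main vs sub: r {res['r']:.2f}, Z {res['Z']:.2f}, "
      f"p {res['p']:.2g} (n={res['n']})")

# flower-wide founders anticorrelate across one flower's organs
f1 = meta.index[meta["flower"] == "F1"]
neg = fl.negative_pair_test(vaf.loc["F1-FOUNDER-L1", f1],
                            vaf.loc["F1-FOUNDER-L2", f1], n_perm=10_000, seed=5)
print(f"F1 founders L1 vs L2: r {neg['r']:.2f} "
      f"(negative: {neg['negative']}) - complementary cell fractions")

cands = ["F1-FOUNDER-L1", "F1-FOUNDER-L2", "F2-FOUNDER-L2", "F2-FD-L1"]
nest = fl.nest_mutations(vaf, cands, anchors, n_perm=10_000, seed=5)
print("\nnesting of flower-wide mutations into anchor groups:")
print(nest["group"].to_string())
print("(Group1 = low-abundance L1 lineage, Group2 = high-abundance L2)")
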