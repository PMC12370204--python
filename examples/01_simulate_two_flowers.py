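"""Simulate the two-flower study design and inspect the ground truth.

A chain of branch initiation events carries two genetically isolated
cell layers (L1 epidermis, L2 interior). Two flowers attach near the
tip; each acquires flower-wide founder mutations at its anlagen, plus
radial sector mutations, against a background of Poisson branch
mutations. Read counts are drawn at ~64x depth.
"""

import floralineage as fl

cfg = fl.default_two_flower_config(seed=1)
truth, table = fl.simulate_dataset(cfg)

print(f"samples: {len(truth.samples)} "
      f"({int(truth.samples['is_control'].sum())} canopy controls)")
print(f"mutations: {len(truth.mutations)}")
print(truth.mutations["kind"].value_counts().to_string())

# an L2 founder marks ~90% of carpel cells -> expected VAF ~45%
ev = truth.expected_vaf
print(f"\nL2 founder, F1 carpel expected VAF: {ev.loc['F1-FOUNDER-L2','F1-carpel1']:.1f}%")
print(f"L1 founder, F1 petal  expected VAF: {ev.loc['F1-FOUNDER-L1','F1-petal1']:.2f}%")
print("(heterozygous halving: VAF = layer share / 2; "
      "L1 is at most 25.1% of a petal, so its VAF never exceeds ~12.6%)")
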