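"""Nesting mutations into the two deep cell lineages and founder inference.

Because L1 and L2 never exchange cells, two mutations subfixed in the
same layer track the same cell-abundance signal across samples and their
VAFs correlate positively, while mutations in opposite layers correlate
negatively (the layers' cell fractions are complementary). Correlation
strength is standardised against a permutation null: sample labels of
one vector are shuffled, and

    Z = (r_obs - mean(r_null)) / sd(r_null)

with the p-value taken from the permutation distribution (add-one
corrected). Candidates that correlate positively with every anchor of a
lineage group are nested into it. Sector mutations with too little
signal for correlation are assigned by a max-VAF threshold over non-petal
organs (petals are excluded because the two layers' VAF distributions
overlap there). Finally, the per-sample VAF ratio of a flower-wide
mutation to a same-group anchor separates founder-event mutations
(ratio ~ 1: the mutation marks all cells the anchor marks) from
first-daughter mutations (ratio ~ 0.5: it arose one division later and
marks half of them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnchorSet",
    "LineageAssignment",
    "permutation_z",
    "negative_pair_test",
    "assign_group_by_threshold",
    "founder_classify",
    "nest_mutations",
]

NON_PETAL_ORGANS = ("carpel", "sepal", "stamen")


@dataclass(frozen=True)
class AnchorSet:
    """Anchor (deep branch) mutation ids per lineage group."""

    group1: tuple  # low-abundance lineage (L1) anchors
    group2: tuple  # high-abundance lineage (L2) anchors

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("each group needs at least one anchor")
        if set(self.group1) & set(self.group2):
            raise ValueError("anchor groups must be disjoint")

    def items(self):
        return (("Group1", self.group1), ("Group2", self.group2))


@dataclass
class LineageAssignment:
    mutation: str
    group: str  # "Group1" | "Group2" | "unassigned"
    max_nonpetal_vaf: float
    n_records: int
    reason: str = ""


def _shared(vaf_a, vaf_b):
    a = np.asarray(vaf_a, dtype=float)
    b = np.asarray(vaf_b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def permutation_z(
    vaf_a,
    vaf_b,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> dict:
    """Permutation-standardised Pearson correlation of two VAF vectors.

    The observed r is computed on the samples where both vectors are
    measured; the null is built by permuting one vector's sample labels
    ``n_perm`` times. Z standardises r_obs against the null; the p-value
    is the add-one-corrected permutation tail (two-sided by default;
    ``"less"`` gives one-sided evidence for negative correlation,
    ``"greater"`` for positive).
    """
    a, b = _shared(vaf_a, vaf_b)
    n = len(a)
    if n < 4:
        raise ValueError(f"need >= 4 shared non-missing samples, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: correlation undefined")
    r_obs = float(stats.pearsonr(a, b)[0])
    if rng is None:
        rng = np.random.default_rng(seed)
    ac = (a - a.mean()) / a.std()
    bc = (b - b.mean()) / b.std()
    perms = rng.permuted(np.tile(bc, (n_perm, 1)), axis=1)
    r_null = perms @ ac / n
    z = (r_obs - r_null.mean()) / r_null.std(ddof=1)
    eps = 1e-12
    if alternative == "two-sided":
        hits = np.sum(np.abs(r_null) >= abs(r_obs) - eps)
    elif alternative == "less":
        hits = np.sum(r_null <= r_obs + eps)
    elif alternative == "greater":
        hits = np.sum(r_null >= r_obs - eps)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + hits) / (n_perm + 1.0)
    return {"r": r_obs, "Z": float(z), "p": float(p), "n": n, "n_perm": n_perm}


def negative_pair_test(
    vaf_a, vaf_b, n_perm: int = 10_000, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """One-sided evidence that two VAF vectors are negatively correlated,
    as expected for flower-wide mutations marking opposite layers."""
    res = permutation_z(vaf_a, vaf_b, n_perm=n_perm, seed=seed, rng=rng,
                        alternative="less")
    res["slope_sign"] = int(np.sign(res["r"]))
    res["negative"] = res["r"] < 0 and res["p"] < 0.05
    return res


def assign_group_by_threshold(
    vaf: pd.DataFrame,
    metadata: pd.DataFrame,
    mutations=None,
    threshold: float = 21.0,
    min_records: int = 3,
    group1_flowerwide: tuple = (),
) -> pd.DataFrame:
    """Assign mutations to lineage groups by their max non-petal VAF.

    The max VAF over carpel, sepal and stamen samples is compared to the
    threshold: above it the mutation joins Group 2 (high-abundance, L2),
    below it Group 1 (low-abundance, L1). Petal samples are excluded
    because the two groups' VAF distributions overlap there. Mutations
    observed only in petals or with fewer than ``min_records`` presence
    records are unassigned.

    ``group1_flowerwide`` recomputes the threshold as the maximum
    non-petal VAF of the designated flower-wide Group 1 mutations (how
    the 21.0% default was derived in the first place).
    """
    if group1_flowerwide:
        ref = vaf.loc[list(group1_flowerwide)]
        organs = metadata.loc[ref.columns, "organ"]
        nonpetal = ref.loc[:, organs.isin(NON_PETAL_ORGANS).to_numpy()]
        threshold = float(np.nanmax(nonpetal.to_numpy()))
    if mutations is None:
        mutations = list(vaf.index)
    organs = metadata.loc[vaf.columns, "organ"]
    nonpetal_cols = organs.isin(NON_PETAL_ORGANS).to_numpy()
    rows = []
    for mut in mutations:
        v = vaf.loc[mut]
        observed = v.notna() & (v > 0)
        n_records = int(observed.sum())
        np_vals = v[nonpetal_cols & observed.to_numpy()]
        if n_records < min_records:
            rows.append(LineageAssignment(mut, "unassigned", np.nan, n_records,
                                          f"fewer than {min_records} records"))
            continue
        if len(np_vals) == 0:
            rows.append(LineageAssignment(mut, "unassigned", np.nan, n_records,
                                          "petal-only observations"))
            continue
        mx = float(np_vals.max())
        group = "Group2" if mx > threshold else "Group1"
        rows.append(LineageAssignment(mut, group, mx, n_records,
                                      f"max non-petal VAF vs {threshold:.1f}%"))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("mutation")
    out.attrs["threshold"] = threshold
    return out


def founder_classify(
    vaf: pd.DataFrame,
    mutation: str,
    anchor: str,
    founder_window: tuple = (0.75, 1.25),
    daughter_window: tuple = (0.35, 0.65),
    min_shared: int = 3,
    samples=None,
) -> dict:
    """Founder-event vs first-daughter classification by VAF ratio.

    ``anchor`` may be a single same-group anchor id or several; with
    several, the per-sample reference is their mean VAF, which steadies
    the denominator for low-abundance (L1) comparisons. The per-sample
    ratio VAF_mut / VAF_anchor is taken over samples where
    both are measured and the anchor is non-zero. A median ratio inside
    ``founder_window`` means the mutation marks the whole founder lineage
    the anchor marks; inside ``daughter_window`` it marks half of it
    (origin one cell division later); anything else is indeterminate.

    ``samples`` should restrict the comparison to the mutation's own
    structural context (the samples of its flower): outside it the
    mutation is absent for reasons that say nothing about its fraction
    within the founder lineage. Within that context zero-VAF samples are
    genuine observations and enter the ratios as zeros.
    """
    vm = vaf.loc[mutation]
    if isinstance(anchor, str):
        va = vaf.loc[anchor]
    else:
        va = vaf.loc[list(anchor)].mean(axis=0)
        anchor = "+".join(anchor)
    if samples is not None:
        vm = vm[list(samples)]
        va = va[list(samples)]
    keep = vm.notna() & va.notna() & (va > 0)
    if int((vm.notna() & va.notna()).sum()) < min_shared:
        raise ValueError(
            f"{mutation} and anchor {anchor} share fewer than {min_shared} samples"
        )
    if not keep.any():
        raise ValueError(f"anchor {anchor} has zero VAF in all shared samples")
    ratios = (vm[keep] / va[keep]).to_numpy()
    med = float(np.median(ratios))
    q1, q3 = np.percentile(ratios, [25, 75])
    if founder_window[0] <= med <= founder_window[1]:
        label = "founder_event"
    elif daughter_window[0] <= med <= daughter_window[1]:
        label = "first_daughter"
    else:
        label = "indeterminate"
    return {
        "mutation": mutation, "anchor": anchor, "label": label,
        "median_ratio": med, "iqr": (float(q1), float(q3)), "n": int(keep.sum()),
    }


def nest_mutations(
    vaf: pd.DataFrame,
    candidates,
    anchors: AnchorSet,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    restrict_to_candidate: bool = True,
) -> pd.DataFrame:
    """Nest candidate mutations into anchor-defined lineage groups.

    Each candidate is tested against every anchor with the permutation
    correlation test (one-sided, positive). It joins a group when it is
    positively correlated (p < alpha) with all of that group's anchors;
    the per-anchor statistics record the nesting evidence. Anchors are
    never tested against themselves.

    Nesting is a statement about shared cell-abundance signal, so by
    default the correlation is computed over the samples where the
    candidate is actually observed (its flower or leaf): including
    samples where a floral candidate is structurally absent would turn
    the test into one of mere presence overlap with the anchors.

    No multiplicity correction is applied by default, matching per-test
    reporting of individual p-values; callers wanting Benjamini–Hochberg
    can correct the returned p columns.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cand in candidates:
        rec = {"mutation": cand, "group": "ungrouped"}
        vc = vaf.loc[cand]
        cols = vc.index[vc.notna() & (vc > 0)] if restrict_to_candidate else vc.index
        memberships = []
        for group, group_anchors in anchors.items():
            tests = []
            for anc in group_anchors:
                if anc == cand:
                    continue
                try:
                    res = permutation_z(
                        vc[cols], vaf.loc[anc, cols], n_perm=n_perm, rng=rng,
                        alternative="greater",
                    )
                except ValueError:
                    res = {"r": np.nan, "Z": np.nan, "p": np.nan, "n": 0}
                tests.append((anc, res))
                rec[f"r_{anc}"] = res["r"]
                rec[f"Z_{anc}"] = res["Z"]
                rec[f"p_{anc}"] = res["p"]
            if tests and all(
                np.isfinite(res["r"]) and res["r"] > 0 and res["p"] < alpha
                for _, res in tests
            ):
                memberships.append(group)
        if len(memberships) == 1:
            rec["group"] = memberships[0]
        elif len(memberships) > 1:
            rec["group"] = "ambiguous"
        rows.append(rec)
    return pd.DataFrame(rows).set_index("mutation")
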