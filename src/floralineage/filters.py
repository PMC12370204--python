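"""Candidate-SNV filtering cascade and de novo presence calling.

Somatic candidates from a deeply sequenced set of organ samples are
screened in three steps, mirroring the standard pipeline for calling
de novo mutations against a panel of control samples:

1. **Parental heterozygosity** — drop sites with alternate reads in the
   control panel (more than ``max_cmp_depth`` alt reads in any single
   control, or alt reads seen in more than ``max_cmp_total`` controls).
2. **Local quality** — drop sites with no well-supported carrier, sites
   missing (zero coverage) in too many controls, strand-biased sites,
   sites with three or more alleles, and SNVs adjacent to an INDEL.
3. **Hard annotation thresholds** — GATK-style site-level filters
   (QD, QUAL, SOR, FS, MQ, MQRankSum, ReadPosRankSum).

Every step conserves counts (removed + retained = input) and records a
per-site removal reason. A de novo floral mutation is then defined as a
retained site present in at least one sample of one flower and absent
from every sample outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANNOTATION_FIELDS",
    "CandidateTable",
    "FilterConfig",
    "FilterReport",
    "filter_parental",
    "filter_local_quality",
    "filter_hard_thresholds",
    "run_filter_cascade",
    "presence_matrix",
    "call_denovo",
]

ANNOTATION_FIELDS = ("QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: Default hard-filter thresholds; a site is removed when the comparison holds.
DEFAULT_HARD_THRESHOLDS: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "QUAL": ("<", 30.0),
    "SOR": (">", 4.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}


@dataclass
class CandidateTable:
    """A collection of candidate sites with per-sample read counts.

    ``sites`` is indexed by site id and carries chrom, pos (1-based), ref,
    alt, n_alleles (total alleles including ref), indel_dist (signed bp to
    the nearest INDEL call; NaN if none known) and the seven annotation
    fields. ``alt``/``total`` are site x sample read-count matrices;
    ``alt_fwd``/``ref_fwd`` carry the forward-strand split used by the
    strand-bias rule.
    """

    sites: pd.DataFrame
    alt: pd.DataFrame
    total: pd.DataFrame
    alt_fwd: pd.DataFrame | None = None
    ref_fwd: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, mat in (("alt", self.alt), ("total", self.total)):
            if not mat.index.equals(self.sites.index):
                raise ValueError(f"{name} matrix index does not match sites")
        if (self.alt.to_numpy() < 0).any() or (self.total.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.alt.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("alt reads exceed total reads")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")

    @property
    def site_ids(self) -> pd.Index:
        return self.sites.index

    @property
    def samples(self) -> pd.Index:
        return self.alt.columns

    def __len__(self) -> int:
        return len(self.sites)

    def subset(self, site_ids) -> "CandidateTable":
        return CandidateTable(
            sites=self.sites.loc[site_ids],
            alt=self.alt.loc[site_ids],
            total=self.total.loc[site_ids],
            alt_fwd=None if self.alt_fwd is None else self.alt_fwd.loc[site_ids],
            ref_fwd=None if self.ref_fwd is None else self.ref_fwd.loc[site_ids],
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three-step cascade and de novo calling."""

    max_cmp_depth: int = 2        # max alt reads tolerated in any single control
    max_cmp_total: int = 3        # max number of controls with >=1 alt read
    min_supp_depth: int = 5       # best carrier must have >= this many alt reads
    max_cmp_miss: int = 3         # max controls with zero coverage at the site
    indel_window: int = 5         # |distance to nearest INDEL| <= window is removed
    max_alleles: int = 2          # total alleles incl. ref; >2 (triallelic) removed
    strand_alpha: float = 0.001   # Fisher exact alpha for pooled carrier strand bias
    strand_min_each: int = 6      # with >= this many alt reads, require both strands
    hard_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_HARD_THRESHOLDS)
    )
    presence_min_alt: int = 2     # carrier-side presence threshold for de novo calls

    def __post_init__(self) -> None:
        for name, (_, thr) in self.hard_thresholds.items():
            if not np.isfinite(thr):
                raise ValueError(f"hard threshold for {name} must be finite")


@dataclass
class FilterReport:
    """Cascade arithmetic (input -> removed -> retained per step) and reasons."""

    steps: list = field(default_factory=list)
    reasons: dict = field(default_factory=dict)
    flagged: dict = field(default_factory=dict)

    def add_step(self, name: str, n_input: int, removed_ids, reasons: dict) -> None:
        removed_ids = list(removed_ids)
        self.steps.append(
            {
                "step": name,
                "input": n_input,
                "removed": len(removed_ids),
                "retained": n_input - len(removed_ids),
            }
        )
        self.reasons.update(reasons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def check_conservation(self) -> bool:
        ok = all(s["input"] == s["removed"] + s["retained"] for s in self.steps)
        for prev, nxt in zip(self.steps, self.steps[1:]):
            ok = ok and prev["retained"] == nxt["input"]
        return ok

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        rep = FilterReport(
            steps=self.steps + other.steps,
            reasons={**self.reasons, **other.reasons},
            flagged={**self.flagged, **other.flagged},
        )
        return rep


def _validate_controls(table: CandidateTable, controls) -> list:
    controls = list(controls)
    if not controls:
        raise ValueError(
            "de novo filtering requires at least one designated control sample"
        )
    missing = [c for c in controls if c not in table.samples]
    if missing:
        raise ValueError(f"control samples not in table: {missing}")
    return controls


def filter_parental(
    table: CandidateTable, controls, config: FilterConfig | None = None
) -> tuple[CandidateTable, FilterReport]:
    """Step 1: remove sites explained by parental (inherited) heterozygosity.

    A site is removed iff any control carries more than ``max_cmp_depth``
    alt reads, or alt reads are observed in more than ``max_cmp_total``
    controls.
    """
    config = config or FilterConfig()
    controls = _validate_controls(table, controls)
    ctrl_alt = table.alt[controls]
    deep = (ctrl_alt > config.max_cmp_depth).any(axis=1)
    wide = (ctrl_alt >= 1).sum(axis=1) > config.max_cmp_total
    removed = deep | wide
    reasons = {}
    for sid in table.site_ids[removed]:
        reasons[sid] = "parental:control_depth" if deep[sid] else "parental:control_count"
    report = FilterReport()
    report.add_step("parental", len(table), table.site_ids[removed], reasons)
    return table.subset(table.site_ids[~removed]), report


def _strand_bias_pvalues(table: CandidateTable) -> pd.Series:
    """Two-sided Fisher exact p on pooled carrier strand counts per site.

    Carriers are samples with >=1 alt read; alt and ref reads are pooled
    over carriers into a 2x2 (strand x allele) table. Sites with no strand
    information get NaN.
    """
    if table.alt_fwd is None or table.ref_fwd is None:
        return pd.Series(np.nan, index=table.site_ids)
    carriers = table.alt >= 1
    alt_f = (table.alt_fwd * carriers).sum(axis=1)
    alt_r = ((table.alt - table.alt_fwd) * carriers).sum(axis=1)
    ref = table.total - table.alt
    ref_f = (table.ref_fwd * carriers).sum(axis=1)
    ref_r = ((ref - table.ref_fwd) * carriers).sum(axis=1)
    pvals = {}
    for sid in table.site_ids:
        tab = np.array([[alt_f[sid], alt_r[sid]], [ref_f[sid], ref_r[sid]]])
        if tab[0].sum() == 0:
            pvals[sid] = 1.0
            continue
        pvals[sid] = stats.fisher_exact(tab, alternative="two-sided")[1]
    return pd.Series(pvals)


def filter_local_quality(
    table: CandidateTable, controls, config: FilterConfig | None = None
) -> tuple[CandidateTable, FilterReport]:
    """Step 2: remove sites with poor local quality.

    Removal reasons, in the order they are recorded: no sample with at
    least ``min_supp_depth`` supporting alt reads; zero coverage in more
    than ``max_cmp_miss`` controls; three or more alleles; strand bias
    (pooled-carrier Fisher test at ``strand_alpha``, plus a both-strands
    requirement once alt reads reach ``strand_min_each``); within
    ``indel_window`` bp of an INDEL. Sites lacking the annotations a rule
    needs are flagged in the report rather than silently passed.
    """
    config = config or FilterConfig()
    controls = _validate_controls(table, controls)

    no_support = ~(table.alt >= config.min_supp_depth).any(axis=1)
    miss = (table.total[controls] == 0).sum(axis=1) > config.max_cmp_miss
    multi = table.sites["n_alleles"] > config.max_alleles

    sb_p = _strand_bias_pvalues(table)
    biased = sb_p < config.strand_alpha
    if table.alt_fwd is not None:
        carriers = table.alt >= 1
        alt_f = (table.alt_fwd * carriers).sum(axis=1)
        alt_tot = (table.alt * carriers).sum(axis=1)
        alt_r = alt_tot - alt_f
        one_sided = (alt_tot >= config.strand_min_each) & ((alt_f == 0) | (alt_r == 0))
        biased = biased | one_sided

    indel_dist = table.sites["indel_dist"]
    near_indel = indel_dist.abs() <= config.indel_window

    flagged = {}
    if table.alt_fwd is None:
        flagged.update({sid: "no_strand_counts" for sid in table.site_ids})
    for sid in table.site_ids[indel_dist.isna()]:
        flagged[sid] = flagged.get(sid, "") + ";no_indel_distance"

    removed = no_support | miss | multi | biased | near_indel
    reasons = {}
    order = [
        ("quality:no_support", no_support),
        ("quality:missing_controls", miss),
        ("quality:multiallelic", multi),
        ("quality:strand_bias", biased),
        ("quality:near_indel", near_indel),
    ]
    for sid in table.site_ids[removed]:
        for label, mask in order:
            if bool(mask[sid]):
                reasons[sid] = label
                break
    report = FilterReport(flagged=flagged)
    report.add_step("local_quality", len(table), table.site_ids[removed], reasons)
    return table.subset(table.site_ids[~removed]), report


def filter_hard_thresholds(
    table: CandidateTable, config: FilterConfig | None = None
) -> tuple[CandidateTable, FilterReport]:
    """Step 3: GATK-style hard annotation filters.

    A site is removed iff any configured predicate holds, with strict
    comparisons (a value exactly at a threshold passes). Missing
    annotations — the rank-sum fields are absent for sites without
    heterozygous genotypes — pass their predicate.
    """
    config = config or FilterConfig()
    removed = pd.Series(False, index=table.site_ids)
    reasons = {}
    for name, (op, thr) in config.hard_thresholds.items():
        vals = table.sites[name].astype(float)
        hit = (vals < thr) if op == "<" else (vals > thr)
        hit = hit.fillna(False)
        for sid in table.site_ids[hit & ~removed]:
            reasons[sid] = f"hard:{name}{op}{thr}"
        removed |= hit
    report = FilterReport()
    report.add_step("hard_thresholds", len(table), table.site_ids[removed], reasons)
    return table.subset(table.site_ids[~removed]), report


def run_filter_cascade(
    table: CandidateTable, controls, config: FilterConfig | None = None
) -> tuple[CandidateTable, FilterReport]:
    """Apply the three filtering steps in order and merge the reports."""
    config = config or FilterConfig()
    t1, r1 = filter_parental(table, controls, config)
    t2, r2 = filter_local_quality(t1, controls, config)
    t3, r3 = filter_hard_thresholds(t2, config)
    return t3, r1.merged_with(r2).merged_with(r3)


def presence_matrix(table: CandidateTable, config: FilterConfig | None = None) -> pd.DataFrame:
    """Per (site, sample) presence call: 1 present, 0 absent, NaN missing.

    Present means at least ``presence_min_alt`` alt reads; a sample with
    zero total reads at the site is missing, never absent.
    """
    config = config or FilterConfig()
    present = (table.alt >= config.presence_min_alt).astype(float)
    present[table.total == 0] = np.nan
    return present


def call_denovo(
    table: CandidateTable,
    metadata: pd.DataFrame,
    config: FilterConfig | None = None,
    group_col: str = "flower",
) -> tuple[pd.DataFrame, pd.Series]:
    """Label retained sites that are de novo for exactly one flower.

    ``metadata`` is indexed by sample with a ``group_col`` column (NaN for
    samples outside any flower, e.g. branch leaves or canopy controls).
    A mutation is de novo for flower F iff it is present in at least one
    sample of F and in no sample outside F. Missing (uncovered) samples
    provide no evidence either way.

    Returns ``(presence, assignment)`` where ``assignment`` maps site id
    to the flower label or NaN when the site fails specificity.
    """
    config = config or FilterConfig()
    missing = [s for s in table.samples if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    present = presence_matrix(table, config)
    groups = metadata.loc[table.samples, group_col]
    labels = {}
    for sid in table.site_ids:
        row = present.loc[sid]
        carrier_groups = groups[row == 1.0]
        if len(carrier_groups) == 0:
            labels[sid] = np.nan
        elif carrier_groups.isna().any() or carrier_groups.nunique() != 1:
            labels[sid] = np.nan
        else:
            labels[sid] = carrier_groups.iloc[0]
    return present, pd.Series(labels, name="denovo_flower")
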