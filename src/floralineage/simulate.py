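"""Forward simulation of somatic mutations in a layered shoot meristem.

The simulated plant is a chain of branch initiation events (nodes) along
which two genetically isolated cell layers — L1 (epidermis lineage) and
L2 (interior lineage) — co-propagate. At every initiation event each
layer independently acquires ``Poisson(mu_event)`` heterozygous mutations
that subfix in all descendant cells of that layer from that node onward.
Flowers attach at configured nodes; the floral anlagen is itself an
initiation event where forced founder mutations (marking all cells of a
layer, fraction-within-layer 1.0) and first-daughter mutations (arising
one division later, fraction 0.5) can be planted, along with radial
sector mutations confined to wedges of organ units.

Organ samples mix the two layers in organ-specific proportions; read
counts are drawn per site and sample as Poisson total depth and binomial
alternate reads at the expected allele fraction

    E[alt fraction] = g * share_layer(organ) / 2

where ``g`` is the fraction within the layer and ``share`` the layer's
read share of the organ (cell proportion, optionally ploidy-weighted
under the endopolyploidy scenarios). The simulator also emits decoy sites
of known artifact classes so the filter cascade can be audited against
exact planted counts, and split-lysate subsample pairs for the
repeatability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .filters import CandidateTable
from .vaf import DEFAULT_LAYER_FRACTIONS, LayerModel, layer_read_share

__all__ = [
    "WedgeSpec",
    "FlowerSpec",
    "DecoyConfig",
    "SimConfig",
    "SimTruth",
    "simulate_tree",
    "compose_organ_sample",
    "sample_reads",
    "make_split_pair",
    "simulate_dataset",
    "default_two_flower_config",
]

LAYERS = ("L1", "L2")
ORGAN_TYPES = ("sepal", "petal", "stamen", "carpel", "leaf")
CHROMOSOMES = tuple(f"Pp{i:02d}" for i in range(1, 9))
CHROM_LENGTH = 28_000_000  # ~227 Mb peach genome over 8 chromosomes
BASES = ("A", "C", "G", "T")

#: Passing site annotations used for true (non-decoy) simulated sites.
PASSING_ANNOTATIONS = {
    "QD": 25.0,
    "QUAL": 900.0,
    "SOR": 1.0,
    "FS": 2.0,
    "MQ": 60.0,
    "MQRankSum": 0.0,
    "ReadPosRankSum": 0.0,
}


@dataclass(frozen=True)
class WedgeSpec:
    """A radial sector: mutations confined to the listed organ units."""

    organs: tuple  # organ-unit names within the flower, e.g. ("sepal1", "petal1")
    layer: str = "L2"
    n_mutations: int = 1


@dataclass(frozen=True)
class FlowerSpec:
    """One flower: its anlagen node, organ inventory, and planted events."""

    name: str
    node: int
    organs: dict = field(
        default_factory=lambda: {"sepal": 5, "petal": 5, "stamen": 5, "carpel": 1}
    )
    founders: tuple = ("L1", "L2")        # layers with forced anlagen founder mutations
    first_daughters: tuple = ()           # layers with forced first-daughter mutations
    wedges: tuple = ()                    # WedgeSpec sectors
    split_units: tuple = ()               # organ units emitted as -a/-b subsample pairs

    def organ_units(self) -> list:
        units = []
        for organ, n in self.organs.items():
            for k in range(1, n + 1):
                units.append((f"{organ}{k}", organ))
        return units


@dataclass(frozen=True)
class DecoyConfig:
    """Counts of planted artifact sites per filter-stage class."""

    n_parental: int = 0
    n_no_support: int = 0
    n_missing_controls: int = 0
    n_strand_bias: int = 0
    n_triallelic: int = 0
    n_indel_adjacent: int = 0
    n_hard_fail: int = 0

    def total(self) -> int:
        return (
            self.n_parental + self.n_no_support + self.n_missing_controls
            + self.n_strand_bias + self.n_triallelic + self.n_indel_adjacent
            + self.n_hard_fail
        )


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: ~64x depth, one mutation per lineage per event,
    organ layer fractions from histological counts, two founder cells."""

    seed: int = 0
    depth_mean: float = 64.3
    n_branch_nodes: int = 4
    flowers: tuple = ()
    leaves_per_node: int = 2
    n_control_leaves: int = 8
    founder_cells: tuple = (1, 1)         # (L1, L2) founders at floral initiation
    mu_event: float = 1.0                 # expected mutations per lineage per event
    first_daughter_prob: float = 0.0      # random anlagen mutations at fraction 0.5
    deep_anchor_layers: tuple = ("L1", "L2")  # forced trunk-node anchors
    layer_fractions: dict = field(default_factory=lambda: dict(DEFAULT_LAYER_FRACTIONS))
    #: Beta concentration for the per-lysate L1 share around its organ mean.
    #: Micro-punched plugs capture few cell files, so the local L1:L2 ratio
    #: varies well beyond read noise (observed low-lineage VAFs range up to
    #: ~21% against organ means near 7%); None disables the jitter.
    layer_concentration: float | None = 25.0
    endopolyploidy_scenario: str = "none"  # none | L1_only | both_layers
    ploidy_class_weights: dict = field(default_factory=lambda: {2.0: 0.7, 8.0: 0.3})
    split_dropout: float = 0.0            # per (mutation, subsample) dropout rate
    decoys: DecoyConfig = field(default_factory=DecoyConfig)

    def __post_init__(self) -> None:
        if self.n_branch_nodes < 1:
            raise ValueError("tree must have at least one branch node")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.mu_event < 0:
            raise ValueError("mu_event must be non-negative")
        if any(n < 1 for n in self.founder_cells):
            raise ValueError("founder cell counts must be >= 1")
        for organ, f in self.layer_fractions.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"layer fraction for {organ!r} must be in (0,1)")
        if self.endopolyploidy_scenario not in ("none", "L1_only", "both_layers"):
            raise ValueError(f"unknown scenario {self.endopolyploidy_scenario!r}")
        if self.layer_concentration is not None and self.layer_concentration <= 0:
            raise ValueError("layer_concentration must be positive")
        for fl in self.flowers:
            if not 0 <= fl.node < self.n_branch_nodes:
                raise ValueError(f"flower {fl.name} node {fl.node} outside tree")

    def layer_model(self) -> LayerModel:
        return LayerModel(fractions=dict(self.layer_fractions))

    def ploidy_weights(self) -> dict | None:
        """Mean genome-copy weight per layer under the configured scenario."""
        if self.endopolyploidy_scenario == "none":
            return None
        elevated = sum(c * w for c, w in self.ploidy_class_weights.items())
        baseline = 2.0  # uniform diploid
        if self.endopolyploidy_scenario == "L1_only":
            return {"L1": elevated, "L2": baseline}
        return {"L1": elevated, "L2": elevated}


@dataclass
class SimTruth:
    """Ground truth: per-mutation origin and the expected VAF% per sample.

    ``mutations`` is indexed by mutation id with columns layer, kind
    (anchor / branch / anlagen_founder / first_daughter / random_anlagen /
    sector), node, flower, fraction_within_layer, organs (wedge members or
    None), chrom, pos, ref, alt. ``samples`` is the sample inventory;
    ``expected_vaf`` is a mutations x samples matrix in percent.
    """

    mutations: pd.DataFrame
    samples: pd.DataFrame
    expected_vaf: pd.DataFrame
    #: realised per-lysate VAF expectations after layer-share jitter; set by
    #: :func:`simulate_dataset`, equal to ``expected_vaf`` until then
    realized_vaf: pd.DataFrame | None = None

    @property
    def expected_fraction(self) -> pd.DataFrame:
        return self.expected_vaf / 100.0


def default_two_flower_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study scenario: two flowers on sibling sub-branches,
    each with 5 sepals / 5 petals / 5 stamens / 1 carpel, forced founder
    mutations in both layers, an L1 first-daughter mutation in the second
    flower, and sector wedges pairing each petal with adjacent sepals and
    a stamen."""

    def wedges(prefix_layers):
        ws = []
        for i, layer in enumerate(prefix_layers, start=1):
            organs = (f"sepal{i}", f"sepal{i % 5 + 1}", f"petal{i}", f"stamen{i}")
            ws.append(WedgeSpec(organs=organs, layer=layer, n_mutations=1))
        return tuple(ws)

    f1 = FlowerSpec(
        name="F1", node=2,
        wedges=wedges(("L1", "L2", "L1")),
    )
    # the second flower's L1 founder is unmarked: its flower-wide L1
    # mutation arose one division later (the first-daughter case)
    f2 = FlowerSpec(
        name="F2", node=3,
        founders=("L2",),
        first_daughters=("L1",),
        wedges=wedges(("L2", "L1", "L2", "L1")),
        split_units=tuple(f"sepal{i}" for i in range(1, 4)),
    )
    cfg = SimConfig(seed=seed, flowers=(f1, f2), **overrides)
    return cfg


def sector_recovery_config(
    seed: int = 0,
    n_wedges: int = 3,
    muts_per_wedge: int = 4,
    **overrides,
) -> SimConfig:
    """A single flower whose radial anatomy is fully wedged: wedge *i*
    holds (sepal_i, petal_i, stamen_i) with ``muts_per_wedge`` planted
    sector mutations, alternating layers. The carpel carries only the
    flower-wide founders, mirroring its early genetic isolation. Used to
    audit sector recovery in the zero-noise limit."""
    wedges = tuple(
        WedgeSpec(
            organs=(f"sepal{i}", f"petal{i}", f"stamen{i}"),
            layer=LAYERS[i % 2],
            n_mutations=muts_per_wedge,
        )
        for i in range(1, n_wedges + 1)
    )
    flower = FlowerSpec(
        name="F1", node=1,
        organs={"sepal": n_wedges, "petal": n_wedges, "stamen": n_wedges, "carpel": 1},
        wedges=wedges,
    )
    return SimConfig(seed=seed, n_branch_nodes=2, flowers=(flower,),
                     mu_event=0.0, **overrides)


def _draw_site(rng: np.random.Generator) -> dict:
    chrom = CHROMOSOMES[rng.integers(len(CHROMOSOMES))]
    pos = int(rng.integers(1, CHROM_LENGTH))
    ref, alt = rng.choice(len(BASES), size=2, replace=False)
    return {"chrom": chrom, "pos": pos, "ref": BASES[ref], "alt": BASES[alt]}


def simulate_tree(config: SimConfig) -> SimTruth:
    """Run the branching simulation and return ground truth plus the
    sample inventory and expected VAF matrix."""
    rng = np.random.default_rng(config.seed)
    muts: list[dict] = []

    def add(mut_id, layer, kind, node, fraction, flower=None, organs=None):
        muts.append(
            dict(
                id=mut_id, layer=layer, kind=kind, node=node, flower=flower,
                fraction_within_layer=fraction, organs=organs, **_draw_site(rng),
            )
        )

    # forced deep anchors: one per layer at the trunk node and one at the
    # next initiation event, mirroring a main-branch / sub-branch marker
    # pair for each lineage
    for layer in config.deep_anchor_layers:
        add(f"ANCHOR-{layer}-main", layer, "anchor", 0, 1.0)
        if config.n_branch_nodes > 1:
            add(f"ANCHOR-{layer}-sub", layer, "anchor", 1, 1.0)

    # stochastic branch mutations, one Poisson draw per lineage per node
    for node in range(config.n_branch_nodes):
        for layer in LAYERS:
            for j in range(rng.poisson(config.mu_event)):
                add(f"BR-n{node}-{layer}-{j + 1}", layer, "branch", node, 1.0)

    for fl in config.flowers:
        for layer in fl.founders:
            add(f"{fl.name}-FOUNDER-{layer}", layer, "anlagen_founder",
                fl.node, 1.0, flower=fl.name)
        for layer in fl.first_daughters:
            add(f"{fl.name}-FD-{layer}", layer, "first_daughter",
                fl.node, 0.5, flower=fl.name)
        for layer in LAYERS:
            for j in range(rng.poisson(config.mu_event)):
                frac = 0.5 if rng.random() < config.first_daughter_prob else 1.0
                add(f"{fl.name}-ANL-{layer}-{j + 1}", layer, "random_anlagen",
                    fl.node, frac, flower=fl.name)
        for w, wedge in enumerate(fl.wedges, start=1):
            for j in range(wedge.n_mutations):
                add(f"{fl.name}-SEC{w}-{wedge.layer}-{j + 1}", wedge.layer,
                    "sector", fl.node, 1.0, flower=fl.name, organs=tuple(wedge.organs))

    mutations = pd.DataFrame(muts).set_index("id") if muts else pd.DataFrame(
        columns=["layer", "kind", "node", "flower", "fraction_within_layer",
                 "organs", "chrom", "pos", "ref", "alt"]
    )

    samples = _sample_inventory(config)
    expected = _expected_vaf_matrix(config, mutations, samples)
    return SimTruth(mutations=mutations, samples=samples, expected_vaf=expected)


def _sample_inventory(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(1, config.n_control_leaves + 1):
        rows.append(dict(sample=f"CTRL-leaf{i}", flower=None, organ="leaf",
                         organ_unit=None, node=-1, is_control=True,
                         split_group=None, subsample=None))
    for node in range(config.n_branch_nodes):
        for j in range(1, config.leaves_per_node + 1):
            rows.append(dict(sample=f"BR-n{node}-leaf{j}", flower=None, organ="leaf",
                             organ_unit=None, node=node, is_control=False,
                             split_group=None, subsample=None))
    for fl in config.flowers:
        for unit, organ in fl.organ_units():
            base = f"{fl.name}-{unit}"
            if unit in fl.split_units:
                for sub in ("a", "b"):
                    rows.append(dict(sample=f"{base}-{sub}", flower=fl.name,
                                     organ=organ, organ_unit=unit, node=fl.node,
                                     is_control=False, split_group=base, subsample=sub))
            else:
                rows.append(dict(sample=base, flower=fl.name, organ=organ,
                                 organ_unit=unit, node=fl.node, is_control=False,
                                 split_group=None, subsample=None))
    cols = ["sample", "flower", "organ", "organ_unit", "node", "is_control",
            "split_group", "subsample"]
    return pd.DataFrame(rows, columns=cols).set_index("sample")


def compose_organ_sample(
    organ: str,
    truth_mutations: pd.DataFrame,
    config: SimConfig,
    flower: str | None = None,
    node: int | None = None,
    organ_unit: str | None = None,
    is_control: bool = False,
) -> pd.Series:
    """Expected alt-read fraction per mutation for one organ sample.

    Under scenario ``none`` and ``both_layers`` the ploidy weights cancel
    and the expectations coincide; ``L1_only`` inflates L1-mutation
    fractions by the L1 ploidy-weight ratio. Controls (off-branch canopy
    samples) carry none of the simulated mutations.
    """
    model = config.layer_model()
    if organ not in model.fractions:
        raise KeyError(f"no layer fraction configured for organ {organ!r}")
    weights = config.ploidy_weights()
    shares = {
        layer: layer_read_share(layer, organ, model, weights) for layer in LAYERS
    }
    out = {}
    for mut_id, m in truth_mutations.iterrows():
        if is_control:
            out[mut_id] = 0.0
            continue
        if m["flower"] is None or (isinstance(m["flower"], float) and np.isnan(m["flower"])):
            present = node is not None and node >= m["node"]
        else:
            present = flower == m["flower"]
            if present and m["organs"] is not None and not (
                isinstance(m["organs"], float) and np.isnan(m["organs"])
            ):
                present = organ_unit in m["organs"]
        if not present:
            out[mut_id] = 0.0
        else:
            out[mut_id] = m["fraction_within_layer"] * shares[m["layer"]] / 2.0
    return pd.Series(out, name=organ)


def _expected_vaf_matrix(
    config: SimConfig, mutations: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    cols = {}
    for sample, s in samples.iterrows():
        frac = compose_organ_sample(
            s["organ"], mutations, config, flower=s["flower"], node=s["node"],
            organ_unit=s["organ_unit"], is_control=bool(s["is_control"]),
        )
        cols[sample] = 100.0 * frac
    mat = pd.DataFrame(cols)
    mat.index.name = "mutation"
    return mat


def _passing_annotations(n: int, rng: np.random.Generator | None) -> pd.DataFrame:
    """Annotation block for well-behaved sites; jittered when an rng is given."""
    ann = pd.DataFrame({k: np.full(n, v) for k, v in PASSING_ANNOTATIONS.items()})
    if rng is not None and n:
        ann["QD"] = rng.uniform(15, 35, n)
        ann["QUAL"] = rng.uniform(200, 2000, n)
        ann["SOR"] = rng.uniform(0.3, 2.5, n)
        ann["FS"] = rng.uniform(0.0, 10.0, n)
        ann["MQ"] = rng.uniform(55, 60, n)
        ann["MQRankSum"] = np.clip(rng.normal(0, 1, n), -5, 5)
        ann["ReadPosRankSum"] = np.clip(rng.normal(0, 1, n), -5, 5)
    ann["n_alleles"] = 2
    ann["indel_dist"] = 10_000
    return ann


def sample_reads(
    expected_fraction: pd.DataFrame,
    depth_mean: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
    site_info: pd.DataFrame | None = None,
) -> CandidateTable:
    """Draw read counts for a mutations x samples expected-fraction matrix.

    Per cell, total reads ~ Poisson(depth_mean) and alt ~ Binomial(total,
    fraction); strand splits are symmetric binomial. ``deterministic``
    replaces sampling by expected values (fixed depth, rounded counts) —
    the zero-noise / infinite-depth limit used for exact-count fixtures.
    """
    frac = expected_fraction.to_numpy(dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("expected fractions must lie in [0,1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if deterministic:
        total = np.full(frac.shape, int(round(depth_mean)))
        alt = np.rint(total * frac).astype(int)
        alt_fwd = alt // 2
        ref_fwd = (total - alt) // 2
        ann_rng = None
    else:
        total = rng.poisson(depth_mean, size=frac.shape)
        alt = rng.binomial(total, frac)
        alt_fwd = rng.binomial(alt, 0.5)
        ref_fwd = rng.binomial(total - alt, 0.5)
        ann_rng = rng

    idx = expected_fraction.index
    cols = expected_fraction.columns
    ann = _passing_annotations(len(idx), ann_rng)
    ann.index = idx
    if site_info is not None:
        sites = site_info.loc[idx, ["chrom", "pos", "ref", "alt"]].copy()
    else:
        srng = np.random.default_rng(0 if seed is None else seed)
        sites = pd.DataFrame([_draw_site(srng) for _ in idx], index=idx)
    sites = pd.concat([sites, ann], axis=1)
    sites["truth_class"] = "true"

    def mat(arr):
        return pd.DataFrame(arr, index=idx, columns=cols)

    return CandidateTable(
        sites=sites, alt=mat(alt), total=mat(total),
        alt_fwd=mat(alt_fwd), ref_fwd=mat(ref_fwd),
    )


def make_split_pair(
    fraction: pd.Series,
    depth_mean: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dropout: float = 0.0,
    deterministic: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two independent read draws from one lysate's cell-fraction vector.

    Both subsamples share the underlying fractions (same cells in the
    lysate) but carry independent read noise. ``dropout`` injects false
    negatives: each truly present mutation is zeroed in a subsample with
    that probability (amplification dropout). Returns two frames with
    columns ref/alt/total indexed by mutation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        if deterministic:
            total = np.full(len(fraction), int(round(depth_mean)))
            alt = np.rint(total * fraction.to_numpy()).astype(int)
        else:
            total = rng.poisson(depth_mean, size=len(fraction))
            alt = rng.binomial(total, fraction.to_numpy())
            if dropout > 0:
                drop = rng.random(len(fraction)) < dropout
                alt = np.where(drop, 0, alt)
        out.append(
            pd.DataFrame(
                {"ref": total - alt, "alt": alt, "total": total}, index=fraction.index
            )
        )
    return out[0], out[1]


def _jitter_layer_shares(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-lysate realised L1 share drawn Beta(m*kappa, (1-m)*kappa) around
    the organ-mean share m. One draw per lysate: split subsamples of the
    same punch share their draw, so the jitter is biological, not
    technical. Returns the realised expected-fraction matrix."""
    model = config.layer_model()
    weights = config.ploidy_weights()
    kappa = config.layer_concentration
    muts = truth.mutations
    g = muts["fraction_within_layer"].to_numpy()[:, None]
    is_l1 = (muts["layer"] == "L1").to_numpy()[:, None]
    present = truth.expected_vaf.to_numpy() > 0

    shares = {}
    cols = []
    for sample, s in truth.samples.iterrows():
        if s["is_control"]:
            cols.append(0.0)
            continue
        lysate = s["split_group"] or sample
        if lysate not in shares:
            m = layer_read_share("L1", s["organ"], model, weights)
            shares[lysate] = rng.beta(m * kappa, (1 - m) * kappa)
        cols.append(shares[lysate])
    s_l1 = np.asarray(cols)[None, :]
    frac = np.where(is_l1, s_l1, 1.0 - s_l1) * g / 2.0
    frac = np.where(present, frac, 0.0)
    return pd.DataFrame(frac, index=truth.expected_vaf.index,
                        columns=truth.expected_vaf.columns)


def _decoy_tables(
    config: SimConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> CandidateTable | None:
    """Planted artifact sites; each class fails exactly one cascade step."""
    d = config.decoys
    if d.total() == 0:
        return None
    depth = int(round(config.depth_mean))
    sample_ids = list(samples.index)
    controls = list(samples.index[samples["is_control"]])
    focal = [s for s in sample_ids if s not in controls]
    if d.n_missing_controls and len(controls) <= 3:
        raise ValueError("missing-control decoys need more than 3 control samples")
    n = len(sample_ids)

    rows, alts, totals, alt_fs, ref_fs = [], [], [], [], []

    def emit(site_id, cls, alt_vec, total_vec, alt_f=None, ann_override=None,
             n_alleles=2, indel_dist=10_000, alt_allele=None):
        info = _draw_site(rng)
        if alt_allele is not None:
            info["alt"] = alt_allele
        ann = dict(PASSING_ANNOTATIONS)
        if ann_override:
            ann.update(ann_override)
        rows.append(dict(id=site_id, truth_class=cls, n_alleles=n_alleles,
                         indel_dist=indel_dist, **info, **ann))
        alt_vec = np.asarray(alt_vec)
        total_vec = np.asarray(total_vec)
        alts.append(alt_vec)
        totals.append(total_vec)
        alt_fs.append(alt_vec // 2 if alt_f is None else np.asarray(alt_f))
        ref_fs.append((total_vec - alt_vec) // 2)

    def base_counts(carrier_alt=depth // 2, n_carriers=2):
        alt_vec = np.zeros(n, dtype=int)
        total_vec = np.full(n, depth, dtype=int)
        for s in focal[:n_carriers]:
            alt_vec[sample_ids.index(s)] = carrier_alt
        return alt_vec, total_vec

    for i in range(d.n_parental):
        alt_vec = np.full(n, depth // 2, dtype=int)
        total_vec = np.full(n, depth, dtype=int)
        emit(f"DECOY-parental-{i + 1}", "parental", alt_vec, total_vec)
    for i in range(d.n_no_support):
        alt_vec, total_vec = base_counts(carrier_alt=4)
        emit(f"DECOY-nosupp-{i + 1}", "no_support", alt_vec, total_vec)
    for i in range(d.n_missing_controls):
        alt_vec, total_vec = base_counts()
        for s in controls:
            total_vec[sample_ids.index(s)] = 0
            alt_vec[sample_ids.index(s)] = 0
        emit(f"DECOY-miss-{i + 1}", "missing_controls", alt_vec, total_vec)
    for i in range(d.n_strand_bias):
        alt_vec, total_vec = base_counts(carrier_alt=20, n_carriers=3)
        emit(f"DECOY-strand-{i + 1}", "strand_bias", alt_vec, total_vec,
             alt_f=alt_vec.copy())  # every alt read on the forward strand
    for i in range(d.n_triallelic):
        alt_vec, total_vec = base_counts()
        emit(f"DECOY-triallelic-{i + 1}", "triallelic", alt_vec, total_vec,
             n_alleles=3, alt_allele="A,T")
    for i in range(d.n_indel_adjacent):
        alt_vec, total_vec = base_counts()
        emit(f"DECOY-indel-{i + 1}", "indel_adjacent", alt_vec, total_vec,
             indel_dist=int(rng.integers(-5, 6)))
    hard_fails = [
        {"QD": 1.5}, {"QUAL": 20.0}, {"SOR": 5.0}, {"FS": 70.0},
        {"MQ": 30.0}, {"MQRankSum": -13.0}, {"ReadPosRankSum": -9.0},
    ]
    for i in range(d.n_hard_fail):
        alt_vec, total_vec = base_counts()
        emit(f"DECOY-hard-{i + 1}", "hard_fail", alt_vec, total_vec,
             ann_override=hard_fails[i % len(hard_fails)])

    sites = pd.DataFrame(rows).set_index("id")

    def mat(stack):
        return pd.DataFrame(np.vstack(stack), index=sites.index, columns=sample_ids)

    return CandidateTable(sites=sites, alt=mat(alts), total=mat(totals),
                          alt_fwd=mat(alt_fs), ref_fwd=mat(ref_fs))


def _concat_tables(a: CandidateTable, b: CandidateTable) -> CandidateTable:
    sites = pd.concat([a.sites, b.sites])
    return CandidateTable(
        sites=sites,
        alt=pd.concat([a.alt, b.alt]),
        total=pd.concat([a.total, b.total]),
        alt_fwd=pd.concat([a.alt_fwd, b.alt_fwd]),
        ref_fwd=pd.concat([a.ref_fwd, b.ref_fwd]),
    )


def simulate_dataset(
    config: SimConfig, deterministic: bool = False
) -> tuple[SimTruth, CandidateTable]:
    """End-to-end generation: tree, samples, read counts, decoys.

    Split-unit subsamples share their lysate's cell fractions by
    construction (identical expected-fraction columns) and receive
    independent read noise; ``split_dropout`` zeroes truly present
    mutations per subsample at that rate. Fixed seed implies bit-identical
    output.
    """
    truth = simulate_tree(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fraction = truth.expected_fraction
    if not deterministic and config.layer_concentration is not None:
        fraction = _jitter_layer_shares(config, truth, rng)
    truth.realized_vaf = 100.0 * fraction
    table = sample_reads(
        fraction, config.depth_mean, rng=rng,
        deterministic=deterministic, site_info=truth.mutations,
    )
    if not deterministic and config.split_dropout > 0:
        meta = truth.samples
        subs = meta.index[meta["subsample"].notna()]
        present = truth.expected_fraction[subs] > 0
        drop = rng.random(present.shape) < config.split_dropout
        zero = present.to_numpy() & drop
        alt = table.alt.copy()
        alt.loc[:, subs] = np.where(zero, 0, alt[subs].to_numpy())
        fwd = table.alt_fwd.copy()
        fwd.loc[:, subs] = np.minimum(fwd[subs].to_numpy(), alt[subs].to_numpy())
        table = CandidateTable(sites=table.sites, alt=alt, total=table.total,
                               alt_fwd=fwd, ref_fwd=table.ref_fwd)
    decoys = _decoy_tables(config, truth.samples, rng)
    if decoys is not None:
        table = _concat_tables(table, decoys)
    return truth, table
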