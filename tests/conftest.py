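import numpy as np
import pandas as pd
import pytest

import floralineage as fl
from floralineage.simulate import sector_recovery_config


@pytest.fixture(scope="session")
def stochastic_sim():
    """Default two-flower scenario with read noise at ~64x."""
    cfg = fl.default_two_flower_config(seed=11)
    truth, table = fl.simulate_dataset(cfg)
    return cfg, truth, table


@pytest.fixture(scope="session")
def audit_sim():
    """Deterministic (expected-value) reads with planted decoy classes and
    no first-daughter events, so per-step filter removals are exact."""
    f1 = fl.FlowerSpec(name="F1", node=2)
    f2 = fl.FlowerSpec(name="F2", node=3,
                       split_units=("sepal1", "sepal2"))
    cfg = fl.SimConfig(
        seed=5, flowers=(f1, f2), mu_event=0.5,
        decoys=fl.DecoyConfig(
            n_parental=6, n_no_support=4, n_missing_controls=3,
            n_strand_bias=3, n_triallelic=2, n_indel_adjacent=2, n_hard_fail=7,
        ),
    )
    truth, table = fl.simulate_dataset(cfg, deterministic=True)
    return cfg, truth, table


@pytest.fixture(scope="session")
def wedge_sim():
    """Single fully wedged flower in the zero-noise limit."""
    cfg = sector_recovery_config(seed=3, n_wedges=3, muts_per_wedge=16)
    truth, table = fl.simulate_dataset(cfg, deterministic=True)
    return cfg, truth, table


def make_table(alt, total, annotations=None, alt_fwd=None, ref_fwd=None,
               n_alleles=2, indel_dist=10_000):
    """Small CandidateTable builder for filter unit tests."""
    alt = pd.DataFrame(alt)
    total = pd.DataFrame(total)
    n = len(alt)
    sites = pd.DataFrame({
        "chrom": ["Pp01"] * n,
        "pos": np.arange(1, n + 1) * 100,
        "ref": ["A"] * n,
        "alt": ["T"] * n,
        "n_alleles": n_alleles if np.iterable(n_alleles) else [n_alleles] * n,
        "indel_dist": indel_dist if np.iterable(indel_dist) else [indel_dist] * n,
    }, index=alt.index)
    for name, default in [("QD", 25.0), ("QUAL", 900.0), ("SOR", 1.0),
                          ("FS", 2.0), ("MQ", 60.0), ("MQRankSum", 0.0),
                          ("ReadPosRankSum", 0.0)]:
        vals = annotations.get(name, default) if annotations else default
        sites[name] = vals
    if alt_fwd is None:
        alt_fwd = alt // 2
    if ref_fwd is None:
        ref_fwd = (total - alt) // 2
    return fl.CandidateTable(sites=sites, alt=alt, total=total,
                             alt_fwd=pd.DataFrame(alt_fwd),
                             ref_fwd=pd.DataFrame(ref_fwd))
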