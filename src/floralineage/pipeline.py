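"""End-to-end pipeline driver: filter -> de novo calls -> VAF/CVF ->
split QC -> sectors -> lineage inference, with all artifacts written to
an output directory and every parameter echoed into the run log.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as flio
from .filters import CandidateTable, FilterConfig, call_denovo, run_filter_cascade
from .lineage import AnchorSet, assign_group_by_threshold, founder_classify, nest_mutations
from .sectors import (build_sharing_matrix, kmeans_sectors, nj_bootstrap,
                      petal_sharing_chisq, petal_sharing_counts)
from .splitqc import split_qc_summary
from .vaf import cvf_sum_check, vaf_matrix

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, reported with the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, per-module parameters, and the single global seed."""

    variants_path: str | None = None        # VCF, or sites TSV with counts_path
    counts_path: str | None = None
    metadata_path: str | None = None
    anchors: dict | None = None             # {"group1": [...], "group2": [...]}
    out_dir: str = "results"
    seed: int = 0
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    k_per_flower: dict = field(default_factory=dict)
    n_boot: int = 1000
    n_perm: int = 10_000
    assign_threshold: float = 21.0
    min_sector_organs: int = 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def param_dict(self) -> dict:
        """Analysis parameters only — file locations do not change results,
        so they are excluded from the config hash."""
        d = self.to_dict()
        for key in ("variants_path", "counts_path", "metadata_path", "out_dir"):
            d.pop(key)
        return d


def run_pipeline(
    config: RunConfig,
    table: CandidateTable | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis; returns the report bundle.

    Inputs may be given in memory (``table``, ``metadata``) or through the
    paths in ``config``. Stage failures abort with the stage name; stages
    without applicable input (no split pairs, no anchors) are skipped and
    noted in the log. Reruns with an identical config and inputs are
    byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = flio.config_hash(config.param_dict())
    log: list[str] = [f"config_hash={cfg_hash}", f"seed={config.seed}"]
    log.extend(f"param {k}={v}" for k, v in sorted(config.to_dict().items()))
    bundle: dict = {"config_hash": cfg_hash}

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise PipelineError(name, exc) from exc

    def _load():
        nonlocal table, metadata
        if table is None:
            table = flio.read_variants(config.variants_path,
                                       counts_path=config.counts_path)
        if metadata is None:
            metadata = flio.read_metadata(config.metadata_path)

    stage("load", _load)
    controls = list(metadata.index[metadata["is_control"]])

    def _filter():
        retained, report = run_filter_cascade(table, controls, config.filter_config)
        flio.write_table(report.to_frame(), out / "filter_report.tsv",
                         cfg_hash, index=False)
        reasons = pd.Series(report.reasons, name="reason")
        flio.write_table(reasons.to_frame(), out / "filter_reasons.tsv", cfg_hash,
                         index_label="site")
        # review table: retained sites for manual inspection (replaces IGV step)
        flio.write_table(retained.sites, out / "review_sites.tsv", cfg_hash,
                         index_label="site")
        bundle["filter_report"] = report
        bundle["retained"] = retained
        return retained

    retained = stage("filter", _filter)

    def _denovo():
        presence, assignment = call_denovo(retained, metadata, config.filter_config)
        flio.write_table(presence, out / "presence.tsv", cfg_hash,
                         index_label="mutation")
        flio.write_table(assignment.to_frame(), out / "denovo_flowers.tsv", cfg_hash,
                         index_label="mutation")
        bundle["presence"] = presence
        bundle["denovo"] = assignment
        return presence, assignment

    presence, denovo = stage("denovo", _denovo)

    def _vaf():
        vaf = vaf_matrix(retained.alt, retained.total)
        flio.write_vaf_matrix(vaf, out / "vaf_matrix.tsv", cfg_hash)
        bundle["vaf"] = vaf
        return vaf

    vaf = stage("vaf", _vaf)

    if metadata["split_group"].notna().any():
        def _split():
            qc = split_qc_summary(vaf, presence, metadata)
            flio.write_table(qc["labels"], out / "splitqc_labels.tsv", cfg_hash,
                             index=False)
            summary = {"concordance": qc["concordance"],
                       "n_pairs": qc["n_pairs"], "n_mutations": qc["n_mutations"]}
            if qc["deming"] is not None:
                summary["deming"] = dataclasses.asdict(qc["deming"])
            (out / "splitqc_summary.json").write_text(json.dumps(summary, indent=2))
            bundle["splitqc"] = qc
            log.append(f"splitqc: concordance {qc['concordance']['concordance_pct']:.1f}%")
            return qc
        stage("splitqc", _split)
    else:
        log.append("splitqc: skipped (no split pairs in metadata)")

    flowers = sorted(set(metadata["flower"].dropna()))

    def _sectors():
        results = {}
        for flower in flowers:
            sharing = build_sharing_matrix(presence, metadata, flower,
                                           config.min_sector_organs)
            if sharing.empty:
                log.append(f"sectors[{flower}]: no sectoring information")
                continue
            k = config.k_per_flower.get(flower, 3)
            k = min(k, len(sharing))
            part = kmeans_sectors(sharing, k, seed=config.seed)
            try:
                tree, supports = nj_bootstrap(sharing, n_boot=config.n_boot,
                                              seed=config.seed)
                newick = str(tree).strip()
                (out / f"sectors_{flower}.nwk").write_text(newick + "\n")
            except ValueError as exc:
                tree, supports, newick = None, {}, None
                log.append(f"sectors[{flower}]: dendrogram undefined ({exc})")
            flio.write_table(part.to_frame(), out / f"sectors_{flower}_kmeans.tsv",
                             cfg_hash)
            counts = petal_sharing_counts(sharing, metadata)
            results[flower] = {"sharing": sharing, "kmeans": part, "tree": tree,
                               "supports": supports, "petal_counts": counts}
        all_counts = {
            key: sum(r["petal_counts"][key] for r in results.values())
            for key in ("petal_stamen", "petal_sepal", "petal_petal")
        } if results else None
        if all_counts and sum(all_counts.values()) > 0:
            chisq = petal_sharing_chisq(all_counts)
            (out / "petal_sharing_chisq.json").write_text(json.dumps(chisq, indent=2))
            bundle["petal_chisq"] = chisq
        bundle["sectors"] = results
        return results

    stage("sectors", _sectors)

    if config.anchors:
        def _lineages():
            anchors = AnchorSet(group1=tuple(config.anchors["group1"]),
                                group2=tuple(config.anchors["group2"]))
            candidates = [m for m in vaf.index
                          if m not in anchors.group1 + anchors.group2]
            nesting = nest_mutations(vaf, candidates, anchors,
                                     n_perm=config.n_perm, seed=config.seed)
            assign = assign_group_by_threshold(vaf, metadata,
                                               threshold=config.assign_threshold)
            flio.write_table(nesting, out / "nesting.tsv", cfg_hash,
                             index_label="mutation")
            flio.write_table(assign, out / "lineage_assignment.tsv", cfg_hash,
                             index_label="mutation")
            sums = {}
            for g1 in anchors.group1:
                for g2 in anchors.group2:
                    try:
                        chk = cvf_sum_check(vaf, (g1, g2))
                        sums[f"{g1}+{g2}"] = {"mean": chk["mean"],
                                              "n": chk["n_samples"]}
                    except ValueError:
                        continue
            (out / "cvf_sums.json").write_text(json.dumps(sums, indent=2))
            bundle["nesting"] = nesting
            bundle["assignment"] = assign
            bundle["cvf_sums"] = sums
            return nesting
        stage("lineages", _lineages)
    else:
        log.append("lineages: skipped (no anchors configured)")

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    bundle["log"] = log
    return bundle
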