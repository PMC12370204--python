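"""File formats: VCF and TSV candidate tables, metadata, VAF matrices.

Coordinates are 1-based inclusive everywhere (VCF convention). Organ
codes are {sepal, petal, stamen, carpel, leaf}; samples are named
``F<flower>-<organ><index>`` with an ``-a``/``-b`` suffix for split-pair
subsamples. Missing VAF is written as ``NA``, never 0. Numeric output
tables carry a header line naming the config hash when one is supplied.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .filters import ANNOTATION_FIELDS, CandidateTable

__all__ = [
    "config_hash",
    "read_variants",
    "write_variants_tsv",
    "write_variants_vcf",
    "read_metadata",
    "write_metadata",
    "write_vaf_matrix",
    "read_vaf_matrix",
    "write_table",
]

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "n_alleles", "indel_dist",
                *ANNOTATION_FIELDS]
CONTIGS = {f"Pp{i:02d}": 30_000_000 for i in range(1, 9)}


def config_hash(config) -> str:
    """Short stable hash of a config mapping, echoed into output headers."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, cfg_hash: str | None = None, **kwargs) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", **kwargs)


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


# ---------------------------------------------------------------- TSV dialect

def write_variants_tsv(table: CandidateTable, sites_path, counts_path,
                       cfg_hash: str | None = None) -> None:
    """Two files: per-site annotations, and long-format per-sample counts
    (site, sample, ref_reads, alt_reads, total, alt_fwd, ref_fwd)."""
    cols = [c for c in SITE_COLUMNS if c in table.sites.columns]
    write_table(table.sites[cols], sites_path, cfg_hash, index_label="site")
    long = []
    for sample in table.samples:
        df = pd.DataFrame({
            "site": table.site_ids,
            "sample": sample,
            "ref_reads": (table.total[sample] - table.alt[sample]).to_numpy(),
            "alt_reads": table.alt[sample].to_numpy(),
            "total": table.total[sample].to_numpy(),
            "alt_fwd": (
                table.alt_fwd[sample].to_numpy()
                if table.alt_fwd is not None else np.nan
            ),
            "ref_fwd": (
                table.ref_fwd[sample].to_numpy()
                if table.ref_fwd is not None else np.nan
            ),
        })
        long.append(df)
    write_table(pd.concat(long, ignore_index=True), counts_path, cfg_hash, index=False)


def _read_variants_tsv(sites_path, counts_path) -> CandidateTable:
    sites = _read_table(sites_path).set_index("site")
    long = _read_table(counts_path)
    sample_order = list(pd.unique(long["sample"]))
    alt = long.pivot(index="site", columns="sample", values="alt_reads")
    total = long.pivot(index="site", columns="sample", values="total")
    alt_fwd = long.pivot(index="site", columns="sample", values="alt_fwd")
    ref_fwd = long.pivot(index="site", columns="sample", values="ref_fwd")
    order = sites.index
    has_strand = alt_fwd.notna().all().all()
    return CandidateTable(
        sites=sites,
        alt=alt.loc[order, sample_order].astype(int),
        total=total.loc[order, sample_order].astype(int),
        alt_fwd=alt_fwd.loc[order, sample_order].astype(int) if has_strand else None,
        ref_fwd=ref_fwd.loc[order, sample_order].astype(int) if has_strand else None,
    )


# ---------------------------------------------------------------- VCF dialect

def write_variants_vcf(table: CandidateTable, path) -> None:
    """Minimal VCF: one record per site, per-sample AD plus strand-split
    ADF/ADR, site annotations in INFO. Multiallelic sites keep their full
    ALT list so the triallelic filter can re-derive allele counts."""
    header = pysam.VariantHeader()
    for contig, length in CONTIGS.items():
        header.contigs.add(contig, length=length)
    for name in ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
        header.info.add(name, 1, "Float", f"{name} site annotation")
    header.info.add("INDELDIST", 1, "Integer", "Signed distance to nearest INDEL")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt...)")
    header.formats.add("ADF", "R", "Integer", "Forward-strand allelic depths")
    header.formats.add("ADR", "R", "Integer", "Reverse-strand allelic depths")
    for sample in table.samples:
        header.add_sample(str(sample))
    # site ids survive the round trip through the ID column
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        order = table.sites.sort_values(["chrom", "pos"]).index
        for sid in order:
            s = table.sites.loc[sid]
            alts = tuple(str(s["alt"]).split(","))
            rec = vcf.new_record(
                contig=s["chrom"], start=int(s["pos"]) - 1,
                alleles=(s["ref"], *alts), id=str(sid),
            )
            rec.qual = float(s["QUAL"])
            for name in ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
                val = s[name]
                if pd.notna(val):
                    rec.info[name] = float(val)
            if pd.notna(s["indel_dist"]):
                rec.info["INDELDIST"] = int(s["indel_dist"])
            n_alt = len(alts)
            for sample in table.samples:
                alt_n = int(table.alt.loc[sid, sample])
                tot = int(table.total.loc[sid, sample])
                ref_n = tot - alt_n
                pad = [0] * (n_alt - 1)  # counts beyond the first alt not tracked
                rec.samples[str(sample)]["DP"] = tot
                rec.samples[str(sample)]["AD"] = [ref_n, alt_n, *pad]
                if table.alt_fwd is not None:
                    af = int(table.alt_fwd.loc[sid, sample])
                    rf = int(table.ref_fwd.loc[sid, sample])
                    rec.samples[str(sample)]["ADF"] = [rf, af, *pad]
                    rec.samples[str(sample)]["ADR"] = [ref_n - rf, alt_n - af, *pad]
            vcf.write(rec)


def _read_variants_vcf(path) -> CandidateTable:
    rows, alt_rows, tot_rows, af_rows, rf_rows = [], [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            sid = rec.id or f"{rec.chrom}:{rec.pos}"
            alts = rec.alts or ()
            def info_get(key):
                try:
                    return rec.info.get(key, np.nan)
                except (KeyError, ValueError):  # field absent from the header
                    return np.nan

            row = {
                "site": sid, "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": ",".join(alts),
                "n_alleles": 1 + len(alts),
                "indel_dist": info_get("INDELDIST"),
                "QUAL": rec.qual,
            }
            for name in ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
                row[name] = info_get(name)
            rows.append(row)
            ad = {s: rec.samples[s].get("AD") for s in samples}
            alt_rows.append([ad[s][1] if ad[s] is not None else 0 for s in samples])
            tot_rows.append([rec.samples[s].get("DP", 0) or 0 for s in samples])
            adf = {s: rec.samples[s].get("ADF") for s in samples}
            if all(v is not None for v in adf.values()):
                af_rows.append([adf[s][1] for s in samples])
                rf_rows.append([adf[s][0] for s in samples])
    sites = pd.DataFrame(rows).set_index("site")
    idx = sites.index
    alt = pd.DataFrame(alt_rows, index=idx, columns=samples)
    total = pd.DataFrame(tot_rows, index=idx, columns=samples)
    has_strand = len(af_rows) == len(sites)
    return CandidateTable(
        sites=sites, alt=alt, total=total,
        alt_fwd=pd.DataFrame(af_rows, index=idx, columns=samples) if has_strand else None,
        ref_fwd=pd.DataFrame(rf_rows, index=idx, columns=samples) if has_strand else None,
    )


def read_variants(path, dialect: str | None = None, counts_path=None) -> CandidateTable:
    """Load candidate sites from VCF or the TSV pair.

    ``dialect`` is inferred from the extension when omitted (``.vcf`` vs
    ``.tsv``); the TSV dialect needs the companion ``counts_path``.
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if dialect == "vcf":
        return _read_variants_vcf(path)
    if counts_path is None:
        raise ValueError("TSV dialect requires counts_path")
    return _read_variants_tsv(path, counts_path)


# ----------------------------------------------------------------- metadata

def write_metadata(metadata: pd.DataFrame, path, cfg_hash: str | None = None) -> None:
    write_table(metadata, path, cfg_hash, index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    meta = _read_table(path).set_index("sample")
    if "is_control" in meta.columns:
        meta["is_control"] = meta["is_control"].astype(bool)
    return meta


# ---------------------------------------------------------------- VAF matrix

def write_vaf_matrix(vaf: pd.DataFrame, path, cfg_hash: str | None = None) -> None:
    """Mutations as rows, samples as columns, missing written as NA."""
    write_table(vaf, path, cfg_hash, index_label="mutation")


def read_vaf_matrix(path) -> pd.DataFrame:
    return _read_table(path).set_index("mutation")


# ------------------------------------------------------------------- config

def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
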