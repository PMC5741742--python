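"""Parental-origin calling from per-SNP allele read counts.

Strain-distinguishing SNPs let transcript reads in a hybrid clone be
assigned to the ES-parent or the fibroblast-parent genome. The pipeline
is: (1) keep only informative sites — homozygous-divergent between the two
parental lines in their own transcriptomes; (2) call each SNP in each
clone mono- or biallelic from its allele counts; (3) roll per-SNP calls up
to a per-gene verdict: expressed from ONE_PARENT, from BOTH, or MIXED
(some SNPs monoallelic, some biallelic).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import round_half_up

__all__ = [
    "ONE_ES",
    "ONE_FIB",
    "BOTH",
    "NO_DATA",
    "ONE_PARENT",
    "MIXED",
    "ORIGIN_CLASSES",
    "read_allele_counts",
    "write_allele_counts",
    "read_snp_sites",
    "write_snp_sites",
    "read_snp_vcf",
    "filter_informative_snps",
    "call_snp",
    "call_clone_snps",
    "classify_gene_origin",
    "gene_origin_table",
    "summarize_origin",
]

# per-SNP calls
ONE_ES = "ONE_ES"
ONE_FIB = "ONE_FIB"
BOTH = "BOTH"
NO_DATA = "NO_DATA"
# per-gene classes
ONE_PARENT = "ONE_PARENT"
MIXED = "MIXED"
ORIGIN_CLASSES = (ONE_PARENT, BOTH, MIXED)

SITE_COLUMNS = ("snp_id", "chromosome", "position", "gene_id", "allele_ES", "allele_FIB")
COUNT_COLUMNS = ("snp_id", "sample_id", "reads_ES_allele", "reads_FIB_allele")


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "sample_id": str})
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"allele-count table missing columns: {sorted(missing)}")
    if counts.duplicated(["snp_id", "sample_id"]).any():
        raise ValueError("duplicate (snp_id, sample_id) rows in allele counts")
    if (counts[["reads_ES_allele", "reads_FIB_allele"]] < 0).any().any():
        raise ValueError("negative read counts")
    return counts


def write_allele_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.loc[:, list(COUNT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_snp_sites(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chromosome": str})
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise ValueError(f"SNP site table missing columns: {sorted(missing)}")
    return sites


def write_snp_sites(sites: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in sites.columns if c in SITE_COLUMNS or c == "informative"]
    sites.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_snp_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read sites and allele counts from a minimal VCF dialect.

    Convention: REF is the ES-parent strain allele, ALT the fibroblast
    strain allele; ``INFO/GENE`` names the gene the site maps to; the
    per-sample ``AD`` field carries (ref, alt) read depths. Coordinates
    are 1-based as in any VCF.
    """
    import pysam

    site_rows, count_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"site {rec.id or rec.pos}: exactly one ALT required")
            snp_id = rec.id or f"{rec.chrom}_{rec.pos}"
            site_rows.append(
                {
                    "snp_id": snp_id,
                    "chromosome": rec.chrom,
                    "position": rec.pos,
                    "gene_id": rec.info["GENE"],
                    "allele_ES": rec.ref,
                    "allele_FIB": rec.alts[0],
                }
            )
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None:
                    continue
                count_rows.append(
                    {
                        "snp_id": snp_id,
                        "sample_id": s,
                        "reads_ES_allele": int(ad[0]),
                        "reads_FIB_allele": int(ad[1]),
                    }
                )
    return (
        pd.DataFrame(site_rows, columns=list(SITE_COLUMNS)),
        pd.DataFrame(count_rows, columns=list(COUNT_COLUMNS)),
    )


def _pooled_parent_counts(
    counts: pd.DataFrame, meta: pd.DataFrame, role: str
) -> pd.DataFrame:
    samples = meta.loc[meta["role"] == role, "sample_id"]
    sub = counts[counts["sample_id"].isin(samples)]
    return sub.groupby("snp_id")[["reads_ES_allele", "reads_FIB_allele"]].sum()


def filter_informative_snps(
    sites: pd.DataFrame,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_parent_coverage: int = 10,
    max_minor_fraction: float = 0.05,
) -> pd.DataFrame:
    """Keep sites homozygous-divergent between the parental transcriptomes.

    A site survives iff, in each parental line (replicates pooled), total
    coverage reaches ``min_parent_coverage`` and the foreign allele makes
    up at most ``max_minor_fraction`` of reads. Heterozygous parental sites
    and sites without parental data are dropped.
    """
    es = _pooled_parent_counts(counts, meta, "parent_ES")
    fib = _pooled_parent_counts(counts, meta, "parent_FIB")
    keep = []
    for row in sites.itertuples():
        ok = True
        for pooled, own in ((es, "reads_ES_allele"), (fib, "reads_FIB_allele")):
            if row.snp_id not in pooled.index:
                ok = False
                break
            r = pooled.loc[row.snp_id]
            total = int(r["reads_ES_allele"] + r["reads_FIB_allele"])
            foreign = total - int(r[own])
            if total < min_parent_coverage or foreign > max_minor_fraction * total:
                ok = False
                break
        keep.append(ok)
    return sites[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def call_snp(
    reads_es: int,
    reads_fib: int,
    min_allele_reads: int = 2,
    min_minor_fraction: float = 0.1,
) -> str:
    """Mono-/biallelic call for one SNP in one clone.

    ``BOTH`` needs every allele at ``min_allele_reads`` reads and the minor
    allele at ``min_minor_fraction`` of the total; otherwise the majority
    allele wins, or ``NO_DATA`` below the read floor.
    """
    total = reads_es + reads_fib
    if total < min_allele_reads:
        return NO_DATA
    minor = min(reads_es, reads_fib)
    if minor >= min_allele_reads and minor / total >= min_minor_fraction:
        return BOTH
    return ONE_ES if reads_es >= reads_fib else ONE_FIB


def call_clone_snps(
    sites: pd.DataFrame,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    clone_id: str,
    min_allele_reads: int = 2,
    min_minor_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-SNP calls for one clone, replicate reads pooled per SNP."""
    samples = meta.loc[meta["line_id"] == clone_id, "sample_id"]
    if samples.empty:
        raise KeyError(f"unknown clone: {clone_id!r}")
    sub = counts[counts["sample_id"].isin(samples) & counts["snp_id"].isin(sites["snp_id"])]
    pooled = sub.groupby("snp_id")[["reads_ES_allele", "reads_FIB_allele"]].sum()
    pooled = pooled.reindex(sites["snp_id"], fill_value=0)
    calls = [
        call_snp(int(es), int(fib), min_allele_reads, min_minor_fraction)
        for es, fib in zip(pooled["reads_ES_allele"], pooled["reads_FIB_allele"])
    ]
    return pd.DataFrame(
        {
            "snp_id": sites["snp_id"].to_numpy(),
            "gene_id": sites["gene_id"].to_numpy(),
            "clone_id": clone_id,
            "call": calls,
        }
    )


def classify_gene_origin(calls: Iterable[str], strict: bool = False) -> dict | None:
    """Aggregate one gene's per-SNP calls into an origin verdict.

    ``BOTH`` if every SNP with data is biallelic; ``ONE_PARENT`` if every
    SNP is monoallelic (a mixture of ONE_ES and ONE_FIB still counts as
    one-parent unless ``strict``, where it becomes ``MIXED``); ``MIXED``
    otherwise. Returns None when no SNP has data.
    """
    informative = [c for c in calls if c != NO_DATA]
    if not informative:
        return None
    n_bi = sum(c == BOTH for c in informative)
    if n_bi == len(informative):
        origin = BOTH
    elif n_bi == 0:
        mono = {c for c in informative}
        origin = MIXED if strict and len(mono) > 1 else ONE_PARENT
    else:
        origin = MIXED
    return {
        "origin": origin,
        "n_snps_informative": len(informative),
        "n_snps_biallelic": n_bi,
    }


def gene_origin_table(
    snp_calls: pd.DataFrame, strict: bool = False
) -> pd.DataFrame:
    """Per-gene origin calls for one clone from a per-SNP call table."""
    rows = []
    for (gene, clone), grp in snp_calls.groupby(["gene_id", "clone_id"], sort=True):
        res = classify_gene_origin(grp["call"], strict=strict)
        if res is None:
            continue
        rows.append({"gene_id": gene, "clone_id": clone, **res})
    return pd.DataFrame(
        rows,
        columns=["gene_id", "clone_id", "origin", "n_snps_informative", "n_snps_biallelic"],
    )


def summarize_origin(
    calls: pd.DataFrame | Mapping[str, int], rounding: int = 1
) -> pd.DataFrame:
    """Counts and percentages per origin class for one clone.

    Accepts a per-gene call table (column ``origin``) or a mapping of
    class -> count.
    """
    if isinstance(calls, pd.DataFrame):
        if calls.empty:
            raise ValueError("empty origin call set")
        counts = {c: int((calls["origin"] == c).sum()) for c in ORIGIN_CLASSES}
    else:
        counts = {c: int(calls.get(c, 0)) for c in ORIGIN_CLASSES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty origin call set")
    return pd.DataFrame(
        [
            {
                "origin": c,
                "n_genes": counts[c],
                "percent": round_half_up(100.0 * counts[c] / total, rounding),
            }
            for c in ORIGIN_CLASSES
        ]
    )
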