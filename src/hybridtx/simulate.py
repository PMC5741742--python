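"""Synthetic hybrid-clone expression and allele-count generator.

Emulates the study design: two parental lines (an ES-cell line and a
fibroblast line), each in diploid and tetraploid form, plus four hybrid
clones (two with an ES-like phenotype, two fibroblast-like), every line
measured in replicate. Ground-truth pool, dominance-group and
parental-origin labels are recorded so that every downstream stage can be
scored exactly.

Geometry of the truth labels (all on the FPKM scale, floor = 10):

* pool-a genes are low (< floor) in every line;
* pool-b genes share one expressed mean across all lines;
* pool-c genes differ between parents by less than 2-fold, hybrids sit at
  the geometric midpoint;
* pool-d genes differ by more than 2-fold; per clone the hybrid mean is
  placed at the phenotype-matching parent (group 1), the geometric
  midpoint (group 2), the opposite parent (group 3), outside the parental
  range by a safe margin (group 4), or below the floor (low-in-clone).

Genes destined for group 2 in any clone have their parental fold change
resampled above ``group2_min_log2_fold`` so the midpoint is genuinely
outside both 2-fold proximity bands; a fold too small to realise the
requested geometry is never emitted with an inconsistent label.

Replicate noise is multiplicative lognormal (FPKM is positive and
heavy-tailed); allele counts are binomial over a per-SNP coverage drawn
from ``coverage_law``, with hybrids at a 1:1 parental genome ratio so
biallelic genes have allele fraction 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import META_COLUMNS, write_expression, write_sample_sheet, read_expression
from .groups import GROUP1, GROUP2, GROUP3, GROUP4, LOW_IN_CLONE, GROUP_LABELS
from .origin import (
    BOTH,
    MIXED,
    ONE_PARENT,
    read_allele_counts,
    read_snp_sites,
    write_allele_counts,
    write_snp_sites,
)
from .pools import POOL_A, POOL_B, POOL_C, POOL_D

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_expression",
    "simulate_allele_counts",
    "write_fixture",
    "read_fixture",
    "DEFAULT_GROUP_PROPORTIONS",
    "DEFAULT_POOL_PROPORTIONS",
]

# Pool sizes of the motivating experiment (low / equal / minor / differential),
# used as default mixing proportions.
_POOL_COUNTS = {POOL_A: 14794, POOL_B: 2274, POOL_C: 2988, POOL_D: 2848}
DEFAULT_POOL_PROPORTIONS = {k: v / sum(_POOL_COUNTS.values()) for k, v in _POOL_COUNTS.items()}

# Dominance-group fractions of the differential pool observed in an ES-like
# and a fibroblast-like clone (tme14 and tmf2 of the motivating experiment).
_ES_GROUP_COUNTS = {GROUP1: 933, GROUP2: 607, GROUP3: 293, GROUP4: 460, LOW_IN_CLONE: 555}
_FIB_GROUP_COUNTS = {GROUP1: 828, GROUP2: 704, GROUP3: 391, GROUP4: 488, LOW_IN_CLONE: 437}
DEFAULT_GROUP_PROPORTIONS = {
    "ES_like": {k: v / 2848 for k, v in _ES_GROUP_COUNTS.items()},
    "FIB_like": {k: v / 2848 for k, v in _FIB_GROUP_COUNTS.items()},
}

DEFAULT_ORIGIN_PROPORTIONS = {ONE_PARENT: 0.011, BOTH: 0.968, MIXED: 0.021}

PARENT_LINES = (
    ("tauGFP", "parent_ES", "2N", "NA"),
    ("tauGFP4N", "parent_ES", "4N", "NA"),
    ("m5S", "parent_FIB", "2N", "NA"),
    ("m5S4N8", "parent_FIB", "4N", "NA"),
)

_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 20)) + ("chrX",)
_BASES = np.array(list("ACGT"))


def _check_proportions(p: Mapping[str, float], name: str) -> None:
    if any(v < 0 for v in p.values()):
        raise ValueError(f"{name} has negative entries")
    if abs(sum(p.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(p.values())!r})")


@dataclass
class SimulationConfig:
    """Study-design parameters for the generator.

    ``noise_sd`` is the standard deviation, in natural-log units, of the
    multiplicative lognormal replicate noise. ``fold_law`` is the support
    of the uniform |log2 fold| drawn for pool-d genes; it must stay above
    1 (the 2-fold differential threshold). ``label_resample_prob`` is the
    probability that a clone re-draws a gene's dominance label instead of
    inheriting the label shared by clones of its phenotype; same-phenotype
    clones therefore agree on most labels, as observed in the motivating
    experiment, while per-clone marginal proportions are preserved.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    clone_specs: Sequence[tuple[str, str]] = (
        ("tme14", "ES_like"),
        ("tme17", "ES_like"),
        ("tmf2", "FIB_like"),
        ("tmf5", "FIB_like"),
    )
    group_proportions: Mapping[str, Mapping[str, float]] | None = None
    pool_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POOL_PROPORTIONS)
    )
    base_expression_law: tuple[float, float] = (1.8, 0.4)  # log10 loc/scale
    fold_law: tuple[float, float] = (1.2, 5.0)  # |log2| uniform support
    minor_fold_law: tuple[float, float] = (0.3, 0.8)
    noise_sd: float = 0.05
    snp_per_gene_law: tuple[str, float] = ("poisson", 2.0)
    coverage_law: tuple[str, float] = ("poisson", 100.0)
    origin_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORIGIN_PROPORTIONS)
    )
    biallelic_fraction: float = 0.5  # ES-allele fraction at biallelic SNPs (1:1 genomes)
    contamination_rate: float = 0.0
    parent_het_rate: float = 0.0
    fpkm_floor: float = 10.0
    group2_min_log2_fold: float = 3.0
    group4_fold: float = 4.0
    group4_direction: str = "up"  # "up" | "down" | "random"
    label_resample_prob: float = 0.2
    pool_d_lower_parent_range: tuple[float, float] = (15.0, 200.0)
    low_gene_range: tuple[float, float] = (0.05, 5.0)
    low_in_clone_range: tuple[float, float] = (0.5, 4.0)
    ploidy_distortion_sd: float = 0.0  # lognormal per-gene factor on 2N parents
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes and n_replicates must be positive")
        if not self.clone_specs:
            raise ValueError("at least one hybrid clone is required")
        for _, phen in self.clone_specs:
            if phen not in {"ES_like", "FIB_like"}:
                raise ValueError(f"clone phenotype must be ES_like/FIB_like, got {phen!r}")
        _check_proportions(self.pool_proportions, "pool_proportions")
        _check_proportions(self.origin_proportions, "origin_proportions")
        for clone_id, props in self._clone_group_proportions().items():
            _check_proportions(props, f"group_proportions[{clone_id}]")
        if not self.fold_law[0] > 1.0:
            raise ValueError("fold_law support must exceed 1 in |log2|")
        if not (0 < self.minor_fold_law[0] <= self.minor_fold_law[1] < 1.0):
            raise ValueError("minor_fold_law support must lie strictly inside (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.group2_min_log2_fold > self.fold_law[1]:
            raise ValueError("group2_min_log2_fold exceeds the fold_law upper bound")
        if self.group4_direction not in {"up", "down", "random"}:
            raise ValueError("group4_direction must be 'up', 'down' or 'random'")

    def _clone_group_proportions(self) -> dict[str, dict[str, float]]:
        """Per-clone label proportions, resolved from the per-phenotype default."""
        props = self.group_proportions or {}
        out = {}
        for clone_id, phen in self.clone_specs:
            if clone_id in props:
                out[clone_id] = dict(props[clone_id])
            elif phen in props:
                out[clone_id] = dict(props[phen])
            else:
                out[clone_id] = dict(DEFAULT_GROUP_PROPORTIONS[phen])
        return out


@dataclass
class SimulationTruth:
    """Ground-truth labels and latent means behind a simulated dataset."""

    pools: pd.Series  # gene_id -> pool label
    groups: pd.DataFrame  # gene_id, clone_id, group (pool-d genes only)
    origins: pd.DataFrame  # gene_id, clone_id, origin (genes with >=1 SNP)
    sites: pd.DataFrame  # snp table with an `informative` flag
    snp_clone_p: pd.DataFrame  # snp_id, clone_id, p_es (latent allele fraction)
    line_means: pd.DataFrame  # noiseless per-line means, genes x lines


def _draw_counts(rng: np.random.Generator, law: tuple[str, float], size: int) -> np.ndarray:
    kind, param = law
    if kind == "poisson":
        return rng.poisson(param, size=size)
    if kind == "fixed":
        return np.full(size, int(param))
    raise ValueError(f"unknown count law: {kind!r}")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=size)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate the expression matrix, sample sheet and ground truth."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes
    genes = pd.Index([f"g{i:06d}" for i in range(n)], name="gene_id")
    floor = config.fpkm_floor

    pool_labels = np.array(list(config.pool_proportions))
    pools = rng.choice(pool_labels, size=n, p=[config.pool_proportions[k] for k in pool_labels])

    is_a = pools == POOL_A
    is_b = pools == POOL_B
    is_c = pools == POOL_C
    is_d = pools == POOL_D

    loc, scale = config.base_expression_law
    base = np.maximum(10.0 ** rng.normal(loc, scale, size=n), 2.0 * floor)

    m_es = np.empty(n)
    m_fib = np.empty(n)
    mid = np.empty(n)

    low_means = _log_uniform(rng, *config.low_gene_range, size=n)
    m_es[is_a] = m_fib[is_a] = mid[is_a] = low_means[is_a]
    m_es[is_b] = m_fib[is_b] = mid[is_b] = base[is_b]

    f_c = rng.uniform(*config.minor_fold_law, size=n) * rng.choice([-1.0, 1.0], size=n)
    m_es[is_c] = base[is_c] * 2.0 ** (f_c[is_c] / 2.0)
    m_fib[is_c] = base[is_c] * 2.0 ** (-f_c[is_c] / 2.0)
    mid[is_c] = base[is_c]

    # pool-d geometry: lower parent in a comfortably-expressed range, fold > 2
    fold = rng.uniform(*config.fold_law, size=n)
    lower = _log_uniform(rng, *config.pool_d_lower_parent_range, size=n)
    es_is_high = rng.random(n) < 0.5

    clone_ids = [c for c, _ in config.clone_specs]
    phen_of = dict(config.clone_specs)
    clone_props = config._clone_group_proportions()

    # shared phenotype-level label, re-drawn per clone with label_resample_prob
    d_idx = np.flatnonzero(is_d)
    group_of: dict[str, np.ndarray] = {}
    phen_props = {}
    for phen in dict.fromkeys(p for _, p in config.clone_specs):
        members = [clone_props[c] for c in clone_ids if phen_of[c] == phen]
        phen_props[phen] = {
            lab: float(np.mean([m[lab] for m in members])) for lab in GROUP_LABELS
        }
    shared = {}
    labels_arr = np.array(GROUP_LABELS)
    for phen, props in phen_props.items():
        shared[phen] = rng.choice(
            labels_arr, size=len(d_idx), p=[props[lab] for lab in GROUP_LABELS]
        )
    for clone in clone_ids:
        phen = phen_of[clone]
        lab = shared[phen].copy()
        redraw = rng.random(len(d_idx)) < config.label_resample_prob
        if redraw.any():
            props = clone_props[clone]
            lab[redraw] = rng.choice(
                labels_arr, size=int(redraw.sum()), p=[props[l] for l in GROUP_LABELS]
            )
        group_of[clone] = lab

    # realizability: group-2 geometry needs the midpoint outside both 2-fold
    # bands; resample the fold for genes slated group 2 in any clone
    needs_g2 = np.zeros(len(d_idx), dtype=bool)
    for clone in clone_ids:
        needs_g2 |= group_of[clone] == GROUP2
    too_small = needs_g2 & (fold[d_idx] < config.group2_min_log2_fold)
    if too_small.any():
        logger.info(
            "resampling parental fold for %d genes to realise group-2 geometry",
            int(too_small.sum()),
        )
        fold[d_idx[too_small]] = rng.uniform(
            config.group2_min_log2_fold, config.fold_law[1], size=int(too_small.sum())
        )

    upper = lower * 2.0 ** fold
    m_es[is_d] = np.where(es_is_high[is_d], upper[is_d], lower[is_d])
    m_fib[is_d] = np.where(es_is_high[is_d], lower[is_d], upper[is_d])
    mid[is_d] = lower[is_d] * 2.0 ** (fold[is_d] / 2.0)

    # group-4 "novel" level: beyond the parental range by group4_fold
    g4_up = np.ones(n, dtype=bool)
    if config.group4_direction == "down":
        g4_up[:] = False
    elif config.group4_direction == "random":
        g4_up = rng.random(n) < 0.5
    g4_down_ok = lower / config.group4_fold >= 1.2 * floor
    fell_back = is_d & ~g4_up & ~g4_down_ok
    if fell_back.any():
        logger.info(
            "group-4 'down' placement would drop %d genes below the floor; using 'up'",
            int(fell_back.sum()),
        )
    g4_up |= ~g4_down_ok
    novel = np.where(g4_up, upper * config.group4_fold, lower / config.group4_fold)

    low_in_clone = _log_uniform(rng, *config.low_in_clone_range, size=n)

    # per-line noiseless means
    means = {}
    for line, role, ploidy, _ in PARENT_LINES:
        m = m_es if role == "parent_ES" else m_fib
        if ploidy == "2N" and config.ploidy_distortion_sd > 0:
            m = m * np.exp(rng.normal(0.0, config.ploidy_distortion_sd, size=n))
        means[line] = m.copy()
    for clone in clone_ids:
        phen = phen_of[clone]
        match = m_es if phen == "ES_like" else m_fib
        other = m_fib if phen == "ES_like" else m_es
        cm = mid.copy()  # pools a/b/c: hybrids at the shared/midpoint mean
        lab = group_of[clone]
        cm_d = np.select(
            [lab == GROUP1, lab == GROUP2, lab == GROUP3, lab == GROUP4, lab == LOW_IN_CLONE],
            [match[d_idx], mid[d_idx], other[d_idx], novel[d_idx], low_in_clone[d_idx]],
        )
        cm[d_idx] = cm_d
        means[clone] = cm
    line_means_df = pd.DataFrame(means, index=genes)

    # samples: replicates with multiplicative lognormal noise
    sample_rows, cols = [], {}
    line_meta = list(PARENT_LINES) + [
        (c, "hybrid", "near4N", phen_of[c]) for c in clone_ids
    ]
    for line, role, ploidy, phen in line_meta:
        for r in range(1, config.n_replicates + 1):
            sid = f"{line}_r{r}"
            noise = (
                np.exp(rng.normal(0.0, config.noise_sd, size=n))
                if config.noise_sd > 0
                else 1.0
            )
            cols[sid] = means[line] * noise
            sample_rows.append(
                {
                    "sample_id": sid,
                    "line_id": line,
                    "role": role,
                    "ploidy": ploidy,
                    "phenotype": phen,
                    "replicate": r,
                }
            )
    matrix = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(sample_rows, columns=list(META_COLUMNS))

    groups_df = pd.DataFrame(
        [
            {"gene_id": genes[i], "clone_id": clone, "group": group_of[clone][k]}
            for clone in clone_ids
            for k, i in enumerate(d_idx)
        ],
        columns=["gene_id", "clone_id", "group"],
    )

    sites, origins, snp_clone_p = _simulate_snp_truth(config, rng, genes, clone_ids)

    truth = SimulationTruth(
        pools=pd.Series(pools, index=genes, name="pool"),
        groups=groups_df,
        origins=origins,
        sites=sites,
        snp_clone_p=snp_clone_p,
        line_means=line_means_df,
    )
    return matrix, meta, truth


def _simulate_snp_truth(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: pd.Index,
    clone_ids: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw SNP sites, per-gene origin classes and latent allele fractions."""
    n_snps = _draw_counts(rng, config.snp_per_gene_law, len(genes))
    gene_idx = np.repeat(np.arange(len(genes)), n_snps)
    total = int(n_snps.sum())
    ref = rng.integers(0, 4, size=total)
    alt = (ref + rng.integers(1, 4, size=total)) % 4
    sites = pd.DataFrame(
        {
            "snp_id": [f"s{i:07d}" for i in range(total)],
            "chromosome": rng.choice(np.array(_CHROMOSOMES), size=total),
            "position": rng.integers(1, 100_000_000, size=total),
            "gene_id": genes.to_numpy()[gene_idx],
            "allele_ES": _BASES[ref],
            "allele_FIB": _BASES[alt],
            "informative": rng.random(total) >= config.parent_het_rate,
        }
    )

    origin_rows, p_rows = [], []
    classes = list(config.origin_proportions)
    probs = np.array([config.origin_proportions[c] for c in classes])
    snp_ids_of = sites.groupby("gene_id", sort=False)["snp_id"].agg(list)
    for gene, snp_ids in snp_ids_of.items():
        k = len(snp_ids)
        for clone in clone_ids:
            if k == 1:  # MIXED needs >= 2 SNPs
                p2 = probs.copy()
                p2[classes.index(MIXED)] = 0.0
                p2 = p2 / p2.sum()
                origin = rng.choice(classes, p=p2)
            else:
                origin = rng.choice(classes, p=probs)
            origin_rows.append({"gene_id": gene, "clone_id": clone, "origin": origin})
            if origin == BOTH:
                p_es = np.full(k, config.biallelic_fraction)
            elif origin == ONE_PARENT:
                p_es = np.full(k, 1.0 if rng.random() < 0.5 else 0.0)
            else:
                n_mono = int(rng.integers(1, k))
                mono = rng.permutation(k) < n_mono
                side = 1.0 if rng.random() < 0.5 else 0.0
                p_es = np.where(mono, side, config.biallelic_fraction)
            for sid, p in zip(snp_ids, p_es):
                p_rows.append({"snp_id": sid, "clone_id": clone, "p_es": float(p)})

    origins = pd.DataFrame(origin_rows, columns=["gene_id", "clone_id", "origin"])
    snp_clone_p = pd.DataFrame(p_rows, columns=["snp_id", "clone_id", "p_es"])
    return sites, origins, snp_clone_p


def simulate_allele_counts(config: SimulationConfig, truth: SimulationTruth) -> pd.DataFrame:
    """Binomially sample per-SNP allele reads for every sample.

    Coverage is drawn from ``coverage_law`` wherever the sample's line
    expresses the SNP's gene (noiseless line mean >= 1 FPKM) and is zero
    otherwise, so SNPs in silent pool-a genes may yield empty rows.
    Parental samples put ``1 - contamination_rate`` of reads on their own
    strain allele; heterozygous-in-parent sites (the ones the informative
    filter must remove) are 50:50 in both parents. Hybrid reads follow the
    latent per-SNP allele fraction recorded in the truth.
    """
    rng = np.random.default_rng([config.seed, 1])
    sites = truth.sites
    n_sites = len(sites)
    gene_ids = sites["gene_id"].to_numpy()
    het = ~sites["informative"].to_numpy()

    clone_ids = [c for c, _ in config.clone_specs]
    if n_sites == 0:
        return pd.DataFrame(
            columns=["snp_id", "sample_id", "reads_ES_allele", "reads_FIB_allele"]
        )
    p_lookup = truth.snp_clone_p.pivot(index="snp_id", columns="clone_id", values="p_es")
    p_lookup = p_lookup.reindex(index=sites["snp_id"], columns=clone_ids)
    frames = []
    lines = list(truth.line_means.columns)
    expressed = truth.line_means.ge(1.0)
    for line in lines:
        if line in clone_ids:
            p_es = p_lookup[line].to_numpy()
        else:
            is_es = line in {l for l, role, _, _ in PARENT_LINES if role == "parent_ES"}
            own = 1.0 - config.contamination_rate
            p_es = np.where(het, 0.5, own if is_es else 1.0 - own)
        on = expressed[line].reindex(pd.Index(gene_ids)).to_numpy()
        for r in range(1, config.n_replicates + 1):
            cov = _draw_counts(rng, config.coverage_law, n_sites)
            cov = np.where(on, cov, 0)
            reads_es = rng.binomial(cov, p_es)
            frames.append(
                pd.DataFrame(
                    {
                        "snp_id": sites["snp_id"].to_numpy(),
                        "sample_id": f"{line}_r{r}",
                        "reads_ES_allele": reads_es,
                        "reads_FIB_allele": cov - reads_es,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_fixture(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    counts: pd.DataFrame,
    truth: SimulationTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the TSV file set a downstream run consumes.

    Files: ``expression.tsv``, ``samples.tsv``, ``allele_counts.tsv``,
    ``snp_sites.tsv`` and ``truth.tsv`` (long format: one row per gene x
    clone with pool, group and origin labels; empty where undefined).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "allele_counts": out / "allele_counts.tsv",
        "snp_sites": out / "snp_sites.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression(matrix, paths["expression"])
    write_sample_sheet(meta, paths["samples"])
    write_allele_counts(counts, paths["allele_counts"])
    write_snp_sites(truth.sites, paths["snp_sites"])

    clone_ids = truth.groups["clone_id"].drop_duplicates().tolist()
    if not clone_ids:
        clone_ids = truth.origins["clone_id"].drop_duplicates().tolist()
    grid = pd.MultiIndex.from_product(
        [matrix.index, clone_ids], names=["gene_id", "clone_id"]
    ).to_frame(index=False)
    grid["pool"] = truth.pools.reindex(grid["gene_id"]).to_numpy()
    grid = grid.merge(truth.groups, how="left", on=["gene_id", "clone_id"])
    grid = grid.merge(truth.origins, how="left", on=["gene_id", "clone_id"])
    grid[["gene_id", "pool", "clone_id", "group", "origin"]].to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


def read_fixture(
    out_dir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back a fixture: (matrix, meta, counts, sites, truth-labels)."""
    out = Path(out_dir)
    matrix, meta = read_expression(out / "expression.tsv", out / "samples.tsv")
    counts = read_allele_counts(out / "allele_counts.tsv")
    sites = read_snp_sites(out / "snp_sites.tsv")
    truth = pd.read_csv(out / "truth.tsv", sep="\t", dtype={"gene_id": str, "clone_id": str})
    return matrix, meta, counts, sites, truth
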