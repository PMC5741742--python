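"""Partition genes into expression pools from the parental comparison.

Every gene falls into exactly one of four pools:

* ``A_LOW`` — mean FPKM below the floor in both reference parental lines
  and in every hybrid clone (unexpressed throughout the experiment);
* ``B_EQUAL`` — expressed, no significant parental difference;
* ``C_MINOR`` — significant parental difference below the fold threshold;
* ``D_DIFFERENTIAL`` — parental fold change above the threshold and
  significant. Only pool-D genes enter dominance-group classification.

The equal-vs-minor split uses a Welch t-test on log2(FPKM+pseudocount)
across replicates, BH-adjusted across all tested genes; a fold-only mode
(pool B iff fold <= ``equal_fold``) is available when replicate counts do
not support a test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ClassificationConfig
from .expression import line_mean_matrix, reference_parent_lines

__all__ = [
    "POOL_A",
    "POOL_B",
    "POOL_C",
    "POOL_D",
    "POOLS",
    "partition_pools",
    "pool_summary",
]

POOL_A = "A_LOW"
POOL_B = "B_EQUAL"
POOL_C = "C_MINOR"
POOL_D = "D_DIFFERENTIAL"
POOLS = (POOL_A, POOL_B, POOL_C, POOL_D)


def _welch_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values, defined for zero-variance rows.

    When both groups have zero variance the t statistic is undefined; the
    natural limit is used instead: p = 0 if the means differ, 1 if equal.
    Needed so that noiseless replicates still partition cleanly.
    """
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    degenerate = se2 == 0
    p = np.ones(len(x))
    ok = ~degenerate
    if ok.any():
        t = (mx[ok] - my[ok]) / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (vx[ok] / nx) ** 2 / (nx - 1) + (vy[ok] / ny) ** 2 / (ny - 1)
        )
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate & (mx != my)] = 0.0
    return p


def partition_pools(
    matrix: pd.DataFrame, meta: pd.DataFrame, config: ClassificationConfig | None = None
) -> pd.DataFrame:
    """Assign every gene to one pool.

    Returns a DataFrame indexed by gene with columns ``pool``,
    ``mean_ES_parent``, ``mean_FIB_parent``, ``log2_ratio`` (pseudocounted)
    and ``p_adj`` (NaN for pool-A genes, which are never tested).
    """
    config = config or ClassificationConfig()
    es_line, fib_line = reference_parent_lines(meta, config.reference_ploidy)
    means = line_mean_matrix(matrix, meta)
    hybrid_lines = meta.loc[meta["role"] == "hybrid", "line_id"].drop_duplicates()
    if hybrid_lines.empty:
        raise ValueError("no hybrid lines in sample sheet")

    m_es = means[es_line].to_numpy()
    m_fib = means[fib_line].to_numpy()
    psi = config.pseudocount
    log2_ratio = np.log2((m_es + psi) / (m_fib + psi))
    log2_t = np.log2(config.fold_threshold)

    low_lines = [es_line, fib_line, *hybrid_lines]
    is_low = (means[low_lines] < config.fpkm_floor).all(axis=1).to_numpy()

    pool = np.empty(len(means), dtype=object)
    pool[is_low] = POOL_A
    tested = ~is_low
    p_adj = np.full(len(means), np.nan)

    if config.pool_mode == "ttest":
        es_cols = meta.loc[meta["line_id"] == es_line, "sample_id"].tolist()
        fib_cols = meta.loc[meta["line_id"] == fib_line, "sample_id"].tolist()
        if len(es_cols) < 2 or len(fib_cols) < 2:
            raise ValueError(
                "pool_mode='ttest' needs >=2 replicates per reference parent; "
                "use pool_mode='fold_only'"
            )
        x = np.log2(matrix[es_cols].to_numpy(dtype=float) + psi)
        y = np.log2(matrix[fib_cols].to_numpy(dtype=float) + psi)
        p = _welch_pvalues(x[tested], y[tested])
        if tested.any():
            p_adj[tested] = multipletests(p, method="fdr_bh")[1]
        significant = p_adj <= config.alpha
        big_fold = np.abs(log2_ratio) > log2_t
        pool[tested & significant & big_fold] = POOL_D
        pool[tested & significant & ~big_fold] = POOL_C
        pool[tested & ~significant] = POOL_B
    else:
        fold = np.abs(log2_ratio)
        pool[tested & (fold > log2_t)] = POOL_D
        pool[tested & (fold <= log2_t) & (fold > np.log2(config.equal_fold))] = POOL_C
        pool[tested & (fold <= np.log2(config.equal_fold))] = POOL_B

    return pd.DataFrame(
        {
            "pool": pool,
            "mean_ES_parent": m_es,
            "mean_FIB_parent": m_fib,
            "log2_ratio": log2_ratio,
            "p_adj": p_adj,
        },
        index=means.index.rename("gene_id"),
    )


def pool_summary(assignments: pd.DataFrame) -> pd.Series:
    """Gene counts per pool (always all four pools, zeros included)."""
    if assignments.empty:
        raise ValueError("empty assignment list")
    counts = assignments["pool"].value_counts()
    return pd.Series({p: int(counts.get(p, 0)) for p in POOLS}, name="n_genes")
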