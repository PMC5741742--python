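"""Shared configuration and small numeric helpers.

The thresholds collected in :class:`ClassificationConfig` drive every
classification stage: the low-expression floor (FPKM 10), the fold-change
threshold that separates "differential" from "minor" parental differences
and defines parent-proximity bands (2-fold), and the pseudocount added to
FPKM before log ratios.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

__all__ = ["ClassificationConfig", "round_half_up"]


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for pool partitioning and dominance-group classification.

    Parameters
    ----------
    fpkm_floor : float
        Genes with mean FPKM below this value are treated as unexpressed
        ("low"). Default 10.
    fold_threshold : float
        Fold change defining both "differentially expressed" between parents
        and the proximity band around a parent ("at the level of"). Default 2.
    pseudocount : float
        Added to FPKM before taking log ratios, stabilising near-zero values.
    alpha : float
        BH-adjusted significance level for the equal-vs-minor parental split.
    reference_ploidy : str
        Which parental pair anchors the comparisons, ``"4N"`` (ploidy-matched
        to near-tetraploid hybrids) or ``"2N"``.
    rounding : int
        Decimals for reported percentages (round half up).
    pool_mode : str
        ``"ttest"`` (Welch on log2(FPKM+pseudocount), BH-adjusted) or
        ``"fold_only"`` (pool B iff fold <= ``equal_fold``).
    equal_fold : float
        Fold bound for pool B in ``fold_only`` mode.
    """

    fpkm_floor: float = 10.0
    fold_threshold: float = 2.0
    pseudocount: float = 1.0
    alpha: float = 0.05
    reference_ploidy: str = "4N"
    rounding: int = 1
    pool_mode: str = "ttest"
    equal_fold: float = 1.2

    def __post_init__(self) -> None:
        if not self.fpkm_floor > 0:
            raise ValueError("fpkm_floor must be > 0")
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.reference_ploidy not in {"2N", "4N"}:
            raise ValueError("reference_ploidy must be '2N' or '4N'")
        if self.pool_mode not in {"ttest", "fold_only"}:
            raise ValueError("pool_mode must be 'ttest' or 'fold_only'")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Python's built-in ``round`` is banker's rounding; percentage tables in
    this domain round 0.05 up, so 96.75 -> 96.8 at one decimal.
    """
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))
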