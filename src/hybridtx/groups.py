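"""Dominance-group classification of differentially expressed genes.

For each hybrid clone, every pool-D gene (parental fold change above the
threshold) is placed in one of five categories given the clone's phenotype:

* ``GROUP1_CONSISTENT`` — expressed at the level of the phenotype-matching
  parent (genes silenced/activated in line with the clone's phenotype);
* ``GROUP2_INTERMEDIATE`` — between the parents, outside both 2-fold
  proximity bands;
* ``GROUP3_MEMORY`` — at the level of the opposite parent (expression
  inconsistent with the phenotype, "epigenetic memory");
* ``GROUP4_NOVEL`` — outside the parental range by more than the fold
  threshold (expression seen in neither parent);
* ``LOW_IN_CLONE`` — below the FPKM floor in that clone.

"At the level of" a parent means within ``fold_threshold`` of it in log
space after adding the pseudocount. When the hybrid falls within both
parental bands (possible when the parental ratio is between T and T^2),
the nearer parent wins; an exact tie goes to group 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ClassificationConfig, round_half_up
from .expression import line_means, reference_parent_lines
from .pools import POOL_A, POOL_D

__all__ = [
    "GROUP1",
    "GROUP2",
    "GROUP3",
    "GROUP4",
    "LOW_IN_CLONE",
    "GROUP_LABELS",
    "classify_gene",
    "classify_clone",
    "CloneClassification",
    "summarize_group_fractions",
]

GROUP1 = "GROUP1_CONSISTENT"
GROUP2 = "GROUP2_INTERMEDIATE"
GROUP3 = "GROUP3_MEMORY"
GROUP4 = "GROUP4_NOVEL"
LOW_IN_CLONE = "LOW_IN_CLONE"
GROUP_LABELS = (GROUP1, GROUP2, GROUP3, GROUP4, LOW_IN_CLONE)


def classify_gene(
    hybrid_mean: float,
    match_parent_mean: float,
    other_parent_mean: float,
    config: ClassificationConfig | None = None,
) -> str:
    """Classify one gene in one clone from three mean FPKM values.

    ``match_parent_mean`` is the mean in the parent whose phenotype the
    clone adopted. The gene must be differentially expressed between the
    parents (pool D), otherwise the decision regions are ill-defined and a
    ``ValueError`` is raised.
    """
    config = config or ClassificationConfig()
    psi = config.pseudocount
    band = np.log2(config.fold_threshold)

    parent_gap = abs(
        np.log2((match_parent_mean + psi) / (other_parent_mean + psi))
    )
    if not parent_gap > band:
        raise ValueError(
            "parental means are not more than fold_threshold apart: "
            f"{match_parent_mean} vs {other_parent_mean} (gene is not pool D)"
        )

    if hybrid_mean < config.fpkm_floor:
        return LOW_IN_CLONE

    d_match = abs(np.log2((hybrid_mean + psi) / (match_parent_mean + psi)))
    d_other = abs(np.log2((hybrid_mean + psi) / (other_parent_mean + psi)))
    in_match = d_match <= band
    in_other = d_other <= band

    if in_match and (not in_other or d_match <= d_other):
        return GROUP1
    if in_other:
        return GROUP3
    lo = min(match_parent_mean, other_parent_mean)
    hi = max(match_parent_mean, other_parent_mean)
    if lo < hybrid_mean < hi:
        return GROUP2
    return GROUP4


@dataclass
class CloneClassification:
    """Per-gene labels for one clone, plus pool-A genes that switched on."""

    records: pd.DataFrame
    activated_from_low: pd.DataFrame


def classify_clone(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    pools: pd.DataFrame,
    clone_id: str,
    config: ClassificationConfig | None = None,
    evaluate_low_pool: bool = False,
) -> CloneClassification:
    """Classify every pool-D gene for one hybrid clone.

    With ``evaluate_low_pool=True``, pool-A genes whose mean in this clone
    reaches the FPKM floor are reported in a separate ``activated_from_low``
    table (they have no parental contrast, so no group label); they are
    never merged into the group counts.
    """
    config = config or ClassificationConfig()
    row = meta.loc[meta["line_id"] == clone_id]
    if row.empty:
        raise KeyError(f"unknown clone: {clone_id!r}")
    if (row["role"] != "hybrid").any():
        raise ValueError(f"line {clone_id!r} is not a hybrid clone")
    phenotype = row["phenotype"].iloc[0]
    if phenotype not in {"ES_like", "FIB_like"}:
        raise ValueError(f"clone {clone_id!r} has no usable phenotype")

    es_line, fib_line = reference_parent_lines(meta, config.reference_ploidy)
    match_line, other_line = (
        (es_line, fib_line) if phenotype == "ES_like" else (fib_line, es_line)
    )
    hybrid = line_means(matrix, meta, clone_id)
    m_match = line_means(matrix, meta, match_line)
    m_other = line_means(matrix, meta, other_line)

    d_genes = pools.index[pools["pool"] == POOL_D]
    psi = config.pseudocount
    recs = []
    for gene in d_genes:
        h, m, o = hybrid[gene], m_match[gene], m_other[gene]
        label = classify_gene(h, m, o, config)
        recs.append(
            {
                "gene_id": gene,
                "clone_id": clone_id,
                "label": label,
                "hybrid_mean": h,
                "d_match": abs(np.log2((h + psi) / (m + psi))),
                "d_other": abs(np.log2((h + psi) / (o + psi))),
            }
        )
    columns = ["gene_id", "clone_id", "label", "hybrid_mean", "d_match", "d_other"]
    records = pd.DataFrame(recs, columns=columns)

    activated = pd.DataFrame(columns=["gene_id", "clone_id", "hybrid_mean"])
    if evaluate_low_pool:
        a_genes = pools.index[pools["pool"] == POOL_A]
        on = [g for g in a_genes if hybrid[g] >= config.fpkm_floor]
        activated = pd.DataFrame(
            {
                "gene_id": on,
                "clone_id": clone_id,
                "hybrid_mean": [hybrid[g] for g in on],
            },
            columns=["gene_id", "clone_id", "hybrid_mean"],
        )
    return CloneClassification(records=records, activated_from_low=activated)


def summarize_group_fractions(
    records: pd.DataFrame | Mapping[str, int], rounding: int = 1
) -> pd.DataFrame:
    """Counts and percentages per label for one clone.

    Accepts either a per-gene record table (column ``label``) or a mapping
    of label -> count. Percentages are over groups 1-4 only; genes low in
    the clone are counted but excluded from the denominator, as the summary
    table convention has it.
    """
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise ValueError("empty record set")
        counts = {
            lab: int((records["label"] == lab).sum()) for lab in GROUP_LABELS
        }
    else:
        counts = {lab: int(records.get(lab, 0)) for lab in GROUP_LABELS}
        if sum(counts.values()) == 0:
            raise ValueError("empty record set")
    denom = sum(counts[lab] for lab in GROUP_LABELS[:4])
    rows = []
    for lab in GROUP_LABELS:
        if lab == LOW_IN_CLONE or denom == 0:
            pct = np.nan
        else:
            pct = round_half_up(100.0 * counts[lab] / denom, rounding)
        rows.append({"label": lab, "n_genes": counts[lab], "percent": pct})
    return pd.DataFrame(rows)
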