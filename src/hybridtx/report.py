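"""Assemble result tables and run manifest for a full pipeline run."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cluster import Dendrogram
from .expression import line_mean_matrix
from .cluster import log_transform

__all__ = ["build_report"]


def build_report(
    pools: pd.DataFrame,
    group_summaries: Mapping[str, pd.DataFrame],
    origin_summaries: Mapping[str, pd.DataFrame],
    dendrogram: Dendrogram,
    out_dir: str | Path,
    *,
    matrix: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    marker_panels: Mapping[str, list[str]] | None = None,
    manifest_extra: Mapping | None = None,
) -> dict[str, Path]:
    """Write pools.tsv, table1.tsv, table2.tsv, clusters.nwk, optional
    heatmap matrices for marker-gene panels, and a run manifest.

    ``group_summaries`` / ``origin_summaries`` map clone id to the
    per-clone summary tables; heatmap panels are line-mean log10(FPKM+1)
    sub-matrices for configured gene lists.
    """
    for name, obj in (
        ("pools", pools),
        ("group summaries", group_summaries),
        ("origin summaries", origin_summaries),
        ("dendrogram", dendrogram),
    ):
        if obj is None:
            raise ValueError(f"missing stage output: {name}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["pools"] = out / "pools.tsv"
    pools.to_csv(paths["pools"], sep="\t", index_label="gene_id")

    t2 = []
    for clone, summary in group_summaries.items():
        s = summary.copy()
        s.insert(0, "clone", clone)
        t2.append(s.rename(columns={"label": "subgroup"}))
    paths["table2"] = out / "table2.tsv"
    pd.concat(t2, ignore_index=True).to_csv(paths["table2"], sep="\t", index=False)

    t1 = []
    for clone, summary in origin_summaries.items():
        s = summary.copy()
        s.insert(0, "clone", clone)
        t1.append(s)
    paths["table1"] = out / "table1.tsv"
    pd.concat(t1, ignore_index=True).to_csv(paths["table1"], sep="\t", index=False)

    paths["clusters"] = out / "clusters.nwk"
    paths["clusters"].write_text(dendrogram.newick + "\n")

    skipped_panels = []
    if marker_panels:
        if matrix is None or meta is None:
            raise ValueError("missing stage output: expression matrix for heatmaps")
        means = log_transform(line_mean_matrix(matrix, meta))
        for panel, genes in marker_panels.items():
            present = [g for g in genes if g in means.index]
            if not present:
                skipped_panels.append(panel)
                continue
            p = out / f"heatmap_{panel}.tsv"
            means.loc[present].to_csv(p, sep="\t", index_label="gene_id")
            paths[f"heatmap_{panel}"] = p

    manifest = {
        "n_genes": int(len(pools)),
        "pool_counts": pools["pool"].value_counts().to_dict(),
        "clones": sorted(group_summaries),
        "skipped_heatmap_panels": skipped_panels,
        "versions": _versions(),
    }
    if manifest_extra:
        manifest.update(dict(manifest_extra))
    paths["manifest"] = out / "manifest.yaml"
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths


def _versions() -> dict[str, str]:
    import numpy, scipy, pandas, statsmodels  # noqa: E401

    from . import __version__

    return {
        "hybridtx": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }
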