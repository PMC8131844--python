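"""Per-taxon summaries of label calls and fold-change matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import TAXONOMIC_RANKS, TaxonomyTable

__all__ = ["summarize_labeled", "lfc_matrix", "render_lfc_heatmap"]


def summarize_labeled(
    calls: pd.DataFrame,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    taxonomy: TaxonomyTable,
    rank: str = "phylum",
    pooled_denominator: bool = False,
) -> pd.DataFrame:
    """Count labeled OTUs per taxon and express their reads as a percentage.

    For each comparison and each taxon at ``rank``: the number of labeled
    OTUs, and 100 × (reads of those OTUs summed over all fractions of the
    labeled gradient) / (all reads of that gradient).  With
    ``pooled_denominator`` the labeled and control gradients are pooled in
    both numerator and denominator.  OTUs unassigned at the chosen rank
    aggregate under "unclassified".
    """
    if rank not in TAXONOMIC_RANKS:
        raise ValueError(f"unknown rank {rank!r}; ranks are {TAXONOMIC_RANKS}")
    missing = set(calls["otu_id"]) - set(counts.index)
    if missing:
        raise ValueError(f"label calls refer to OTUs absent from counts: {sorted(missing)[:5]}")

    taxon = taxonomy.rank(rank).replace("", "unclassified")
    rows = []
    for comparison, grp in calls.groupby("comparison", sort=False):
        treatment = grp["treatment"].iloc[0]
        timepoint = grp["timepoint_days"].iloc[0]
        isotopes = ("labeled", "control") if pooled_denominator else ("labeled",)
        sel = (
            (metadata["treatment"] == treatment)
            & (metadata["timepoint_days"] == timepoint)
            & metadata["isotope"].isin(isotopes)
        )
        sample_ids = metadata.loc[sel, "sample_id"].tolist()
        grand = counts[sample_ids].to_numpy().sum()
        labeled_ids = grp.loc[grp["labeled"], "otu_id"]
        if labeled_ids.empty or grand == 0:
            continue
        otu_reads = counts.loc[labeled_ids, sample_ids].sum(axis=1)
        per_taxon = otu_reads.groupby(taxon.reindex(labeled_ids).fillna("unclassified")).agg(
            ["count", "sum"]
        )
        for name, row in per_taxon.iterrows():
            rows.append(
                {
                    "comparison": comparison,
                    "treatment": treatment,
                    "timepoint_days": timepoint,
                    "taxon": name,
                    "rank": rank,
                    "n_labeled_otus": int(row["count"]),
                    "pct_total_reads": 100.0 * row["sum"] / grand,
                }
            )
    columns = [
        "comparison",
        "treatment",
        "timepoint_days",
        "taxon",
        "rank",
        "n_labeled_otus",
        "pct_total_reads",
    ]
    return pd.DataFrame(rows, columns=columns)


def lfc_matrix(calls: pd.DataFrame, taxa_filter: list[str] | None = None,
               taxonomy: TaxonomyTable | None = None) -> pd.DataFrame:
    """Pivot heavy-window log2 fold changes to an OTU × comparison matrix.

    Untested cells are missing (NaN), not zero — an OTU absent from one
    incubation could not be analyzed there.  ``taxa_filter`` restricts rows
    to OTUs whose lineage matches any listed taxon (requires ``taxonomy``).
    """
    if calls.empty or calls["comparison"].nunique() < 1:
        raise ValueError("need at least one comparison")
    sub = calls
    if taxa_filter:
        if taxonomy is None:
            raise ValueError("taxa_filter requires a taxonomy table")
        keep = taxonomy.matches(taxa_filter)
        sub = calls[calls["otu_id"].map(keep).fillna(False)]
    wide = sub.pivot_table(
        index="otu_id",
        columns="comparison",
        values="heavy_log2_fold_change",
        aggfunc="first",
        dropna=False,
    )
    wide.columns.name = None
    return wide


def render_lfc_heatmap(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Optional heatmap rendering of an lfc matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * matrix.shape[1] + 2), max(3, 0.18 * matrix.shape[0] + 1))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="heavy-window log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
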