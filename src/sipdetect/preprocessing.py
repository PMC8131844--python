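"""OTU-table hygiene filters applied before labeled-OTU detection.

Three rules, applied in a fixed order so removal accounting is reproducible:

1. singleton removal — OTUs whose total count across all samples is exactly 1;
2. taxon exclusion — OTUs whose lineage matches a blocked taxon (by default
   Cyanobacteria, which cannot be separated from DNA carried in with an
   algal substrate);
3. relative-abundance floor — OTUs contributing strictly less than 0.005%
   of all reads in the table.

The retained OTU set is order-independent; only the attribution of a
removal to a rule depends on the order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TAXONOMIC_RANKS",
    "TaxonomyTable",
    "FilterReport",
    "load_taxonomy",
    "remove_singletons",
    "filter_min_rel_abundance",
    "exclude_taxa",
    "preprocess",
]

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class TaxonomyTable:
    """Per-OTU ranked lineages, parsed from semicolon-delimited strings."""

    def __init__(self, table: pd.DataFrame):
        if not {"otu_id", "lineage"}.issubset(table.columns):
            raise ValueError("taxonomy table needs columns otu_id, lineage")
        if table["otu_id"].duplicated().any():
            raise ValueError("duplicate otu_id in taxonomy table")
        if (table["lineage"].fillna("").str.strip() == "").any():
            raise ValueError("empty lineage in taxonomy table")
        df = table[["otu_id", "lineage"]].copy()
        ranks = df["lineage"].str.split(";", expand=True).reindex(
            columns=range(len(TAXONOMIC_RANKS))
        )
        ranks.columns = TAXONOMIC_RANKS
        for col in TAXONOMIC_RANKS:
            ranks[col] = ranks[col].fillna("").str.strip()
        self.table = pd.concat([df, ranks], axis=1).set_index("otu_id", drop=False)

    @property
    def otu_ids(self) -> pd.Index:
        return self.table.index

    def rank(self, rank: str) -> pd.Series:
        """Per-OTU name at the given rank ('' where unassigned)."""
        if rank not in TAXONOMIC_RANKS:
            raise ValueError(f"unknown rank {rank!r}; ranks are {TAXONOMIC_RANKS}")
        return self.table[rank]

    def matches(self, patterns: Sequence[str]) -> pd.Series:
        """Boolean per OTU: lineage contains any pattern as an exact token (case-insensitive)."""
        wanted = {p.strip().lower() for p in patterns if p.strip()}
        if not wanted:
            return pd.Series(False, index=self.table.index)
        tokens = self.table["lineage"].str.lower().str.split(";").map(
            lambda toks: {t.strip() for t in toks}
        )
        return tokens.map(lambda toks: bool(toks & wanted))


def load_taxonomy(path: str | Path) -> TaxonomyTable:
    return TaxonomyTable(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class FilterReport:
    """Accounting of one preprocessing pass; removals attribute each OTU to the
    first rule that dropped it (singleton → taxon exclusion → abundance floor)."""

    n_input_otus: int
    n_singletons_removed: int
    n_taxon_excluded: int
    n_below_abundance_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_singletons_removed + self.n_taxon_excluded + self.n_below_abundance_removed
        )
        if self.n_input_otus != self.n_retained + removed:
            raise ValueError("filter report does not reconcile")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input_otus": self.n_input_otus,
            "n_singletons_removed": self.n_singletons_removed,
            "n_taxon_excluded": self.n_taxon_excluded,
            "n_below_abundance_removed": self.n_below_abundance_removed,
            "n_retained": self.n_retained,
        }


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("count table is empty")
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("count table contains negative entries")


def remove_singletons(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop OTUs whose total count over all samples equals exactly 1.

    The rule is literal: an all-zero row is not a singleton (it falls to the
    abundance floor instead).
    """
    _check_counts(counts)
    totals = counts.sum(axis=1)
    removed = counts.index[totals == 1].tolist()
    return counts.drop(index=removed), removed


def filter_min_rel_abundance(
    counts: pd.DataFrame, floor: float = 0.00005
) -> tuple[pd.DataFrame, list[str]]:
    """Drop OTUs whose share of the table's grand total is strictly below ``floor``.

    The default floor 0.00005 is the 0.005% relative-abundance threshold.
    """
    _check_counts(counts)
    grand = counts.to_numpy().sum()
    if grand == 0:
        raise ValueError("count table grand total is zero; relative abundance undefined")
    share = counts.sum(axis=1) / grand
    removed = counts.index[share < floor].tolist()
    return counts.drop(index=removed), removed


def exclude_taxa(
    counts: pd.DataFrame,
    taxonomy: TaxonomyTable,
    patterns: Sequence[str] = ("Cyanobacteria",),
) -> tuple[pd.DataFrame, list[str]]:
    """Drop OTUs whose lineage contains any blocked taxon name at any rank."""
    _check_counts(counts)
    missing = counts.index.difference(taxonomy.otu_ids)
    if len(missing):
        raise ValueError(f"otu_id(s) missing from taxonomy: {missing[:5].tolist()}")
    hit = taxonomy.matches(patterns).reindex(counts.index)
    removed = counts.index[hit.to_numpy(dtype=bool)].tolist()
    return counts.drop(index=removed), removed


def preprocess(
    counts: pd.DataFrame,
    taxonomy: TaxonomyTable | None,
    metadata: pd.DataFrame | None = None,
    min_rel_abundance: float = 0.00005,
    exclude: Sequence[str] = ("Cyanobacteria",),
    keep_singletons: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full filter chain and return the table plus an accounting report.

    If ``metadata`` is given, every count column must appear in its
    ``sample_id`` column.  If ``taxonomy`` is None the taxon-exclusion rule
    is skipped (only valid when ``exclude`` is empty).
    """
    _check_counts(counts)
    if metadata is not None:
        orphans = [c for c in counts.columns if c not in set(metadata["sample_id"])]
        if orphans:
            raise ValueError(f"count columns absent from fraction metadata: {orphans[:5]}")
    if taxonomy is None and tuple(exclude):
        raise ValueError("taxon exclusion requested but no taxonomy table given")

    n_input = counts.shape[0]
    if keep_singletons:
        singles: list[str] = []
    else:
        counts, singles = remove_singletons(counts)
    if taxonomy is not None and tuple(exclude):
        counts, taxa_removed = exclude_taxa(counts, taxonomy, exclude)
    else:
        taxa_removed = []
    counts, low = filter_min_rel_abundance(counts, min_rel_abundance)
    report = FilterReport(
        n_input_otus=n_input,
        n_singletons_removed=len(singles),
        n_taxon_excluded=len(taxa_removed),
        n_below_abundance_removed=len(low),
        n_retained=counts.shape[0],
    )
    return counts, report
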