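"""TSV readers for the package's table formats.

All tables are plain TSV with headers: ``counts.tsv`` (first column otu_id,
remaining columns one per sequenced fraction), ``fractions.tsv`` (sample_id,
treatment, isotope, timepoint_days, fraction_index, buoyant_density),
``taxonomy.tsv`` (otu_id, lineage) and ``truth.tsv`` (simulator ground truth).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocessing import TaxonomyTable

__all__ = ["read_counts", "read_fractions", "read_taxonomy", "read_truth"]

_FRACTION_COLUMNS = {
    "sample_id",
    "treatment",
    "isotope",
    "timepoint_days",
    "fraction_index",
    "buoyant_density",
}


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.name != "otu_id":
        raise ValueError(f"{path}: first column must be named otu_id")
    if counts.index.duplicated().any():
        raise ValueError(f"{path}: duplicate otu_id rows")
    values = counts.to_numpy()
    if (values < 0).any() or not (values == values.astype(int)).all():
        raise ValueError(f"{path}: counts must be non-negative integers")
    return counts.astype(int)


def read_fractions(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = _FRACTION_COLUMNS - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id rows")
    bad = ~meta["isotope"].isin(["labeled", "control"])
    if bad.any():
        raise ValueError(f"{path}: isotope must be 'labeled' or 'control'")
    return meta


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    return TaxonomyTable(pd.read_csv(path, sep="\t"))


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    required = {"otu_id", "is_labeled", "gc", "afe_13C", "afe_15N", "rel_abundance"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return truth
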