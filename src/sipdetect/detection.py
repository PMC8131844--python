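"""Dual-criterion HRSIP labeled-OTU detection.

An OTU is called *labeled* when (1) it is significantly more abundant in the
heavy fractions (buoyant density > 1.70 g/ml by default) of the
isotope-labeled gradient than in the heavy fractions of the paired control
gradient, and (2) it is **not** significantly more abundant in the light
fractions — the second criterion screens out OTUs that are more abundant
throughout the labeled gradient because the two slurries simply differed in
composition, not because the OTU took up label.

Both window comparisons are two-group negative-binomial Wald tests on
size-factor-normalized counts, treating the fractions inside a window as the
replicate units for their gradient.  One-sided p-values (alternative:
log2 fold change above a small positive null, 0.25 by default) are
Benjamini–Hochberg adjusted within each (comparison, window) family and
thresholded at a 10% false discovery rate.  OTUs with no reads in either the
labeled or the control gradient cannot be compared and are reported as
untested, never as labeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocessing import TaxonomyTable, preprocess

__all__ = [
    "WindowSpec",
    "WindowError",
    "DesignError",
    "split_windows",
    "size_factors",
    "estimate_dispersions",
    "test_window",
    "bh_adjust",
    "classify",
    "detect",
]

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8


class WindowError(ValueError):
    """A gradient has no fractions on one side of the heavy threshold."""


class DesignError(ValueError):
    """The sample layout cannot support the requested comparison."""


@dataclass(frozen=True)
class WindowSpec:
    """Heavy/light partition of gradient fractions at a density cutoff.

    Heavy means buoyant density strictly greater than ``heavy_threshold``
    (g/ml); light is the complement.
    """

    heavy_threshold: float = 1.70


def split_windows(
    metadata: pd.DataFrame, spec: WindowSpec = WindowSpec()
) -> dict[tuple, tuple[list[str], list[str]]]:
    """Partition each gradient's fractions into heavy and light sample-id lists.

    Gradients are keyed by (treatment, isotope, timepoint_days).  Raises
    :class:`WindowError` if any gradient ends up with an empty window.
    """
    if metadata["buoyant_density"].isna().any():
        raise ValueError("every fraction needs a buoyant_density")
    out: dict[tuple, tuple[list[str], list[str]]] = {}
    for key, grp in metadata.groupby(["treatment", "isotope", "timepoint_days"], sort=False):
        heavy = grp.loc[grp["buoyant_density"] > spec.heavy_threshold, "sample_id"].tolist()
        light = grp.loc[grp["buoyant_density"] <= spec.heavy_threshold, "sample_id"].tolist()
        if not heavy or not light:
            raise WindowError(
                f"gradient {key} has {len(heavy)} heavy and {len(light)} light fractions "
                f"at threshold {spec.heavy_threshold} g/ml"
            )
        out[key] = (heavy, light)
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample scale factors, rescaled to geometric mean 1.

    The reference is the per-OTU geometric mean over OTUs positive in every
    sample; each sample's factor is the median ratio of its counts to the
    reference.  When no OTU is positive everywhere, the reference falls back
    to OTUs positive in at least half the samples (with a logged warning),
    and finally to per-sample totals.
    """
    values = counts.to_numpy(dtype=float)
    positive_all = (values > 0).all(axis=1)
    if positive_all.any():
        ref_rows = values[positive_all]
    else:
        frac_positive = (values > 0).mean(axis=1)
        fallback = frac_positive >= 0.5
        if fallback.any():
            logger.warning(
                "size_factors: no OTU positive in all %d samples; "
                "falling back to %d OTUs positive in >= 50%% of samples",
                values.shape[1],
                int(fallback.sum()),
            )
            ref_rows = values[fallback]
        else:
            logger.warning("size_factors: no usable reference OTUs; using library-size factors")
            totals = values.sum(axis=0)
            factors = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
            return pd.Series(factors, index=counts.columns, name="size_factor")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_counts = np.where(ref_rows > 0, np.log(np.where(ref_rows > 0, ref_rows, 1.0)), np.nan)
        log_ref = np.nanmean(log_counts, axis=1)  # geometric mean over positive entries
        log_factors = np.nanmedian(log_counts - log_ref[:, None], axis=0)
    log_factors = log_factors - np.mean(log_factors)  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def estimate_dispersions(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> pd.Series:
    """Per-OTU negative-binomial dispersions from normalized counts.

    Method-of-moments on the pooled within-group variance, shrunk 50/50
    toward a mean–dispersion trend (``alpha ~ a0 + a1/mean``) fitted across
    OTUs, floored at 1e-8.  OTUs whose moment estimate is non-positive fall
    back to the trend (Poisson-like when the trend is flat).
    """
    n_a, n_b = group_a.shape[1], group_b.shape[1]
    mu_a = group_a.mean(axis=1)
    mu_b = group_b.mean(axis=1)
    ss = ((group_a.sub(mu_a, axis=0)) ** 2).sum(axis=1) + (
        (group_b.sub(mu_b, axis=0)) ** 2
    ).sum(axis=1)
    dof = max(n_a + n_b - 2, 1)
    s2 = ss / dof
    mu = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (s2 - mu) / (mu**2)
    alpha_raw = alpha_raw.replace([np.inf, -np.inf], np.nan)
    alpha_mom = alpha_raw.clip(lower=0.0).fillna(0.0)

    usable = (alpha_raw > 0) & (mu > 0)
    if usable.sum() >= 2:
        x = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable].to_numpy()])
        coef, *_ = np.linalg.lstsq(x, alpha_raw[usable].to_numpy(), rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
    else:
        a0 = a1 = 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / mu.replace(0, np.nan)
    trend = trend.fillna(0.0).clip(lower=0.0)

    alpha = 0.5 * alpha_mom + 0.5 * trend
    return alpha.clip(lower=_DISPERSION_FLOOR)


def test_window(
    counts: pd.DataFrame,
    labeled_ids: Sequence[str],
    control_ids: Sequence[str],
    lfc_null: float = 0.25,
    detected_in_both: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-OTU one-sided NB Wald test: labeled-window vs control-window counts.

    Parameters
    ----------
    counts
        Full OTU × sample table (only the listed columns are used).
    labeled_ids, control_ids
        Sample ids of the same window in the labeled and control gradient;
        each group needs at least 2 fractions.
    lfc_null
        Null log2-fold-change threshold; the alternative is l2fc > lfc_null.
    detected_in_both
        Optional per-OTU flag that the OTU has reads in *both* incubations
        overall (all fractions, not just this window).  OTUs failing it are
        reported untested.  Defaults to presence in both window groups.

    Returns a DataFrame indexed by otu_id with columns log2_fold_change, se,
    wald_stat, p_one_sided, mean_norm_count, tested.
    """
    labeled_ids = list(labeled_ids)
    control_ids = list(control_ids)
    if len(labeled_ids) < 2 or len(control_ids) < 2:
        raise DesignError(
            f"need >= 2 fractions per group, got {len(labeled_ids)} labeled / "
            f"{len(control_ids)} control"
        )
    sub = counts.loc[:, labeled_ids + control_ids].astype(float)
    sf = size_factors(sub)
    normed = sub.div(sf, axis=1)
    ql, qc = normed[labeled_ids], normed[control_ids]
    mu_l, mu_c = ql.mean(axis=1), qc.mean(axis=1)

    if detected_in_both is None:
        tested = (ql.sum(axis=1) > 0) & (qc.sum(axis=1) > 0)
    else:
        tested = detected_in_both.reindex(counts.index).fillna(False).astype(bool)

    # Small-count stabilizer: a zero *window* mean for an OTU present in both
    # incubations gets a +0.5 pseudo-mean; pure zeros in an incubation are
    # untested instead.
    mu_l_adj = mu_l.where(~(tested & (mu_l == 0)), 0.5)
    mu_c_adj = mu_c.where(~(tested & (mu_c == 0)), 0.5)

    alpha = estimate_dispersions(ql, qc)
    n_l, n_c = len(labeled_ids), len(control_ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(mu_l_adj / mu_c_adj)
        var_l = (mu_l_adj + alpha * mu_l_adj**2) / n_l
        var_c = (mu_c_adj + alpha * mu_c_adj**2) / n_c
        se = np.sqrt(var_l / mu_l_adj**2 + var_c / mu_c_adj**2) / _LN2
        wald = (l2fc - lfc_null) / se
    p = pd.Series(norm.sf(wald), index=counts.index)

    result = pd.DataFrame(
        {
            "log2_fold_change": l2fc,
            "se": se,
            "wald_stat": wald,
            "p_one_sided": p,
            "mean_norm_count": normed.mean(axis=1),
            "tested": tested,
        },
        index=counts.index,
    )
    result.index.name = "otu_id"
    stat_cols = ["log2_fold_change", "se", "wald_stat", "p_one_sided"]
    result.loc[~tested, stat_cols] = np.nan
    return result


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    NaN entries (untested hypotheses) are excluded from the family size and
    propagated as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    result = np.empty(m)
    result[order] = adjusted
    out[mask] = result
    return out


def classify(heavy: Mapping, light: Mapping, fdr: float = 0.10) -> dict:
    """Combine one OTU's heavy- and light-window results into a label call.

    criterion1: significant heavy enrichment (heavy padj < fdr, tested only).
    criterion2_violated: significant light enrichment — the compositional-
    difference guard.  labeled = criterion1 AND NOT criterion2_violated.
    """
    if "otu_id" in heavy and "otu_id" in light and heavy["otu_id"] != light["otu_id"]:
        raise ValueError(
            f"mismatched otu_id: heavy={heavy['otu_id']!r} light={light['otu_id']!r}"
        )
    heavy_tested = bool(heavy.get("tested", True))
    light_tested = bool(light.get("tested", True))
    criterion1 = heavy_tested and float(heavy["padj"]) < fdr
    criterion2_violated = light_tested and float(light["padj"]) < fdr
    labeled = criterion1 and not criterion2_violated
    reason = ""
    if not heavy_tested:
        reason = "not detected in both incubations"
    elif not criterion1:
        reason = "no significant heavy enrichment"
    elif criterion2_violated:
        reason = "enriched throughout gradient (light window significant)"
    return {
        "criterion1": criterion1,
        "criterion2_violated": criterion2_violated,
        "labeled": labeled,
        "reason": reason,
    }


def _gradient_samples(metadata: pd.DataFrame, treatment, timepoint, isotope) -> pd.DataFrame:
    sel = (
        (metadata["treatment"] == treatment)
        & (metadata["timepoint_days"] == timepoint)
        & (metadata["isotope"] == isotope)
    )
    return metadata.loc[sel]


def detect(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    taxonomy: TaxonomyTable | None = None,
    spec: WindowSpec = WindowSpec(),
    fdr: float = 0.10,
    lfc_null: float = 0.25,
    comparisons: Sequence[tuple] | None = None,
    preprocess_options: Mapping | None = None,
    run_preprocess: bool = True,
) -> pd.DataFrame:
    """Run the full detection pipeline and return a long-format label-call table.

    For each (treatment, timepoint) comparison with both a labeled and a
    control gradient: preprocess the table, split fractions at the heavy
    threshold, test heavy and light windows, BH-adjust within each
    (comparison, window) family, and apply the dual criterion.

    Returns one row per (comparison, OTU) with window statistics, criterion
    flags, the labeled verdict, and a reason string for negative calls.
    """
    metadata = metadata.copy()
    if comparisons is None:
        pairs = metadata[["treatment", "timepoint_days"]].drop_duplicates()
        comparisons = [tuple(r) for r in pairs.to_numpy()]

    if run_preprocess:
        opts = dict(preprocess_options or {})
        if taxonomy is None:
            opts.setdefault("exclude", ())
        counts, report = preprocess(counts, taxonomy, metadata, **opts)
        logger.info("preprocess %s", report.to_dict())

    rows: list[pd.DataFrame] = []
    for treatment, timepoint in comparisons:
        lab_meta = _gradient_samples(metadata, treatment, timepoint, "labeled")
        ctl_meta = _gradient_samples(metadata, treatment, timepoint, "control")
        if lab_meta.empty or ctl_meta.empty:
            raise DesignError(
                f"comparison ({treatment}, day {timepoint}) lacks a "
                f"{'labeled' if lab_meta.empty else 'control'} gradient"
            )
        windows = split_windows(pd.concat([lab_meta, ctl_meta]), spec)
        heavy_l, light_l = windows[(treatment, "labeled", timepoint)]
        heavy_c, light_c = windows[(treatment, "control", timepoint)]

        detected = (counts[lab_meta["sample_id"]].sum(axis=1) > 0) & (
            counts[ctl_meta["sample_id"]].sum(axis=1) > 0
        )
        heavy = test_window(counts, heavy_l, heavy_c, lfc_null, detected_in_both=detected)
        light = test_window(counts, light_l, light_c, lfc_null, detected_in_both=detected)
        heavy["padj"] = bh_adjust(heavy["p_one_sided"].to_numpy())
        light["padj"] = bh_adjust(light["p_one_sided"].to_numpy())

        criterion1 = heavy["tested"] & (heavy["padj"] < fdr)
        criterion2_violated = light["tested"] & (light["padj"] < fdr)
        labeled = criterion1 & ~criterion2_violated
        reason = np.select(
            [
                ~heavy["tested"],
                ~criterion1,
                criterion2_violated,
            ],
            [
                "not detected in both incubations",
                "no significant heavy enrichment",
                "enriched throughout gradient (light window significant)",
            ],
            default="",
        )
        calls = pd.DataFrame(
            {
                "otu_id": counts.index,
                "comparison": f"{treatment}_T{timepoint:g}",
                "treatment": treatment,
                "timepoint_days": timepoint,
                "heavy_log2_fold_change": heavy["log2_fold_change"].to_numpy(),
                "heavy_se": heavy["se"].to_numpy(),
                "heavy_p": heavy["p_one_sided"].to_numpy(),
                "heavy_padj": heavy["padj"].to_numpy(),
                "light_log2_fold_change": light["log2_fold_change"].to_numpy(),
                "light_p": light["p_one_sided"].to_numpy(),
                "light_padj": light["padj"].to_numpy(),
                "tested": heavy["tested"].to_numpy(),
                "criterion1": criterion1.to_numpy(),
                "criterion2_violated": criterion2_violated.to_numpy(),
                "labeled": labeled.to_numpy(),
                "reason": reason,
            }
        )
        rows.append(calls)
    return pd.concat(rows, ignore_index=True)
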