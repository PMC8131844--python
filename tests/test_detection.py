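import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sipdetect as sd
from sipdetect.detection import (
    DesignError,
    WindowError,
    bh_adjust,
    classify,
    size_factors,
    split_windows,
)
from sipdetect.detection import test_window as window_test
from sipdetect.gradients import expected_fraction_profiles, fraction_centers

from conftest import taxonomy_from_truth


def _meta_for(config, treatment="sub", timepoint=7):
    centers = fraction_centers(config)
    rows = []
    for isotope in ("labeled", "control"):
        for f, bd in enumerate(centers, start=1):
            rows.append(
                dict(
                    sample_id=f"{treatment}_{isotope}_T{timepoint}_F{f:02d}",
                    treatment=treatment,
                    isotope=isotope,
                    timepoint_days=timepoint,
                    fraction_index=f,
                    buoyant_density=bd,
                )
            )
    return pd.DataFrame(rows)


def _flat_truth(n_otus=10, gc=0.35):
    """Equal-abundance, equal-GC community: every OTU has the same band
    profile, so expected per-fraction proportions are flat."""
    return pd.DataFrame(
        {
            "otu_id": [f"OTU_{i:02d}" for i in range(n_otus)],
            "rel_abundance": np.full(n_otus, 1.0 / n_otus),
            "gc": gc,
            "is_labeled": False,
            "afe_13C": 0.0,
            "afe_15N": 0.0,
            "taxonomy": "Bacteria;Planctomycetes;Phycisphaerae;MSBL9;uncultured;uncultured",
        }
    )


def _deterministic_counts(truth, config, rel_labeled, rel_control, depth=300_000):
    """Integer counts proportional to expected fraction profiles (no sampling)."""
    meta = _meta_for(config)
    pl = expected_fraction_profiles(truth, config, True, rel_abundance=rel_labeled)
    pc = expected_fraction_profiles(truth, config, False, rel_abundance=rel_control)
    cols = {}
    for iso, props in (("labeled", pl), ("control", pc)):
        ids = meta[meta.isotope == iso].sort_values("fraction_index").sample_id
        for f, sid in enumerate(ids):
            cols[sid] = np.round(depth * props.to_numpy()[:, f]).astype(int)
    counts = pd.DataFrame(cols, index=pl.index)[meta.sample_id.tolist()]
    counts.index.name = "otu_id"
    return counts, meta


class TestSplitWindows:
    def test_default_grid_has_seven_heavy_fractions(self, default_config):
        meta = _meta_for(default_config)
        windows = split_windows(meta, sd.WindowSpec(1.70))
        heavy, light = windows[("sub", "labeled", 7)]
        assert len(heavy) == 7 and len(light) == 5

    def test_density_exactly_at_threshold_is_light(self):
        meta = _meta_for(sd.GradientConfig())
        meta.loc[0, "buoyant_density"] = 1.70  # boundary: "higher than" is strict
        windows = split_windows(meta, sd.WindowSpec(1.70))
        heavy, light = windows[("sub", "labeled", 7)]
        assert meta.loc[0, "sample_id"] in light

    def test_all_heavy_raises_window_error(self, default_config):
        meta = _meta_for(default_config)
        with pytest.raises(WindowError):
            split_windows(meta, sd.WindowSpec(1.60))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_sqrt2(self):
        counts = pd.DataFrame({"x": [10, 40, 6], "y": [20, 80, 12]})
        factors = size_factors(counts)
        assert factors["y"] == pytest.approx(np.sqrt(2))
        assert factors["x"] == pytest.approx(1 / np.sqrt(2))

    def test_single_otu_table_factors_proportional_to_counts(self):
        counts = pd.DataFrame([[2.0, 8.0, 4.0]], columns=["a", "b", "c"])
        factors = size_factors(counts)
        # brute force: factors proportional to counts, geometric mean 1
        expected = np.array([2.0, 8.0, 4.0]) / np.exp(np.mean(np.log([2.0, 8.0, 4.0])))
        assert np.allclose(factors, expected)

    def test_fallback_when_no_otu_positive_everywhere(self, caplog):
        counts = pd.DataFrame({"a": [10, 0, 3], "b": [0, 10, 3], "c": [10, 10, 0]})
        with caplog.at_level("WARNING"):
            factors = size_factors(counts)
        assert np.isfinite(factors).all() and (factors > 0).all()


class TestWindowTest:
    def test_otu_absent_from_one_incubation_is_untested(self):
        counts = pd.DataFrame(
            {
                "l1": [0, 100],
                "l2": [0, 110],
                "c1": [0, 90],
                "c2": [0, 95],
            },
            index=["absent", "present"],
        )
        res = window_test(counts, ["l1", "l2"], ["c1", "c2"])
        assert not res.loc["absent", "tested"]
        assert np.isnan(res.loc["absent", "p_one_sided"])
        assert res.loc["present", "tested"]

    def test_identical_groups_are_null(self):
        counts = pd.DataFrame(
            {
                "l1": [50, 100],
                "l2": [60, 120],
                "c1": [50, 100],
                "c2": [60, 120],
            },
            index=["a", "b"],
        )
        res = window_test(counts, ["l1", "l2"], ["c1", "c2"])
        assert np.allclose(res.log2_fold_change, 0.0)
        assert (res.p_one_sided >= 0.5).all()

    def test_single_fraction_group_is_a_design_error(self):
        counts = pd.DataFrame({"l1": [5], "c1": [5], "c2": [6]})
        with pytest.raises(DesignError):
            window_test(counts, ["l1"], ["c1", "c2"])

    def test_tenfold_enrichment_detected_by_monte_carlo_oracle(self):
        """An OTU at ~1% abundance, 10x enriched in the labeled window,
        6 fractions per group at depth 3e4: one-sided p < 0.01 in >95/100
        simulation replicates."""
        rng = np.random.default_rng(9)
        p_ctl = np.ones(50)
        p_ctl[0] = 0.5
        p_ctl /= p_ctl.sum()
        p_lab = p_ctl.copy()
        p_lab[0] *= 10
        p_lab /= p_lab.sum()
        hits = 0
        for _ in range(100):
            cols = {f"L{i}": rng.multinomial(30_000, p_lab) for i in range(6)}
            cols.update({f"C{i}": rng.multinomial(30_000, p_ctl) for i in range(6)})
            counts = pd.DataFrame(cols, index=[f"o{i}" for i in range(50)])
            res = window_test(counts, [f"L{i}" for i in range(6)], [f"C{i}" for i in range(6)])
            hits += res.loc["o0", "p_one_sided"] < 0.01
        assert hits > 95

    def test_swapping_groups_negates_l2fc_and_kills_significance(self, small_experiment):
        counts, meta, truth, _ = small_experiment
        windows = split_windows(meta, sd.WindowSpec())
        heavy_l, _ = windows[("acetate", "labeled", 7)]
        heavy_c, _ = windows[("acetate", "control", 7)]
        fwd = window_test(counts, heavy_l, heavy_c)
        rev = window_test(counts, heavy_c, heavy_l)
        tested = fwd.tested & rev.tested
        assert np.allclose(
            fwd.loc[tested, "log2_fold_change"],
            -rev.loc[tested, "log2_fold_change"],
            atol=1e-9,
        )
        strong = fwd.tested & (fwd.p_one_sided < 0.01)
        assert (rev.loc[strong, "p_one_sided"] > 0.5).all()


class TestBH:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.001, 1.0], [0.002, 1.0]),
        ],
    )
    def test_step_up_examples(self, pvals, expected):
        assert np.allclose(bh_adjust(pvals), expected)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_entries_excluded_from_family(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        # family size 2, not 3
        assert adj[0] == pytest.approx(0.02)
        assert adj[2] == pytest.approx(0.02)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
    def test_matches_statsmodels_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)


class TestClassify:
    def test_heavy_significant_light_not_is_labeled(self):
        call = classify({"padj": 0.02, "tested": True}, {"padj": 0.60, "tested": True})
        assert call["labeled"] and call["criterion1"] and not call["criterion2_violated"]

    def test_enrichment_throughout_gradient_is_rejected(self):
        call = classify({"padj": 0.02, "tested": True}, {"padj": 0.02, "tested": True})
        assert call["criterion1"] and call["criterion2_violated"] and not call["labeled"]

    def test_no_heavy_enrichment_is_not_labeled(self):
        call = classify({"padj": 0.50, "tested": True}, {"padj": 0.01, "tested": True})
        assert not call["labeled"]

    def test_untested_is_never_labeled_with_reason(self):
        call = classify({"padj": np.nan, "tested": False}, {"padj": np.nan, "tested": False})
        assert not call["labeled"] and "not detected" in call["reason"]

    def test_mismatched_otu_ids_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify(
                {"otu_id": "a", "padj": 0.1, "tested": True},
                {"otu_id": "b", "padj": 0.1, "tested": True},
            )

    def test_lowering_fdr_never_adds_labeled_otus(self):
        rng = np.random.default_rng(12)
        heavy = rng.uniform(0, 1, 200)
        light = rng.uniform(0, 1, 200)
        labeled_at = {
            fdr: {
                i
                for i in range(200)
                if classify({"padj": heavy[i], "tested": True},
                            {"padj": light[i], "tested": True}, fdr=fdr)["labeled"]
            }
            for fdr in (0.01, 0.05, 0.10)
        }
        assert labeled_at[0.01] <= labeled_at[0.05]
        # note 0.05 -> 0.10 can also unlabel via criterion 2, so only the
        # criterion-1-monotone direction is asserted for the smallest fdr


class TestDetect:
    def test_null_scenario_rarely_calls_anything(self, default_config):
        """No labeled OTUs, identical compositions: labeled set empty in
        >= 90% of 20 seeded replicates."""
        empty = 0
        for s in range(20):
            truth = sd.make_community(100, 0.0, seed=500 + s)
            counts, meta, truth = sd.simulate_experiment(
                truth, default_config, [7], seed=600 + s
            )
            calls = sd.detect(counts, meta, taxonomy_from_truth(truth))
            empty += int(calls.labeled.sum() == 0)
        assert empty >= 18

    def test_labeled_otus_rank_top_by_heavy_l2fc(self, default_config):
        """20/200 labeled at afe 0.5 with abundance >= 0.5% all rank in the
        top 30 by heavy-window log2 fold change."""
        truth = sd.make_community(200, 0.0, seed=42, afe_13C=0.5)
        rel = truth.rel_abundance.to_numpy()
        lab_idx = np.argsort(rel)[::-1][5:25]
        truth.loc[lab_idx, "is_labeled"] = True
        truth.loc[lab_idx, "afe_13C"] = 0.5
        rel[lab_idx] = np.maximum(rel[lab_idx], 0.006)
        truth["rel_abundance"] = rel / rel.sum()
        counts, meta, truth = sd.simulate_experiment(truth, default_config, [7], seed=43)
        calls = sd.detect(counts, meta, run_preprocess=False)
        ranked = calls.sort_values("heavy_log2_fold_change", ascending=False)
        top30 = set(ranked.head(30).otu_id)
        assert set(truth[truth.is_labeled].otu_id) <= top30

    def test_composition_shift_is_caught_by_light_window_control(self, default_config):
        """An OTU 4x more abundant in every labeled fraction (no density
        shift) must not be called labeled; the same OTU density-shifted by
        0.03 g/ml must be.  The fixture is a deterministic equal-abundance,
        equal-GC community (identical band profiles), so per-fraction
        proportions are flat and the dual criterion itself is what is
        measured."""
        truth = _flat_truth()
        rel = truth.rel_abundance.to_numpy()
        boosted = rel.copy()
        boosted[5] *= 4
        boosted /= boosted.sum()
        counts, meta = _deterministic_counts(truth, default_config, boosted, rel)
        calls = sd.detect(counts, meta, run_preprocess=False).set_index("otu_id")
        target = truth.otu_id.iloc[5]
        assert calls.loc[target, "criterion1"]  # heavy window alone is fooled
        assert calls.loc[target, "criterion2_violated"]
        assert not calls.loc[target, "labeled"]

        truth2 = truth.copy()
        truth2.loc[5, "is_labeled"] = True
        truth2.loc[5, "afe_13C"] = 0.03 / sd.IsotopeDensityModel().shift_13C
        counts2, meta2 = _deterministic_counts(
            truth2, default_config, truth2.rel_abundance.to_numpy(), rel
        )
        calls2 = sd.detect(counts2, meta2, run_preprocess=False).set_index("otu_id")
        assert calls2.loc[target, "labeled"]

    def test_raising_lfc_null_never_adds_labeled_otus(self, small_experiment):
        counts, meta, truth, tax = small_experiment
        loose = sd.detect(counts, meta, tax, lfc_null=0.25)
        strict = sd.detect(counts, meta, tax, lfc_null=1.0)
        loose_set = set(loose[loose.labeled].otu_id)
        strict_set = set(strict[strict.labeled].otu_id)
        assert strict_set <= loose_set

    def test_missing_control_gradient_is_a_design_error(self, small_experiment):
        counts, meta, truth, tax = small_experiment
        lab_only = meta[meta.isotope == "labeled"]
        with pytest.raises(DesignError, match="control"):
            sd.detect(counts[lab_only.sample_id], lab_only, tax)

    def test_untested_otus_never_labeled(self, small_experiment, default_config):
        counts, meta, truth, tax = small_experiment
        counts = counts.copy()
        ctl = meta[meta.isotope == "control"].sample_id
        counts.loc[counts.index[0], ctl] = 0  # wipe from control incubation
        calls = sd.detect(counts, meta, tax, run_preprocess=False).set_index("otu_id")
        row = calls.loc[counts.index[0]]
        assert not row.tested and not row.labeled
        assert "not detected" in row.reason
        assert np.isnan(row.heavy_p)
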