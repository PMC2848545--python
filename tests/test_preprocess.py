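"""Occupancy preprocessing: normalization, scaling, grouping, consolidation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathcom import (
    assign_groups,
    combine_background,
    consolidate_groups,
    consolidate_incremental,
    fold_over_background,
    group_medians,
    probe_dataset_to_occupancy,
    scale_percent,
)


def _probes(index):
    return pd.Index(list(index), name="probe_id")


class TestCombineBackground:
    def test_single_replicate_median_normalized(self):
        rep = pd.DataFrame({"BG_rep1": [1.0, 2.0, 4.0]}, index=_probes("abc"))
        out = combine_background(rep)
        assert list(out) == [0.5, 1.0, 2.0]

    def test_identical_replicates_reduce_to_one(self):
        rep = pd.DataFrame(
            {"BG_rep1": [1.0, 2.0, 4.0], "BG_rep2": [1.0, 2.0, 4.0]},
            index=_probes("abc"),
        )
        assert combine_background(rep).equals(
            combine_background(rep[["BG_rep1"]])
        )

    def test_per_probe_median_across_replicates(self):
        rep = pd.DataFrame(
            {"r1": [1.0, 1.0], "r2": [2.0, 1.0], "r3": [3.0, 1.0]},
            index=_probes("ab"),
        )
        normed = rep / rep.median(axis=0)
        expected = normed.median(axis=1)
        assert combine_background(rep).equals(expected)

    def test_nonpositive_signal_rejected(self):
        rep = pd.DataFrame({"r1": [1.0, 0.0]}, index=_probes("ab"))
        with pytest.raises(ValueError):
            combine_background(rep)


class TestFoldOverBackground:
    def test_tt_median_exactly_one_after_centering(self):
        rng = np.random.default_rng(0)
        idx = _probes([f"p{i}" for i in range(101)])
        signal = pd.Series(rng.lognormal(1, 0.5, 101), index=idx)
        bg = pd.Series(rng.lognormal(0, 0.2, 101), index=idx)
        tt = pd.Series([i % 3 == 0 for i in range(101)], index=idx)
        folds = fold_over_background(signal, bg, tt)
        assert folds[tt].median() == pytest.approx(1.0, abs=1e-12)

    def test_signal_equal_background_gives_unit_folds(self):
        idx = _probes("abcd")
        s = pd.Series([2.0, 3.0, 4.0, 5.0], index=idx)
        tt = pd.Series([True, True, False, False], index=idx)
        assert (fold_over_background(s, s, tt) == 1.0).all()

    def test_doubling_one_probe_doubles_its_fold_only(self):
        idx = _probes("abcd")
        s = pd.Series([1.0, 1.0, 1.0, 1.0], index=idx)
        bg = pd.Series([1.0, 1.0, 1.0, 1.0], index=idx)
        tt = pd.Series([True, True, True, False], index=idx)
        base = fold_over_background(s, bg, tt)
        s2 = s.copy()
        s2["d"] *= 2
        out = fold_over_background(s2, bg, tt)
        assert out["d"] == pytest.approx(2 * base["d"])
        assert (out[:3] == base[:3]).all()

    def test_missing_tt_probes_rejected(self):
        idx = _probes("ab")
        s = pd.Series([1.0, 2.0], index=idx)
        with pytest.raises(ValueError):
            fold_over_background(s, s, pd.Series([False, False], index=idx))


class TestScalePercent:
    def test_endpoints(self):
        folds = np.concatenate([np.linspace(1.0, 5.0, 100)])
        pct = scale_percent(folds, upper_percentile=99)
        assert pct[0] == 0.0          # fold = 1 -> background -> 0%
        p99 = np.sort(folds)[int(np.ceil(0.99 * 100)) - 1]
        assert pct[np.argmax(folds >= p99)] == 100.0

    def test_midpoint_arithmetic(self):
        # p99 = 5: fold 3 -> (3-1)/(5-1) = 50%
        folds = np.array([3.0] + [1.0] * 97 + [5.0, 5.0])
        assert scale_percent(folds)[0] == pytest.approx(50.0)

    def test_sub_background_clamped_to_zero(self):
        folds = np.array([0.2, 1.0, 2.0] + [1.0] * 96 + [5.0])
        pct = scale_percent(folds)
        assert pct[0] == 0.0 and pct[1] == 0.0

    def test_degenerate_dataset_rejected(self):
        with pytest.raises(ValueError):
            scale_percent(np.full(100, 0.9))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.0, 20.0, allow_nan=False, width=16), min_size=30, max_size=80))
    def test_monotone_and_idempotent(self, vals):
        folds = np.asarray(vals)
        if np.sort(folds)[int(np.ceil(0.99 * len(folds))) - 1] <= 1.0:
            return  # degenerate by construction
        pct = scale_percent(folds)
        order = np.argsort(folds)
        assert (np.diff(pct[order]) >= -1e-9).all()
        # re-expressing percents as folds on the same scale is a fixed point
        p99 = np.sort(folds)[int(np.ceil(0.99 * len(folds))) - 1]
        refolds = 1.0 + pct / 100.0 * (p99 - 1.0)
        assert np.allclose(scale_percent(refolds), pct, atol=1e-9)


class TestAssignGroups:
    def test_cutoff_tie_goes_high(self):
        table = pd.DataFrame({"T": [9.99, 10.0]}, index=["a", "b"])
        labels = assign_groups(table, codes=["T"])
        assert list(labels) == ["(L)", "(H)"]

    def test_three_factor_archetypes_give_eight_groups(self, archetype3):
        labels = assign_groups(archetype3, codes=list("TBP"))
        assert labels.nunique() == 8

    def test_all_zero_single_group(self):
        table = pd.DataFrame(np.zeros((5, 3)), columns=list("TBP"))
        assert set(assign_groups(table)) == {"(L,L,L)"}

    def test_three_tier_variant(self):
        table = pd.DataFrame({"T": [5.0, 15.0, 25.0]})
        labels = assign_groups(table, cutoffs=(10, 20), codes=["T"])
        assert list(labels) == ["(L)", "(M)", "(H)"]


def _labeled(parents, children):
    idx = pd.RangeIndex(len(parents))
    return pd.Series(parents, index=idx), pd.Series(children, index=idx)


class TestConsolidation:
    def test_both_large_children_kept(self):
        p, c = _labeled(["(H)"] * 270, ["(H,L)"] * 150 + ["(H,H)"] * 120)
        out = consolidate_groups(p, c)
        assert out.value_counts().to_dict() == {"(H,L)": 150, "(H,H)": 120}

    def test_small_child_merged(self):
        p, c = _labeled(["(H)"] * 103, ["(H,L)"] * 95 + ["(H,H)"] * 8)
        out = consolidate_groups(p, c)
        assert out.value_counts().to_dict() == {"(H,L)": 103}

    def test_skewed_split_merged_under_larger_label(self):
        p, c = _labeled(["(L)"] * 95, ["(L,H)"] * 80 + ["(L,L)"] * 15)
        out = consolidate_groups(p, c)
        assert out.value_counts().to_dict() == {"(L,H)": 95}

    def test_balanced_medium_split_kept(self):
        p, c = _labeled(["(L)"] * 90, ["(L,H)"] * 50 + ["(L,L)"] * 40)
        out = consolidate_groups(p, c)
        assert out.value_counts().to_dict() == {"(L,H)": 50, "(L,L)": 40}

    def test_membership_conserved(self):
        rng = np.random.default_rng(1)
        parents = rng.choice(["(L)", "(H)"], size=400).tolist()
        children = [p[:-1] + "," + rng.choice(["L", "H"]) + ")" for p in parents]
        p, c = _labeled(parents, children)
        out = consolidate_groups(p, c)
        assert len(out) == 400
        # no group smaller than the smaller merged child
        for parent in ("(L)", "(H)"):
            kept = out[p == parent].value_counts()
            orig = c[p == parent].value_counts()
            assert kept.min() >= orig.min()

    def test_non_refining_child_rejected(self):
        p, c = _labeled(["(H)"] * 20, ["(L,H)"] * 20)
        with pytest.raises(ValueError):
            consolidate_groups(p, c)

    def test_incremental_skips_consolidation_below_four_factors(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            rng.uniform(0, 100, size=(50, 3)), columns=list("TBP")
        )
        labels = consolidate_incremental(table, "TBP")
        assert labels.equals(assign_groups(table, codes=list("TBP")))


class TestGroupMedians:
    def test_single_gene_group_is_identity(self):
        table = pd.DataFrame({"T": [42.0], "B": [7.0]}, index=["g1"])
        med = group_medians(table, pd.Series(["(H,L)"], index=["g1"]))
        assert med.loc["(H,L)", "T"] == 42.0

    def test_median_of_three(self):
        table = pd.DataFrame({"T": [10.0, 20.0, 90.0]})
        med = group_medians(table, pd.Series(["g"] * 3))
        assert med.loc["g", "T"] == 20.0

    def test_low_columns_stay_below_cutoff(self, small_probe_config):
        """After grouping at the cutoff, an L-labeled column's median can
        never reach the cutoff."""
        from pathcom import generate_probe_dataset

        probes = generate_probe_dataset(small_probe_config)
        occ = probe_dataset_to_occupancy(probes, list("TBP"))
        labels = assign_groups(occ, codes=list("TBP"))
        med = group_medians(occ, labels)
        for label, row in med.iterrows():
            for code, letter in zip("TBP", label.strip("()").split(",")):
                if letter == "L":
                    assert row[code] < 10.0
                else:
                    assert row[code] >= 10.0
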