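"""Feature-table filters, normalization, fold changes, synchronized groups."""

import numpy as np
import pandas as pd
import pytest

from carnlib.downstream import (
    blank_and_rt_filter,
    log2fc_by_group,
    relative_abundance,
    synchronized_groups,
)
from carnlib.spectra_io import FeatureTable
from carnlib.synthetic_data import simulate_timecourse


def build_table(matrix, rt=None, tissue=None, timepoint=None, group=None, blanks=()):
    matrix = pd.DataFrame(matrix).astype(float)
    n_feat, n_samp = matrix.shape
    features = pd.DataFrame(
        {
            "mz": np.linspace(200, 300, n_feat),
            "rt": rt if rt is not None else np.full(n_feat, 2.0),
            "annotation": [None] * n_feat,
        },
        index=matrix.index,
    )
    samples = pd.DataFrame(
        {
            "tissue": tissue if tissue is not None else ["liver"] * n_samp,
            "timepoint": timepoint if timepoint is not None else list(range(n_samp)),
            "group": group if group is not None else ["g"] * n_samp,
            "is_blank": [c in blanks for c in matrix.columns],
        },
        index=matrix.columns,
    )
    return FeatureTable(matrix, features, samples)


class TestBlankAndRtFilter:
    def _table(self, sample_max, blank_max, rt=2.0):
        return build_table(
            {"s1": {"F1": sample_max}, "blank": {"F1": blank_max}},
            rt=[rt],
            blanks=("blank",),
        )

    def test_five_fold_rule_boundary(self):
        kept = blank_and_rt_filter(self._table(130.0, 25.0))  # 130 >= 5*25
        assert list(kept.matrix.index) == ["F1"]
        removed = blank_and_rt_filter(self._table(100.0, 25.0))
        assert list(removed.matrix.index) == []

    def test_feature_absent_from_blanks_survives(self):
        table = build_table(
            {"s1": {"F1": 10.0}, "blank": {"F1": np.nan}}, blanks=("blank",)
        )
        assert list(blank_and_rt_filter(table).matrix.index) == ["F1"]

    @pytest.mark.parametrize("rt,kept", [(0.1, False), (5.0, True), (8.5, False),
                                         (0.2, True), (8.0, True)])
    def test_rt_window(self, rt, kept):
        table = build_table({"s1": {"F1": 100.0}}, rt=[rt])
        with pytest.warns(UserWarning):  # no blanks present
            out = blank_and_rt_filter(table)
        assert (len(out.matrix) == 1) == kept

    def test_blank_columns_dropped_and_idempotent(self):
        table = self._table(200.0, 10.0)
        once = blank_and_rt_filter(table)
        assert "blank" not in once.matrix.columns
        with pytest.warns(UserWarning):
            twice = blank_and_rt_filter(once)
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)


class TestRelativeAbundance:
    def test_series_normalized_to_max(self):
        table = build_table({"t0": {"F1": 2.0}, "t1": {"F1": 4.0}, "t2": {"F1": 8.0}})
        out = relative_abundance(table)
        assert out.matrix.loc["F1"].tolist() == [0.25, 0.5, 1.0]

    def test_constant_series_all_one(self):
        table = build_table({"t0": {"F1": 3.0}, "t1": {"F1": 3.0}})
        assert relative_abundance(table).matrix.loc["F1"].tolist() == [1.0, 1.0]

    def test_per_tissue_maxima_are_one(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            rng.uniform(1, 100, (4, 6)),
            index=[f"F{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(6)],
        )
        table = build_table(matrix, tissue=["liver"] * 3 + ["gut"] * 3)
        out = relative_abundance(table)
        for tissue in ("liver", "gut"):
            cols = out.samples.index[out.samples.tissue == tissue]
            assert np.allclose(out.matrix[cols].max(axis=1), 1.0)

    def test_zero_max_left_missing(self):
        table = build_table({"t0": {"F1": 0.0}, "t1": {"F1": 0.0}})
        out = relative_abundance(table)
        assert out.matrix.loc["F1"].isna().all()


class TestLog2FC:
    def _table(self):
        return build_table(
            {
                "c1": {"F1": 2.0}, "c2": {"F1": 2.0}, "c3": {"F1": 2.0},
                "g1": {"F1": 8.0}, "g2": {"F1": 8.0}, "g3": {"F1": 8.0},
            },
            group=["ctrl"] * 3 + ["trt"] * 3,
        )

    def test_median_ratio(self):
        out = log2fc_by_group(self._table(), "ctrl", pseudocount=0.0)
        assert out.loc["F1", "trt"] == pytest.approx(2.0)
        assert out.loc["F1", "ctrl"] == 0.0

    def test_zero_control_finite_with_pseudocount(self):
        table = build_table(
            {"c1": {"F1": 0.0}, "g1": {"F1": 8.0}}, group=["ctrl", "trt"]
        )
        out = log2fc_by_group(table, "ctrl", pseudocount=1.0)
        assert out.loc["F1", "trt"] == pytest.approx(np.log2(9.0))

    def test_absent_control_is_an_error(self):
        with pytest.raises(ValueError):
            log2fc_by_group(self._table(), "germfree")


def correlated_profile(x, r, rng):
    """A vector with exact Pearson correlation r against x."""
    e = rng.normal(size=x.size)
    x_c = (x - x.mean()) / x.std()
    e_c = e - e.mean()
    e_c -= x_c * (e_c @ x_c) / (x_c @ x_c)
    e_c /= np.sqrt((e_c ** 2).mean())
    y = r * x_c + np.sqrt(1 - r ** 2) * e_c
    return y * 2.0 + 10.0  # positive affine: correlation preserved


class TestSynchronizedGroups:
    @staticmethod
    def _table_from_profiles(profiles, timepoints):
        matrix = {}
        for j, t in enumerate(timepoints):
            matrix[f"liver_t{t}"] = {fid: prof[j] for fid, prof in profiles.items()}
        return build_table(
            matrix,
            rt=[2.0] * len(profiles),
            tissue=["liver"] * len(timepoints),
            timepoint=list(timepoints),
        )

    def test_identical_profiles_form_one_group(self):
        prof = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0])
        table = self._table_from_profiles({"F1": prof, "F2": prof * 2.0}, range(6))
        (group,) = synchronized_groups(table, "liver")
        assert group.members == {"F1", "F2"}
        assert group.pairwise_min_r == pytest.approx(1.0)

    @pytest.mark.parametrize("r,expected_groups", [(0.94, 0), (0.96, 1)])
    def test_threshold_boundary(self, r, expected_groups):
        rng = np.random.default_rng(9)
        x = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0])
        y = correlated_profile(x, r, rng)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(r, abs=1e-12)
        table = self._table_from_profiles({"F1": x, "F2": y}, range(6))
        assert len(synchronized_groups(table, "liver")) == expected_groups

    def test_min_shared_timepoints_gate(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        y = x.copy()
        y[2:] = np.nan  # only 2 shared timepoints
        table = self._table_from_profiles({"F1": x, "F2": y}, range(4))
        assert synchronized_groups(table, "liver") == []

    def test_too_few_timepoints_warns_empty(self):
        table = self._table_from_profiles({"F1": np.array([1.0, 2.0])}, range(2))
        with pytest.warns(UserWarning):
            assert synchronized_groups(table, "liver") == []

    def test_planted_groups_recovered_at_zero_noise(self):
        template = np.array([1.0, 4.0, 2.0, 9.0, 5.0, 7.0, 3.0, 8.0])
        table, truth = simulate_timecourse(
            n_features=20,
            tissues=["liver", "gut"],
            timepoints=list(range(8)),
            planted_groups=[("liver", 4, template), ("gut", 3, template[::-1])],
            noise_sd=0.0,
            seed=3,
        )
        for tissue, members in truth:
            groups = synchronized_groups(table, tissue)
            recovered = [g for g in groups if g.members >= members]
            assert recovered, f"planted group in {tissue} not recovered"

    def test_invariant_to_feature_order(self):
        prof = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0])
        profiles = {"F1": prof, "F2": prof * 1.5, "F3": prof[::-1].copy()}
        t1 = self._table_from_profiles(profiles, range(6))
        t2 = self._table_from_profiles(dict(reversed(profiles.items())), range(6))
        g1 = sorted(tuple(sorted(g.members)) for g in synchronized_groups(t1, "liver"))
        g2 = sorted(tuple(sorted(g.members)) for g in synchronized_groups(t2, "liver"))
        assert g1 == g2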