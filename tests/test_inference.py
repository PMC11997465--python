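import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from commphylo import (UntestableError, across_scale_letters,
                       assemble_report, ttest_vs_zero)
from commphylo.inference import anova_oneway, compact_letter_display


class TestTTestVsZero:
    def test_closed_form_fixture(self):
        rep = ttest_vs_zero([0.5, 0.7, 0.9, 1.1, 1.3])
        # closed form: t = mean/(sd/√n) with mean 0.9, sd 0.31623, n 5
        assert rep.mean == pytest.approx(0.9)
        assert rep.t_stat == pytest.approx(6.3640, abs=5e-5)
        assert rep.df == 4
        p_oracle = 2 * stats.t.sf(6.363961030678928, df=4)
        assert rep.p_two_tailed == pytest.approx(p_oracle, rel=1e-6)
        assert rep.p_two_tailed == pytest.approx(0.0031, abs=2e-4)
        assert rep.direction == "clustered"

    def test_symmetric_values_give_t_zero(self):
        rep = ttest_vs_zero([-1.0, 1.0])
        assert rep.t_stat == pytest.approx(0.0)
        assert rep.p_two_tailed == pytest.approx(1.0)
        assert rep.direction == "random"

    def test_single_value_untestable(self):
        with pytest.raises(UntestableError):
            ttest_vs_zero([1.5])

    def test_zero_variance_untestable(self):
        with pytest.raises(UntestableError, match="zero variance"):
            ttest_vs_zero([2.0, 2.0, 2.0])

    def test_nan_values_dropped_and_counted(self):
        rep = ttest_vs_zero([0.5, np.nan, 0.7, 0.9, np.nan, 1.1, 1.3])
        assert rep.n == 5
        assert rep.n_excluded == 2
        assert rep.t_stat == pytest.approx(6.3640, abs=5e-5)

    def test_negative_mean_direction_labels(self):
        vals = [-2.0, -2.5, -1.5, -2.2, -1.8]
        assert ttest_vs_zero(vals).direction == "overdispersed"
        assert ttest_vs_zero(vals, positive_means="divergent").direction == \
            "convergent"

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0.3, 1.0, size=int(rng.integers(3, 40)))
            rep = ttest_vs_zero(x)
            ref = stats.ttest_1samp(x, 0.0)
            assert rep.t_stat == pytest.approx(float(ref.statistic), rel=1e-9)
            assert rep.p_two_tailed == pytest.approx(float(ref.pvalue),
                                                     rel=1e-6)


class TestAcrossScaleLetters:
    def test_same_distribution_usually_one_letter(self):
        rng = np.random.default_rng(1)
        share = 0
        n_runs = 80
        for _ in range(n_runs):
            groups = {s: rng.normal(0, 1, 15) for s in ("a", "b", "c")}
            letters = across_scale_letters(groups, alpha=0.05)
            share += len(set(letters.values())) == 1
        assert share / n_runs >= 0.90

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(2)
        groups = {"s1": rng.normal(0, 1, 20), "s2": rng.normal(5, 1, 20)}
        letters = across_scale_letters(groups)
        assert letters["s1"] != letters["s2"]

    def test_single_group_single_letter(self):
        assert across_scale_letters({"s1": [0.1, 0.4, 0.2]}) == {"s1": "a"}

    def test_untestable_group_lettered_dash(self):
        rng = np.random.default_rng(3)
        groups = {"s1": rng.normal(0, 1, 10), "s2": rng.normal(4, 1, 10),
                  "s3": [1.0]}
        letters = across_scale_letters(groups)
        assert letters["s3"] == "–"
        assert letters["s1"] != letters["s2"]

    @pytest.mark.parametrize("method", ["tukey", "dunn"])
    def test_letters_encode_pairwise_significance_graph(self, method):
        # brute-force check on up to 5 groups: groups share a letter
        # iff the post-hoc test does not separate them
        rng = np.random.default_rng(4)
        for rep in range(10):
            k = int(rng.integers(2, 6))
            means = rng.choice([0.0, 0.0, 2.5, 5.0], size=k)
            groups = {f"g{i}": rng.normal(means[i], 1.0, 25)
                      for i in range(k)}
            if method == "tukey":
                from commphylo.inference import _pairwise_tukey
                sig = _pairwise_tukey(groups, 0.05)
            else:
                from commphylo.inference import _pairwise_dunn
                sig = _pairwise_dunn(groups, 0.05)
            letters = across_scale_letters(groups, method=method)
            for a, b in itertools.combinations(groups, 2):
                shares = bool(set(letters[a]) & set(letters[b]))
                assert shares == (not sig[(a, b)]), (letters, sig)

    def test_anova_helper_matches_scipy(self):
        rng = np.random.default_rng(5)
        groups = {s: rng.normal(0, 1, 12) for s in ("x", "y", "z")}
        f, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups.values())
        assert f == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


class TestCompactLetterDisplay:
    def test_chain_overlap_pattern(self):
        # A≁B, B≁C but A≠C: B must share a letter with both, A and C none
        labels = ["A", "B", "C"]
        means = {"A": 2.0, "B": 1.0, "C": 0.0}
        sig = {("A", "B"): False, ("B", "A"): False,
               ("B", "C"): False, ("C", "B"): False,
               ("A", "C"): True, ("C", "A"): True}
        out = compact_letter_display(labels, means, sig)
        assert set(out["A"]) & set(out["B"])
        assert set(out["B"]) & set(out["C"])
        assert not (set(out["A"]) & set(out["C"]))

    def test_all_different_all_distinct(self):
        labels = ["A", "B", "C"]
        means = {"A": 3.0, "B": 2.0, "C": 1.0}
        sig = {(a, b): True for a in labels for b in labels if a != b}
        out = compact_letter_display(labels, means, sig)
        assert len({out[l] for l in labels}) == 3
        assert all(len(out[l]) == 1 for l in labels)


class TestAssembleReport:
    def make_ses_frame(self, rng):
        rows = []
        for layer in ("tree", "shrub"):
            for pool in ("plot", "regional"):
                for index in ("NRI", "NTI", "FD_SES"):
                    for weighting in ("abundance", "occurrence"):
                        for scale in ("100m2", "400m2", "2500m2"):
                            for q in range(6):
                                rows.append({
                                    "layer": layer, "pool": pool,
                                    "index": index, "weighting": weighting,
                                    "scale": scale,
                                    "ses": rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_full_grid_cardinality(self):
        rng = np.random.default_rng(6)
        rep = assemble_report(self.make_ses_frame(rng))["scale_report"]
        # 2 layers × 2 pools × 3 indices × 2 weightings × 3 scales
        assert len(rep) == 72
        assert set(rep["direction"]) <= {"clustered", "overdispersed",
                                         "random", "divergent", "convergent"}

    def test_empty_input_metadata_only(self):
        out = assemble_report(pd.DataFrame(columns=["ses"]),
                              metadata={"seed": 1})
        assert out["scale_report"].empty
        assert not out["metadata"].empty

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(7)
        frame = self.make_ses_frame(rng)
        a = assemble_report(frame)["scale_report"]
        b = assemble_report(frame)["scale_report"]
        pd.testing.assert_frame_equal(a, b)
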