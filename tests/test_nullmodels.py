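import numpy as np
import pandas as pd
import pytest
from scipy import stats

from commphylo import (CommunityMatrix, NullSpec, SpeciesPool,
                       ValidationError, compute_ses_table,
                       cophenetic_distances, independent_swap, mpd,
                       results_to_frame, ses_engine, simulate_yule_tree,
                       taxa_label_shuffle)


def cm_from_array(arr, species=None):
    arr = np.asarray(arr)
    species = species or [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=species)
    df.insert(0, "layer", "tree")
    df.insert(0, "grid_col", range(arr.shape[0]))
    df.insert(0, "grid_row", 0)
    df.insert(0, "plot_id", "p1")
    return CommunityMatrix(df)


class TestIndependentSwap:
    def test_only_possible_swap_performed(self):
        # values move within their species column, so each species'
        # abundance multiset is preserved exactly
        cm = cm_from_array([[5, 0], [0, 3]])
        out = independent_swap(cm, burnin=1, seed=0)
        np.testing.assert_array_equal(out.abundance_array(),
                                      [[0, 3], [5, 0]])

    def test_no_checkerboard_warns_and_returns_input(self):
        cm = cm_from_array([[1, 1], [1, 1]])
        with pytest.warns(UserWarning, match="swaps possible"):
            out = independent_swap(cm, burnin=5, seed=0)
        np.testing.assert_array_equal(out.abundance_array(),
                                      cm.abundance_array())

    def test_marginals_preserved_after_10000_swaps(self):
        rng = np.random.default_rng(1)
        arr = (rng.random((20, 30)) < 0.3) * rng.integers(1, 20, (20, 30))
        cm = cm_from_array(arr.astype(float))
        out = independent_swap(cm, burnin=10_000, seed=2)
        occ_in, occ_out = arr > 0, out.abundance_array() > 0
        np.testing.assert_array_equal(occ_in.sum(1), occ_out.sum(1))
        np.testing.assert_array_equal(occ_in.sum(0), occ_out.sum(0))
        # species abundance multisets preserved exactly
        for j in range(arr.shape[1]):
            assert sorted(arr[:, j]) == sorted(out.abundance_array()[:, j])
        assert not np.array_equal(arr, out.abundance_array())

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValidationError):
            independent_swap(cm_from_array([[1, 2]]), burnin=1)


class TestTaxaLabelShuffle:
    def test_pool_of_one_is_identity(self):
        phy = simulate_yule_tree(6, seed=0)
        dm = cophenetic_distances(phy)
        pool = SpeciesPool("plot", frozenset([dm.ids[0]]))
        out = taxa_label_shuffle(dm, pool, seed=3)
        assert tuple(out.ids) == tuple(dm.ids)

    def test_reproducible_and_values_untouched(self):
        phy = simulate_yule_tree(10, seed=1)
        dm = cophenetic_distances(phy)
        pool = SpeciesPool("plot", frozenset(dm.ids))
        a = taxa_label_shuffle(dm, pool, seed=7)
        b = taxa_label_shuffle(dm, pool, seed=7)
        assert tuple(a.ids) == tuple(b.ids)
        np.testing.assert_array_equal(a.data, dm.data)

    def test_nonpool_labels_fixed(self):
        phy = simulate_yule_tree(8, seed=2)
        dm = cophenetic_distances(phy)
        keep = set(list(dm.ids)[:3])
        pool = SpeciesPool("plot", frozenset(set(dm.ids) - keep))
        out = taxa_label_shuffle(dm, pool, seed=5)
        for lab in keep:
            assert out.ids[dm.index(lab)] == lab

    def test_positionwise_uniformity(self):
        phy = simulate_yule_tree(5, seed=4)
        dm = cophenetic_distances(phy)
        pool = SpeciesPool("plot", frozenset(dm.ids))
        rng = np.random.default_rng(11)
        counts = {lab: np.zeros(5) for lab in dm.ids}
        n_draws = 10_000
        for _ in range(n_draws):
            out = taxa_label_shuffle(dm, pool, seed=rng)
            for pos, lab in enumerate(out.ids):
                counts[lab][pos] += 1
        for lab in dm.ids:
            chi2 = ((counts[lab] - n_draws / 5) ** 2 / (n_draws / 5)).sum()
            assert stats.chi2.sf(chi2, df=4) > 0.001

    def test_eigenvalues_invariant(self):
        phy = simulate_yule_tree(12, seed=6)
        dm = cophenetic_distances(phy)
        pool = SpeciesPool("plot", frozenset(dm.ids))
        out = taxa_label_shuffle(dm, pool, seed=1)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(out.data)),
                                   np.sort(np.linalg.eigvalsh(dm.data)),
                                   rtol=1e-9)

    def test_missing_pool_member_errors(self):
        phy = simulate_yule_tree(4, seed=0)
        dm = cophenetic_distances(phy)
        with pytest.raises(ValidationError, match="absent"):
            taxa_label_shuffle(dm, SpeciesPool("plot", frozenset(["zzz"])), 0)


class TestSESEngine:
    def setup_method(self):
        self.phy = simulate_yule_tree(20, seed=9)
        self.dm = cophenetic_distances(self.phy)
        self.pool = SpeciesPool("plot", frozenset(self.dm.ids))

    def test_sign_conventions_and_extreme_clustering(self):
        # quadrat of the two most closely related species: obs MPD below
        # every null draw → maximal NRI and minimal rank p
        d = self.dm.data + np.eye(20) * 1e9
        i, j = np.unravel_index(np.argmin(d), d.shape)
        ab = {self.dm.ids[i]: 1, self.dm.ids[j]: 1}
        cm = cm_from_array(np.array([[1 if s in ab else 0 for s in self.dm.ids]] * 2),
                           species=list(self.dm.ids))
        res = ses_engine(cm, self.dm, "MPD", "occurrence",
                         NullSpec(model="taxa_labels", n_rand=199, seed=0),
                         pool=self.pool)
        for r in res:
            assert r.index == "NRI"
            assert r.ses > 0  # clustering → positive NRI
            assert r.p_rank <= 2 / 200

    def test_overdispersed_pair_gives_negative_nri(self):
        d = self.dm.data
        i, j = np.unravel_index(np.argmax(d), d.shape)
        ab = [1 if s in (self.dm.ids[i], self.dm.ids[j]) else 0
              for s in self.dm.ids]
        cm = cm_from_array(np.array([ab, ab]), species=list(self.dm.ids))
        res = ses_engine(cm, self.dm, "MPD", "occurrence",
                         NullSpec(n_rand=199, seed=1), pool=self.pool)
        assert all(r.ses < 0 for r in res)

    def test_obs_at_null_mean_gives_zero_ses(self):
        r = next(iter(compute_ses_table(
            cm_from_array([[1, 1, 0, 0], [0, 0, 1, 1]]),
            self._flat_dm(), metrics=["MFD"], weightings=["occurrence"],
            null=NullSpec(n_rand=49, seed=0))))
        # constant distance matrix: every null draw equals obs → sd 0 → NaN
        assert np.isnan(r.ses)

    @staticmethod
    def _flat_dm():
        from skbio import DistanceMatrix
        return DistanceMatrix(2.0 * (1 - np.eye(4)),
                              ids=["s0", "s1", "s2", "s3"])

    def test_undefined_for_richness_below_two(self):
        cm = cm_from_array([[1, 0, 0, 0], [1, 1, 1, 0]],
                           species=list(self.dm.ids)[:4])
        res = ses_engine(cm, self.dm, "MPD", "abundance",
                         NullSpec(n_rand=49, seed=0), pool=self.pool)
        assert np.isnan(res[0].ses)
        assert np.isfinite(res[1].ses)

    def test_bit_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(3)
        arr = (rng.random((6, 20)) < 0.4) * rng.integers(1, 9, (6, 20))
        cm = cm_from_array(arr.astype(float), species=list(self.dm.ids))
        spec = NullSpec(model="taxa_labels", n_rand=99, seed=42)
        a = results_to_frame(compute_ses_table(cm, self.dm, null=spec,
                                               pool=self.pool))
        b = results_to_frame(compute_ses_table(cm, self.dm, null=spec,
                                               pool=self.pool))
        pd.testing.assert_frame_equal(a, b)

    def test_swap_null_runs_and_matches_sign_logic(self):
        rng = np.random.default_rng(5)
        arr = (rng.random((10, 20)) < 0.35) * rng.integers(1, 9, (10, 20))
        cm = cm_from_array(arr.astype(float), species=list(self.dm.ids))
        res = compute_ses_table(
            cm, self.dm, metrics=["MPD", "MNTD"],
            weightings=["abundance"],
            null=NullSpec(model="independent_swap", n_rand=49,
                          swap_burnin=300, seed=8))
        frame = results_to_frame(res)
        assert set(frame["index"]) == {"NRI", "NTI"}
        assert frame["ses"].notna().all()
        # NRI = −(obs − mean)/sd exactly
        row = frame.iloc[0]
        assert row.ses == pytest.approx(
            -(row.obs - row.null_mean) / row.null_sd, rel=1e-12)

    def test_fd_ses_sign_is_unflipped(self):
        rng = np.random.default_rng(6)
        arr = (rng.random((4, 20)) < 0.5) * 1.0
        cm = cm_from_array(arr, species=list(self.dm.ids))
        frame = results_to_frame(compute_ses_table(
            cm, self.dm, metrics=["MFD"], weightings=["occurrence"],
            null=NullSpec(n_rand=99, seed=2), pool=self.pool))
        for _, row in frame.dropna(subset=["ses"]).iterrows():
            assert row.ses == pytest.approx(
                (row.obs - row.null_mean) / row.null_sd, rel=1e-12)
            assert row["index"] == "FD_SES"
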