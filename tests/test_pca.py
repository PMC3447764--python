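"""Proportional coding, SVD imputation and PCA structure recovery."""

import numpy as np
import pandas as pd
import pytest

from snppanel.panel import HET, HOM_ALT, HOM_REF, MISSING, PanelError, SubpopulationScheme
from snppanel.pca import (
    CodedMatrix,
    eigen_anova,
    loading_screen,
    pca,
    proportional_coding,
    svd_impute,
)
from snppanel.simulate import SubpopSpec, assemble_panel, small_config

from conftest import make_panel


class TestProportionalCoding:
    def test_codes_follow_common_allele(self):
        # common allele (from all accessions) is REF at m0, ALT at m1
        panel = make_panel(
            [
                [HOM_REF, HOM_ALT],
                [HOM_REF, HOM_ALT],
                [HET, HET],
                [HOM_ALT, HOM_REF],
            ]
        )
        coded = proportional_coding(panel, panel.accession_ids)
        assert coded.values[0, 0] == 2.0  # hom common
        assert coded.values[2, 0] == 1.0  # het
        assert coded.values[3, 0] == 0.0  # hom rare
        # at m1 the common allele is ALT, so codes flip
        assert coded.values[0, 1] == 2.0
        assert coded.values[3, 1] == 0.0

    def test_missing_becomes_nan(self):
        panel = make_panel([[MISSING], [HOM_REF], [HOM_REF]])
        coded = proportional_coding(panel, panel.accession_ids)
        assert np.isnan(coded.values[0, 0])

    def test_undefined_reference_marker_excluded(self):
        panel = make_panel([[HOM_REF, MISSING], [HOM_REF, MISSING]])
        coded = proportional_coding(panel, panel.accession_ids)
        assert coded.marker_ids == ["m0"]


class TestSvdImpute:
    def test_complete_matrix_unchanged(self):
        x = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(svd_impute(x.copy(), rank=2), x)

    def test_exact_rank_recovery(self):
        # construct an exactly rank-2 matrix, mask 10% of cells; the
        # construction is its own oracle
        rng = np.random.default_rng(41)
        u = rng.normal(size=(40, 2))
        v = rng.normal(size=(2, 60))
        x = u @ v
        mask = rng.random(x.shape) < 0.10
        xm = x.copy()
        xm[mask] = np.nan
        completed = svd_impute(xm, rank=2, tol=1e-10, max_iter=500)
        assert np.allclose(completed[mask], x[mask], atol=1e-6)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(20, 30))
        mask = rng.random(x.shape) < 0.2
        xm = x.copy()
        xm[mask] = np.nan
        completed = svd_impute(xm, rank=5)
        assert np.array_equal(completed[~mask], x[~mask])

    def test_beats_column_mean_on_structured_panel(self):
        cfg = small_config(
            seed=43,
            subpops=[SubpopSpec("a", 40, 0.4), SubpopSpec("b", 40, 0.4)],
            n_markers_per_chrom=(200,),
            map_length_cM=(100.0,),
            missing_rate=0.0,
        )
        panel, _ = assemble_panel(cfg)
        coded = proportional_coding(panel, panel.accession_ids)
        x = coded.values
        rng = np.random.default_rng(44)
        mask = rng.random(x.shape) < 0.05
        xm = x.copy()
        xm[mask] = np.nan
        completed = svd_impute(xm, rank=5)
        col_mean = np.nanmean(xm, axis=0)
        mse_svd = np.mean((completed[mask] - x[mask]) ** 2)
        mse_mean = np.mean((np.broadcast_to(col_mean, x.shape)[mask] - x[mask]) ** 2)
        assert mse_svd < mse_mean

    def test_refuses_mostly_missing(self):
        x = np.full((10, 10), np.nan)
        x[0, :] = 1.0
        with pytest.raises(PanelError):
            svd_impute(x, rank=2)


class TestPca:
    def test_perfectly_correlated_markers_load_on_pc1(self):
        z = np.array([2.0, 1.0, 0.0, 2.0, 0.0])
        x = np.column_stack([z, z])
        res = pca(x)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(45)
        x = rng.normal(size=(15, 25))
        res = pca(x)
        assert res.variance_explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_loadings_unit_norm(self):
        rng = np.random.default_rng(46)
        res = pca(rng.normal(size=(10, 20)), n_components=3)
        norms = np.linalg.norm(res.loadings.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0)

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(47)
        x = rng.normal(size=(12, 18))
        perm = rng.permutation(18)
        v1 = pca(x).variance_explained
        v2 = pca(x[:, perm]).variance_explained
        assert np.allclose(v1, v2)

    def test_two_groups_split_by_pc1_sign(self):
        cfg = small_config(
            seed=48,
            subpops=[SubpopSpec("a", 30, 0.3), SubpopSpec("b", 30, 0.3)],
            n_markers_per_chrom=(300,),
            map_length_cM=(100.0,),
            ld_scale_cM=0.01,
        )
        panel, _ = assemble_panel(cfg)
        coded = proportional_coding(panel, panel.inbred_ids(), group=panel.inbred_ids())
        completed = svd_impute(coded, rank=5)
        res = pca(completed, coded.accession_ids, coded.marker_ids, n_components=2)
        scheme = SubpopulationScheme.from_panel(panel)
        signs = {
            lab: np.sign(res.scores.loc[ids, "PC1"]).to_numpy()
            for lab, ids in scheme.groups().items()
        }
        # each group on one side of the axis
        assert abs(signs["a"].mean()) > 0.9
        assert abs(signs["b"].mean()) > 0.9
        assert np.sign(signs["a"].mean()) != np.sign(signs["b"].mean())


class TestLoadingScreen:
    def _result_with_loadings(self, loadings, chroms):
        mk = pd.DataFrame(
            {"chrom": chroms},
            index=pd.Index([f"m{i}" for i in range(len(chroms))], name="marker_id"),
        )
        res = type("R", (), {})()
        res.loadings = pd.DataFrame(
            {"PC1": loadings}, index=mk.index
        )
        return res, mk

    def test_all_below_threshold_empty(self):
        res, mk = self._result_with_loadings([0.01, -0.015, 0.0], ["1", "2", "3"])
        tab, summary = loading_screen(res, mk, threshold=0.02)
        assert len(tab) == 0

    def test_threshold_strict(self):
        res, mk = self._result_with_loadings([0.02, 0.021], ["1", "1"])
        tab, _ = loading_screen(res, mk, threshold=0.02)
        assert list(tab.index) == ["m1"]

    def test_percentages_sum_to_100(self):
        res, mk = self._result_with_loadings([0.5, -0.4, 0.3, 0.0], ["1", "2", "2", "3"])
        _, summary = loading_screen(res, mk, threshold=0.02)
        assert summary["percentage"].sum() == pytest.approx(100.0)

    def test_differentiating_chromosome_dominates_screen(self):
        # construction oracle: only chromosome-2 markers differ between the
        # groups, so screened markers should concentrate there
        rng = np.random.default_rng(49)
        n = 40
        g = np.zeros((2 * n, 60), dtype=np.int8)
        chroms = ["1"] * 30 + ["2"] * 30
        g[:, :30] = rng.choice(
            [HOM_REF, HOM_ALT], size=(2 * n, 30), p=[0.7, 0.3]
        )  # shared noise
        g[:n, 30:] = HOM_REF
        g[n:, 30:] = HOM_ALT
        panel = make_panel(
            g, chroms=chroms, cms=list(np.arange(30.0)) * 2,
            subpops=["a"] * n + ["b"] * n,
        )
        coded = proportional_coding(panel, panel.accession_ids)
        res = pca(coded.values, coded.accession_ids, coded.marker_ids, n_components=2)
        # threshold above the noise-loading band of this small matrix
        _, summary = loading_screen(
            res, panel.markers.set_index("marker_id"), threshold=0.05
        )
        assert summary.loc["2", "percentage"] > 95.0


class TestEigenAnova:
    def _result(self, scores_by_group):
        ids, vals, assign = [], [], {}
        for lab, scores in scores_by_group.items():
            for i, s in enumerate(scores):
                aid = f"{lab}{i}"
                ids.append(aid)
                vals.append(s)
                assign[aid] = lab
        res = type("R", (), {})()
        res.scores = pd.DataFrame({"PC1": vals}, index=ids)
        return res, SubpopulationScheme(assign)

    def test_disjoint_groups_highly_significant(self):
        res, scheme = self._result(
            {"a": [0.0, 0.1, 0.2, 0.1], "b": [5.0, 5.1, 5.2, 5.3]}
        )
        out = eigen_anova(res, scheme, pc_set=("PC1",))
        assert out.loc["PC1", "p_value"] < 0.001

    def test_identical_scores_give_null(self):
        res, scheme = self._result({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        out = eigen_anova(res, scheme, pc_set=("PC1",))
        assert out.loc["PC1", "F"] == 0.0
        assert out.loc["PC1", "p_value"] == 1.0

    def test_single_group_is_error(self):
        res, scheme = self._result({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(PanelError):
            eigen_anova(res, scheme, pc_set=("PC1",))

    def test_permuted_labels_give_uniform_p(self):
        # permutation oracle: under random labels p is U(0,1); check the
        # empirical distribution over repetitions is not concentrated
        rng = np.random.default_rng(50)
        scores = rng.normal(size=30)
        pvals = []
        for _ in range(200):
            labels = rng.permutation(["a"] * 15 + ["b"] * 15)
            res = type("R", (), {})()
            ids = [f"s{i}" for i in range(30)]
            res.scores = pd.DataFrame({"PC1": scores}, index=ids)
            scheme = SubpopulationScheme(dict(zip(ids, labels)))
            pvals.append(eigen_anova(res, scheme, pc_set=("PC1",)).loc["PC1", "p_value"])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01
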