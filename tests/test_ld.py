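"""Pairwise r^2, decay fits (LOESS / Hill-Weir), baselines, decay distance."""

import numpy as np
import pandas as pd
import pytest

from snppanel.panel import HOM_ALT, HOM_REF, MISSING, PanelError, SubpopulationScheme
from snppanel import qc
from snppanel.ld import (
    DecayFit,
    LdPointSet,
    baseline_r2,
    decay_distance,
    hill_weir_expected_r2,
    hill_weir_fit,
    loess_decay,
    pairwise_r2,
    r2_matrix,
)
from snppanel.simulate import SubpopSpec, assemble_panel, small_config

from conftest import make_panel


def _points(d, r2, n_acc=100, chrom="1", label="g"):
    return LdPointSet(
        pairs=pd.DataFrame(
            {
                "marker_a": [f"a{i}" for i in range(len(d))],
                "marker_b": [f"b{i}" for i in range(len(d))],
                "distance_cM": d,
                "r2": r2,
                "n_obs": n_acc,
            }
        ),
        chromosome=chrom,
        group_label=label,
        n_accessions=n_acc,
        n_pairs_dropped=0,
    )


class TestPairwiseR2:
    def test_duplicated_marker_gives_one(self):
        rng = np.random.default_rng(81)
        col = rng.choice([HOM_REF, HOM_ALT], size=50, p=[0.6, 0.4]).astype(np.int8)
        panel = make_panel(np.column_stack([col, col]), cms=[0.0, 3.0])
        pts = pairwise_r2(panel, panel.accession_ids, "1", panel.marker_ids)
        assert pts.pairs["r2"].iloc[0] == pytest.approx(1.0)
        assert pts.pairs["distance_cM"].iloc[0] == pytest.approx(3.0)

    def test_independent_markers_r2_at_noise_floor(self):
        # sampling-theory oracle: E[r^2] ~ 1/n for independent loci
        rng = np.random.default_rng(82)
        n = 400
        g = rng.choice([HOM_REF, HOM_ALT], size=(n, 40), p=[0.5, 0.5]).astype(np.int8)
        panel = make_panel(g)
        pts = pairwise_r2(panel, panel.accession_ids, "1", panel.marker_ids)
        assert pts.pairs["r2"].mean() == pytest.approx(1 / n, abs=2 / n)

    def test_copula_chromosome_decays_with_distance(self):
        cfg = small_config(
            seed=83,
            subpops=[SubpopSpec("a", 100, 0.2), SubpopSpec("b", 5, 0.2)],
            n_markers_per_chrom=(100, 20),
            map_length_cM=(50.0, 50.0),
            ld_scale_cM=5.0,
            selfing_inbreeding=1.0,
        )
        panel, _ = assemble_panel(cfg)
        ids = SubpopulationScheme.from_panel(panel).groups()["a"]
        mids = qc.filter_markers(panel, min_maf=0.1, require_map=True, group=ids)
        pts = pairwise_r2(panel, ids, "1", mids)
        near = pts.pairs[pts.pairs["distance_cM"] < 2]["r2"].mean()
        far = pts.pairs[pts.pairs["distance_cM"] > 20]["r2"].mean()
        assert near > 5 * far

    def test_sparse_joint_observations_dropped(self):
        g = np.full((12, 2), HOM_REF, dtype=np.int8)
        g[:6, 0] = MISSING  # only 6 joint observations
        g[6:, 1] = HOM_ALT
        panel = make_panel(g)
        pts = pairwise_r2(panel, panel.accession_ids, "1", panel.marker_ids, min_obs=10)
        assert len(pts.pairs) == 0
        assert pts.n_pairs_dropped == 1

    def test_r2_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(84)
        h = rng.choice([0.0, 1.0], size=(80, 5))
        r2, _ = r2_matrix(h, min_obs=5)
        assert np.allclose(r2, r2.T, equal_nan=True)
        r2_flipped, _ = r2_matrix(1.0 - h, min_obs=5)
        assert np.allclose(r2, r2_flipped, equal_nan=True)


class TestLoess:
    def test_constant_input_gives_flat_curve(self):
        rng = np.random.default_rng(85)
        d = rng.uniform(0, 30, 50)
        fit = loess_decay(_points(d, np.full(50, 0.4)))
        assert np.allclose(fit.curve, 0.4, atol=1e-8)

    def test_noiseless_line_reproduced(self):
        d = np.linspace(0, 10, 60)
        r2 = 0.9 - 0.05 * d
        fit = loess_decay(_points(d, r2))
        assert np.allclose(fit.evaluate(d), r2, atol=0.01)

    def test_too_few_points_is_error(self):
        with pytest.raises(PanelError):
            loess_decay(_points(np.arange(10.0), np.full(10, 0.3)))

    def test_degenerate_distances_is_error(self):
        with pytest.raises(PanelError):
            loess_decay(_points(np.full(30, 2.0), np.full(30, 0.3)))


class TestHillWeir:
    def test_limit_at_large_c_is_zero(self):
        # the drift expectation vanishes as C grows; the sample-size term
        # leaves a 1/n floor, so take the joint limit with large n
        assert hill_weir_expected_r2(1e9, 10**9) == pytest.approx(0.0, abs=1e-6)
        # at finite n the asymptote is the sampling floor 1/n
        assert hill_weir_expected_r2(1e9, 100) == pytest.approx(0.01, abs=1e-4)

    def test_value_at_c_zero_large_n(self):
        assert hill_weir_expected_r2(0.0, 10**9) == pytest.approx(10 / 22)

    def test_self_consistency_recovers_rho(self):
        # data generated from the model itself at rho = 0.5, n = 100
        rng = np.random.default_rng(86)
        d = rng.uniform(0.1, 40, 300)
        r2 = hill_weir_expected_r2(0.5 * d, 100) + rng.normal(0, 0.02, 300)
        fit = hill_weir_fit(_points(d, np.clip(r2, 0, 1)), n=100)
        assert fit.rho == pytest.approx(0.5, abs=0.05)

    def test_small_sample_rejected(self):
        with pytest.raises(PanelError):
            hill_weir_fit(_points(np.arange(30.0), np.full(30, 0.2), n_acc=5))


class TestBaseline:
    def test_fixed_method(self):
        panel, _ = assemble_panel(small_config(seed=87))
        ids = SubpopulationScheme.from_panel(panel).groups()["popA"]
        assert baseline_r2(panel, ids, panel.marker_ids, method="fixed") == 0.2

    def test_constant_unlinked_distribution_returns_constant(self):
        # duplicated calls across two chromosomes: every unlinked pair has
        # r^2 = 1, and the percentile of a constant distribution is that
        # constant
        rng = np.random.default_rng(88)
        col = rng.choice([HOM_REF, HOM_ALT], size=60, p=[0.5, 0.5]).astype(np.int8)
        g = np.column_stack([col] * 4)
        panel = make_panel(g, chroms=["1", "1", "2", "2"], cms=[0.0, 1.0, 0.0, 1.0])
        val = baseline_r2(
            panel, panel.accession_ids, panel.marker_ids, min_pairs=1,
            rng=np.random.default_rng(0),
        )
        assert val == pytest.approx(1.0)

    def test_single_chromosome_is_error(self):
        panel = make_panel(np.full((30, 4), HOM_REF, dtype=np.int8))
        with pytest.raises(PanelError):
            baseline_r2(panel, panel.accession_ids, panel.marker_ids, min_pairs=1)

    def test_empirical_percentile_matches_chi2_null(self):
        # sampling-distribution oracle: for independent biallelic markers,
        # n * r^2 ~ chi-square(1), so the empirical 95th percentile of
        # unlinked r^2 is about 3.84 / n
        from scipy.stats import chi2

        rng = np.random.default_rng(89)
        n = 200
        g = rng.choice([HOM_REF, HOM_ALT], size=(n, 60), p=[0.5, 0.5]).astype(np.int8)
        panel = make_panel(g, chroms=["1"] * 30 + ["2"] * 30, cms=list(np.arange(30.0)) * 2)
        val = baseline_r2(
            panel, panel.accession_ids, panel.marker_ids,
            parametric=False, rng=np.random.default_rng(1),
        )
        expected = chi2.ppf(0.95, df=1) / n
        assert val == pytest.approx(expected, rel=0.35)


class TestDecayDistance:
    def test_never_crossing_is_not_determined(self):
        fit = DecayFit("LOESS", np.linspace(0, 20, 2001), np.full(2001, 0.5))
        dd, started_below = decay_distance(fit, 0.2)
        assert dd is None and not started_below

    def test_exponential_curve_closed_form(self):
        grid = np.arange(0.0, 10.0, 0.01)
        fit = DecayFit("NLR", grid, np.exp(-grid))
        dd, _ = decay_distance(fit, 0.2)
        assert dd == pytest.approx(-np.log(0.2), abs=0.011)

    def test_started_below_reports_zero(self):
        grid = np.arange(0.0, 5.0, 0.01)
        fit = DecayFit("NLR", grid, np.full(len(grid), 0.1))
        dd, started_below = decay_distance(fit, 0.2)
        assert dd == 0.0 and started_below

    def test_matches_brute_force_grid_scan(self):
        rng = np.random.default_rng(90)
        grid = np.arange(0.0, 30.0, 0.01)
        curve = np.clip(0.8 * np.exp(-grid / 7.0) + 0.01, 0, 1)
        fit = DecayFit("NLR", grid, curve)
        dd, _ = decay_distance(fit, 0.25)
        brute = grid[np.argmax(curve <= 0.25)]
        assert dd == pytest.approx(brute)

    def test_lower_baseline_never_shortens_decay(self):
        grid = np.arange(0.0, 30.0, 0.01)
        curve = np.clip(0.8 * np.exp(-grid / 7.0), 0, 1)
        fit = DecayFit("LOESS", grid, curve)
        d_hi, _ = decay_distance(fit, 0.3)
        d_lo, _ = decay_distance(fit, 0.1)
        assert d_lo >= d_hi
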