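"""Difference maps, fraction-changed, PCA, AUC and gene-set effects."""

import numpy as np
import pandas as pd
import pytest

from chromastress import ncounter as nc
from chromastress import responsiveness as resp
from chromastress.errors import ConfigError, EstimationError
from chromastress.synthetic import SimConfig, gen_count_experiment

from conftest import make_diffmap


def pipeline(cfg, true_fits=False):
    counts, truth = gen_count_experiment(cfg)
    if true_fits:
        # bypass estimation: normalize with the planted per-sample (a, b)
        fits = {sid: nc.NormalizationFit(sid, a=row.a, b=row.b, fit_r2=1.0,
                                         reference_id="truth")
                for sid, row in truth.sample_params.iterrows()
                if row.strain != "WT"}
    else:
        fits = nc.fit_samples(counts, robust=True)
    norm = nc.normalize(counts, fits)
    vs = nc.fit_stabilizer(norm, fits) if fits else None
    return resp.difference_map(norm, vs), truth


class TestDifferenceMap:
    def test_null_mutant_column_near_zero(self):
        cfg = SimConfig(n_probes=40, n_mutants=3, noise_model="none",
                        hyper_frac=0.0, hypo_frac=0.0, mutant_noise_sd=0.0,
                        wt_scale_range=(1.0, 1.0), wt_background_range=(0.0, 0.0),
                        seed=1)
        dm, _ = pipeline(cfg)
        assert np.nanmax(np.abs(dm.values.to_numpy())) < 1e-6

    def test_hypo_mutant_negative_at_induced_probes_during_stress(self):
        cfg = SimConfig(n_probes=60, n_mutants=6, noise_model="none",
                        hyper_frac=0.0, hypo_frac=1.0, mutant_noise_sd=0.0,
                        wt_scale_range=(1.0, 1.0), wt_background_range=(0.0, 0.0),
                        seed=2)
        dm, truth = pipeline(cfg, true_fits=True)
        induced = truth.probe_archetype.index[truth.probe_archetype == "induced"]
        for m in dm.mutants:
            for t in (15.0, 45.0):
                vals = dm.values.loc[induced, (m, t)]
                assert (vals < 0).all()

    def test_antisymmetry_under_swap(self):
        vs = nc.VarianceStabilizer(glog_offset=20.0)
        x = np.array([10.0, 200.0, 5000.0])
        y = np.array([30.0, 180.0, 2500.0])
        np.testing.assert_allclose(vs.delta_h(x, y), -vs.delta_h(y, x))


class TestFractionChanged:
    def test_all_zero_map(self):
        dm = make_diffmap(np.zeros((4, 2)), ["m1"], [0.0, 15.0])
        frac = resp.fraction_changed(dm)
        assert (frac["frac_up"] == 0).all() and (frac["frac_down"] == 0).all()

    def test_hand_enumerated_toy_map(self):
        # single time point, 2 mutants x 3 probes:
        # entries {0.6, -0.7, 0.2, 0.5, -0.4, 1.2}; threshold 0.5 (strict)
        vals = np.array([[0.6, 0.5], [-0.7, -0.4], [0.2, 1.2]])
        dm = make_diffmap(vals, ["m1", "m2"], [15.0])
        frac = resp.fraction_changed(dm, threshold=0.5)
        assert frac.loc[15.0, "frac_up"] == pytest.approx(2.0 / 6.0)
        assert frac.loc[15.0, "frac_down"] == pytest.approx(1.0 / 6.0)

    def test_monotone_in_threshold_and_inf_limit(self, rng):
        dm = make_diffmap(rng.normal(0, 1, (30, 8)),
                          ["a", "b"], [0.0, 15.0, 45.0, 90.0])
        prev = None
        for thr in (0.25, 0.5, 1.0, 2.0, np.inf):
            frac = resp.fraction_changed(dm, threshold=thr)
            tot = (frac["frac_up"] + frac["frac_down"]).to_numpy()
            if prev is not None:
                assert np.all(tot <= prev + 1e-12)
            prev = tot
        assert np.all(tot == 0.0)

    def test_masked_entries_excluded_from_denominator(self):
        vals = np.array([[0.6, np.nan], [np.nan, 0.7]])
        dm = make_diffmap(vals, ["m1", "m2"], [15.0])
        frac = resp.fraction_changed(dm, threshold=0.5)
        assert frac.loc[15.0, "frac_up"] == pytest.approx(1.0)


class TestPCA:
    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(0, 1, (5, 4))
        dm = make_diffmap(X.T, [f"m{i}" for i in range(5)], [15.0])
        res = resp.pca_responsiveness(dm)
        Xc = X - X.mean(axis=0)
        w, _ = np.linalg.eigh(Xc.T @ Xc / (5 - 1))
        w = w[::-1]
        np.testing.assert_allclose(res.variance_explained,
                                   (w / w.sum())[:len(res.variance_explained)],
                                   atol=1e-8)
        # score variances are the eigenvalues
        sv = res.scores.to_numpy().var(axis=0, ddof=1)
        np.testing.assert_allclose(sv, w[:sv.size], atol=1e-8)

    def test_opposite_profiles_symmetric_scores(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        X = np.stack([v, -v])
        dm = make_diffmap(X.T, ["m1", "m2"], [15.0])
        res = resp.pca_responsiveness(dm, n_components=1)
        s = res.scores["PC1"].to_numpy()
        assert s[0] == pytest.approx(-s[1], rel=1e-9)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_probe_reordering_invariance(self, rng):
        X = rng.normal(0, 1, (6, 10))
        probes = [f"p{i}" for i in range(10)]
        dm = make_diffmap(X.T, [f"m{i}" for i in range(6)], [15.0],
                          probes=probes)
        perm = rng.permutation(10)
        dm2 = make_diffmap(X.T[perm], [f"m{i}" for i in range(6)], [15.0],
                           probes=[probes[i] for i in perm])
        r1 = resp.pca_responsiveness(dm)
        r2 = resp.pca_responsiveness(dm2)
        np.testing.assert_allclose(np.abs(r1.scores.to_numpy()),
                                   np.abs(r2.scores.to_numpy()), atol=1e-9)

    def test_variance_explained_shape(self, rng):
        dm = make_diffmap(rng.normal(0, 1, (20, 12)),
                          [f"m{i}" for i in range(6)], [0.0, 15.0])
        res = resp.pca_responsiveness(dm)
        ve = res.variance_explained
        assert ve.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(ve) <= 1e-12)

    def test_hyper_hypo_opposite_pc1_signs(self):
        cfg = SimConfig(n_probes=60, n_mutants=12, noise_model="poisson",
                        hyper_frac=0.5, hypo_frac=0.5, mutant_noise_sd=0.05,
                        wt_scale_range=(1.0, 1.0), wt_background_range=(0.0, 0.0),
                        seed=21)
        dm, truth = pipeline(cfg)
        induced = truth.probe_archetype.index[truth.probe_archetype == "induced"]
        res = resp.pca_responsiveness(dm, induced_probes=induced)
        s = res.scores["PC1"]
        hyper = truth.mutant_class[truth.mutant_class == "hyper"].index
        hypo = truth.mutant_class[truth.mutant_class == "hypo"].index
        assert s[hyper].mean() > 0 > s[hypo].mean()

    def test_pc1_rank_orders_planted_amplitudes(self):
        # with every mutant carrying an amplitude factor, PC1 must
        # rank-correlate with the planted factors at rho >= 0.9
        from scipy.stats import spearmanr
        cfg = SimConfig(n_probes=200, n_mutants=60, hyper_frac=0.5,
                        hypo_frac=0.5, mutant_noise_sd=0.1, seed=8,
                        wt_scale_range=(1.0, 1.0),
                        wt_background_range=(0.0, 0.0))
        dm, truth = pipeline(cfg)
        induced = truth.probe_archetype.index[truth.probe_archetype == "induced"]
        res = resp.pca_responsiveness(dm, induced_probes=induced)
        rho = spearmanr(res.scores["PC1"],
                        truth.mutant_factor[res.scores.index]).statistic
        assert rho >= 0.9

    def test_degenerate_input_is_error(self):
        dm = make_diffmap(np.ones((4, 3)), ["a", "b", "c"], [15.0])
        with pytest.raises(EstimationError):
            resp.pca_responsiveness(dm)


class TestAUC:
    def test_constant_effect_closed_form(self):
        dm = make_diffmap(np.full((3, 4), 0.8), ["m1"],
                          [0.0, 15.0, 45.0, 90.0])
        auc = resp.auc_effect(dm, ["p0", "p1"])
        assert auc["m1"] == pytest.approx(0.8 * 90.0)

    def test_toy_series_matches_trapezoid_oracle(self):
        # series (0, 1, 1, 0) at t = (0, 15, 45, 90):
        # segments 15*(0+1)/2 + 30*(1+1)/2 + 45*(1+0)/2 = 7.5 + 30 + 22.5
        series = np.array([0.0, 1.0, 1.0, 0.0])
        times = [0.0, 15.0, 45.0, 90.0]
        dm = make_diffmap(series[None, :], ["m1"], times)
        auc = resp.auc_effect(dm, ["p0"])
        assert auc["m1"] == pytest.approx(60.0)
        assert auc["m1"] == pytest.approx(np.trapezoid(series, times))

    def test_zero_map_zero_auc_and_empty_set_error(self):
        dm = make_diffmap(np.zeros((3, 4)), ["m1"], [0.0, 15.0, 45.0, 90.0])
        assert resp.auc_effect(dm, ["p0"])["m1"] == 0.0
        with pytest.raises(ConfigError):
            resp.auc_effect(dm, [])


class TestGenesetScatter:
    def test_identical_sets_on_diagonal(self, rng):
        X = rng.normal(0, 1, (6, 4))
        X[3:] = X[:3]  # second set mirrors the first probe-for-probe
        dm = make_diffmap(X, ["m1"], [0.0, 15.0, 45.0, 90.0])
        sc = resp.geneset_scatter(dm, ["p0", "p1", "p2"], ["p3", "p4", "p5"])
        np.testing.assert_allclose(sc["mean_a"], sc["mean_b"])

    def test_single_gene_sets_equal_own_entries(self):
        vals = np.array([[0.3, -0.1], [0.9, 0.4]])
        dm = make_diffmap(vals, ["m1"], [0.0, 15.0])
        sc = resp.geneset_scatter(dm, ["p0"], ["p1"])
        assert sc.loc[("m1", 0.0), "mean_a"] == 0.3
        assert sc.loc[("m1", 15.0), "mean_b"] == 0.4

    def test_overlapping_sets_rejected(self):
        dm = make_diffmap(np.zeros((3, 2)), ["m1"], [0.0, 15.0])
        with pytest.raises(ConfigError):
            resp.geneset_scatter(dm, ["p0", "p1"], ["p1", "p2"])
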