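"""Generators: forward-model identities, moment checks, determinism."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from chromastress import kinetics as K
from chromastress.errors import ConfigError
from chromastress.metagene import assign_bins, metagene_profile
from chromastress.synthetic import (SimConfig, gen_cell_traces,
                                    gen_count_experiment, gen_image_sequence,
                                    gen_tiling_dataset)


class TestSimConfig:
    def test_invalid_fields_named(self):
        with pytest.raises(ConfigError, match="hyper_frac"):
            SimConfig(hyper_frac=1.5).validate()
        with pytest.raises(ConfigError, match="time_points_min"):
            SimConfig(time_points_min=(0, 45, 15)).validate()
        with pytest.raises(ConfigError, match="scale_range"):
            SimConfig(scale_range=(0.0, 1.0)).validate()
        with pytest.raises(ConfigError, match="noise_model"):
            SimConfig(noise_model="cauchy").validate()


class TestCountExperiment:
    def test_zero_noise_identity_case(self):
        # a=1, b=0, no noise, null mutants: observed equals the latent
        # wild-type trajectory exactly
        cfg = SimConfig(n_probes=20, n_mutants=2, noise_model="none",
                        scale_range=(1.0, 1.0), background_range=(0.0, 0.0),
                        hyper_frac=0.0, hypo_frac=0.0, mutant_noise_sd=0.0,
                        seed=3)
        counts, truth = gen_count_experiment(cfg)
        np.testing.assert_array_equal(counts.values.to_numpy(),
                                      truth.latent.to_numpy())
        for t_idx, t in enumerate(cfg.time_points_min):
            col = counts.values[f"mut000_t{t:g}_r1"]
            np.testing.assert_allclose(col, truth.wt_trajectory[t], rtol=1e-12)

    def test_affine_forcing(self):
        cfg = SimConfig(n_probes=15, n_mutants=2, noise_model="none",
                        scale_range=(2.0, 2.0), background_range=(50.0, 50.0),
                        hyper_frac=0.0, hypo_frac=0.0, mutant_noise_sd=0.0,
                        seed=4)
        counts, truth = gen_count_experiment(cfg)
        np.testing.assert_allclose(counts.values.to_numpy(),
                                   2.0 * truth.latent.to_numpy() + 50.0,
                                   rtol=1e-12)

    def test_poisson_moments(self):
        # every entry is one Poisson draw with mean a*latent+b; standardized
        # residuals over ~10^4 entries should average ~0 with unit variance
        cfg = SimConfig(n_probes=200, n_mutants=8, seed=5)
        counts, truth = gen_count_experiment(cfg)
        sp = truth.sample_params
        mean = (truth.latent.to_numpy() * sp["a"].to_numpy()[None, :]
                + sp["b"].to_numpy()[None, :])
        z = (counts.values.to_numpy() - mean) / np.sqrt(mean)
        n = z.size
        assert abs(z.mean()) < 3.0 / np.sqrt(n)
        assert abs(z.var() - 1.0) < 3.0 * np.sqrt(2.0 / n)

    def test_poisson_counts_are_nonnegative_integers(self):
        counts, _ = gen_count_experiment(SimConfig(n_probes=30, n_mutants=3,
                                                   seed=6))
        v = counts.values.to_numpy()
        assert np.all(v >= 0)
        assert np.all(v == np.round(v))

    def test_seed_determinism(self):
        cfg = SimConfig(n_probes=25, n_mutants=4, seed=9)
        c1, _ = gen_count_experiment(cfg)
        c2, _ = gen_count_experiment(cfg)
        np.testing.assert_array_equal(c1.values.to_numpy(), c2.values.to_numpy())

    def test_planted_complex_indices_respected(self):
        cfg = SimConfig(n_probes=20, n_mutants=10, seed=2,
                        planted_complexes=((0, 1, 2), (5, 6)),
                        hyper_frac=0.0, hypo_frac=0.0)
        _, truth = gen_count_experiment(cfg)
        assert list(truth.mutant_class.iloc[[0, 1, 2]]) == ["complex_0"] * 3
        assert list(truth.mutant_class.iloc[[5, 6]]) == ["complex_1"] * 2


class TestCellTraces:
    def test_zero_noise_equals_protein_curve(self):
        cfg = SimConfig(n_cells=5, noise_sd_frac=0.0, seed=1)
        traces, truth = gen_cell_traces(cfg)
        for cid, row in truth.cell_params.iterrows():
            p = K.KineticParams(row.t_on, row.t_off, row.beta, row.gamma, row.g0)
            g = traces.trace(cid).sort_values("time_min")["gfp"].to_numpy()
            np.testing.assert_allclose(g, K.protein_curve(traces.times, p),
                                       rtol=1e-12)

    def test_no_responders_all_flat_at_basal(self):
        cfg = SimConfig(n_cells=10, responder_frac=0.0, noise_sd_frac=0.0,
                        seed=2)
        traces, truth = gen_cell_traces(cfg)
        for cid, row in truth.cell_params.iterrows():
            g = traces.trace(cid)["gfp"].to_numpy()
            np.testing.assert_allclose(g, row.g0, rtol=1e-12)
        assert not truth.cell_params["responder"].any()

    def test_noise_moment_check(self):
        # mean squared residual vs the true curve estimates sigma^2 per cell;
        # standardized over 500 cells it must match within 3 SE
        cfg = SimConfig(n_cells=500, seed=3)
        traces, truth = gen_cell_traces(cfg)
        ratios = []
        for cid, row in truth.cell_params.iterrows():
            p = K.KineticParams(row.t_on, row.t_off, row.beta, row.gamma, row.g0)
            g = traces.trace(cid).sort_values("time_min")["gfp"].to_numpy()
            resid = g - K.protein_curve(traces.times, p)
            ratios.append(np.mean(resid ** 2) / row.noise_sd ** 2)
        n_obs = len(ratios) * traces.times.size
        # each ratio ~ chi2_k/k; SE of the grand mean is sqrt(2/n_obs)
        assert abs(np.mean(ratios) - 1.0) < 3.0 * np.sqrt(2.0 / n_obs)


class TestImageSequence:
    def test_zero_drift_static_centroids(self):
        cfg = SimConfig(n_cells=3, n_frames=4, max_drift_px=0.0,
                        image_noise_sd=0.0, seed=4)
        _, truth = gen_image_sequence(cfg)
        for _, grp in truth.centroids.groupby("cell_id"):
            assert grp["x"].nunique() == 1 and grp["y"].nunique() == 1

    def test_budding_event_recorded_once(self):
        cfg = SimConfig(n_cells=5, n_frames=6, seed=5, budding_events=((2, 3),))
        _, truth = gen_image_sequence(cfg)
        assert len(truth.lineage_events) == 1
        assert truth.lineage_events[0][1] == 3

    def test_impossible_packing_is_error(self):
        cfg = SimConfig(n_cells=500, n_frames=3, image_shape=(128, 128), seed=6)
        with pytest.raises(ConfigError, match="place"):
            gen_image_sequence(cfg)


class TestTilingDataset:
    def test_constant_shape_zero_noise(self):
        cfg = SimConfig(n_genes=20, tiling_noise_sd=0.0, seed=7)
        sig, ann, _ = gen_tiling_dataset(
            cfg,
            shape_by_label={l: ("flat", 1.0) for l in ("RPG", "Ribi", "other")},
            timemod_by_label={l: (1.0,) * 6 for l in ("RPG", "Ribi", "other")})
        asn = assign_bins(sig, ann)
        vals = sig.values.iloc[asn["probe_index"]].to_numpy()
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)

    def test_minus_strand_peak_at_high_coordinate_end(self):
        # a 5'-peaked shape on a minus-strand gene must put the highest
        # probe values at the gene's larger genomic coordinate (its TSS)
        cfg = SimConfig(n_genes=40, tiling_noise_sd=0.0, seed=8)
        sig, ann, _ = gen_tiling_dataset(
            cfg,
            shape_by_label={l: ("five_prime_peak", 2.0)
                            for l in ("RPG", "Ribi", "other")},
            timemod_by_label={l: (1.0,) * 6 for l in ("RPG", "Ribi", "other")})
        mids = sig.midpoints()
        t0 = sig.values.columns[0]
        for _, gene in ann[ann["strand"] == "-"].iterrows():
            lo, hi = gene["tes"], gene["tss"]
            in_gene = (mids >= lo) & (mids < hi)
            if in_gene.sum() < 3:
                continue
            vals = sig.values.loc[in_gene, t0].to_numpy()
            best = mids[in_gene][np.argmax(vals)]
            assert abs(best - hi) < abs(best - lo)

    def test_planted_amplitude_roundtrip(self):
        cfg = SimConfig(n_genes=60, tiling_noise_sd=0.0, seed=9)
        A = 3.0
        sig, ann, _ = gen_tiling_dataset(
            cfg,
            shape_by_label={l: ("five_prime_peak", A)
                            for l in ("RPG", "Ribi", "other")},
            timemod_by_label={l: (1.0,) * 6 for l in ("RPG", "Ribi", "other")})
        prof = metagene_profile(sig, ann, groupby="label")
        t0 = prof.means.columns[0]
        bin1 = prof.means.xs(1, level="bin")[t0].dropna()
        assert np.all(np.abs(bin1 - A) / A < 0.10)

    def test_short_gene_warns_but_is_emitted(self):
        cfg = SimConfig(n_genes=5, gene_length_range=(100, 200), seed=10)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            _, ann, _ = gen_tiling_dataset(cfg)
        assert len(ann) == 5
        assert any("shorter" in str(x.message) for x in w)
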