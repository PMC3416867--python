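"""Generator for probe x sample count experiments with planted mutant effects.

Forward model, per probe i and sample j (strain m, time t):

    latent[i, j] = L_i * 2**(phi_m * dev_i(t) + delta_k[i] + eta_m[i])
    observed[i, j] = a_j * latent[i, j] + b_j + noise

``L_i`` is a log-uniform baseline, ``dev_i(t)`` the wild-type log2
deviation from t = 0 drawn from a small archetype library (induced,
repressed, transient, flat), ``phi_m`` the amplitude factor of hyper
(>1) / hypo (<1) mutants, ``delta_k`` a per-complex shared effect vector
and ``eta_m`` a per-mutant idiosyncratic effect.  Wild-type samples have
``phi = 1`` and no planted effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ConfigError
from ..ncounter import CountMatrix
from .config import GroundTruth, SimConfig

# archetype anchor shapes at fractions (0, 1/6, 1/2, 1) of the final time
_ANCHORS = np.array([0.0, 1.0 / 6.0, 0.5, 1.0])
_SHAPES = {
    "induced": np.array([0.0, 0.7, 1.0, 0.9]),
    "repressed": np.array([0.0, -0.6, -1.0, -0.8]),
    "transient": np.array([0.0, 1.0, 0.4, 0.1]),
    "flat": np.array([0.0, 0.0, 0.0, 0.0]),
}
_ARCHETYPE_PROBS = {"induced": 0.35, "repressed": 0.35,
                    "transient": 0.15, "flat": 0.15}


def _mutant_classes(cfg: SimConfig, rng: np.random.Generator):
    """Assign hyper/hypo/complex_k/null labels and amplitude factors."""
    classes = np.array(["null"] * cfg.n_mutants, dtype=object)
    factors = np.ones(cfg.n_mutants)
    complex_of = np.full(cfg.n_mutants, -1)
    for k, grp in enumerate(cfg.planted_complexes):
        for i in grp:
            classes[i] = f"complex_{k}"
            complex_of[i] = k
    free = np.flatnonzero(complex_of < 0)
    free = rng.permutation(free)
    n_hyper = int(round(cfg.hyper_frac * cfg.n_mutants))
    n_hypo = int(round(cfg.hypo_frac * cfg.n_mutants))
    if n_hyper + n_hypo > free.size:
        raise ConfigError("hyper_frac/hypo_frac leave no room beside planted_complexes")
    hyper_idx = free[:n_hyper]
    hypo_idx = free[n_hyper:n_hyper + n_hypo]
    classes[hyper_idx] = "hyper"
    classes[hypo_idx] = "hypo"
    factors[hyper_idx] = rng.uniform(*cfg.hyper_factor_range, size=n_hyper)
    factors[hypo_idx] = rng.uniform(*cfg.hypo_factor_range, size=n_hypo)
    return classes, factors, complex_of


def gen_count_experiment(cfg: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a full count experiment; deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.time_points_min, dtype=float)
    t_max = times.max() if times.max() > 0 else 1.0

    probe_ids = [f"probe_{i:04d}" for i in range(cfg.n_probes)]
    archetypes = rng.choice(list(_ARCHETYPE_PROBS), size=cfg.n_probes,
                            p=list(_ARCHETYPE_PROBS.values()))
    lo, hi = cfg.expression_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_probes))
    amp = rng.uniform(1.0, 3.0, size=cfg.n_probes)

    dev = np.zeros((cfg.n_probes, times.size))  # wild-type log2 deviation vs t=0
    for i, arch in enumerate(archetypes):
        dev[i] = amp[i] * np.interp(times / t_max, _ANCHORS, _SHAPES[arch])
    wt_latent = baseline[:, None] * 2.0 ** dev

    classes, factors, complex_of = _mutant_classes(cfg, rng)
    complex_effects = {k: rng.normal(0.0, cfg.complex_effect_sd, cfg.n_probes)
                       for k in range(len(cfg.planted_complexes))}
    eta = rng.normal(0.0, cfg.mutant_noise_sd, (cfg.n_mutants, cfg.n_probes))

    mutant_ids = [f"mut{m:03d}" for m in range(cfg.n_mutants)]
    sample_ids, meta_rows, latent_cols = [], [], []
    noisy = cfg.noise_model != "none"

    for ti, t in enumerate(times):
        for rep in range(1, cfg.n_wt_replicates + 1):
            sid = f"WT_t{t:g}_r{rep}"
            lat = wt_latent[:, ti].copy()
            if noisy and cfg.wt_rep_cv > 0:
                sd = cfg.wt_rep_cv
                lat = lat * np.exp(rng.normal(-0.5 * sd * sd, sd, cfg.n_probes))
            sample_ids.append(sid)
            meta_rows.append(("WT", t, rep))
            latent_cols.append(lat)
    for m, mid in enumerate(mutant_ids):
        extra = eta[m].copy()
        if complex_of[m] >= 0:
            extra = extra + complex_effects[complex_of[m]]
        for ti, t in enumerate(times):
            sid = f"{mid}_t{t:g}_r1"
            lat = baseline * 2.0 ** (factors[m] * dev[:, ti] + extra)
            sample_ids.append(sid)
            meta_rows.append((mid, t, 1))
            latent_cols.append(lat)

    latent = np.column_stack(latent_cols)
    a = rng.uniform(*cfg.scale_range, size=len(sample_ids))
    b = rng.uniform(*cfg.background_range, size=len(sample_ids))
    is_wt = np.array([m[0] == "WT" for m in meta_rows])
    if cfg.wt_scale_range is not None:
        a[is_wt] = rng.uniform(*cfg.wt_scale_range, size=int(is_wt.sum()))
    if cfg.wt_background_range is not None:
        b[is_wt] = rng.uniform(*cfg.wt_background_range, size=int(is_wt.sum()))
    mean = a[None, :] * latent + b[None, :]

    if cfg.noise_model == "poisson":
        observed = rng.poisson(mean).astype(float)
    elif cfg.noise_model == "lognormal":
        cv = cfg.lognormal_cv
        mult = np.exp(rng.normal(-0.5 * cv * cv, cv, mean.shape))
        add = rng.normal(0.0, np.sqrt(np.maximum(b, 1e-12))[None, :], mean.shape)
        observed = np.clip(a[None, :] * latent * mult + b[None, :] + add, 0.0, None)
    else:
        observed = mean

    meta = pd.DataFrame(meta_rows, columns=["strain", "time_min", "replicate"],
                        index=pd.Index(sample_ids, name="sample_id"))
    values = pd.DataFrame(observed, index=pd.Index(probe_ids, name="probe_id"),
                          columns=meta.index)
    probe_meta = pd.DataFrame({"sense": ["sense"] * cfg.n_probes},
                              index=values.index)
    counts = CountMatrix(values=values, sample_meta=meta, probe_meta=probe_meta)

    truth = GroundTruth(
        sample_params=pd.DataFrame({"a": a, "b": b}, index=meta.index).join(meta),
        mutant_class=pd.Series(classes, index=mutant_ids, name="class"),
        mutant_factor=pd.Series(factors, index=mutant_ids, name="factor"),
        wt_trajectory=pd.DataFrame(wt_latent, index=values.index, columns=times),
        latent=pd.DataFrame(latent, index=values.index, columns=meta.index),
        probe_archetype=pd.Series(archetypes, index=values.index, name="archetype"),
        complex_effects=complex_effects,
    )
    return counts, truth
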