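"""Simulation configuration and ground-truth containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ..errors import ConfigError

#: stress time points of the count experiment design, minutes
DEFAULT_TIMES = (0.0, 15.0, 45.0, 90.0)


@dataclass
class SimConfig:
    """Parameters of the synthetic study design.

    The defaults mirror the emulated experiment: 200 probes x 202 mutants
    sampled at t = 0, 15, 45 and 90 min after stress, each time point
    anchored by 4 wild-type replicates.  ``hyper_frac``/``hypo_frac``
    mutants scale the log-deviation from t = 0 of every probe up/down;
    ``planted_complexes`` are groups of mutant indices sharing one effect
    vector (emulating members of a chromatin complex); the rest are null.

    background_range / scale_range : per-sample additive background b
        (counts) and multiplicative scale a (unitless) draws.
    noise_model : "poisson" (counts), "lognormal" (multiplicative CV on the
        signal plus Gaussian additive noise on the background) or "none".
    wt_rep_cv : wild-type replicate-to-replicate latent CV (free parameter;
        the emulated study does not report one).
    """

    n_probes: int = 200
    n_mutants: int = 202
    time_points_min: Sequence[float] = DEFAULT_TIMES
    n_wt_replicates: int = 4
    planted_complexes: Sequence[Sequence[int]] = ()
    hyper_frac: float = 0.1
    hypo_frac: float = 0.1
    background_range: tuple[float, float] = (20.0, 200.0)
    scale_range: tuple[float, float] = (0.5, 2.0)
    noise_model: str = "poisson"
    seed: int = 0

    # wild-type samples can carry their own scale/background ranges (None =
    # same as mutants); pinning them at (1, 1)/(0, 0) makes the composite
    # reference coincide with the latent scale, so planted per-sample (a, b)
    # are directly identifiable rather than identifiable only relative to
    # the reference composite
    wt_scale_range: tuple[float, float] | None = None
    wt_background_range: tuple[float, float] | None = None

    # secondary knobs of the count generator
    expression_range: tuple[float, float] = (5.0, 5000.0)
    wt_rep_cv: float = 0.1
    lognormal_cv: float = 0.25
    complex_effect_sd: float = 0.5
    mutant_noise_sd: float = 0.25
    hyper_factor_range: tuple[float, float] = (1.3, 2.0)
    hypo_factor_range: tuple[float, float] = (0.2, 0.7)

    # single-cell trace generator
    n_cells: int = 200
    trace_times_min: Sequence[float] = tuple(float(t) for t in range(0, 181, 10))
    responder_frac: float = 0.87
    noise_sd_frac: float = 0.05
    t_on_range: tuple[float, float] = (5.0, 25.0)
    duration_range: tuple[float, float] = (20.0, 60.0)
    beta_range: tuple[float, float] = (5.0, 20.0)
    g0_range: tuple[float, float] = (50.0, 150.0)
    gamma: float = 0.034657359027997264  # ln2/20 per min

    # image generator
    n_frames: int = 10
    image_shape: tuple[int, int] = (768, 768)
    cell_radius: float = 10.0
    max_drift_px: float = 3.0
    budding_events: Sequence[tuple[int, int]] = ()
    mcherry_intensity: float = 180.0
    image_background: float = 10.0
    image_noise_sd: float = 2.0
    frame_interval_min: float = 10.0

    # tiling generator
    n_genes: int = 60
    probe_spacing_bp: int = 250
    gene_length_range: tuple[int, int] = (1000, 3000)
    tiling_times_min: Sequence[float] = (0.0, 4.0, 8.0, 15.0, 30.0, 60.0)
    tiling_noise_sd: float = 0.1
    label_fracs: tuple[float, float] = (0.15, 0.15)  # RPG, Ribi

    def validate(self) -> "SimConfig":
        def _positive(name):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("n_probes", "n_mutants", "n_wt_replicates", "n_cells",
                     "n_frames", "n_genes", "probe_spacing_bp", "gamma"):
            _positive(name)
        for name in ("hyper_frac", "hypo_frac", "responder_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.hyper_frac + self.hypo_frac > 1.0:
            raise ConfigError("hyper_frac + hypo_frac must be <= 1")
        if self.scale_range[0] <= 0:
            raise ConfigError("scale_range must be strictly positive")
        if self.background_range[0] < 0:
            raise ConfigError("background_range must be nonnegative")
        tp = list(self.time_points_min)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("time_points_min must be strictly increasing")
        if self.noise_model not in ("poisson", "lognormal", "none"):
            raise ConfigError(
                f"noise_model must be poisson|lognormal|none, got {self.noise_model!r}")
        flat = [i for grp in self.planted_complexes for i in grp]
        if len(flat) != len(set(flat)):
            raise ConfigError("planted_complexes must not overlap")
        if flat and (min(flat) < 0 or max(flat) >= self.n_mutants):
            raise ConfigError("planted_complexes indices out of range for n_mutants")
        return self


@dataclass
class GroundTruth:
    """Planted truth behind one generated dataset.

    Only the fields relevant to the generator that produced it are set.
    """

    sample_params: pd.DataFrame | None = None      # sample_id -> a, b
    mutant_class: pd.Series | None = None          # hyper | hypo | complex_k | null
    mutant_factor: pd.Series | None = None         # amplitude factor (hyper/hypo)
    wt_trajectory: pd.DataFrame | None = None      # probe x time latent expression
    latent: pd.DataFrame | None = None             # probe x sample latent expression
    probe_archetype: pd.Series | None = None       # induced | repressed | transient | flat
    complex_effects: dict | None = None            # complex id -> per-probe log2 vector
    cell_params: pd.DataFrame | None = None        # per-cell kinetic params + responder
    centroids: pd.DataFrame | None = None          # frame, cell_id, x, y
    lineage_events: list | None = None             # (cell_id, frame) budding records
    gene_shapes: pd.DataFrame | None = None        # per-gene shape name/amplitude
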