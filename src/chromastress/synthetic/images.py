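"""Generator for two-channel (mCherry + GFP) time-lapse image stacks.

Cells are rendered as uniform bright discs on a dark background: the
mCherry (constitutive marker) channel at fixed intensity, the GFP channel
at each cell's reporter trace value for that frame.  Cells drift by at
most ``max_drift_px`` per frame.  A budding event inserts a second,
equal-size disc overlapping the mother at 1.8 radii; the resulting merged
blob either fails the circularity gate or shifts its centroid by ~0.9
radii in one frame, so the track breaks downstream — mirroring how
budding defeats nearest-neighbor tracking in real movies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .config import GroundTruth, SimConfig
from .traces import CellTraceSet, gen_cell_traces


@dataclass
class ImageSequence:
    """Aligned per-channel stacks, shape (n_frames, H, W), plus frame times."""

    mcherry: np.ndarray
    gfp: np.ndarray
    times: np.ndarray


def _place_centers(n: int, shape: tuple[int, int], min_sep: float,
                   rng: np.random.Generator, margin: float,
                   max_tries: int = 20000) -> np.ndarray:
    centers = []
    for _ in range(max_tries):
        c = np.array([rng.uniform(margin, shape[0] - margin),
                      rng.uniform(margin, shape[1] - margin)])
        if all(np.hypot(*(c - o)) >= min_sep for o in centers):
            centers.append(c)
            if len(centers) == n:
                return np.array(centers)
    raise ConfigError(
        f"could not place {n} non-overlapping cells in {shape} after {max_tries} tries; "
        "reduce n_cells or cell_radius")


def _paint_disc(img: np.ndarray, cy: float, cx: float, r: float,
                value: float) -> None:
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, img.shape[0])
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, img.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    patch = img[y0:y1, x0:x1]
    patch[mask] = np.maximum(patch[mask], value)


def gen_image_sequence(cfg: SimConfig, traces: CellTraceSet | None = None
                       ) -> tuple[ImageSequence, GroundTruth]:
    """Render a drifting-disc movie; deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    r = float(cfg.cell_radius)
    n, n_frames = cfg.n_cells, cfg.n_frames
    shape = tuple(cfg.image_shape)

    if traces is None:
        tcfg_times = tuple(cfg.frame_interval_min * f for f in range(n_frames))
        from dataclasses import replace
        traces, trace_truth = gen_cell_traces(
            replace(cfg, trace_times_min=tcfg_times), rng=rng)
    else:
        trace_truth = None
        if len(traces.times) < n_frames:
            raise ConfigError("traces must cover every frame")
    gfp_by_cell = {cid: grp.sort_values("time_min")["gfp"].to_numpy()
                   for cid, grp in traces.frame.groupby("cell_id")}
    cell_ids = sorted(gfp_by_cell)
    if len(cell_ids) < n:
        raise ConfigError("traces provide fewer cells than n_cells")
    cell_ids = cell_ids[:n]

    # generous separation: bodies, cumulative random-walk drift, and margin
    min_sep = 2 * r + 2 * cfg.max_drift_px * np.sqrt(n_frames) + 6
    centers = _place_centers(n, shape, min_sep, rng, margin=r + cfg.max_drift_px * n_frames + 2)

    bud_of = dict(cfg.budding_events)  # cell index -> frame of budding
    for ci, fr in bud_of.items():
        if not (0 <= ci < n) or not (0 <= fr < n_frames):
            raise ConfigError(f"budding_events entry ({ci}, {fr}) out of range")
    bud_angle = {ci: rng.uniform(0, 2 * np.pi) for ci in bud_of}

    mch = np.full((n_frames,) + shape, cfg.image_background, dtype=float)
    gfp = np.full((n_frames,) + shape, cfg.image_background / 2.0, dtype=float)
    cent_rows = []
    pos = centers.copy()
    for f in range(n_frames):
        if f > 0 and cfg.max_drift_px > 0:
            ang = rng.uniform(0, 2 * np.pi, n)
            mag = rng.uniform(0, cfg.max_drift_px, n)
            pos = pos + np.column_stack([mag * np.sin(ang), mag * np.cos(ang)])
        for c in range(n):
            cy, cx = pos[c]
            g_val = float(gfp_by_cell[cell_ids[c]][f])
            _paint_disc(mch[f], cy, cx, r, cfg.mcherry_intensity)
            _paint_disc(gfp[f], cy, cx, r, g_val)
            if c in bud_of and f >= bud_of[c]:
                by = cy + 1.8 * r * np.sin(bud_angle[c])
                bx = cx + 1.8 * r * np.cos(bud_angle[c])
                _paint_disc(mch[f], by, bx, r, cfg.mcherry_intensity)
                _paint_disc(gfp[f], by, bx, r, g_val)
            cent_rows.append({"frame": f, "cell_id": cell_ids[c],
                              "y": cy, "x": cx})
    if cfg.image_noise_sd > 0:
        mch += rng.normal(0, cfg.image_noise_sd, mch.shape)
        gfp += rng.normal(0, cfg.image_noise_sd, gfp.shape)
        np.clip(mch, 0, None, out=mch)
        np.clip(gfp, 0, None, out=gfp)

    times = np.array([cfg.frame_interval_min * f for f in range(n_frames)])
    truth = GroundTruth(
        centroids=pd.DataFrame(cent_rows),
        lineage_events=[(cell_ids[ci], fr) for ci, fr in sorted(bud_of.items())],
        cell_params=trace_truth.cell_params if trace_truth is not None else None,
    )
    return ImageSequence(mcherry=mch, gfp=gfp, times=times), truth
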