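"""Cell detection, reciprocal-closest-hit tracking, and trace extraction.

Cells are detected per frame by thresholding the constitutive mCherry
channel (Otsu by default), labeling connected bright regions and gating
on area and circularity (4πA/P²).  Successive frames are linked by a
reciprocal closest hit: detections i (frame t) and j (frame t+1) match
iff each is the other's nearest neighbor and they lie within ``max_move``
pixels.  A budding event puts two candidates at t+1 near one detection at
t; such ambiguous links terminate the chain, so budded cells never yield
complete traces.  Only cells traced through every frame are returned by
default; their GFP trace is the mean intensity inside the detection mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .errors import ChromastressError
from .synthetic.images import ImageSequence
from .synthetic.traces import CellTraceSet

MAX_MOVE_PX = 5.0
AREA_GATE = (50.0, 5000.0)
CIRCULARITY_GATE = (0.7, 1.15)


@dataclass
class CellDetection:
    """One gated detection in one frame."""

    frame: int
    centroid: tuple[float, float]   # (x, y) px, intensity-weighted
    area: float                     # px^2
    perimeter: float                # px
    circularity: float              # 4*pi*A/P^2
    label: int
    coords: np.ndarray = field(repr=False, default=None)  # (N, 2) row/col mask pixels


def detect_cells(image, threshold: float | None = None,
                 area_range: tuple[float, float] = AREA_GATE,
                 circularity_range: tuple[float, float] = CIRCULARITY_GATE,
                 frame: int = 0) -> list[CellDetection]:
    """Detect bright, roundish regions in one grayscale frame.

    ``threshold=None`` selects Otsu's threshold on the image histogram.
    An empty or featureless image yields an empty list, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0 or img.max() == img.min():
        return []
    thr = float(threshold) if threshold is not None else float(threshold_otsu(img))
    mask = img > thr
    if not mask.any():
        return []
    labels = sk_label(mask)
    dets = []
    for rp in regionprops(labels, intensity_image=img):
        area = float(rp.area)
        per = float(rp.perimeter)
        circ = 4.0 * np.pi * area / (per * per) if per > 0 else 0.0
        if not (area_range[0] <= area <= area_range[1]):
            continue
        if not (circularity_range[0] <= circ <= circularity_range[1]):
            continue
        cy, cx = rp.centroid_weighted
        dets.append(CellDetection(frame=frame, centroid=(float(cx), float(cy)),
                                  area=area, perimeter=per, circularity=circ,
                                  label=int(rp.label), coords=rp.coords))
    return dets


@dataclass
class MatchResult:
    """Frame-to-frame matching outcome (indices into the detection lists)."""

    pairs: list[tuple[int, int]]
    unmatched_t: list[int]
    unmatched_t1: list[int]
    ambiguous_t: list[int]   # detections at t claimed by >= 2 candidates at t+1


def _nearest(d_row: np.ndarray, areas_self: float, areas_other: np.ndarray,
             labels_other: np.ndarray) -> int:
    """Index of the nearest neighbor; ties by area difference, then label."""
    dmin = d_row.min()
    cand = np.flatnonzero(np.abs(d_row - dmin) < 1e-9)
    if cand.size > 1:
        adiff = np.abs(areas_other[cand] - areas_self)
        cand = cand[np.abs(adiff - adiff.min()) < 1e-9]
        if cand.size > 1:
            cand = cand[[np.argmin(labels_other[cand])]]
    return int(cand[0])


def match_frames(dets_t: list[CellDetection], dets_t1: list[CellDetection],
                 max_move: float = MAX_MOVE_PX) -> MatchResult:
    """Reciprocal-closest-hit matching with a maximum movement of max_move px."""
    n, m = len(dets_t), len(dets_t1)
    if n == 0 or m == 0:
        return MatchResult([], list(range(n)), list(range(m)), [])
    p0 = np.array([d.centroid for d in dets_t])
    p1 = np.array([d.centroid for d in dets_t1])
    a0 = np.array([d.area for d in dets_t])
    a1 = np.array([d.area for d in dets_t1])
    l0 = np.array([d.label for d in dets_t])
    l1 = np.array([d.label for d in dets_t1])
    d = np.hypot(p0[:, None, 0] - p1[None, :, 0], p0[:, None, 1] - p1[None, :, 1])

    nn_fwd = np.array([_nearest(d[i], a0[i], a1, l1) for i in range(n)])
    nn_bwd = np.array([_nearest(d[:, j], a1[j], a0, l0) for j in range(m)])

    # a detection at t claimed as nearest by >= 2 in-range candidates at t+1
    claims = np.zeros(n, dtype=int)
    for j in range(m):
        i = nn_bwd[j]
        if d[i, j] <= max_move:
            claims[i] += 1
    ambiguous = [int(i) for i in np.flatnonzero(claims >= 2)]

    pairs = []
    for i in range(n):
        j = nn_fwd[i]
        if nn_bwd[j] == i and d[i, j] <= max_move:
            pairs.append((i, int(j)))
    matched_t = {i for i, _ in pairs}
    matched_t1 = {j for _, j in pairs}
    return MatchResult(pairs=pairs,
                       unmatched_t=[i for i in range(n) if i not in matched_t],
                       unmatched_t1=[j for j in range(m) if j not in matched_t1],
                       ambiguous_t=ambiguous)


def _mean_intensity(img: np.ndarray, coords: np.ndarray) -> float:
    return float(img[coords[:, 0], coords[:, 1]].mean())


def extract_traces(seq: ImageSequence, threshold: float | None = None,
                   max_move: float = MAX_MOVE_PX,
                   area_range: tuple[float, float] = AREA_GATE,
                   circularity_range: tuple[float, float] = CIRCULARITY_GATE,
                   include_partial: bool = False
                   ) -> tuple[CellTraceSet, list[list[CellDetection]]]:
    """Track cells across the movie and read out per-cell channel means.

    Chains start from the first frame and follow reciprocal matches;
    chains hitting an ambiguous (budding-style) link or losing their match
    terminate.  By default only complete chains (one detection per frame)
    are returned.
    """
    if seq.mcherry.shape != seq.gfp.shape:
        raise ChromastressError(
            f"channel shape mismatch: mcherry {seq.mcherry.shape} "
            f"vs gfp {seq.gfp.shape}")
    n_frames = seq.mcherry.shape[0]
    frames = [detect_cells(seq.mcherry[f], threshold=threshold,
                           area_range=area_range,
                           circularity_range=circularity_range, frame=f)
              for f in range(n_frames)]
    matches = [match_frames(frames[f], frames[f + 1], max_move=max_move)
               for f in range(n_frames - 1)]

    chains = [[i] for i in range(len(frames[0]))]
    for f, mr in enumerate(matches):
        fwd = dict(mr.pairs)
        ambiguous = set(mr.ambiguous_t)
        for chain in chains:
            if len(chain) != f + 1:
                continue  # already terminated
            i = chain[-1]
            if i in ambiguous or i not in fwd:
                continue
            chain.append(fwd[i])

    rows = []
    kept = 0
    for chain in chains:
        complete = len(chain) == n_frames
        if not complete and not include_partial:
            continue
        cell_id = f"track_{kept:04d}"
        kept += 1
        for f, di in enumerate(chain):
            det = frames[f][di]
            rows.append({
                "cell_id": cell_id, "strain": "NA",
                "time_min": float(seq.times[f]),
                "gfp": _mean_intensity(seq.gfp[f], det.coords),
                "mcherry": _mean_intensity(seq.mcherry[f], det.coords),
                "x": det.centroid[0], "y": det.centroid[1],
                "complete": complete,
            })
    frame = pd.DataFrame(rows, columns=["cell_id", "strain", "time_min", "gfp",
                                        "mcherry", "x", "y", "complete"])
    return CellTraceSet(frame=frame, times=np.asarray(seq.times, dtype=float)), frames


def classify_responders(traces: CellTraceSet | pd.DataFrame,
                        fold_threshold: float = 1.5, min_frames: int = 2,
                        basal_frames: int = 3) -> tuple[pd.Series, float]:
    """Flag responding cells and estimate the responder fraction.

    A cell responds iff its GFP exceeds ``fold_threshold`` times its basal
    level (median of the first ``basal_frames`` samples) for at least
    ``min_frames`` consecutive frames.
    """
    df = traces.frame if hasattr(traces, "frame") else traces
    flags = {}
    for cell_id, grp in df.groupby("cell_id", sort=True):
        g = grp.sort_values("time_min")["gfp"].to_numpy()
        if g.size < 3:
            raise ChromastressError(f"trace {cell_id!r} has < 3 time points")
        basal = float(np.median(g[:basal_frames]))
        above = g > fold_threshold * basal
        run = best = 0
        for a in above:
            run = run + 1 if a else 0
            best = max(best, run)
        flags[cell_id] = best >= min_frames
    flags = pd.Series(flags, name="responder")
    return flags, float(flags.mean()) if len(flags) else float("nan")
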