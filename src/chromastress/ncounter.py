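"""Count normalization against time-matched wild type, and the glog Δh statistic.

Digital molecule-counting assays report, per sample j and probe i, a raw
count M[i, j].  Samples differ in assay efficiency and background, so each
mutant sample is brought onto the scale of the average of the wild-type
replicates at the same time point by a linear model

    M[i, j] ≈ a_j * ref[i] + b_j          (a_j > 0)

where a_j is a multiplicative efficiency factor and b_j an additive
background in counts, estimated by least squares under the assumption that
most probes do not change between a mutant and wild type at the same time.
The regression runs in count space (the background is additive in counts,
not in log space); a robust variant iteratively trims the largest-residual
probes so that a minority of genuinely changed genes cannot bias the fit.

Differences are then expressed with a variance-stabilized statistic

    Δh = h(x) - h(y),   h(v) = log2(v + sqrt(v^2 + c^2)) / s

a generalized-log (arsinh-family) transform.  For values well above the
offset c, Δh coincides with the plain log2 ratio; near zero it degrades
gracefully instead of exploding, so its spread is roughly constant across
the intensity range.  The offset is set from the estimated per-sample
backgrounds (see :func:`fit_stabilizer`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, MissingReferenceError

WT_STRAIN = "WT"


@dataclass
class CountMatrix:
    """Raw probe x sample counts plus per-sample metadata.

    values : DataFrame, probes in rows (index = probe ids), samples in columns
    sample_meta : DataFrame indexed by sample id with columns
        (strain, time_min, replicate)
    probe_meta : optional DataFrame indexed by probe id (e.g. a ``sense``
        flag for sense/antisense probe pairs)
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    probe_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def probe_ids(self):
        return self.values.index

    def wt_samples(self, time_min=None, wt_strain: str = WT_STRAIN):
        meta = self.sample_meta
        sel = meta["strain"] == wt_strain
        if time_min is not None:
            sel &= meta["time_min"] == time_min
        return meta.index[sel]


@dataclass
class NormalizedMatrix:
    """Counts on the wild-type reference scale: (raw - b)/a per sample."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    floor: float = 1.0


@dataclass
class NormalizationFit:
    """Per-sample linear normalization against a wild-type reference."""

    sample_id: str
    a: float
    b: float
    fit_r2: float
    reference_id: str
    n_used: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")


A_FLOOR = 1e-6


def build_reference(counts: CountMatrix, time_min,
                    wt_strain: str = WT_STRAIN) -> pd.Series:
    """Per-probe arithmetic mean of the wild-type replicates at one time."""
    cols = counts.wt_samples(time_min, wt_strain)
    if len(cols) == 0:
        raise MissingReferenceError(
            f"no wild-type ({wt_strain!r}) sample at time {time_min} min")
    return counts.values[cols].mean(axis=1)


def estimate_scale(sample, reference, robust: bool = False,
                   trim_frac: float = 0.1, n_iter: int = 3,
                   min_probes: int = 10, sample_id: str = "",
                   reference_id: str = "") -> NormalizationFit:
    """Least-squares fit sample ≈ a*reference + b in count space.

    ``robust=True`` repeats the fit ``n_iter`` times, each round dropping
    the ``trim_frac`` fraction of probes with the largest absolute
    residuals — the probes most likely to be genuinely changed genes.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(sample, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_probes:
        raise EstimationError(
            f"need >= {min_probes} shared finite probes, got {x.size}")
    if np.ptp(x) == 0:
        raise EstimationError("degenerate reference: zero variance")

    use = np.ones(x.size, dtype=bool)
    rounds = n_iter if robust else 1
    a = b = 1.0
    for _ in range(rounds):
        xs, ys = x[use], y[use]
        A = np.column_stack([xs, np.ones_like(xs)])
        (a, b), *_ = np.linalg.lstsq(A, ys, rcond=None)
        if robust:
            resid = np.abs(y - (a * x + b))
            cut = np.quantile(resid[use], 1.0 - trim_frac)
            nxt = use & (resid <= cut)
            if nxt.sum() < min_probes:
                break
            use = nxt

    a = max(float(a), A_FLOOR)
    xs, ys = x[use], y[use]
    pred = a * xs + b
    ss_res = float(np.sum((ys - pred) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return NormalizationFit(sample_id=sample_id, a=a, b=float(b),
                            fit_r2=max(min(r2, 1.0), 0.0),
                            reference_id=reference_id, n_used=int(use.sum()))


def fit_samples(counts: CountMatrix, wt_strain: str = WT_STRAIN,
                robust: bool = False, include_wt: bool = True,
                **kwargs) -> dict[str, NormalizationFit]:
    """Fit every sample against its time-matched wild-type reference."""
    refs = {t: build_reference(counts, t, wt_strain)
            for t in sorted(counts.sample_meta["time_min"].unique())}
    fits: dict[str, NormalizationFit] = {}
    for sid in counts.values.columns:
        meta = counts.sample_meta.loc[sid]
        if not include_wt and meta["strain"] == wt_strain:
            continue
        t = meta["time_min"]
        fits[sid] = estimate_scale(counts.values[sid], refs[t], robust=robust,
                                   sample_id=str(sid),
                                   reference_id=f"{wt_strain}@t{t}", **kwargs)
    return fits


def normalize(counts: CountMatrix, fits: dict[str, NormalizationFit],
              floor: float = 1.0, wt_strain: str = WT_STRAIN) -> NormalizedMatrix:
    """Apply (raw - b)/a per sample, flooring at ``floor`` counts.

    Wild-type reference columns pass through unchanged (they define the
    scale the other samples are mapped onto).
    """
    out = counts.values.astype(float).copy()
    for sid in out.columns:
        if counts.sample_meta.loc[sid, "strain"] == wt_strain:
            continue
        if sid not in fits:
            raise EstimationError(f"no normalization fit for sample {sid!r}")
        f = fits[sid]
        out[sid] = (out[sid] - f.b) / f.a
    out = out.clip(lower=floor)
    return NormalizedMatrix(values=out, sample_meta=counts.sample_meta.copy(),
                            floor=floor)


@dataclass(frozen=True)
class VarianceStabilizer:
    """Parameters of the generalized-log transform h behind Δh."""

    glog_offset: float
    glog_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.glog_scale <= 0:
            raise ValueError("glog_scale must be > 0")
        if self.glog_offset < 0:
            raise ValueError("glog_offset must be >= 0")

    def h(self, v):
        v = np.asarray(v, dtype=float)
        return np.log2(v + np.sqrt(v * v + self.glog_offset ** 2)) / self.glog_scale

    def delta_h(self, x, y):
        """Stabilized difference h(x) - h(y); antisymmetric in (x, y)."""
        return self.h(x) - self.h(y)


def delta_h(x, y, vs: VarianceStabilizer):
    """Functional form of :meth:`VarianceStabilizer.delta_h`."""
    return vs.delta_h(x, y)


def fit_stabilizer(norm: NormalizedMatrix, fits: dict[str, NormalizationFit],
                   noise_factor: float = 0.5) -> VarianceStabilizer:
    """Set the glog offset from the estimated per-sample backgrounds.

    The offset that makes Var(Δh) flat under additive-plus-multiplicative
    noise is (additive SD)/(multiplicative CV); as a simple moment rule we
    take ``noise_factor`` times the median background expressed on the
    normalized scale, median_j(b_j / a_j).  With typical backgrounds of
    tens-to-hundreds of counts and CVs of 20–30% this lands at the right
    order of magnitude, which is all the arsinh transform needs.
    """
    if not fits:
        raise EstimationError("fit_stabilizer requires at least one fit")
    v = norm.values.to_numpy(dtype=float)
    if not np.any(np.nan_to_num(v) > 0):
        raise EstimationError("all-zero normalized matrix")
    b_scaled = np.array([f.b / f.a for f in fits.values()])
    offset = float(noise_factor * np.median(np.abs(b_scaled)))
    return VarianceStabilizer(glog_offset=offset)
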