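"""Single-cell induction kinetics: promoter window, mRNA ODE, protein integral.

The model describes reporter induction in a single cell after an acute
stress at t = 0.  The promoter switches on at ``t_on`` and off at ``t_off``
(a square window T(t)); while on, mRNA is produced at a constant rate
``beta`` and decays exponentially at rate ``gamma``:

    dm/dt = beta * T(t) - gamma * m,        m(t_on) = 0

which has the closed-form (logistic-saturation) solution

    m(t) = (beta/gamma) * (1 - exp(-gamma (t - t_on)))        t_on <= t <= t_off
    m(t) = m(t_off) * exp(-gamma (t - t_off))                 t  > t_off

Fluorescent protein is taken to be the running integral of mRNA (constant
translation rate, no protein degradation, translation constant absorbed
into beta), offset by the basal pre-stress level ``g0``:

    G(t) = g0 + integral_0^t m(s) ds

``G`` is continuous with continuous first derivative and saturates at
``g0 + beta * (t_off - t_on) / gamma`` — the total mRNA produced divided
by its decay rate.

``gamma`` is held fixed during fitting (default ln2/20 per minute, a 20 min
mRNA half-life): with protein-only observations beta and gamma are jointly
unidentifiable up to the plateau constraint, so the per-cell fit estimates
(t_on, t_off, beta, g0) only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigError, EstimationError

#: default mRNA decay rate, 1/min (20-minute half-life)
DEFAULT_GAMMA = float(np.log(2.0) / 20.0)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the single-cell induction model.

    t_on, t_off : promoter window boundaries, minutes (t_on <= t_off)
    beta        : mRNA production rate while the promoter is on, a.u./min
    gamma       : mRNA decay rate, 1/min (> 0)
    g0          : basal reporter level before induction, a.u.
    """

    t_on: float
    t_off: float
    beta: float
    gamma: float = DEFAULT_GAMMA
    g0: float = 0.0

    def __post_init__(self) -> None:
        if self.t_off < self.t_on:
            raise ConfigError(f"t_off ({self.t_off}) must be >= t_on ({self.t_on})")
        if self.beta < 0:
            raise ConfigError(f"beta must be >= 0, got {self.beta}")
        if self.gamma <= 0:
            raise ConfigError(f"gamma must be > 0, got {self.gamma}")
        if self.g0 < 0:
            raise ConfigError(f"g0 must be >= 0, got {self.g0}")

    @property
    def plateau(self) -> float:
        """Asymptotic reporter level g0 + beta*(t_off - t_on)/gamma."""
        return self.g0 + self.beta * (self.t_off - self.t_on) / self.gamma


@dataclass
class KineticFit:
    """Result of fitting one cell trace."""

    params: KineticParams
    sse: float
    converged: bool
    n_starts_tried: int
    cell_id: str | None = None
    strain: str | None = None


def promoter_state(t, params: KineticParams):
    """Square promoter window T(t): 1 on the closed interval [t_on, t_off]."""
    t = np.asarray(t, dtype=float)
    return ((t >= params.t_on) & (t <= params.t_off)).astype(float)


def mrna_curve(t, params: KineticParams):
    """Stress-induced mRNA level m(t); zero before t_on, continuous everywhere."""
    t = np.asarray(t, dtype=float)
    b, g = params.beta, params.gamma
    ton, toff = params.t_on, params.t_off
    m = np.zeros_like(t)
    on = (t >= ton) & (t <= toff)
    after = t > toff
    m[on] = (b / g) * -np.expm1(-g * (t[on] - ton))
    m_off = (b / g) * -np.expm1(-g * (toff - ton))
    m[after] = m_off * np.exp(-g * (t[after] - toff))
    return m


def protein_curve(t, params: KineticParams):
    """Reporter level G(t) = g0 + integral of m, in closed form (C^1 piecewise)."""
    t = np.asarray(t, dtype=float)
    b, g = params.beta, params.gamma
    ton, toff = params.t_on, params.t_off
    G = np.full_like(t, float(params.g0))

    on = (t >= ton) & (t <= toff)
    after = t > toff
    dt_on = t[on] - ton
    # integral of (b/g)(1 - e^{-g s}) from 0 to dt
    G[on] += (b / g) * (dt_on + np.expm1(-g * dt_on) / g)

    dwin = toff - ton
    G_off = params.g0 + (b / g) * (dwin + np.expm1(-g * dwin) / g)
    m_off = (b / g) * -np.expm1(-g * dwin)
    dt_af = t[after] - toff
    # integral of m_off e^{-g s} from 0 to dt
    G[after] = G_off + (m_off / g) * -np.expm1(-g * dt_af)
    return G


def _pack_params(t_on: float, delta: float, beta: float, g0: float,
                 gamma: float) -> KineticParams:
    return KineticParams(t_on=t_on, t_off=t_on + delta, beta=beta,
                         gamma=gamma, g0=g0)


def fit_trace(times, gfp, gamma: float = DEFAULT_GAMMA,
              bounds: dict | None = None, n_starts: tuple[int, int] = (5, 5),
              ftol: float = 1e-8, cell_id: str | None = None,
              strain: str | None = None) -> KineticFit:
    """Fit (t_on, t_off, beta, g0) of the induction model to one GFP trace.

    Bounded nonlinear least squares over (t_on, delta, beta, g0) with
    t_off = t_on + delta, delta >= 0 (so the t_on <= t_off constraint is
    structural).  Multi-start over an ``n_starts`` grid of (t_on, delta)
    seeds spanning the observation window; the best-SSE solution wins.

    Parameters
    ----------
    times, gfp : observation times (min) and reporter levels (a.u.)
    gamma : fixed mRNA decay rate (1/min)
    bounds : optional overrides with keys among {"t_on", "delta", "beta",
        "g0"}, each a (lo, hi) pair
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(gfp, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise EstimationError("times and gfp must be matching 1-D arrays")
    if t.size < 4:
        raise EstimationError("need at least 4 observations to fit 4 parameters")
    order = np.argsort(t)
    t, y = t[order], y[order]

    t0, t1 = float(t[0]), float(t[-1])
    span = t1 - t0
    rng_y = max(float(y.max() - y.min()), 1e-12)

    default_bounds = {
        "t_on": (t0, t1),
        "delta": (0.0, span),
        "beta": (0.0, 100.0 * gamma * rng_y / max(span / 10.0, 1e-6)),
        "g0": (0.0, float(y.max()) + 1e-9),
    }
    if bounds:
        default_bounds.update(bounds)
    lo = np.array([default_bounds[k][0] for k in ("t_on", "delta", "beta", "g0")])
    hi = np.array([default_bounds[k][1] for k in ("t_on", "delta", "beta", "g0")])

    def residuals(theta):
        p = _pack_params(theta[0], max(theta[1], 0.0), max(theta[2], 0.0),
                         max(theta[3], 0.0), gamma)
        return protein_curve(t, p) - y

    n_on, n_delta = n_starts
    ton_seeds = np.linspace(t0, t0 + 0.8 * span, n_on)
    delta_seeds = np.linspace(max(span / 20.0, 1.0), 0.8 * span, n_delta)
    g0_seed = min(max(float(y[0]), lo[3]), hi[3])

    best = None
    n_tried = 0
    for ts in ton_seeds:
        for ds in delta_seeds:
            # crude rate seed: rise of the trace over the seeded window
            beta_seed = gamma * rng_y / max(ds / 2.0, 1e-6)
            x0 = np.clip(np.array([ts, ds, beta_seed, g0_seed]), lo, hi)
            try:
                res = least_squares(residuals, x0, bounds=(lo, hi),
                                    method="trf", ftol=ftol, xtol=1e-10)
            except Exception:
                continue
            n_tried += 1
            sse = float(np.sum(res.fun ** 2))
            if best is None or sse < best[0] - 1e-12:
                best = (sse, res.x, res.status > 0)

    if best is None:
        raise EstimationError("all optimization starts failed")
    sse, x, ok = best
    params = _pack_params(float(x[0]), float(max(x[1], 0.0)),
                          float(max(x[2], 0.0)), float(max(x[3], 0.0)), gamma)
    return KineticFit(params=params, sse=sse, converged=bool(ok),
                      n_starts_tried=n_tried, cell_id=cell_id, strain=strain)


def fit_traces(trace_set, gamma: float = DEFAULT_GAMMA, **kwargs) -> list[KineticFit]:
    """Fit every cell in a long-format trace table (cell_id, time_min, gfp)."""
    fits = []
    df = trace_set.frame if hasattr(trace_set, "frame") else trace_set
    for cell_id, grp in df.groupby("cell_id", sort=True):
        strain = str(grp["strain"].iloc[0]) if "strain" in grp else None
        fits.append(fit_trace(grp["time_min"].to_numpy(), grp["gfp"].to_numpy(),
                              gamma=gamma, cell_id=str(cell_id), strain=strain,
                              **kwargs))
    return fits


def fits_frame(fits: list[KineticFit]) -> pd.DataFrame:
    """Tabulate fits (cell_id, strain, t_on, t_off, beta, g0, sse, converged)."""
    rows = [{
        "cell_id": f.cell_id, "strain": f.strain,
        "t_on": f.params.t_on, "t_off": f.params.t_off,
        "beta": f.params.beta, "g0": f.params.g0,
        "sse": f.sse, "converged": f.converged,
    } for f in fits]
    return pd.DataFrame(rows)


def population_summary(fits: list[KineticFit], bins=None) -> dict:
    """Per-strain medians/IQRs and histograms of t_on, t_off and beta.

    Parameters
    ----------
    fits : converged fits are summarized; at least one is required
    bins : optional dict parameter -> histogram bin edges; defaults to 10
        equal bins over the observed range of each parameter
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise EstimationError("population_summary requires >= 1 converged fit")
    df = fits_frame(good)
    df["strain"] = df["strain"].fillna("unknown")

    params = ("t_on", "t_off", "beta")
    stats = df.groupby("strain")[list(params)].agg(
        ["median", lambda s: s.quantile(0.75) - s.quantile(0.25), "count"])
    stats.columns = [f"{p}_{n}" for p, n in zip(
        [c[0] for c in stats.columns],
        ["median", "iqr", "n"] * len(params))]

    hists = {}
    for p in params:
        v = df[p].to_numpy()
        edges = (bins or {}).get(p)
        if edges is None:
            lo, hi = float(v.min()), float(v.max())
            edges = np.linspace(lo, hi if hi > lo else lo + 1.0, 11)
        counts = {}
        for strain, grp in df.groupby("strain"):
            counts[strain], _ = np.histogram(grp[p].to_numpy(), bins=edges)
        hists[p] = {"edges": np.asarray(edges), "counts": counts}
    return {"stats": stats, "histograms": hists}
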