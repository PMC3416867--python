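"""Generator for tiling-probe modification signal with planted metagene shapes."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..metagene import N_BODY, UPSTREAM_BP, TilingSignal
from .config import GroundTruth, SimConfig

#: spacing between adjacent gene territories so upstream windows never overlap
_GAP_BP = 2 * UPSTREAM_BP + 100

#: shape functions of (upstream offset u in [-300, 0)) or (body fraction f).
#: Body values are constant within each 5% metagene bin (the planted shape is
#: literally a per-bin profile), so strand-mirror recovery is exact at zero noise.
def _shape_value(name: str, amplitude: float, off: float, frac: float | None) -> float:
    if frac is not None:
        frac = (np.floor(frac * N_BODY) + 0.5) / N_BODY  # bin midpoint
    if name == "flat":
        return amplitude
    if name == "five_prime_peak":
        # amplitude over the upstream window, exponential decay along the body
        return amplitude if frac is None else amplitude * float(np.exp(-5.0 * frac))
    if name == "three_prime_peak":
        return 0.0 if frac is None else amplitude * float(np.exp(-5.0 * (1.0 - frac)))
    raise ValueError(f"unknown shape {name!r}")


DEFAULT_SHAPES = {
    "RPG": ("five_prime_peak", 2.0),
    "Ribi": ("five_prime_peak", 1.0),
    "other": ("flat", 0.5),
}
DEFAULT_TIMEMOD = {
    "RPG": (1.0, 1.1, 1.3, 1.6, 1.9, 2.0),
    "Ribi": (1.0, 0.9, 0.7, 0.5, 0.4, 0.35),
    "other": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
}


def gen_tiling_dataset(cfg: SimConfig, shape_by_label: dict | None = None,
                       timemod_by_label: dict | None = None
                       ) -> tuple[TilingSignal, pd.DataFrame, GroundTruth]:
    """Simulate tiling signal over non-overlapping genes on both strands.

    Probe value = shape(gene-relative position | label) * time modulation
    + Gaussian noise; probes outside any gene territory sit at zero (plus
    noise).  Genes shorter than one probe spacing trigger a warning but
    are still emitted, so sparse-bin handling downstream gets exercised.

    Returns (signal, annotation, ground truth); the annotation carries
    gene_id/chrom/strand/tss/tes/label/pol2_level.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shapes = {**DEFAULT_SHAPES, **(shape_by_label or {})}
    timemods = {**DEFAULT_TIMEMOD, **(timemod_by_label or {})}
    times = np.asarray(cfg.tiling_times_min, dtype=float)

    frac_rpg, frac_ribi = cfg.label_fracs
    labels = rng.choice(["RPG", "Ribi", "other"], size=cfg.n_genes,
                        p=[frac_rpg, frac_ribi, 1.0 - frac_rpg - frac_ribi])
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1,
                           size=cfg.n_genes)
    pol2 = np.exp(rng.normal(0.0, 1.0, size=cfg.n_genes))

    rows = []
    pos = _GAP_BP
    for g in range(cfg.n_genes):
        start, end = pos, pos + int(lengths[g])
        if lengths[g] < cfg.probe_spacing_bp:
            warnings.warn(
                f"gene_{g:03d} shorter ({lengths[g]} bp) than probe spacing "
                f"({cfg.probe_spacing_bp} bp); body bins will be sparse")
        tss, tes = (start, end) if strands[g] == "+" else (end, start)
        rows.append({"gene_id": f"gene_{g:03d}", "chrom": "chrS",
                     "strand": strands[g], "tss": tss, "tes": tes,
                     "start": start, "end": end, "label": labels[g],
                     "pol2_level": float(pol2[g])})
        pos = end + _GAP_BP
    ann = pd.DataFrame(rows)
    total_len = pos

    spacing = cfg.probe_spacing_bp
    starts = np.arange(0, total_len, spacing)
    probes = pd.DataFrame({"chrom": "chrS", "start": starts,
                           "end": np.minimum(starts + spacing, total_len)})
    mids = (probes["start"].to_numpy() + probes["end"].to_numpy()) / 2.0

    values = np.zeros((len(probes), times.size))
    for _, gene in ann.iterrows():
        name, amp = shapes[gene["label"]]
        mod = np.asarray(timemods[gene["label"]], dtype=float)
        if mod.size != times.size:
            raise ValueError(
                f"time modulation for {gene['label']!r} has {mod.size} entries "
                f"for {times.size} time points")
        length = abs(gene["tes"] - gene["tss"])
        off = (mids - gene["tss"]) if gene["strand"] == "+" else (gene["tss"] - mids)
        upstream = (off >= -UPSTREAM_BP) & (off < 0)
        body = (off >= 0) & (off < length)
        for pi in np.flatnonzero(upstream):
            base = _shape_value(name, amp, off[pi], None)
            values[pi] = base * mod
        for pi in np.flatnonzero(body):
            base = _shape_value(name, amp, off[pi], off[pi] / length)
            values[pi] = base * mod
    if cfg.tiling_noise_sd > 0:
        values = values + rng.normal(0.0, cfg.tiling_noise_sd, values.shape)

    sig = TilingSignal(
        probes=probes,
        values=pd.DataFrame(values, columns=[f"{t:g}" for t in times]))
    truth = GroundTruth(gene_shapes=pd.DataFrame({
        "gene_id": ann["gene_id"], "label": ann["label"],
        "shape": [shapes[l][0] for l in ann["label"]],
        "amplitude": [shapes[l][1] for l in ann["label"]],
    }).set_index("gene_id"))
    return sig, ann.drop(columns=["start", "end"]), truth
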