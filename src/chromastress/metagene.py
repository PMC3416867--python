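"""Strand-aware metagene aggregation of tiling-probe modification signal.

Every gene is mapped onto a common 26-bin "metagene" axis: six upstream
bins of 50 bp covering −300..0 relative to the TSS (bin 1 most distal)
followed by twenty body bins of 5% of gene length each (bins 7–26,
TSS→TES).  Probe membership is by midpoint; coordinates are 0-based
half-open, and for minus-strand genes the TSS is the larger coordinate so
gene-relative offsets always increase 5′→3′.  Profiles average the probe
values per bin across a gene group (functional label or Pol2-occupancy
class) at each time point; bins with no probes are reported masked (NaN),
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

N_UPSTREAM = 6
N_BODY = 20
N_BINS = N_UPSTREAM + N_BODY
UPSTREAM_BP = 300
UPSTREAM_STEP = 50

ANNOTATION_COLUMNS = ("gene_id", "chrom", "strand", "tss", "tes",
                      "label", "pol2_level")

#: default region scheme for temporal change maps
DEFAULT_REGIONS = {
    "promoter": tuple(range(1, 7)),
    "five_prime": tuple(range(7, 17)),
    "three_prime": tuple(range(17, 27)),
}


@dataclass
class TilingSignal:
    """Tiling-probe signal: probe intervals plus one value column per time.

    probes : DataFrame (chrom, start, end), 0-based half-open, non-overlapping
    values : DataFrame aligned with probes, one column per time point (min)
    """

    probes: pd.DataFrame
    values: pd.DataFrame

    @property
    def times(self) -> np.ndarray:
        return np.asarray([float(c) for c in self.values.columns])

    def midpoints(self) -> np.ndarray:
        return (self.probes["start"].to_numpy() + self.probes["end"].to_numpy()) / 2.0


def check_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (strand-oriented TSS/TES)."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ConfigError(f"annotation missing columns {missing}")
    plus = ann["strand"] == "+"
    minus = ann["strand"] == "-"
    if not (plus | minus).all():
        raise ConfigError("strand must be '+' or '-'")
    if (ann["tss"] == ann["tes"]).any():
        raise ConfigError("tss must differ from tes")
    if not (ann.loc[plus, "tss"] < ann.loc[plus, "tes"]).all():
        raise ConfigError("plus-strand genes require tss < tes")
    if not (ann.loc[minus, "tss"] > ann.loc[minus, "tes"]).all():
        raise ConfigError("minus-strand genes require tss > tes")
    return ann


def _relative(mid: float, tss: float, strand: str) -> float:
    return mid - tss if strand == "+" else tss - mid


def assign_bin(probe, gene) -> int | None:
    """Metagene bin (1..26) of one probe for one gene, or None if outside.

    ``probe`` needs fields chrom/start/end; ``gene`` needs
    chrom/strand/tss/tes.  Upstream offsets in [−300, 0) map to bins 1–6;
    body fractions in [0, 1) map to bins 7–26 (the TSS itself is body
    bin 7).
    """
    if probe["chrom"] != gene["chrom"]:
        return None
    mid = (probe["start"] + probe["end"]) / 2.0
    off = _relative(mid, gene["tss"], gene["strand"])
    length = abs(gene["tes"] - gene["tss"])
    if -UPSTREAM_BP <= off < 0:
        return 1 + int((off + UPSTREAM_BP) // UPSTREAM_STEP)
    if off >= 0:
        frac = off / length
        if frac < 1.0:
            return 1 + N_UPSTREAM + int(frac * N_BODY)
    return None


def assign_bins(sig: TilingSignal, ann: pd.DataFrame) -> pd.DataFrame:
    """Vectorized probe→(gene, bin) assignment over a whole design.

    Assumes the upstream-extended gene intervals are non-overlapping (each
    probe midpoint falls in at most one gene's territory).  Returns a
    DataFrame (probe_index, gene_id, bin).
    """
    check_annotation(ann)
    out = []
    mids = sig.midpoints()
    for chrom, genes in ann.groupby("chrom"):
        sel = np.flatnonzero((sig.probes["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        # extended territory: upstream 300 bp + gene body, genome order
        ext_start = np.where(genes["strand"] == "+",
                             genes["tss"] - UPSTREAM_BP,
                             np.minimum(genes["tss"], genes["tes"]))
        ext_end = np.where(genes["strand"] == "+",
                           np.maximum(genes["tss"], genes["tes"]),
                           genes["tss"] + UPSTREAM_BP)
        order = np.argsort(ext_start)
        ext_start, ext_end = ext_start[order], ext_end[order]
        g = genes.iloc[order]
        m = mids[sel]
        idx = np.searchsorted(ext_start, m, side="right") - 1
        ok = (idx >= 0) & (m < ext_end[np.clip(idx, 0, None)])
        for pi, gi in zip(sel[ok], idx[ok]):
            row = g.iloc[gi]
            off = _relative(mids[pi], row["tss"], row["strand"])
            length = abs(row["tes"] - row["tss"])
            if -UPSTREAM_BP <= off < 0:
                b = 1 + int((off + UPSTREAM_BP) // UPSTREAM_STEP)
            elif off >= 0 and off / length < 1.0:
                b = 1 + N_UPSTREAM + int(off / length * N_BODY)
            else:
                continue
            out.append((pi, row["gene_id"], b))
    return pd.DataFrame(out, columns=["probe_index", "gene_id", "bin"])


def pol2_classes(ann: pd.DataFrame, k: int = 4) -> pd.Series:
    """Quantile cut of genes into k equal-size Pol2-occupancy classes (1..k).

    Ties are assigned to the lower class: if all levels are equal, every
    gene lands in class 1.
    """
    levels = ann["pol2_level"].to_numpy(dtype=float)
    n = levels.size
    if k > n:
        raise ConfigError(f"k={k} exceeds number of genes ({n})")
    s = np.sort(levels)
    bounds = np.array([s[int(np.ceil(n * i / k)) - 1] for i in range(1, k + 1)])
    cls = 1 + np.searchsorted(bounds, levels, side="left")
    cls = np.minimum(cls, k)
    return pd.Series(cls, index=ann["gene_id"].to_numpy(), name="pol2_class")


@dataclass
class MetageneProfile:
    """Average modification signal per (group, bin) per time point.

    means / n_probes : DataFrames with MultiIndex (group, bin 1..26) rows
    and one column per time point; empty bins are NaN in ``means``.
    """

    means: pd.DataFrame
    n_probes: pd.DataFrame


def _gene_groups(ann: pd.DataFrame, groupby: str, k: int) -> pd.Series:
    if groupby == "label":
        return pd.Series(ann["label"].to_numpy(), index=ann["gene_id"].to_numpy())
    if groupby == "pol2":
        return pol2_classes(ann, k=k).map(lambda c: f"pol2_q{c}")
    raise ConfigError(f"groupby must be 'label' or 'pol2', got {groupby!r}")


def metagene_profile(sig: TilingSignal, ann: pd.DataFrame,
                     groupby: str = "label", k: int = 4) -> MetageneProfile:
    """26-bin average profile per gene group per time point."""
    groups = _gene_groups(ann, groupby, k)
    asn = assign_bins(sig, ann)
    asn = asn.assign(group=asn["gene_id"].map(groups))
    vals = sig.values.iloc[asn["probe_index"].to_numpy()].reset_index(drop=True)
    long = pd.concat([asn[["group", "bin"]].reset_index(drop=True), vals], axis=1)

    grouped = long.groupby(["group", "bin"])
    means = grouped.mean(numeric_only=True)
    counts = grouped[vals.columns[0]].apply(lambda s: s.notna().sum())

    full = pd.MultiIndex.from_product(
        [sorted(groups.unique()), range(1, N_BINS + 1)], names=["group", "bin"])
    means = means.reindex(full)
    n_probes = pd.DataFrame(
        {c: counts.reindex(full).fillna(0).astype(int) for c in vals.columns})
    return MetageneProfile(means=means, n_probes=n_probes)


def change_map(sig: TilingSignal, ann: pd.DataFrame,
               regions: dict | None = None) -> pd.DataFrame:
    """Per-gene, per-region signal change relative to the first time point.

    Regions are named sets of metagene bins (default: promoter = upstream
    bins 1–6, five_prime = body bins 7–16, three_prime = body bins 17–26).
    Genes or regions without probes come back masked (NaN).
    """
    regions = regions or DEFAULT_REGIONS
    check_annotation(ann)
    asn = assign_bins(sig, ann)
    bin_to_region = {}
    for name, bins in regions.items():
        for b in bins:
            bin_to_region[b] = name
    asn = asn.assign(region=asn["bin"].map(bin_to_region))
    asn = asn.dropna(subset=["region"])
    vals = sig.values.iloc[asn["probe_index"].to_numpy()].reset_index(drop=True)
    long = pd.concat([asn[["gene_id", "region"]].reset_index(drop=True), vals],
                     axis=1)
    region_vals = long.groupby(["gene_id", "region"]).mean(numeric_only=True)

    full = pd.MultiIndex.from_product(
        [ann["gene_id"].to_numpy(), list(regions)], names=["gene_id", "region"])
    region_vals = region_vals.reindex(full)
    t0 = region_vals.columns[0]
    return region_vals.sub(region_vals[t0], axis=0)
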