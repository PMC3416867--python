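"""Plain-text readers/writers for every pipeline artifact.

Count matrices use a TSV dialect with three commented metadata rows
(#strain, #time_min, #replicate) above the probe table, so strain/time
metadata travels with the counts.  Traces are long-format TSV; tiling
signal is (chrom, start, end, one column per time point); annotations are
6-column BED (score column = Pol2 level) plus a label column.  All
genomic coordinates are 0-based half-open.  Images are multi-page
grayscale TIFF, one file per channel.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .metagene import TilingSignal
from .ncounter import CountMatrix, NormalizationFit, NormalizedMatrix
from .responsiveness import DifferenceMap
from .synthetic.images import ImageSequence
from .synthetic.traces import CellTraceSet


# -- count matrices -----------------------------------------------------------

def _write_count_like(values: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for field in ("strain", "time_min", "replicate"):
            row = "\t".join(str(meta.loc[s, field]) for s in values.columns)
            fh.write(f"#{field}\t{row}\n")
        fh.write("probe_id\t" + "\t".join(map(str, values.columns)) + "\n")
        values.to_csv(fh, sep="\t", header=False)


def _read_count_like(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    meta_rows = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            name, _, rest = line[1:].rstrip("\n").partition("\t")
            meta_rows[name] = rest.split("\t")
        else:
            body_start = k
            break
    values = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t",
                         index_col=0)
    meta = pd.DataFrame(meta_rows, index=values.columns)
    meta.index.name = "sample_id"
    meta["time_min"] = meta["time_min"].astype(float)
    meta["replicate"] = meta["replicate"].astype(int)
    return values, meta


def write_counts(counts: CountMatrix, path) -> None:
    _write_count_like(counts.values, counts.sample_meta, path)


def read_counts(path) -> CountMatrix:
    values, meta = _read_count_like(path)
    return CountMatrix(values=values, sample_meta=meta)


def write_normalized(norm: NormalizedMatrix, path) -> None:
    _write_count_like(norm.values, norm.sample_meta, path)


def read_normalized(path) -> NormalizedMatrix:
    values, meta = _read_count_like(path)
    return NormalizedMatrix(values=values, sample_meta=meta)


def write_fits(fits: dict[str, NormalizationFit], path) -> None:
    rows = [{"sample_id": f.sample_id, "a": f.a, "b": f.b, "r2": f.fit_r2,
             "reference_id": f.reference_id, "n_used": f.n_used}
            for f in fits.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fits(path) -> dict[str, NormalizationFit]:
    df = pd.read_csv(path, sep="\t")
    return {r.sample_id: NormalizationFit(sample_id=r.sample_id, a=r.a, b=r.b,
                                          fit_r2=r.r2,
                                          reference_id=r.reference_id,
                                          n_used=int(r.n_used))
            for r in df.itertuples()}


# -- difference maps ----------------------------------------------------------

def write_diffmap(dm: DifferenceMap, path) -> None:
    out = dm.values.where(~dm.mask)
    out.columns = [f"{m}@{t:g}" for m, t in out.columns]
    out.to_csv(path, sep="\t")


def read_diffmap(path) -> DifferenceMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = []
    for c in df.columns:
        m, _, t = c.rpartition("@")
        cols.append((m, float(t)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["mutant", "time_min"])
    return DifferenceMap(values=df, mask=~np.isfinite(df))


# -- single-cell traces -------------------------------------------------------

def write_traces(traces: CellTraceSet, path) -> None:
    traces.frame.to_csv(path, sep="\t", index=False)


def read_traces(path) -> CellTraceSet:
    frame = pd.read_csv(path, sep="\t")
    return CellTraceSet(frame=frame,
                        times=np.sort(frame["time_min"].unique()))


# -- images -------------------------------------------------------------------

def write_image_sequence(seq: ImageSequence, mcherry_path, gfp_path) -> None:
    for stack, path in ((seq.mcherry, mcherry_path), (seq.gfp, gfp_path)):
        arr = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr, photometric="minisblack")


def read_image_sequence(mcherry_path, gfp_path, times=None) -> ImageSequence:
    mch = tifffile.imread(mcherry_path).astype(float)
    gfp = tifffile.imread(gfp_path).astype(float)
    if times is None:
        times = np.arange(mch.shape[0], dtype=float)
    return ImageSequence(mcherry=mch, gfp=gfp, times=np.asarray(times, float))


# -- tiling signal and annotation --------------------------------------------

def write_tiling(sig: TilingSignal, path) -> None:
    out = pd.concat([sig.probes.reset_index(drop=True),
                     sig.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_tiling(path) -> TilingSignal:
    df = pd.read_csv(path, sep="\t")
    probes = df[["chrom", "start", "end"]]
    values = df.drop(columns=["chrom", "start", "end"])
    return TilingSignal(probes=probes, values=values)


def write_annotation(ann: pd.DataFrame, path) -> None:
    """BED6 + label: chrom, start, end, gene_id, pol2_level, strand, label."""
    bed = pd.DataFrame({
        "chrom": ann["chrom"],
        "start": np.minimum(ann["tss"], ann["tes"]),
        "end": np.maximum(ann["tss"], ann["tes"]),
        "name": ann["gene_id"],
        "score": ann["pol2_level"],
        "strand": ann["strand"],
        "label": ann["label"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_annotation(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score",
                             "strand", "label"])
    plus = bed["strand"] == "+"
    return pd.DataFrame({
        "gene_id": bed["name"], "chrom": bed["chrom"],
        "strand": bed["strand"],
        "tss": np.where(plus, bed["start"], bed["end"]),
        "tes": np.where(plus, bed["end"], bed["start"]),
        "label": bed["label"], "pol2_level": bed["score"],
    })


# -- network products ---------------------------------------------------------

def write_correlation(mc, path) -> None:
    mc.r.to_csv(path, sep="\t")


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick if newick.endswith("\n") else newick + "\n")
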