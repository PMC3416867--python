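"""Mutant difference maps and responsiveness summaries.

A difference map expresses every mutant sample as a variance-stabilized
Δh against the time-matched wild-type reference, per probe.  Summaries:

* fraction of (mutant, probe) entries changed beyond a |Δh| threshold per
  time point (Δh is log2-equivalent at high expression, so the usual 0.5
  log2 cutoff applies directly);
* PCA over per-mutant concatenated profiles — the first component
  captures the hyper/hypo amplitude axis of the stress response;
* area-under-curve effects over the time course for a gene set (Δh·min);
* paired gene-set means (e.g. ribosomal-protein vs ribosome-biogenesis
  regulons) per mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigError, EstimationError, MissingReferenceError
from .ncounter import WT_STRAIN, NormalizedMatrix, VarianceStabilizer, build_reference


@dataclass
class DifferenceMap:
    """Probe x (mutant, time) Δh map against time-matched wild type.

    values : DataFrame, rows = probes, columns = MultiIndex (mutant, time)
    mask : aligned boolean DataFrame, True where the entry is missing
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    @property
    def mutants(self):
        return self.values.columns.get_level_values(0).unique()

    @property
    def times(self):
        return sorted(self.values.columns.get_level_values(1).unique())

    def mutant_vectors(self) -> pd.DataFrame:
        """One concatenated (probe x time) row vector per mutant, NaN-masked."""
        vals = self.values.where(~self.mask)
        stacked = {}
        for m in self.mutants:
            sub = vals[m]  # probes x times
            stacked[m] = sub.to_numpy().ravel(order="F")
        return pd.DataFrame(stacked).T


def difference_map(norm: NormalizedMatrix, vs: VarianceStabilizer,
                   wt_strain: str = WT_STRAIN) -> DifferenceMap:
    """Δh(mutant value, wild-type reference) for every mutant sample.

    The reference for each time point is the mean of the wild-type
    columns at that time (which pass through normalization unchanged).
    Replicate mutant samples at the same (strain, time) are averaged on
    the Δh scale.
    """
    meta = norm.sample_meta
    wt_cols = meta.index[meta["strain"] == wt_strain]
    if len(wt_cols) == 0:
        raise MissingReferenceError(f"no wild-type ({wt_strain!r}) columns")
    refs = {t: norm.values[meta.index[(meta["strain"] == wt_strain)
                                      & (meta["time_min"] == t)]].mean(axis=1)
            for t in sorted(meta.loc[wt_cols, "time_min"].unique())}

    mut_meta = meta[meta["strain"] != wt_strain]
    missing_t = sorted(set(mut_meta["time_min"]) - set(refs))
    if missing_t:
        raise MissingReferenceError(
            f"no wild-type reference at time point(s) {missing_t}")

    cols, data = [], []
    for (strain, t), grp in mut_meta.groupby(["strain", "time_min"], sort=True):
        d = vs.delta_h(norm.values[grp.index].mean(axis=1), refs[t])
        cols.append((strain, t))
        data.append(pd.Series(d, index=norm.values.index))
    values = pd.concat(data, axis=1)
    values.columns = pd.MultiIndex.from_tuples(cols, names=["mutant", "time_min"])
    mask = ~np.isfinite(values)
    return DifferenceMap(values=values, mask=mask)


def fraction_changed(dm: DifferenceMap, threshold: float = 0.5) -> pd.DataFrame:
    """Per-time fractions of unmasked entries with Δh beyond ±threshold."""
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    out = {}
    vals = dm.values.where(~dm.mask)
    for t in dm.times:
        sub = vals.xs(t, level="time_min", axis=1).to_numpy()
        n = np.isfinite(sub).sum()
        up = float((sub > threshold).sum()) / n if n else np.nan
        down = float((sub < -threshold).sum()) / n if n else np.nan
        out[t] = {"frac_up": up, "frac_down": down}
    return pd.DataFrame(out).T.rename_axis("time_min")


@dataclass
class PCAResult:
    scores: pd.DataFrame          # mutants x components
    loadings: pd.DataFrame        # (probe, time) features x components
    variance_explained: np.ndarray


def pca_responsiveness(dm: DifferenceMap, induced_probes=None,
                       n_components: int | None = None) -> PCAResult:
    """Mean-centered PCA over per-mutant concatenated difference profiles.

    PC1's sign is arbitrary; it is oriented so hyper-responsive mutants
    score positive — concretely, so that the mutant with the largest mean
    Δh over ``induced_probes`` (probes induced in wild type) has a
    positive score.  Without ``induced_probes`` a deterministic fallback
    makes the largest-magnitude PC1 loading positive.
    """
    X = dm.mutant_vectors()
    if X.shape[0] < 2 or dm.values.shape[0] < 2:
        raise EstimationError("PCA requires >= 2 mutants and >= 2 probes")
    # masked entries excluded by feature-mean imputation
    Xf = X.fillna(X.mean(axis=0)).fillna(0.0)
    if np.allclose(Xf.to_numpy().std(axis=0).sum(), 0.0):
        raise EstimationError("rank-deficient input: no between-mutant variance")

    n_comp = min(n_components or min(Xf.shape) - 1, min(Xf.shape) - 1, Xf.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Xf.to_numpy())
    loadings = pca.components_.T

    signs = np.ones(n_comp)
    if induced_probes is not None:
        probe_idx = dm.values.index.get_indexer(pd.Index(induced_probes))
        probe_idx = probe_idx[probe_idx >= 0]
        n_probes = dm.values.shape[0]
        feat = np.concatenate([probe_idx + k * n_probes
                               for k in range(len(dm.times))])
        induced_mean = Xf.to_numpy()[:, feat].mean(axis=1)
        ref_mutant = int(np.argmax(induced_mean))
        if scores[ref_mutant, 0] < 0:
            signs[0] = -1.0
    else:
        if loadings[np.argmax(np.abs(loadings[:, 0])), 0] < 0:
            signs[0] = -1.0
    for k in range(1, n_comp):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            signs[k] = -1.0
    scores = scores * signs
    loadings = loadings * signs

    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    # mutant_vectors ravels probes-fastest within each time block
    feat_index = pd.MultiIndex.from_tuples(
        [(p, t) for t in dm.times for p in dm.values.index],
        names=["probe_id", "time_min"])
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=feat_index, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_)


def auc_effect(dm: DifferenceMap, gene_set, times=None) -> pd.Series:
    """Trapezoidal area under the gene-set mean Δh time course (Δh·min)."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ConfigError("gene_set must be nonempty")
    missing = set(gene_set) - set(dm.values.index)
    if missing:
        raise ConfigError(f"gene_set members not in map: {sorted(missing)[:5]}")
    times = list(times) if times is not None else dm.times
    vals = dm.values.where(~dm.mask)
    out = {}
    for m in dm.mutants:
        series = [vals.loc[gene_set, (m, t)].mean() for t in times]
        out[m] = float(np.trapezoid(series, times))
    return pd.Series(out, name="auc")


def geneset_scatter(dm: DifferenceMap, set_a, set_b,
                    collapse: str = "none") -> pd.DataFrame:
    """Per-mutant mean Δh on two disjoint gene sets (per time or AUC).

    ``collapse="none"`` returns rows (mutant, time) with columns
    (mean_a, mean_b); ``collapse="auc"`` integrates each set's time course.
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ConfigError("gene sets must be nonempty")
    overlap = set(set_a) & set(set_b)
    if overlap:
        raise ConfigError(f"gene sets overlap: {sorted(overlap)[:5]}")
    if collapse == "auc":
        return pd.DataFrame({"auc_a": auc_effect(dm, set_a),
                             "auc_b": auc_effect(dm, set_b)})
    vals = dm.values.where(~dm.mask)
    rows = []
    for m in dm.mutants:
        for t in dm.times:
            rows.append({"mutant": m, "time_min": t,
                         "mean_a": float(vals.loc[set_a, (m, t)].mean()),
                         "mean_b": float(vals.loc[set_b, (m, t)].mean())})
    return pd.DataFrame(rows).set_index(["mutant", "time_min"])
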