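"""Weighted gene coexpression network construction.

Pearson correlation -> soft-threshold power selection by scale-free
topology fit -> unsigned adjacency |cor|^beta -> topological overlap
matrix (TOM) -> average-linkage clustering of the TOM dissimilarity with a
deterministic static height cut -> module eigengenes and kME.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency",
    "tom",
    "detect_modules",
    "module_eigengenes",
    "kme",
    "ModulePartition",
    "ModuleEigengenes",
]


def correlation_matrix(
    expr: pd.DataFrame, max_na_frac: float = 0.5
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Gene-gene Pearson correlation.

    Genes with more than ``max_na_frac`` missing values are removed;
    remaining missing values are handled pairwise-complete.  Zero-variance
    genes get correlation 0 against everything (flagged) and 1 on the
    diagonal.

    Returns ``(cor, removed_genes, zero_variance_genes)``.
    """
    if expr.shape[1] < 3:
        raise ValueError("at least 3 samples required")
    na_frac = expr.isna().mean(axis=1)
    removed = list(expr.index[na_frac > max_na_frac])
    kept = expr.drop(index=removed)

    values = kept.to_numpy(dtype=float)
    sd = np.nanstd(values, axis=1)
    flagged = list(kept.index[sd == 0])

    if np.isnan(values).any():
        cor = kept.T.corr(min_periods=2)  # pairwise-complete
        cor = cor.fillna(0.0)
        c = cor.to_numpy()
    else:
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(values)
        c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=kept.index, columns=kept.index), removed, flagged


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index.

    Connectivities are discretized into ``n_bins`` equal-width bins;
    log10(frequency) is regressed on log10(mean connectivity per bin) and
    the R^2 of that fit is returned, signed by the slope: a power-law
    degree distribution has a *decreasing* frequency-connectivity
    relation, so a positive slope yields a negative index.
    """
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3:
        return 0.0
    slope, icpt = np.polyfit(xs, ys, 1)
    fitted = slope * xs + icpt
    ss_res = float(((ys - fitted) ** 2).sum())
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return float(-np.sign(slope) * (1.0 - ss_res / ss_tot))


def pick_soft_threshold(
    expr: pd.DataFrame,
    betas: range | list[int] = range(1, 21),
    r2_min: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest power whose adjacency yields a scale-free
    degree distribution fit with R^2 >= ``r2_min``.

    Returns ``(chosen_beta, table)`` where the table lists, per power, the
    scale-free fit R^2 and the mean connectivity.  If no power reaches the
    threshold, the power with maximal R^2 is returned with a warning.
    """
    if expr.shape[0] < 50:
        raise ValueError("at least 50 genes required for a degree distribution")
    cor, _, _ = correlation_matrix(expr)
    ac = np.abs(cor.to_numpy())
    rows = []
    for b in betas:
        a = ac**b
        k = a.sum(axis=1) - 1.0  # exclude self
        if np.allclose(k, k[0]):
            rows.append({"beta": b, "r2": 0.0, "mean_k": float(k.mean()),
                         "degenerate": True})
            continue
        rows.append(
            {
                "beta": b,
                "r2": _scale_free_r2(k, n_bins=n_bins),
                "mean_k": float(k.mean()),
                "degenerate": False,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= r2_min]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
    else:
        chosen = int(table.loc[table["r2"].idxmax(), "beta"])
        warnings.warn(
            f"no power reached scale-free R^2 >= {r2_min}; "
            f"using beta={chosen} (max R^2)"
        )
    return chosen, table


def adjacency(cor: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``|cor|^beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(cor.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diagonal 1.
    The dissimilarity used for clustering is 1 - TOM.
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    # (A @ A)_ij counts u = i and u = j (each contributing a_ij with unit diag)
    l = a @ a - 2.0 * a
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


@dataclass
class ModulePartition:
    """Gene -> module label assignment (label 0 = unassigned)."""

    labels: pd.Series
    min_size: int
    cut_height: float = float("nan")

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    @property
    def module_sizes(self) -> dict[int, int]:
        vc = self.labels.value_counts()
        return {int(m): int(vc[m]) for m in self.module_ids}

    def genes(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


def detect_modules(
    dissimilarity: pd.DataFrame, min_size: int = 500, n_heights: int = 200
) -> ModulePartition:
    """Average-linkage clustering of a (TOM) dissimilarity with a static cut.

    Candidate cut heights sweep from 0.99 of the maximal merge height
    downward; the chosen height is the largest one whose clusters of size
    >= ``min_size`` cover the most genes.  Clusters below ``min_size`` are
    labelled 0 (unassigned); modules are numbered 1..K by decreasing size.
    Fully deterministic.
    """
    genes = dissimilarity.index
    n = len(genes)
    if min_size > n:
        warnings.warn("min_size exceeds the number of genes; all unassigned")
        return ModulePartition(
            labels=pd.Series(0, index=genes, name="module"), min_size=min_size
        )
    d = dissimilarity.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    hmax = Z[:, 2].max()
    best_cov, best_h, best_labels = -1, None, None
    for h in np.linspace(0.99 * hmax, 0.0, n_heights):
        flat = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(flat)
        cov = int(sizes[sizes >= min_size].sum())
        if cov > best_cov:  # later (smaller) heights never replace on ties
            best_cov, best_h, best_labels = cov, h, flat
    # relabel: modules ordered by decreasing size, sub-threshold -> 0
    sizes = np.bincount(best_labels)
    big = [c for c in np.argsort(sizes)[::-1] if sizes[c] >= min_size and c > 0]
    mapping = {c: i + 1 for i, c in enumerate(big)}
    labels = np.array([mapping.get(c, 0) for c in best_labels])
    return ModulePartition(
        labels=pd.Series(labels, index=genes, name="module"),
        min_size=min_size,
        cut_height=float(best_h),
    )


@dataclass
class ModuleEigengenes:
    """First principal component of each module across samples.

    ``values`` is samples x modules; each eigengene is sign-oriented so
    that the mean kME of its member genes is non-negative.
    """

    values: pd.DataFrame
    variance_explained: pd.Series


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def module_eigengene(expr: pd.DataFrame, genes: pd.Index) -> tuple[np.ndarray, float]:
    """Eigengene (first right singular vector) of one module; returns
    (oriented eigengene over samples, variance explained)."""
    sub = expr.loc[genes].to_numpy(dtype=float)
    if np.all(sub.std(axis=1) == 0):
        raise ValueError("module contains only constant genes")
    z = _standardize_rows(sub)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    var_expl = float(s[0] ** 2 / (s**2).sum())
    # orient: mean correlation of member genes with the ME must be >= 0
    me_std = (me - me.mean()) / (me.std() or 1.0)
    kme_mean = float((z @ me_std).mean() / z.shape[1])
    if kme_mean < 0:
        me = -me
    return me, var_expl


def module_eigengenes(
    expr: pd.DataFrame, partition: ModulePartition
) -> ModuleEigengenes:
    """Eigengenes of all modules (label 0 excluded)."""
    cols, vals, ve = [], [], []
    for m in partition.module_ids:
        genes = partition.genes(m)
        if len(genes) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        me, var_expl = module_eigengene(expr, genes)
        cols.append(m)
        vals.append(me)
        ve.append(var_expl)
    values = pd.DataFrame(
        np.column_stack(vals) if vals else np.empty((expr.shape[1], 0)),
        index=expr.columns,
        columns=cols,
    )
    return ModuleEigengenes(
        values=values,
        variance_explained=pd.Series(ve, index=cols, name="variance_explained"),
    )


def kme(expr: pd.DataFrame, mes: ModuleEigengenes) -> pd.DataFrame:
    """kME matrix: Pearson correlation of every gene with every module
    eigengene (constant genes get 0, flagged by a zero row)."""
    z = _standardize_rows(expr.to_numpy(dtype=float))
    const = expr.to_numpy(dtype=float).std(axis=1) == 0
    m = mes.values.to_numpy(dtype=float)
    mz = (m - m.mean(axis=0)) / np.where(m.std(axis=0) == 0, 1.0, m.std(axis=0))
    k = (z @ mz) / expr.shape[1]
    k[const] = 0.0
    k = np.clip(k, -1.0, 1.0)
    return pd.DataFrame(k, index=expr.index, columns=mes.values.columns)
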