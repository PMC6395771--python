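"""Negative-binomial Wald differential expression.

Per-gene NB log-link GLMs with a shared design matrix, fitted by
iteratively reweighted least squares with gene-wise moment dispersions
shrunk toward a 1/mean trend.  The group coefficient is reported as
log2(case/control) with a Wald z and two-sided normal p, BH-adjusted
across genes.  DEG sets are called at two thresholds: adjusted p <= 0.05
("strict") and raw p <= 0.01 ("relaxed").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "estimate_size_factors",
    "estimate_dispersions",
    "fit_nb_glm_wald",
    "adjust_bh",
    "call_degs",
    "overlap_and_concordance",
    "DegSets",
]

_LN2 = float(np.log(2.0))


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over genes (nonzero in all
    samples) of the count divided by that gene's geometric mean across
    samples.  If no gene is nonzero everywhere, falls back to per-sample
    medians over each sample's positive counts with a warning.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] == 1:
        return pd.Series(1.0, index=counts.columns, name="size_factor")
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logx = np.log(x[all_pos])
        log_geo = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - log_geo, axis=0))
    else:
        warnings.warn(
            "no gene with nonzero counts in all samples; "
            "falling back to positive-count medians"
        )
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        log_geo = np.nanmean(logx, axis=1, keepdims=True)
        sf = np.exp(np.nanmedian(logx - log_geo, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame, size_factors: pd.Series | None = None
) -> pd.Series:
    """Per-gene NB dispersion alpha with trend shrinkage.

    Method-of-moments on normalized counts, ``alpha_hat = max(0,
    (s^2 - mu) / mu^2)``, then shrunk 50/50 toward a fitted
    mean-dispersion trend ``alpha_tr(mu) = a0 + a1/mu`` (least squares on
    genes with positive raw estimates).  All-zero genes get alpha = 0.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    x = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    mu = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    raw = np.maximum(raw, 0.0)

    usable = (mu > 0) & (raw > 0)
    if usable.sum() >= 10:
        A = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
        coef, *_ = np.linalg.lstsq(A, raw[usable], rcond=None)
        a0, a1 = coef
        with np.errstate(divide="ignore"):
            trend = np.where(mu > 0, a0 + a1 / mu, 0.0)
        trend = np.maximum(trend, 0.0)
    else:
        trend = np.zeros_like(mu)
    alpha = np.where(mu > 0, 0.5 * raw + 0.5 * trend, 0.0)
    return pd.Series(np.maximum(alpha, 0.0), index=counts.index, name="dispersion")


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for NB log-link GLMs sharing a design matrix.

    ``y``: genes x samples, ``X``: samples x p, ``offset``: per-sample log
    offsets, ``alpha``: per-gene dispersions.  Returns (beta, se, converged)
    with beta genes x p and se the Wald standard errors (inverse Fisher
    information diagonal).
    """
    g, n = y.shape
    p = X.shape[1]
    # init: intercept-only log-mean on the offset scale
    beta = np.zeros((g, p))
    mean_init = np.maximum((y / np.exp(offset)[None, :]).mean(axis=1), 1e-8)
    beta[:, 0] = np.log(mean_init)
    converged = np.zeros(g, dtype=bool)
    active = np.ones(g, dtype=bool)

    for _ in range(max_iter):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        eta = beta[idx] @ X.T + offset[None, :]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[idx, None] * mu)  # Fisher weights, log link
        z = eta - offset[None, :] + (y[idx] - mu) / mu  # working response
        XtWX = np.einsum("si,gs,sj->gij", X, W, X)
        XtWz = np.einsum("si,gs,gs->gi", X, W, z)
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack(
                [np.linalg.lstsq(XtWX[i], XtWz[i], rcond=None)[0] for i in range(len(idx))]
            )
        delta = np.max(np.abs(new_beta - beta[idx]), axis=1)
        beta[idx] = new_beta
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    # standard errors at the final fit
    eta = beta @ X.T + offset[None, :]
    eta = np.clip(eta, -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("si,gs,sj->gij", X, W, X)
    se = np.full((g, p), np.nan)
    for i in range(g):
        try:
            cov = np.linalg.inv(XtWX[i])
            d = np.diag(cov)
            se[i] = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            converged[i] = False
    return beta, se, converged


def fit_nb_glm_wald(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: str,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Per-gene NB Wald test for the ``contrast`` design column.

    ``design`` is a samples x p numeric matrix (see
    :func:`strianet.preprocess.build_design_matrix`); ``contrast`` names
    the column whose coefficient is tested (log2 fold change =
    coefficient / ln 2, oriented case/control when the column is a
    case-indicator).  Non-converged or all-zero genes are flagged and
    reported with p = 1.

    Returns a DataFrame with columns ``base_mean, log2fc, se, wald_z, p,
    p_adj, converged``.
    """
    if not set(design.index) == set(counts.columns):
        raise ValueError("design rows must match count matrix samples")
    design = design.loc[counts.columns]
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if contrast not in design.columns:
        raise ValueError(f"contrast column {contrast!r} not in design")
    y = counts.to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, size_factors)
    offset = np.log(size_factors.to_numpy(dtype=float))
    alpha = dispersions.to_numpy(dtype=float)

    nonzero = y.sum(axis=1) > 0
    ci = list(design.columns).index(contrast)

    beta = np.zeros((len(y), X.shape[1]))
    se = np.full((len(y), X.shape[1]), np.nan)
    conv = np.zeros(len(y), dtype=bool)
    if nonzero.any():
        b, s, c = _irls_nb(y[nonzero], X, offset, alpha[nonzero], max_iter=max_iter)
        beta[nonzero], se[nonzero], conv[nonzero] = b, s, c

    log2fc = beta[:, ci] / _LN2
    wald_se = se[:, ci] / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(conv & (wald_se > 0), log2fc / wald_se, 0.0)
    p = np.where(conv & nonzero, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p = np.minimum(p, 1.0)
    log2fc = np.where(nonzero, log2fc, 0.0)

    base_mean = (y / np.exp(offset)[None, :]).mean(axis=1)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": wald_se,
            "wald_z": np.where(conv, z, np.nan),
            "p": p,
            "p_adj": adjust_bh(p),
            "converged": conv & nonzero,
        },
        index=counts.index,
    )
    out.index.name = "gene_id"
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class DegSets:
    """DEG calls at the two reporting thresholds."""

    strict: set = field(default_factory=set)   # adjusted p <= adj_alpha
    relaxed: set = field(default_factory=set)  # raw p <= raw_alpha


def call_degs(
    results: pd.DataFrame, adj_alpha: float = 0.05, raw_alpha: float = 0.01
) -> DegSets:
    """Threshold the DE table into strict (adjusted) and relaxed (raw)
    DEG sets; non-converged genes are excluded."""
    ok = results["converged"].astype(bool) if "converged" in results else True
    strict = set(results.index[(results["p_adj"] <= adj_alpha) & ok])
    relaxed = set(results.index[(results["p"] <= raw_alpha) & ok])
    if not strict <= relaxed and len(strict - relaxed):
        warnings.warn("strict DEG set is not a subset of the relaxed set")
    return DegSets(strict=strict, relaxed=relaxed)


def overlap_and_concordance(
    deg_tables: dict[str, pd.DataFrame],
    deg_sets: dict[str, set],
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Cross-region DEG overlap and log2FC sign concordance.

    ``deg_tables`` maps region -> DE result table (log2fc column);
    ``deg_sets`` maps region -> the gene set to compare.  Returns
    (overlap_counts, concordance_fraction, per_gene_table): Venn-style
    exclusive/shared counts per region combination, the fraction of
    multi-region genes whose log2fc sign is identical in every region
    listing them, and the per-gene log2fc listing.
    """
    regions = list(deg_sets)
    if len(regions) < 2:
        raise ValueError("at least two regions required")
    for r, t in deg_tables.items():
        if t.index.duplicated().any():
            raise ValueError(f"duplicated gene ids in region {r}")

    membership: dict[str, tuple[str, ...]] = {}
    for gene in set().union(*deg_sets.values()):
        combo = tuple(r for r in regions if gene in deg_sets[r])
        membership[gene] = combo

    rows = []
    for k in range(1, len(regions) + 1):
        for combo in itertools.combinations(regions, k):
            n = sum(1 for c in membership.values() if c == combo)
            rows.append({"regions": "+".join(combo), "n_genes": n})
    overlap = pd.DataFrame(rows)

    shared = {g: c for g, c in membership.items() if len(c) > 1}
    per_gene = []
    n_concordant = 0
    for gene, combo in sorted(shared.items()):
        lfc = {r: float(deg_tables[r].loc[gene, "log2fc"]) for r in combo}
        signs = {np.sign(v) for v in lfc.values()}
        concordant = len(signs) == 1 and 0.0 not in signs
        n_concordant += concordant
        row = {"gene": gene, "regions": "+".join(combo), "concordant": concordant}
        row.update({f"log2fc_{r}": lfc.get(r, np.nan) for r in regions})
        per_gene.append(row)
    fraction = n_concordant / len(shared) if shared else float("nan")
    per_gene_df = pd.DataFrame(per_gene)
    return overlap, fraction, per_gene_df
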