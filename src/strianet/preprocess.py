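"""Expression filtering, normalization, hidden-covariate estimation and
sample-weight diagnostics.

The normalization stand-in is size-factor-scaled log2(CPM + pseudocount),
a variance-stabilized log scale adequate for downstream correlation
networks.  Hidden covariates are estimated by a two-step residual SVD with
permutation parallel analysis — the surrogate variables are the right
singular vectors of the expression residual after regressing out the known
design, retained while their singular values exceed the permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import estimate_size_factors

__all__ = [
    "compute_cpm",
    "filter_expressed",
    "normalize_log",
    "build_design_matrix",
    "estimate_surrogate_variables",
    "estimate_sample_weights",
    "compare_weight_distributions",
    "WeightComparison",
]


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``counts * 1e6 / library_size`` per sample."""
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts * 1e6 / lib


def filter_expressed(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    min_cpm: float = 0.3,
    min_frac: float = 0.5,
) -> tuple[pd.DataFrame, pd.Index]:
    """Keep genes with CPM >= ``min_cpm`` in >= ``min_frac`` of the samples
    of at least one group (case or control).

    Returns the filtered count matrix and the kept gene index.  The
    boundary is inclusive: a gene expressed in exactly half of one group's
    samples is kept.
    """
    groups = metadata.loc[counts.columns, "group"]
    present = set(groups.unique())
    if not {"case", "control"} <= present:
        raise ValueError("both case and control groups are required")
    cpm = compute_cpm(counts)
    keep = np.zeros(len(counts), dtype=bool)
    for g in ("case", "control"):
        cols = groups.index[groups == g]
        frac = (cpm[cols] >= min_cpm).mean(axis=1)
        keep |= (frac >= min_frac).to_numpy()
    kept = counts.index[keep]
    return counts.loc[kept], kept


def normalize_log(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(CPM + pseudocount) after median-of-ratios size-factor scaling."""
    sf = estimate_size_factors(counts)
    scaled = counts / sf
    return np.log2(compute_cpm(scaled) + pseudocount)


def build_design_matrix(
    metadata: pd.DataFrame,
    variables: list[str],
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Dummy-coded design matrix (samples x columns) from metadata columns.

    Numeric columns enter as-is (centered); categoricals are dummy-coded
    dropping the first level.  Raises on rank deficiency, naming the
    collinear columns.
    """
    parts = []
    if add_intercept:
        parts.append(pd.DataFrame({"intercept": 1.0}, index=metadata.index))
    for var in variables:
        col = metadata[var]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(pd.DataFrame({var: col.astype(float) - col.astype(float).mean()}))
        else:
            dummies = pd.get_dummies(col, prefix=var, drop_first=True, dtype=float)
            parts.append(dummies)
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]} columns): "
            f"{list(X.columns)}"
        )
    return X


def _residualize(expr: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual of each gene (row) after OLS on design X (samples x p)."""
    beta, *_ = np.linalg.lstsq(X, expr.T, rcond=None)
    return expr - (X @ beta).T


def estimate_surrogate_variables(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    primary: str,
    adjust: list[str] | None = None,
    n_sv: int | str = "auto",
    seed: int = 0,
    n_permutations: int = 20,
) -> pd.DataFrame:
    """Estimate hidden covariates from expression residuals.

    Regress every gene on the known design (primary variable of interest
    plus adjustment variables), then take the right singular vectors of the
    residual matrix as candidate surrogate variables.  When ``n_sv="auto"``
    the number retained is chosen by permutation parallel analysis: each
    gene's residuals are independently permuted ``n_permutations`` times
    and component *i* is kept while its singular value exceeds the 95th
    percentile of the permuted *i*-th singular values (stopping at the
    first failure).  Deterministic given ``seed``.

    Returns a samples x k DataFrame (columns ``SV1..SVk``; k may be 0).
    """
    adjust = adjust or []
    X = build_design_matrix(metadata.loc[expr.columns], [primary] + adjust)
    R = _residualize(expr.to_numpy(dtype=float), X.to_numpy())

    u, s, vt = np.linalg.svd(R, full_matrices=False)
    if n_sv == "auto":
        # compare variance *proportions*: residualizing the permuted matrix
        # removes mass from every component, so raw singular values are not
        # comparable between observed and null
        prop = s**2 / (s**2).sum()
        rng = np.random.default_rng(seed)
        max_k = min(10, len(s))
        perm_prop = np.empty((n_permutations, max_k))
        for b in range(n_permutations):
            Rp = rng.permuted(R, axis=1)
            Rp = _residualize(Rp, X.to_numpy())
            sp = np.linalg.svd(Rp, compute_uv=False)
            perm_prop[b] = (sp**2 / (sp**2).sum())[:max_k]
        thresh = np.quantile(perm_prop, 0.95, axis=0)
        k = 0
        while k < max_k and prop[k] > thresh[k]:
            k += 1
    else:
        k = int(n_sv)
    sv = vt[:k].T
    return pd.DataFrame(
        sv, index=expr.columns, columns=[f"SV{i + 1}" for i in range(k)]
    )


def estimate_sample_weights(expr: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Per-sample quality weights from residual variance about the fitted
    gene-wise means.

    weight_s is proportional to the inverse of sample s's leverage-adjusted
    mean squared residual, normalized to geometric mean 1; approximately
    one for homoscedastic samples, below one for noisy samples.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError("fewer samples than design columns")
    if n != expr.shape[1]:
        raise ValueError("design rows must match expression samples")
    E = expr.to_numpy(dtype=float)
    R = _residualize(E, X)
    hat = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
    msr = (R**2).mean(axis=0) / np.maximum(1.0 - hat, 1e-8)
    if np.max(msr) < 1e-12:  # identical samples within every design cell
        return pd.Series(1.0, index=expr.columns, name="weight")
    msr = np.maximum(msr, 1e-12)
    w = 1.0 / msr
    w = w / np.exp(np.mean(np.log(w)))
    return pd.Series(w, index=expr.columns, name="weight")


@dataclass(frozen=True)
class WeightComparison:
    ks_statistic: float
    p: float
    mean1: float
    var1: float
    median1: float
    mean2: float
    var2: float
    median2: float


def compare_weight_distributions(w1, w2) -> WeightComparison:
    """Two-sample Kolmogorov–Smirnov comparison of weight vectors with
    summary statistics of each (mean, variance, median)."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.size == 0 or w2.size == 0:
        raise ValueError("weight vectors must be non-empty")
    res = stats.ks_2samp(w1, w2, method="asymp")
    return WeightComparison(
        ks_statistic=float(res.statistic),
        p=float(res.pvalue),
        mean1=float(w1.mean()),
        var1=float(w1.var(ddof=1)) if w1.size > 1 else 0.0,
        median1=float(np.median(w1)),
        mean2=float(w2.mean()),
        var2=float(w2.var(ddof=1)) if w2.size > 1 else 0.0,
        median2=float(np.median(w2)),
    )
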