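"""Reference-based module preservation statistics.

Modules detected in the reference (control) network are mapped, with the
same gene membership, onto the test (case) data.  Seven observed
statistics are computed per module — four density statistics on the test
data (meanCor, meanAdj, propVarExplained, meanSignedKME) and three
connectivity statistics between reference and test (cor_kIM, cor_kME,
cor_cor).  A permutation null (random gene sets of the same size) turns
each into a Z-score; Zsummary is the mean of the median density Z and the
median connectivity Z, and medianRank is the permutation-free median of
cross-module preservation ranks.  On the Z scale, ~2 marks very little
preservation and ~10 a well-preserved module.

When Zsummary and medianRank disagree about the least preserved module,
the tie-break compares, for the union of the three least preserved
modules under each criterion, the correlation between reference and test
kME of the module's genes: the module with correlation closest to zero is
selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import ModulePartition, module_eigengene

__all__ = [
    "map_reference_modules",
    "observed_stats",
    "permutation_null",
    "summarize_preservation",
    "module_kme_correlation",
    "select_least_preserved",
    "PreservationStats",
]

DENSITY_STATS = ("meanCor", "meanAdj", "propVarExplained", "meanSignedKME")
CONNECTIVITY_STATS = ("cor_kIM", "cor_kME", "cor_cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


def map_reference_modules(
    ref_partition: ModulePartition, test_expr: pd.DataFrame
) -> tuple[ModulePartition, list[str]]:
    """Apply the reference module membership to the test dataset.

    Genes absent from the test data are dropped (returned for reporting);
    an empty intersection is an error.
    """
    common = ref_partition.labels.index.intersection(test_expr.index)
    if len(common) == 0:
        raise ValueError("reference and test gene universes do not overlap")
    dropped = list(ref_partition.labels.index.difference(test_expr.index))
    labels = ref_partition.labels.loc[common]
    return (
        ModulePartition(labels=labels, min_size=ref_partition.min_size),
        dropped,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _module_stat_vector(
    ref_corr: np.ndarray,
    test_corr: np.ndarray,
    ref_expr: np.ndarray,
    test_expr: np.ndarray,
    idx: np.ndarray,
    beta: float,
) -> dict[str, float]:
    """The 7 preservation statistics for one gene-index set."""
    cr = ref_corr[np.ix_(idx, idx)]
    ct = test_corr[np.ix_(idx, idx)]
    s = len(idx)
    tri = np.triu_indices(s, k=1)

    # density statistics on the test data
    mean_cor = float(ct[tri].mean())
    mean_adj = float((np.abs(ct[tri]) ** beta).mean())

    sub_t = test_expr[idx]
    me_t, pve_t = _eigengene_of(sub_t)
    kme_t = _row_cor_with(sub_t, me_t)
    mean_signed_kme = float(kme_t.mean())

    # connectivity statistics between reference and test
    kim_r = (np.abs(cr) ** beta).sum(axis=1) - 1.0
    kim_t = (np.abs(ct) ** beta).sum(axis=1) - 1.0
    sub_r = ref_expr[idx]
    me_r, _ = _eigengene_of(sub_r)
    kme_r = _row_cor_with(sub_r, me_r)

    return {
        "meanCor": mean_cor,
        "meanAdj": mean_adj,
        "propVarExplained": pve_t,
        "meanSignedKME": mean_signed_kme,
        "cor_kIM": _pearson(kim_r, kim_t),
        "cor_kME": _pearson(kme_r, kme_t),
        "cor_cor": _pearson(cr[tri], ct[tri]),
    }


def _eigengene_of(sub: np.ndarray) -> tuple[np.ndarray, float]:
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - mu) / sd
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    pve = float(s[0] ** 2 / (s**2).sum()) if (s**2).sum() > 0 else 0.0
    me_std = (me - me.mean()) / (me.std() or 1.0)
    if (z @ me_std).mean() < 0:
        me = -me
    return me, pve


def _row_cor_with(sub: np.ndarray, v: np.ndarray) -> np.ndarray:
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - mu) / sd
    vz = (v - v.mean()) / (v.std() or 1.0)
    return (z @ vz) / sub.shape[1]


@dataclass
class PreservationStats:
    """Per-module observed statistics, permutation Zs and composites."""

    observed: pd.DataFrame       # modules x 7 stats
    zscores: pd.DataFrame        # modules x 7 stats
    perm_mean: pd.DataFrame
    perm_sd: pd.DataFrame
    summary: pd.DataFrame        # module, size, Zdensity, Zconnectivity, Zsummary, medianRank
    n_perm: int


def observed_stats(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    partition: ModulePartition,
    beta: float,
) -> pd.DataFrame:
    """Observed preservation statistics for every module (label 0 and
    modules of fewer than 3 genes excluded, the latter with a warning)."""
    common = ref_expr.index.intersection(test_expr.index)
    ref = ref_expr.loc[common].to_numpy(dtype=float)
    test = test_expr.loc[common].to_numpy(dtype=float)
    ref_corr = np.corrcoef(ref)
    test_corr = np.corrcoef(test)
    pos = {g: i for i, g in enumerate(common)}

    rows = {}
    for m in partition.module_ids:
        genes = [g for g in partition.genes(m) if g in pos]
        if len(genes) < 3:
            warnings.warn(f"module {m} has fewer than 3 genes; stats undefined")
            continue
        idx = np.array([pos[g] for g in genes])
        rows[m] = _module_stat_vector(ref_corr, test_corr, ref, test, idx, beta)
    return pd.DataFrame(rows).T.loc[:, list(ALL_STATS)]


def permutation_null(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    partition: ModulePartition,
    beta: float,
    n_perm: int = 100,
    seed: int = 0,
) -> PreservationStats:
    """Permutation preservation analysis.

    For each module, ``n_perm`` random gene sets of the same size are drawn
    from the analysis universe and the statistic vector recomputed;
    Z = (observed - null mean) / null sd per statistic.  Deterministic
    given ``seed``.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    common = ref_expr.index.intersection(test_expr.index)
    ref = ref_expr.loc[common].to_numpy(dtype=float)
    test = test_expr.loc[common].to_numpy(dtype=float)
    ref_corr = np.corrcoef(ref)
    test_corr = np.corrcoef(test)
    pos = {g: i for i, g in enumerate(common)}
    n_universe = len(common)
    rng = np.random.default_rng(seed)

    obs_rows, z_rows, mean_rows, sd_rows = {}, {}, {}, {}
    for m in partition.module_ids:
        genes = [g for g in partition.genes(m) if g in pos]
        if len(genes) < 3:
            warnings.warn(f"module {m} has fewer than 3 genes; skipped")
            continue
        idx = np.array([pos[g] for g in genes])
        obs = _module_stat_vector(ref_corr, test_corr, ref, test, idx, beta)
        null = np.empty((n_perm, len(ALL_STATS)))
        for b in range(n_perm):
            ridx = rng.choice(n_universe, size=len(idx), replace=False)
            vec = _module_stat_vector(ref_corr, test_corr, ref, test, ridx, beta)
            null[b] = [vec[s] for s in ALL_STATS]
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        z = {}
        for j, s in enumerate(ALL_STATS):
            if sd[j] == 0:
                warnings.warn(
                    f"zero permutation sd for {s} in module {m}; Z set to inf"
                )
                z[s] = float(np.sign(obs[s] - mu[j]) * np.inf)
            else:
                z[s] = float((obs[s] - mu[j]) / sd[j])
        obs_rows[m] = obs
        z_rows[m] = z
        mean_rows[m] = dict(zip(ALL_STATS, mu))
        sd_rows[m] = dict(zip(ALL_STATS, sd))

    observed = pd.DataFrame(obs_rows).T.loc[:, list(ALL_STATS)]
    zscores = pd.DataFrame(z_rows).T.loc[:, list(ALL_STATS)]
    perm_mean = pd.DataFrame(mean_rows).T.loc[:, list(ALL_STATS)]
    perm_sd = pd.DataFrame(sd_rows).T.loc[:, list(ALL_STATS)]
    stats_obj = PreservationStats(
        observed=observed,
        zscores=zscores,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        summary=pd.DataFrame(),
        n_perm=n_perm,
    )
    sizes = {m: len(partition.genes(m)) for m in observed.index}
    stats_obj.summary = summarize_preservation(zscores, observed, sizes)
    return stats_obj


def summarize_preservation(
    zscores: pd.DataFrame,
    observed: pd.DataFrame,
    sizes: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Composite preservation scores.

    Zsummary = mean(median density Z, median connectivity Z); medianRank =
    median across statistics of the module's cross-module rank, where rank
    1 is the most preserved module for that statistic (average ranks on
    ties), so the least preserved module has the highest medianRank and
    the lowest Zsummary.
    """
    if len(observed) < 1:
        raise ValueError("at least one module with defined stats required")
    if len(observed) == 1:
        warnings.warn("single module: medianRank degenerates to 1")

    finite_z = zscores.replace([np.inf, -np.inf], np.nan)
    z_density = finite_z[list(DENSITY_STATS)].median(axis=1, skipna=True)
    z_conn = finite_z[list(CONNECTIVITY_STATS)].median(axis=1, skipna=True)
    z_summary = (z_density + z_conn) / 2.0

    # rank 1 = most preserved (largest observed statistic value)
    ranks = observed.rank(axis=0, ascending=False, method="average")
    median_rank = ranks.median(axis=1)

    out = pd.DataFrame(
        {
            "Zdensity": z_density,
            "Zconnectivity": z_conn,
            "Zsummary": z_summary,
            "medianRank": median_rank,
        }
    )
    if sizes is not None:
        out.insert(0, "size", pd.Series(sizes))
    out.index.name = "module"
    return out


def module_kme_correlation(
    kme_ref: pd.DataFrame, kme_test: pd.DataFrame, module: int
) -> tuple[float, float, int]:
    """Correlation of the module's own-module kME between reference and
    test data: returns ``(r, p, n)`` with a standard correlation t-test p."""
    common = kme_ref.index.intersection(kme_test.index)
    x = kme_ref.loc[common, module].to_numpy(dtype=float)
    y = kme_test.loc[common, module].to_numpy(dtype=float)
    if len(common) < 3:
        raise ValueError("fewer than 3 module genes shared between datasets")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(len(common))


@dataclass
class SelectionRationale:
    agreement: bool
    by_median_rank: int
    by_zsummary: int
    candidates: list[int] = field(default_factory=list)
    kme_correlations: dict[int, float] = field(default_factory=dict)
    selected: int = -1


def select_least_preserved(
    stats: PreservationStats,
    kme_ref: pd.DataFrame | None = None,
    kme_test: pd.DataFrame | None = None,
) -> tuple[int, SelectionRationale]:
    """The least preserved module under the two-criterion rule.

    If the module with the highest medianRank is also the one with the
    lowest Zsummary, it is returned directly.  Otherwise the union of the
    three least preserved modules by each criterion forms the candidate
    pool, and the candidate whose reference-vs-test kME correlation is
    closest to zero is selected (requires ``kme_ref``/``kme_test``).
    """
    summary = stats.summary
    by_mr = int(summary["medianRank"].idxmax())
    by_z = int(summary["Zsummary"].idxmin())
    rationale = SelectionRationale(
        agreement=(by_mr == by_z), by_median_rank=by_mr, by_zsummary=by_z
    )
    if by_mr == by_z:
        rationale.selected = by_mr
        return by_mr, rationale

    worst_mr = list(summary["medianRank"].sort_values(ascending=False).index[:3])
    worst_z = list(summary["Zsummary"].sort_values(ascending=True).index[:3])
    candidates = sorted({int(m) for m in worst_mr + worst_z})
    rationale.candidates = candidates
    if kme_ref is None or kme_test is None:
        raise ValueError(
            "medianRank and Zsummary disagree; kME matrices required for tie-break"
        )
    for m in candidates:
        r, _, _ = module_kme_correlation(kme_ref, kme_test, m)
        rationale.kme_correlations[m] = r
    selected = min(candidates, key=lambda m: abs(rationale.kme_correlations[m]))
    rationale.selected = int(selected)
    return int(selected), rationale
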