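"""Gene-set enrichment: hypergeometric over-representation analysis,
randomization (sampling) enrichment, GWAS-style gene filtering and
cross-list direction concordance."""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import adjust_bh

__all__ = [
    "harmonize_ids",
    "ora",
    "mset",
    "gwas_gene_filter",
    "cross_study_concordance",
]

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def harmonize_ids(genes) -> set[str]:
    """Case-folded gene ids with trailing version suffixes (".N") stripped."""
    return {_VERSION_SUFFIX.sub("", str(g)).casefold() for g in genes}


def ora(
    query,
    sets: dict[str, list[str] | set[str]],
    background,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation analysis with hypergeometric upper-tail p-values.

    For each named set, ``p = P(X >= k)`` with universe N = |background|,
    K = |set ∩ background|, draw n = |query|, overlap k; BH-adjusted
    across sets.  Query genes outside the background are dropped with a
    warning; empty sets are dropped with a warning.

    Returns a DataFrame sorted by p with columns ``set, set_size, overlap,
    expected, fold_enrichment, p, fdr, enriched, genes``.
    """
    bg = harmonize_ids(background)
    q = harmonize_ids(query)
    if not q:
        raise ValueError("empty query gene list")
    outside = q - bg
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the background; dropped")
        q = q & bg
        if not q:
            raise ValueError("no query genes left inside the background")

    N, n = len(bg), len(q)
    rows = []
    for name, members in sets.items():
        s = harmonize_ids(members) & bg
        if not s:
            warnings.warn(f"gene set {name!r} empty after harmonization; dropped")
            continue
        K = len(s)
        overlap = q & s
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        expected = n * K / N
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": k,
                "expected": expected,
                "fold_enrichment": (k / expected) if expected > 0 else np.nan,
                "p": min(p, 1.0),
                "genes": ",".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = adjust_bh(out["p"].to_numpy())
        out["enriched"] = out["fdr"] <= fdr_threshold
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
        out = out[
            ["set", "set_size", "overlap", "expected", "fold_enrichment",
             "p", "fdr", "enriched", "genes"]
        ]
    return out


def mset(
    query,
    gene_set,
    background,
    n_iter: int = 10000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Randomization enrichment: empirical p of the query/set overlap
    against uniform same-size draws (without replacement) from the
    background.

    ``p = (1 + #{draws with overlap >= observed}) / (n_iter + 1)`` so the
    p-value is always positive.  Returns ``(p, null_overlaps)``;
    deterministic given ``seed``.
    """
    if n_iter < 100:
        warnings.warn("fewer than 100 iterations; empirical p will be coarse")
    bg = sorted(harmonize_ids(background))
    q = harmonize_ids(query) & set(bg)
    s = harmonize_ids(gene_set) & set(bg)
    if len(q) > len(bg):
        raise ValueError("query larger than background")
    if not q:
        raise ValueError("empty query after harmonization")
    observed = len(q & s)
    in_set = np.array([g in s for g in bg])
    rng = np.random.default_rng(seed)
    n_bg, n_q = len(bg), len(q)
    null = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        draw = rng.choice(n_bg, size=n_q, replace=False)
        null[i] = int(in_set[draw].sum())
    p = (1.0 + float((null >= observed).sum())) / (n_iter + 1.0)
    return min(p, 1.0), null


def gwas_gene_filter(table: pd.DataFrame, p_threshold: float = 1e-5) -> set[str]:
    """Genes from an association table with p strictly below the threshold.

    ``table`` needs columns ``gene`` and ``p``; malformed rows (missing or
    non-numeric p) are skipped with a logged count; duplicates collapse.
    """
    if not {"gene", "p"} <= set(table.columns):
        raise ValueError("association table needs 'gene' and 'p' columns")
    p = pd.to_numeric(table["p"], errors="coerce")
    bad = p.isna().sum()
    if bad:
        warnings.warn(f"skipped {bad} malformed row(s) in association table")
    keep = table.loc[p < p_threshold, "gene"]
    return set(keep.astype(str))


def cross_study_concordance(
    lfc_a: pd.Series, lfc_b: pd.Series
) -> tuple[int, int, float, list[str], list[str]]:
    """Direction concordance of two log2-fold-change maps.

    Returns ``(n_shared, n_same_direction, fraction, inverted, zeros)``
    over the shared genes; genes with a zero log2fc in either list count
    as neither concordant nor inverted and are reported separately.
    """
    common = lfc_a.index.intersection(lfc_b.index)
    if len(common) == 0:
        raise ValueError("no shared genes")
    a = lfc_a.loc[common].astype(float)
    b = lfc_b.loc[common].astype(float)
    prod = np.sign(a) * np.sign(b)
    same = list(common[prod > 0])
    inverted = list(common[prod < 0])
    zeros = list(common[prod == 0])
    nonzero = len(same) + len(inverted)
    fraction = len(same) / nonzero if nonzero else float("nan")
    return len(common), len(same), fraction, inverted, zeros
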