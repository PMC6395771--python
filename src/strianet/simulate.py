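"""Synthetic case/control RNA-seq count data with planted structure.

The generator emulates a small bulk brain-tissue case-control design:
negative-binomial gene counts whose log-means carry latent-factor
coexpression modules, planted differentially expressed genes, a laboratory
batch covariate, and log-uniform library sizes.  One designated module can
be "disrupted" in cases — its correlation structure is destroyed while the
marginal means stay unchanged — mimicking a coexpression module that loses
its network properties in the disease group.

All expression effects are combined on the natural-log scale and
exponentiated to obtain the NB mean; user-facing effect sizes
(``deg_log2fc``, ``batch_effect_sd``) are in log2 units and converted
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "simulate_dataset",
    "simulate_gene_sets",
]

_LN2 = float(np.log(2.0))


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic study.

    Defaults mirror a small postmortem case-control comparison
    (6 cases vs 8 controls per region); recovery-oriented analyses use
    larger groups for stability (see the bundled configuration presets).

    Parameters
    ----------
    n_genes : total number of genes.
    n_case, n_control : samples per group.
    module_sizes : sizes of planted coexpression modules (genes are
        assigned to modules in order; the remainder is background).
    module_loadings : per-module latent-factor loading in [0, 1); a
        single float is broadcast to all modules.
    disrupted_module : index into ``module_sizes`` of the module whose
        correlation structure is destroyed in cases, or ``None``.
    disruption_mode : ``"break_correlation"`` replaces the shared factor
        with i.i.d. per-gene factors in case samples (variance preserved,
        co-variation destroyed); ``"attenuate"`` halves the loading.
    n_deg : number of planted differentially expressed genes (half up,
        half down in cases), sampled outside the disrupted module.
    deg_log2fc : absolute planted effect size, log2 units.
    dispersion : NB dispersion alpha >= 0 (var = mu + alpha * mu^2).
    base_mean_log_range : interval for the natural-log baseline mean
        count at the reference library size.
    batch_levels : number of laboratory batches (round-robin over
        samples); per-gene batch coefficients are N(0, batch_effect_sd)
        in log2 units.
    library_size_range : interval of total read counts per sample;
        sizes are drawn log-uniformly.
    seed : RNG seed; the whole simulation is deterministic given it.
    """

    n_genes: int = 2000
    n_case: int = 6
    n_control: int = 8
    module_sizes: list[int] = field(default_factory=lambda: [100, 150, 200])
    module_loadings: float | list[float] = 0.8
    disrupted_module: int | None = 1
    disruption_mode: str = "break_correlation"
    n_deg: int = 50
    deg_log2fc: float = 2.0
    dispersion: float = 0.05
    base_mean_log_range: tuple[float, float] = (3.0, 7.5)
    batch_levels: int = 2
    batch_effect_sd: float = 0.0
    library_size_range: tuple[float, float] = (5e6, 15e6)
    region: str = "CN"
    seed: int = 0

    def loadings(self) -> np.ndarray:
        if np.isscalar(self.module_loadings):
            return np.full(len(self.module_sizes), float(self.module_loadings))
        return np.asarray(self.module_loadings, dtype=float)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("n_case and n_control must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module_sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        lo = self.loadings()
        if len(lo) != len(self.module_sizes):
            raise ValueError("module_loadings length mismatch with module_sizes")
        if np.any((lo < 0) | (lo >= 1)):
            raise ValueError("module_loadings must lie in [0, 1)")
        if self.disrupted_module is not None and not (
            0 <= self.disrupted_module < len(self.module_sizes)
        ):
            raise ValueError("disrupted_module out of range")
        if self.disruption_mode not in ("break_correlation", "attenuate"):
            raise ValueError("disruption_mode must be break_correlation or attenuate")
        if self.n_deg < 0:
            raise ValueError("n_deg must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.batch_levels < 1:
            raise ValueError("batch_levels must be >= 1")
        if self.library_size_range[0] <= 0 or (
            self.library_size_range[1] < self.library_size_range[0]
        ):
            raise ValueError("library_size_range must be a positive interval")
        if self.base_mean_log_range[1] < self.base_mean_log_range[0]:
            raise ValueError("base_mean_log_range must be an interval")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``module_membership`` maps gene id -> module index (-1 = background);
    ``deg_table`` has columns ``gene`` and ``true_log2fc``;
    ``batch`` and ``library_sizes`` are per-sample Series.
    """

    module_membership: pd.Series
    disrupted_module: int | None
    deg_table: pd.DataFrame
    batch: pd.Series
    library_sizes: pd.Series

    @property
    def deg_genes(self) -> list[str]:
        return list(self.deg_table["gene"])

    def module_genes(self, module: int) -> list[str]:
        return list(self.module_membership.index[self.module_membership == module])


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, alpha) with var = mu + alpha mu^2; alpha=0 degenerates to Poisson."""
    if alpha <= 0:
        return rng.poisson(mean)
    # gamma-Poisson mixture: shape 1/alpha, scale alpha*mu
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def simulate_dataset(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate case and control count matrices plus metadata and truth.

    Returns ``(counts_case, counts_control, metadata, truth)`` where the
    count matrices are genes x samples integer DataFrames sharing the gene
    index, and ``metadata`` covers the concatenated samples with columns
    ``group, sex, age, batch, region`` indexed by sample id.

    The NB log-mean of gene g in sample s is::

        baseline_g + a_m * f_{m,s} + deg_g * [s is case]
                   + b_{g, batch(s)} + ln(L_s / L_ref)

    with per-sample standard-normal module factors ``f_{m,s}``.  Under
    ``break_correlation`` the disrupted module's case samples receive
    independent per-gene factors, so co-variation is destroyed while
    marginal means and variances are untouched.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    g = design.n_genes
    n_case, n_ctrl = design.n_case, design.n_control
    n = n_case + n_ctrl
    gene_ids = np.array([f"G{i:05d}" for i in range(g)])
    sample_ids = [f"case_{i + 1:02d}" for i in range(n_case)] + [
        f"control_{i + 1:02d}" for i in range(n_ctrl)
    ]
    is_case = np.array([1] * n_case + [0] * n_ctrl, dtype=bool)

    # module membership: contiguous blocks, remainder background (-1)
    membership = np.full(g, -1, dtype=int)
    pos = 0
    for m, size in enumerate(design.module_sizes):
        membership[pos : pos + size] = m
        pos += size

    baseline = rng.uniform(*design.base_mean_log_range, size=g)

    # planted DEGs: outside the disrupted module so its marginal means stay
    # group-invariant; half up, half down
    eligible = np.arange(g)
    if design.disrupted_module is not None:
        eligible = eligible[membership != design.disrupted_module]
    if design.n_deg > len(eligible):
        raise ValueError("n_deg exceeds number of eligible genes")
    deg_idx = np.sort(rng.choice(eligible, size=design.n_deg, replace=False))
    signs = np.ones(design.n_deg)
    signs[1::2] = -1.0
    deg_effect = np.zeros(g)
    deg_effect[deg_idx] = signs * design.deg_log2fc * _LN2

    # batch assignment (round-robin) and per-gene batch coefficients
    batch = np.arange(n) % design.batch_levels
    batch_coef = rng.normal(
        0.0, design.batch_effect_sd * _LN2, size=(g, design.batch_levels)
    )

    # library sizes, log-uniform; reference = geometric mean of the range
    lo, hi = design.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    lib_ref = float(np.sqrt(lo * hi))

    loadings = design.loadings()
    factors = rng.standard_normal((len(design.module_sizes), n))

    log_mu = np.tile(baseline[:, None], (1, n))
    for m, a in enumerate(loadings):
        sel = membership == m
        eff_a = a
        if (
            design.disrupted_module == m
            and design.disruption_mode == "attenuate"
        ):
            contrib = np.empty((sel.sum(), n))
            contrib[:, ~is_case] = a * factors[m, ~is_case]
            contrib[:, is_case] = (a / 2.0) * factors[m, is_case]
            log_mu[sel] += contrib
            continue
        if (
            design.disrupted_module == m
            and design.disruption_mode == "break_correlation"
        ):
            contrib = np.empty((sel.sum(), n))
            contrib[:, ~is_case] = a * factors[m, ~is_case]
            # i.i.d. per-gene factors in cases: same marginal law, no sharing
            contrib[:, is_case] = a * rng.standard_normal((sel.sum(), is_case.sum()))
            log_mu[sel] += contrib
            continue
        log_mu[sel] += eff_a * factors[m]

    log_mu += deg_effect[:, None] * is_case[None, :]
    log_mu += batch_coef[:, batch]
    log_mu += np.log(lib / lib_ref)[None, :]

    counts = _nb_sample(rng, np.exp(log_mu), design.dispersion).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_case = counts_df.loc[:, is_case]
    counts_ctrl = counts_df.loc[:, ~is_case]

    # balanced sexes, shuffled so sex is not confounded with group or batch
    sex = rng.permutation(np.where(np.arange(n) % 2 == 0, "M", "F"))
    metadata = pd.DataFrame(
        {
            "group": np.where(is_case, "case", "control"),
            "sex": sex,
            "age": rng.integers(55, 90, size=n),
            "batch": [f"B{b + 1}" for b in batch],
            "region": design.region,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = SyntheticTruth(
        module_membership=pd.Series(membership, index=gene_ids, name="module"),
        disrupted_module=design.disrupted_module,
        deg_table=pd.DataFrame(
            {"gene": gene_ids[deg_idx], "true_log2fc": signs * design.deg_log2fc}
        ),
        batch=pd.Series([f"B{b + 1}" for b in batch], index=sample_ids, name="batch"),
        library_sizes=pd.Series(lib, index=sample_ids, name="library_size"),
    )
    return counts_case, counts_ctrl, metadata, truth


def simulate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int = 10,
    set_size: int = 100,
    enriched_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Build GMT-compatible gene sets; one set over-samples the planted DEGs.

    The first set (``enriched_set``) contains ``round(enriched_fraction *
    set_size)`` genes drawn from the DEG list (all of it if shorter) and the
    remainder from non-DEG genes; the other sets are uniform draws from the
    whole gene universe.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    universe = np.asarray(truth.module_membership.index)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    deg = np.asarray(truth.deg_genes)
    non_deg = universe[~np.isin(universe, deg)]

    n_from_deg = min(int(round(enriched_fraction * set_size)), len(deg))
    picked = list(rng.choice(deg, size=n_from_deg, replace=False)) + list(
        rng.choice(non_deg, size=set_size - n_from_deg, replace=False)
    )
    sets: dict[str, list[str]] = {"enriched_set": sorted(picked)}
    for i in range(1, n_sets):
        sets[f"random_set_{i:02d}"] = sorted(
            rng.choice(universe, size=set_size, replace=False)
        )
    return sets
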