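"""Correlation, soft threshold, adjacency, TOM, module detection, ME, kME."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strianet import network as net
from strianet import preprocess as pp
from strianet import simulate as sim


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference TOM implementation."""
    n = len(a)
    k = a.sum(axis=1) - 1.0
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_adjacency(rng, n=10):
    c = rng.uniform(0, 1, size=(n, n))
    a = (c + c.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestCorrelation:
    def test_self_correlation_unity(self, rng):
        expr = pd.DataFrame(rng.standard_normal((5, 10)))
        cor, _, _ = net.correlation_matrix(expr)
        assert np.allclose(np.diag(cor), 1.0)

    def test_high_missingness_removed(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 10)),
                            index=["ok1", "bad", "ok2"])
        expr.iloc[1, :6] = np.nan  # 60% missing
        cor, removed, _ = net.correlation_matrix(expr)
        assert removed == ["bad"]
        assert "bad" not in cor.index

    def test_anticorrelated_pair(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        cor, _, _ = net.correlation_matrix(expr)
        assert cor.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 8)), index=["a", "b", "c"])
        expr.loc["b"] = 5.0
        cor, _, flagged = net.correlation_matrix(expr)
        assert flagged == ["b"]
        assert cor.loc["b", "a"] == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            net.correlation_matrix(pd.DataFrame(np.ones((4, 2))))


class TestSoftThreshold:
    def test_heterogeneous_modules_reach_scale_free_fit(self):
        """Graded-loading modules produce a hub-dominated connectivity
        distribution with a satisfiable scale-free criterion."""
        d = sim.SyntheticDesign(
            n_genes=800, n_case=1, n_control=30,
            module_sizes=[400, 200, 100, 50],
            module_loadings=[0.95, 0.9, 0.85, 0.75],
            disrupted_module=None, n_deg=0, dispersion=0.1, seed=7,
        )
        _, ctrl, _, _ = sim.simulate_dataset(d)
        expr = pp.normalize_log(ctrl)
        beta, table = net.pick_soft_threshold(expr)
        row = table.set_index("beta").loc[beta]
        assert row["r2"] >= 0.8
        # chosen beta is the smallest satisfying one
        earlier = table[table["beta"] < beta]
        assert (earlier["r2"] < 0.8).all()

    def test_vacuous_criterion_picks_first_beta(self, rng):
        expr = pd.DataFrame(rng.standard_normal((60, 10)))
        beta, _ = net.pick_soft_threshold(expr, r2_min=0.0)
        assert beta == 1

    def test_degenerate_identical_genes_flagged(self):
        x = np.arange(10.0)
        expr = pd.DataFrame(np.tile(x, (60, 1)))
        expr += np.arange(60)[:, None]  # distinct but perfectly correlated
        _, table = net.pick_soft_threshold(expr, r2_min=0.0)
        assert table["degenerate"].all()


class TestAdjacency:
    def test_perfect_correlation_any_power(self):
        cor = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]])
        for b in (1, 5, 9):
            assert net.adjacency(cor, b).iloc[0, 1] == pytest.approx(1.0)

    def test_published_power_hand_value(self):
        cor = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        assert net.adjacency(cor, 9).iloc[0, 1] == pytest.approx(0.001953125)

    def test_identity_power(self, rng):
        c = rng.uniform(-1, 1, size=(5, 5))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        cor = pd.DataFrame(c)
        assert np.allclose(net.adjacency(cor, 1).to_numpy(), np.abs(c) + np.diag(1 - np.abs(np.diag(c))))

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            net.adjacency(pd.DataFrame([[1.0]]), 0.5)

    def test_monotone_in_beta_and_order_preserving(self, rng):
        c = rng.uniform(0.1, 0.9, size=(6, 6))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        cor = pd.DataFrame(c)
        a2 = net.adjacency(cor, 2).to_numpy()
        a5 = net.adjacency(cor, 5).to_numpy()
        off = ~np.eye(6, dtype=bool)
        assert (a5[off] <= a2[off]).all()
        order2 = np.argsort(a2[off])
        order5 = np.argsort(a5[off])
        assert (order2 == order5).all()


class TestTom:
    def test_empty_network(self):
        a = pd.DataFrame(np.eye(4))
        t = net.tom(a).to_numpy()
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(t[off], 0.0)

    def test_three_gene_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        t = net.tom(pd.DataFrame(a))
        assert t.iloc[0, 1] == pytest.approx(0.5)  # (0.25+0.5)/(1+1-0.5)

    def test_single_strong_edge(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.0
        t = net.tom(pd.DataFrame(a))
        assert t.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_adjacencies(self, rng):
        for _ in range(100):
            a = random_adjacency(rng, 10)
            t = net.tom(pd.DataFrame(a)).to_numpy()
            assert np.max(np.abs(t - brute_force_tom(a))) < 1e-12

    def test_range_contract(self, rng):
        for _ in range(20):
            a = random_adjacency(rng, 8)
            t = net.tom(pd.DataFrame(a)).to_numpy()
            assert (t >= -1e-12).all() and (t <= 1 + 1e-12).all()

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.7
        with pytest.raises(ValueError):
            net.tom(pd.DataFrame(a))


def _block_dissimilarity(sizes, rng, within=0.1, between=0.95):
    n = sum(sizes)
    d = np.full((n, n), between)
    pos = 0
    for s in sizes:
        d[pos:pos + s, pos:pos + s] = within
        pos += s
    d += rng.uniform(0, 0.01, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=[f"g{i}" for i in range(n)],
                        columns=[f"g{i}" for i in range(n)])


class TestDetectModules:
    def test_planted_blocks_recovered(self, rng):
        diss = _block_dissimilarity([100, 100], rng)
        part = net.detect_modules(diss, min_size=50)
        assert len(part.module_ids) == 2
        labels = part.labels.to_numpy()
        assert len(set(labels[:100])) == 1 and len(set(labels[100:])) == 1
        assert labels[0] != labels[150]

    def test_min_size_above_n_all_unassigned(self, rng):
        diss = _block_dissimilarity([20], rng)
        with pytest.warns(UserWarning):
            part = net.detect_modules(diss, min_size=50)
        assert (part.labels == 0).all()

    def test_identical_rows_single_module(self):
        n = 30
        diss = pd.DataFrame(np.zeros((n, n)))
        part = net.detect_modules(diss, min_size=10)
        assert len(part.module_ids) == 1
        assert (part.labels == 1).all()

    def test_permutation_equivariance(self, rng):
        diss = _block_dissimilarity([40, 60], rng)
        part = net.detect_modules(diss, min_size=20)
        perm = rng.permutation(len(diss))
        shuffled = diss.iloc[perm, perm]
        part2 = net.detect_modules(shuffled, min_size=20)
        aligned = part2.labels.loc[part.labels.index]
        # same partition up to label names
        df = pd.DataFrame({"a": part.labels, "b": aligned})
        assert df.groupby("a")["b"].nunique().max() == 1
        assert df.groupby("b")["a"].nunique().max() == 1


class TestEigengenes:
    def test_rank_one_module(self):
        profile = np.sin(np.linspace(0, 3, 12))
        expr = pd.DataFrame([profile * s for s in (1.0, 2.0, 3.0)],
                            index=["a", "b", "c"])
        me, ve = net.module_eigengene(expr, expr.index)
        assert ve == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(me, z)[0, 1]) == pytest.approx(1.0)

    def test_orientation_contract_with_anticorrelated_genes(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        me, _ = net.module_eigengene(expr, expr.index)
        kmes = [np.corrcoef(expr.loc[g], me)[0, 1] for g in ("a", "b")]
        assert np.mean(kmes) >= 0

    def test_planted_factor_recovered(self, small_dataset, small_expression):
        truth = small_dataset["truth"]
        expr = small_expression["expr_control"]
        genes = truth.module_genes(0)
        me, _ = net.module_eigengene(expr, pd.Index(genes))
        # eigengene tracks the shared factor: very high average |kME|
        sub = expr.loc[genes].to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        mez = (me - me.mean()) / me.std()
        assert np.abs((z @ mez) / sub.shape[1]).mean() > 0.9

    def test_constant_module_rejected(self):
        expr = pd.DataFrame(np.ones((3, 8)), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            net.module_eigengene(expr, expr.index)


class TestKme:
    def test_gene_equal_to_eigengene(self, rng):
        base = rng.standard_normal(20)
        expr = pd.DataFrame([base, base + rng.normal(0, 0.01, 20)],
                            index=["a", "b"])
        part = net.ModulePartition(
            labels=pd.Series([1, 1], index=["a", "b"]), min_size=1)
        mes = net.module_eigengenes(expr, part)
        k = net.kme(expr, mes)
        assert abs(k.loc["a", 1]) > 0.999

    def test_noise_gene_low_kme(self, rng):
        n = 200
        shared = rng.standard_normal(n)
        module = [shared + rng.normal(0, 0.3, n) for _ in range(10)]
        noise = rng.standard_normal(n)
        expr = pd.DataFrame(module + [noise],
                            index=[f"m{i}" for i in range(10)] + ["noise"])
        part = net.ModulePartition(
            labels=pd.Series([1] * 10 + [0], index=expr.index), min_size=2)
        mes = net.module_eigengenes(expr, part)
        k = net.kme(expr, mes)
        assert abs(k.loc["noise", 1]) < 0.2
        assert (k.to_numpy() >= -1).all() and (k.to_numpy() <= 1).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_tom_brute_force_property(seed):
    """TOM equals the triple-loop oracle on arbitrary random adjacencies."""
    rng = np.random.default_rng(seed)
    a = random_adjacency(rng, rng.integers(3, 12))
    t = net.tom(pd.DataFrame(a)).to_numpy()
    assert np.max(np.abs(t - brute_force_tom(a))) < 1e-12
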