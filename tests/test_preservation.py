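"""Module preservation: mapping, observed stats, permutation Z, selection."""

import numpy as np
import pandas as pd
import pytest

from strianet import network as net
from strianet import preprocess as pp
from strianet import preservation as pres
from strianet import simulate as sim
from strianet.preservation import (
    ALL_STATS,
    CONNECTIVITY_STATS,
    DENSITY_STATS,
    PreservationStats,
)


def _partition(labels, index):
    return net.ModulePartition(
        labels=pd.Series(labels, index=index, name="module"), min_size=1
    )


class TestMapping:
    def test_identity_mapping(self, small_expression, small_dataset):
        truth = small_dataset["truth"]
        expr = small_expression["expr_control"]
        part = _partition(
            (truth.module_membership + 1).clip(lower=0).to_numpy(),
            truth.module_membership.index,
        )
        mapped, dropped = pres.map_reference_modules(part, expr)
        assert dropped == []
        pd.testing.assert_series_equal(mapped.labels, part.labels)

    def test_missing_genes_dropped_and_reported(self, rng):
        idx = [f"g{i}" for i in range(20)]
        part = _partition([1] * 10 + [2] * 10, idx)
        test_expr = pd.DataFrame(rng.standard_normal((10, 6)), index=idx[:10])
        mapped, dropped = pres.map_reference_modules(part, test_expr)
        assert sorted(dropped) == sorted(idx[10:])
        assert len(mapped.labels) == 10

    def test_disjoint_universes_rejected(self, rng):
        part = _partition([1, 1], ["a", "b"])
        test_expr = pd.DataFrame(rng.standard_normal((2, 5)), index=["x", "y"])
        with pytest.raises(ValueError):
            pres.map_reference_modules(part, test_expr)


class TestObservedStats:
    def test_self_comparison_perfect_connectivity(self, small_expression,
                                                  small_dataset):
        truth = small_dataset["truth"]
        expr = small_expression["expr_control"]
        membership = truth.module_membership
        part = _partition((membership + 1).clip(lower=0).to_numpy(),
                          membership.index)
        obs = pres.observed_stats(expr, expr, part, beta=6)
        for stat in CONNECTIVITY_STATS:
            assert np.allclose(obs[stat], 1.0)

    def test_disrupted_module_loses_density(self, small_expression,
                                            small_dataset):
        truth = small_dataset["truth"]
        part = _partition(
            (truth.module_membership + 1).clip(lower=0).to_numpy(),
            truth.module_membership.index,
        )
        obs_ref = pres.observed_stats(
            small_expression["expr_control"], small_expression["expr_control"],
            part, beta=6)
        obs_test = pres.observed_stats(
            small_expression["expr_control"], small_expression["expr_case"],
            part, beta=6)
        disrupted = truth.disrupted_module + 1
        assert obs_ref.loc[disrupted, "meanCor"] >= 0.4
        assert obs_test.loc[disrupted, "meanCor"] <= 0.1

    def test_tiny_module_flagged_undefined(self, rng):
        idx = [f"g{i}" for i in range(10)]
        expr = pd.DataFrame(rng.standard_normal((10, 8)), index=idx)
        part = _partition([1] * 8 + [2] * 2, idx)
        with pytest.warns(UserWarning, match="fewer than 3"):
            obs = pres.observed_stats(expr, expr, part, beta=2)
        assert 2 not in obs.index


class TestPermutationNull:
    def test_seeded_determinism(self, rng):
        idx = [f"g{i}" for i in range(60)]
        ref = pd.DataFrame(rng.standard_normal((60, 12)), index=idx)
        test = pd.DataFrame(rng.standard_normal((60, 12)), index=idx)
        part = _partition([1] * 20 + [2] * 20 + [0] * 20, idx)
        a = pres.permutation_null(ref, test, part, beta=2, n_perm=25, seed=3)
        b = pres.permutation_null(ref, test, part, beta=2, n_perm=25, seed=3)
        pd.testing.assert_frame_equal(a.zscores, b.zscores)

    def test_noise_module_z_near_zero(self, rng):
        idx = [f"g{i}" for i in range(200)]
        ref = pd.DataFrame(rng.standard_normal((200, 20)), index=idx)
        test = pd.DataFrame(rng.standard_normal((200, 20)), index=idx)
        part = _partition([1] * 50 + [2] * 50 + [0] * 100, idx)
        stats = pres.permutation_null(ref, test, part, beta=2, n_perm=50, seed=1)
        assert np.abs(stats.summary["Zsummary"]).max() <= 2.5

    def test_minimum_permutations_enforced(self, rng):
        idx = [f"g{i}" for i in range(20)]
        ref = pd.DataFrame(rng.standard_normal((20, 8)), index=idx)
        part = _partition([1] * 20, idx)
        with pytest.raises(ValueError):
            pres.permutation_null(ref, ref, part, beta=2, n_perm=5)

    def test_preserved_module_exceeds_scale(self, small_expression,
                                            small_dataset):
        """Intact planted module scores above the well-preserved bound (10);
        the disrupted one falls below the weak-preservation bound (2)."""
        truth = small_dataset["truth"]
        part = _partition(
            (truth.module_membership + 1).clip(lower=0).to_numpy(),
            truth.module_membership.index,
        )
        stats = pres.permutation_null(
            small_expression["expr_control"], small_expression["expr_case"],
            part, beta=6, n_perm=50, seed=2,
        )
        intact = 0 + 1
        disrupted = truth.disrupted_module + 1
        assert stats.summary.loc[intact, "Zsummary"] > 10
        assert stats.summary.loc[disrupted, "Zsummary"] < 2


class TestSummaries:
    def _stats_from_observed(self, observed):
        z = observed.copy() * 0.0
        return observed, z

    def test_median_rank_matches_hand_ranking(self):
        observed = pd.DataFrame(
            {s: [3.0, 2.0, 1.0] for s in ALL_STATS}, index=[1, 2, 3]
        )
        # module 1 best on every stat -> rank 1; module 3 worst -> rank 3
        summary = pres.summarize_preservation(observed * 0.0 + 1.0, observed)
        assert summary["medianRank"].tolist() == [1.0, 2.0, 3.0]

    def test_tied_stats_share_ranks(self):
        observed = pd.DataFrame({s: [1.0, 1.0] for s in ALL_STATS}, index=[1, 2])
        summary = pres.summarize_preservation(observed * 0.0, observed)
        assert summary["medianRank"].tolist() == [1.5, 1.5]

    def test_constant_z_passthrough(self):
        z = pd.DataFrame({s: [5.0, 0.0] for s in ALL_STATS}, index=[1, 2])
        obs = z.copy()
        summary = pres.summarize_preservation(z, obs)
        assert summary.loc[1, "Zsummary"] == 5.0

    def test_median_rank_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(4)
        observed = pd.DataFrame(
            rng.standard_normal((4, len(ALL_STATS))), columns=ALL_STATS,
            index=[1, 2, 3, 4],
        )
        z = observed * 0.0
        base = pres.summarize_preservation(z, observed)["medianRank"]
        rescaled = observed.copy()
        rescaled["meanCor"] = np.exp(rescaled["meanCor"] * 3)  # monotone map
        after = pres.summarize_preservation(z, rescaled)["medianRank"]
        pd.testing.assert_series_equal(base, after)

    def test_single_module_warns(self):
        observed = pd.DataFrame({s: [1.0] for s in ALL_STATS}, index=[1])
        with pytest.warns(UserWarning):
            summary = pres.summarize_preservation(observed * 0.0, observed)
        assert summary["medianRank"].iloc[0] == 1.0


class TestKmeCorrelation:
    def _kme(self, values, index):
        return pd.DataFrame({1: values}, index=index)

    def test_identical_kme(self, rng):
        v = rng.uniform(-1, 1, 30)
        idx = [f"g{i}" for i in range(30)]
        r, p, n = pres.module_kme_correlation(self._kme(v, idx),
                                              self._kme(v, idx), 1)
        assert r == pytest.approx(1.0)
        assert n == 30

    def test_sign_flip(self, rng):
        v = rng.uniform(-1, 1, 30)
        idx = [f"g{i}" for i in range(30)]
        r, _, _ = pres.module_kme_correlation(self._kme(v, idx),
                                              self._kme(-v, idx), 1)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        idx = [f"g{i}" for i in range(500)]
        r, _, _ = pres.module_kme_correlation(
            self._kme(rng.uniform(-1, 1, 500), idx),
            self._kme(rng.uniform(-1, 1, 500), idx), 1)
        assert abs(r) < 0.15

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            pres.module_kme_correlation(self._kme([0.1, 0.2], ["a", "b"]),
                                        self._kme([0.1, 0.2], ["a", "b"]), 1)


class TestSelection:
    def _stats(self, zsummary, median_rank):
        modules = list(zsummary)
        summary = pd.DataFrame(
            {"Zsummary": pd.Series(zsummary), "medianRank": pd.Series(median_rank)},
            index=modules,
        )
        empty = pd.DataFrame(index=modules, columns=list(ALL_STATS), dtype=float)
        return PreservationStats(observed=empty, zscores=empty, perm_mean=empty,
                                 perm_sd=empty, summary=summary, n_perm=100)

    def test_agreement_short_circuits(self):
        stats = self._stats({1: 12.0, 2: -3.0, 3: 8.0}, {1: 1.0, 2: 3.0, 3: 2.0})
        selected, rationale = pres.select_least_preserved(stats)
        assert selected == 2
        assert rationale.agreement and rationale.candidates == []

    def test_disagreement_uses_most_neutral_kme(self, rng):
        stats = self._stats(
            {1: 5.0, 2: -1.0, 3: 2.0, 4: 9.0},
            {1: 4.0, 2: 2.0, 3: 3.0, 4: 1.0},
        )
        # candidates: union of 3 worst by each criterion = {1,2,3}
        idx = [f"g{i}" for i in range(30)]
        target = {1: 0.90, 2: 0.50, 3: -0.05}
        base = rng.uniform(-1, 1, 30)
        kme_ref = pd.DataFrame({m: base for m in (1, 2, 3, 4)}, index=idx)
        cols = {}
        for m in (1, 2, 3, 4):
            r = target.get(m, 0.9)
            noise = rng.standard_normal(30)
            noise -= np.polyval(np.polyfit(base, noise, 1), base)  # orthogonalize
            y = r * (base - base.mean()) / base.std() + np.sqrt(1 - r**2) * (
                noise / noise.std()
            )
            cols[m] = y
        kme_test = pd.DataFrame(cols, index=idx)
        selected, rationale = pres.select_least_preserved(stats, kme_ref, kme_test)
        assert not rationale.agreement
        assert selected == 3
        assert abs(rationale.kme_correlations[3]) == min(
            abs(v) for v in rationale.kme_correlations.values()
        )

    def test_disagreement_without_kme_rejected(self):
        stats = self._stats({1: 5.0, 2: -1.0}, {1: 2.0, 2: 1.0})
        with pytest.raises(ValueError):
            pres.select_least_preserved(stats)


class TestEndToEndRecovery:
    def test_disrupted_module_selected(self):
        """Full chain at the recovery design: detection on controls,
        preservation against cases, selection returns the module holding
        the planted disrupted block (which must be its dominant content)."""
        d = sim.SyntheticDesign(
            n_genes=2000, n_case=20, n_control=20, module_sizes=[100, 150, 200],
            module_loadings=0.8, disrupted_module=1, n_deg=50, deg_log2fc=2.0,
            dispersion=0.05, seed=1000,
        )
        case, ctrl, meta, truth = sim.simulate_dataset(d)
        expr = pp.normalize_log(pd.concat([case, ctrl], axis=1))
        ec = expr[ctrl.columns]
        ea = expr[case.columns]
        cor, _, _ = net.correlation_matrix(ec)
        t = net.tom(net.adjacency(cor, 6))
        part = net.detect_modules(1.0 - t, min_size=30)
        assert len(part.module_ids) >= 2
        mapped, _ = pres.map_reference_modules(part, ea)
        stats = pres.permutation_null(ec, ea, mapped, beta=6, n_perm=100, seed=5)
        kme_ref = net.kme(ec, net.module_eigengenes(ec, mapped))
        kme_test = net.kme(ea, net.module_eigengenes(ea, mapped))
        selected, _ = pres.select_least_preserved(stats, kme_ref, kme_test)
        disrupted_genes = set(truth.module_genes(truth.disrupted_module))
        selected_genes = set(mapped.genes(selected))
        # the selected module is the one carrying the disrupted block
        carrier = max(
            part.module_ids,
            key=lambda m: len(disrupted_genes & set(part.genes(m))),
        )
        assert selected == carrier
        assert len(disrupted_genes & selected_genes) >= 0.5 * len(disrupted_genes)

    def test_self_preservation_beats_disruption(self, small_dataset,
                                                small_expression):
        """test=reference yields higher Zsummary than the disrupted case
        data for the disrupted module."""
        truth = small_dataset["truth"]
        ec = small_expression["expr_control"]
        ea = small_expression["expr_case"]
        part = _partition(
            (truth.module_membership + 1).clip(lower=0).to_numpy(),
            truth.module_membership.index,
        )
        self_stats = pres.permutation_null(ec, ec, part, beta=6, n_perm=40, seed=8)
        cross_stats = pres.permutation_null(ec, ea, part, beta=6, n_perm=40, seed=8)
        m = truth.disrupted_module + 1
        assert (self_stats.summary.loc[m, "Zsummary"]
                >= cross_stats.summary.loc[m, "Zsummary"])
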