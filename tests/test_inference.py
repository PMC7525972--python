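import numpy as np
import pandas as pd
import pytest

from glvnet import (
    CoefficientEnsemble,
    FitConfig,
    assemble_series,
    consensus_network,
    enumerate_assemblies,
    fit_glv_series,
    generate_interaction_matrix,
    infer_ensemble,
    simulate_glv_series,
    support_threshold_count,
)
from glvnet.inference import EnsembleSizeError


class TestEnumerateAssemblies:
    def test_two_replicates_three_timepoints(self):
        asm = enumerate_assemblies(2, 3, mode="full")
        assert asm.shape == (8, 3)
        rows = {tuple(r) for r in asm.tolist()}
        assert rows == {
            (1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2),
            (2, 1, 1), (2, 1, 2), (2, 2, 1), (2, 2, 2),
        }

    def test_lexicographic_order(self):
        asm = enumerate_assemblies(2, 2, mode="full")
        assert asm.tolist() == [[1, 1], [1, 2], [2, 1], [2, 2]]

    def test_single_replicate(self):
        asm = enumerate_assemblies(1, 7, mode="full")
        assert asm.shape == (1, 7)
        assert (asm == 1).all()

    def test_ceiling_enforced(self):
        with pytest.raises(EnsembleSizeError, match="subsample"):
            enumerate_assemblies(3, 12, mode="full")

    def test_subsample_distinct_and_seeded(self):
        a1 = enumerate_assemblies(3, 8, mode="subsample", n_subsample=100, seed=5)
        a2 = enumerate_assemblies(3, 8, mode="subsample", n_subsample=100, seed=5)
        np.testing.assert_array_equal(a1, a2)
        assert len({tuple(r) for r in a1.tolist()}) == 100
        assert a1.min() >= 1 and a1.max() <= 3

    def test_subsample_cannot_exceed_total(self):
        with pytest.raises(ValueError, match="distinct"):
            enumerate_assemblies(2, 2, mode="subsample", n_subsample=5, seed=0)


class TestAssembleSeries:
    def test_constant_assembly_reproduces_one_mouse(self, two_group_study):
        table, _ = two_group_study
        series, days = assemble_series(table, "sham", [2] * 6)
        sub = table.subset("sham")
        rel = sub.counts.div(sub.counts.sum(axis=1), axis=0)
        for k, day in enumerate(days):
            mask = (sub.metadata["replicate"] == 2) & (sub.metadata["day"] == day)
            np.testing.assert_allclose(series[:, k], rel.loc[mask].to_numpy()[0])

    def test_columns_sum_to_one(self, two_group_study):
        table, _ = two_group_study
        series, _ = assemble_series(table, "sni", [1, 2, 3, 1, 2, 3])
        np.testing.assert_allclose(series.sum(axis=0), 1.0, atol=1e-12)

    def test_single_point_difference(self, two_group_study):
        table, _ = two_group_study
        s1, _ = assemble_series(table, "sham", [1, 1, 1, 1, 1, 1])
        s2, _ = assemble_series(table, "sham", [1, 1, 1, 2, 1, 1])
        diff_cols = np.where(np.any(s1 != s2, axis=0))[0]
        np.testing.assert_array_equal(diff_cols, [3])

    def test_unknown_replicate_rejected(self, two_group_study):
        table, _ = two_group_study
        with pytest.raises(ValueError, match="replicate"):
            assemble_series(table, "sham", [9] * 6)

    def test_unknown_group_rejected(self, two_group_study):
        table, _ = two_group_study
        with pytest.raises(KeyError, match="nope"):
            assemble_series(table, "nope", [1] * 6)


class TestFitGlvSeries:
    def test_noiseless_recovery_ols(self):
        """Simulator is the oracle: exact recovery when fully identified."""
        p = generate_interaction_matrix(3, density=1.0, seed=1, max_self_rate=0.5)
        grid = np.linspace(0.0, 5.5, 12)
        series = simulate_glv_series(p, [0.8, 1.1, 0.9], grid, noise_sd=0.0)
        b, a = fit_glv_series(series, grid, FitConfig(regression="ols"))
        assert np.abs(b - p.growth).max() < 1e-6
        assert np.abs(a - p.interactions).max() < 1e-6

    def test_constant_series_gives_zero_coefficients(self):
        series = np.full((2, 5), 0.5)
        b, a = fit_glv_series(series, np.arange(5.0), FitConfig(regression="ols"))
        np.testing.assert_allclose(b, 0.0, atol=1e-12)
        np.testing.assert_allclose(a, 0.0, atol=1e-12)

    def test_pls_smoke_59_taxa(self):
        rng = np.random.default_rng(0)
        series = rng.dirichlet(np.ones(59), size=11).T
        b, a = fit_glv_series(
            series, np.arange(11.0), FitConfig(regression="pls", n_components=2)
        )
        assert b.shape == (59,) and a.shape == (59, 59)
        assert np.all(np.isfinite(b)) and np.all(np.isfinite(a))

    def test_ridge_runs_and_is_finite(self):
        rng = np.random.default_rng(1)
        series = rng.uniform(0.1, 1.0, size=(10, 6))
        b, a = fit_glv_series(series, np.arange(6.0), FitConfig(regression="ridge"))
        assert np.all(np.isfinite(a))

    def test_zero_dt_rejected(self):
        with pytest.raises(ValueError, match="zero time step"):
            fit_glv_series(np.ones((2, 3)), [0.0, 0.0, 1.0])

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            FitConfig(regression="lasso")

    def test_pseudocount_handles_zeros(self):
        series = np.array([[0.5, 0.0, 0.5], [0.5, 1.0, 0.5]])
        b, a = fit_glv_series(series, [0.0, 1.0, 2.0], FitConfig(regression="ols"))
        assert np.all(np.isfinite(a))


class TestInferEnsemble:
    def test_single_assembly(self, two_group_study):
        table, _ = two_group_study
        ens = infer_ensemble(table, "sham", np.array([[1, 1, 1, 1, 1, 1]]),
                             FitConfig(regression="ols"))
        assert ens.n_members == 1

    def test_member_order_follows_assembly_order(self, tiny_study):
        table, _ = tiny_study
        asm = enumerate_assemblies(2, 3, mode="full")
        cfg = FitConfig(regression="ols")
        ens = infer_ensemble(table, "group1", asm, cfg)
        flipped = infer_ensemble(table, "group1", asm[::-1], cfg)
        np.testing.assert_array_equal(ens.growth, flipped.growth[::-1])
        np.testing.assert_array_equal(ens.interactions, flipped.interactions[::-1])

    def test_members_equal_direct_fits(self, tiny_study):
        """Member-by-member oracle: each fit equals an independent direct fit."""
        table, _ = tiny_study
        asm = enumerate_assemblies(2, 3, mode="full")
        cfg = FitConfig(regression="ols")
        ens = infer_ensemble(table, "group1", asm, cfg)
        assert ens.n_members == 8
        for m in range(8):
            series, days = assemble_series(table, "group1", asm[m])
            b, a = fit_glv_series(series, days, cfg)
            np.testing.assert_allclose(ens.growth[m], b)
            np.testing.assert_allclose(ens.interactions[m], a)


class TestSupportThresholdCount:
    def test_study_scale_value(self):
        assert support_threshold_count(177_147, 0.7) == 124_003

    def test_small_examples(self):
        assert support_threshold_count(10, 0.7) == 8
        assert support_threshold_count(100, 0.5) == 51

    def test_strict_inequality_at_exact_multiple(self):
        assert support_threshold_count(10, 0.5) == 6

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            support_threshold_count(10, 1.0)


def ensemble_from_sign_patterns(patterns):
    """Build a CoefficientEnsemble from hand-set (n, n) sign matrices."""
    arr = np.array(patterns, dtype=float)
    n = arr.shape[1]
    taxa = [f"t{i}" for i in range(n)]
    return CoefficientEnsemble(
        growth=np.zeros((arr.shape[0], n)),
        interactions=arr,
        taxa=taxa,
        assemblies=np.ones((arr.shape[0], 2), dtype=int),
    )


def brute_force_consensus(patterns, cutoff):
    """Independent hand-count of retained signed edges."""
    arr = np.array(patterns, dtype=float)
    m, n, _ = arr.shape
    edges = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            pos = sum(1 for k in range(m) if arr[k, i, j] > 0)
            neg = sum(1 for k in range(m) if arr[k, i, j] < 0)
            if pos > cutoff * m:
                edges.add((f"t{j}", f"t{i}", 1))
            elif neg > cutoff * m:
                edges.add((f"t{j}", f"t{i}", -1))
    return edges


class TestConsensusNetwork:
    def test_unanimous_positive_edge(self):
        base = np.zeros((3, 3))
        base[0, 1] = 1.0  # t1 -> t0, positive in every member
        ens = ensemble_from_sign_patterns([base] * 5)
        net = consensus_network(ens, cutoff=0.7)
        assert net.n_edges == 1
        edge = net.edges.iloc[0]
        assert (edge["source"], edge["target"], edge["sign"]) == ("t1", "t0", 1)
        assert edge["support"] == 1.0

    def test_65_percent_support_filtered_at_70(self):
        on = np.zeros((2, 2))
        on[0, 1] = 1.0
        members = [on] * 13 + [np.zeros((2, 2))] * 7  # 65% support
        net = consensus_network(ensemble_from_sign_patterns(members), cutoff=0.7)
        assert net.n_edges == 0

    def test_toy_ensemble_matches_brute_force(self):
        rng = np.random.default_rng(12)
        patterns = rng.choice([-1.0, 0.0, 1.0], size=(8, 4, 4), p=[0.45, 0.1, 0.45])
        ens = ensemble_from_sign_patterns(patterns)
        net = consensus_network(ens, cutoff=0.7)
        got = {
            (r.source, r.target, int(r.sign)) for r in net.edges.itertuples()
        }
        assert got == brute_force_consensus(patterns, 0.7)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(3)
        patterns = rng.choice([-1.0, 1.0], size=(20, 5, 5))
        ens = ensemble_from_sign_patterns(patterns)
        edges_by_cutoff = {}
        for cutoff in (0.55, 0.7, 0.85):
            net = consensus_network(ens, cutoff=cutoff)
            edges_by_cutoff[cutoff] = {
                (r.source, r.target, int(r.sign)) for r in net.edges.itertuples()
            }
        assert edges_by_cutoff[0.85] <= edges_by_cutoff[0.7] <= edges_by_cutoff[0.55]

    def test_size_one_ensemble_gives_dense_sign_pattern(self, tiny_study):
        table, _ = tiny_study
        ens = infer_ensemble(table, "group1", np.array([[1, 2, 1]]),
                             FitConfig(regression="ols"))
        net = consensus_network(ens, cutoff=0.7)
        a = ens.interactions[0]
        n = len(ens.taxa)
        expected = sum(
            1 for i in range(n) for j in range(n) if i != j and a[i, j] != 0
        )
        assert net.n_edges == expected
        for row in net.edges.itertuples():
            i, j = ens.taxa.index(row.target), ens.taxa.index(row.source)
            assert np.sign(a[i, j]) == row.sign
            assert row.support == 1.0

    def test_mean_strength_over_supporting_members(self):
        base = np.zeros((2, 2))
        strong, weak = base.copy(), base.copy()
        strong[0, 1], weak[0, 1] = 2.0, 1.0
        net = consensus_network(ensemble_from_sign_patterns([strong, weak]), cutoff=0.7)
        assert net.edges.iloc[0]["mean_strength"] == pytest.approx(1.5)

    def test_no_self_loops_by_default(self, tiny_study):
        table, _ = tiny_study
        ens = infer_ensemble(table, "group1", np.array([[1, 1, 1]]),
                             FitConfig(regression="ols"))
        net = consensus_network(ens)
        assert not (net.edges["source"] == net.edges["target"]).any()

    def test_serialization_round_trip(self, tmp_path):
        base = np.zeros((3, 3))
        base[0, 1], base[2, 0] = 1.0, -0.5
        net = consensus_network(ensemble_from_sign_patterns([base] * 4), cutoff=0.7)
        path = tmp_path / "edges.csv"
        net.write_edgelist(path)
        back = type(net).read_edgelist(path)
        pd.testing.assert_frame_equal(net.edges, back.edges)

    def test_graphml_gexf_writers(self, tmp_path):
        base = np.zeros((2, 2))
        base[0, 1] = 1.0
        net = consensus_network(ensemble_from_sign_patterns([base] * 3))
        net.write_graphml(tmp_path / "n.graphml")
        net.write_gexf(tmp_path / "n.gexf")
        assert (tmp_path / "n.graphml").stat().st_size > 0
        assert (tmp_path / "n.gexf").stat().st_size > 0
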