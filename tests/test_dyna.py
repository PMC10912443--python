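import itertools

import numpy as np
import pandas as pd
import pytest

import woundtraj as wt
from woundtraj.dyna import DynaConfig, build_windows, correlation_network


def brute_force_edges(expr: pd.DataFrame, stringency: float):
    """Independent oracle: all-pairs Pearson r via the textbook formula."""
    edges = set()
    for a, b in itertools.combinations(expr.index, 2):
        x = expr.loc[a].to_numpy(dtype=float)
        y = expr.loc[b].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        r = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum())
            * np.sqrt(((y - y.mean()) ** 2).sum()))
        if abs(r) >= stringency:
            edges.add(frozenset((a, b)))
    return edges


def _meta(days, outcome="healed"):
    n = len(days)
    return wt.validate_sample_meta(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "wound_id": ["w"] * n, "patient_id": ["p"] * n,
        "days_post_injury": days, "outcome": [outcome] * n,
        "colonization": ["colonized"] * n}))


class TestConfig:
    def test_stringency_range(self):
        with pytest.raises(ValueError):
            DynaConfig(stringency=0.0)
        with pytest.raises(ValueError):
            DynaConfig(stringency=1.2)

    def test_two_point_windows_rejected(self):
        with pytest.raises(ValueError, match="min_samples"):
            DynaConfig(min_samples_per_window=2)


class TestWindows:
    def test_consecutive_day_enumeration(self):
        meta = _meta([4, 4, 5, 5, 6])
        wins = build_windows(meta, DynaConfig())["healed"]
        assert [w.label for w in wins] == ["d4-5", "d5-6"]
        assert len(wins[0].sample_ids) == 4 and not wins[0].skipped
        assert len(wins[1].sample_ids) == 3 and not wins[1].skipped

    def test_small_window_flagged_skipped(self):
        meta = _meta([4, 5, 7, 7, 8])
        wins = build_windows(meta, DynaConfig())["healed"]
        by_label = {w.label: w for w in wins}
        assert by_label["d4-5"].skipped  # only 2 samples
        assert not by_label["d7-8"].skipped

    def test_consecutive_bins_adjacency(self):
        meta = _meta([3, 4, 5, 6, 6, 7, 7, 9])
        cfg = DynaConfig(window_scheme="consecutive_bins")
        wins = build_windows(meta, cfg)["healed"]
        labels = [w.label for w in wins]
        assert labels[:3] == ["3-5,6", "6,7", "7,8-10"]
        assert len(wins[0].sample_ids) == 5  # three in 3-5, two in 6

    def test_no_viable_window_warns(self):
        meta = _meta([4, 8])
        with pytest.warns(UserWarning, match="no window"):
            build_windows(meta, DynaConfig())


class TestNetwork:
    def test_collinear_pair_complexity(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(size=6)
        expr = pd.DataFrame([g1, 2 * g1, rng.normal(size=6)],
                            index=["g1", "g2", "g3"])
        net = correlation_network(expr, DynaConfig())
        assert {frozenset(e[:2]) for e in net.edges} == {frozenset(("g1", "g2"))}
        assert net.complexity == pytest.approx(2 / (3 - 1))

    def test_complete_graph_complexity_is_n(self):
        base = np.arange(6.0)
        expr = pd.DataFrame([base * k for k in range(1, 6)],
                            index=[f"g{k}" for k in range(5)])
        net = correlation_network(expr, DynaConfig())
        assert len(net.edges) == 5 * 4 // 2
        assert net.complexity == pytest.approx(5.0)

    def test_no_edges_zero_complexity(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(10, 8)))
        net = correlation_network(expr, DynaConfig(stringency=0.99))
        assert net.edges == [] and net.complexity == 0.0

    def test_anticorrelation_forms_edge(self):
        x = np.arange(5.0)
        expr = pd.DataFrame([x, -x], index=["up", "down"])
        net = correlation_network(expr, DynaConfig())
        assert len(net.edges) == 1 and net.edges[0][2] == pytest.approx(-1.0)

    def test_zero_variance_gene_kept_as_isolated_node(self):
        x = np.arange(5.0)
        expr = pd.DataFrame([x, 2 * x, np.full(5, 3.0)],
                            index=["g1", "g2", "flat"])
        net = correlation_network(expr, DynaConfig())
        assert "flat" in net.nodes and net.degenerate_nodes == ["flat"]
        # denominator stays the full gene count
        assert net.complexity == pytest.approx(2 / (3 - 1))

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(5, 51))
        n_samples = int(rng.integers(4, 11))
        # latent factor structure induces some near-threshold correlations
        factor = rng.normal(size=n_samples)
        loading = rng.normal(size=n_genes)[:, None]
        expr = pd.DataFrame(
            loading * factor + 0.05 * rng.normal(size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)])
        stringency = float(rng.uniform(0.8, 0.995))
        net = correlation_network(expr, DynaConfig(stringency=stringency))
        assert {frozenset(e[:2]) for e in net.edges} == \
            brute_force_edges(expr, stringency)
        assert net.complexity == pytest.approx(
            2 * len(net.edges) / (n_genes - 1))

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(10, 6)),
                            columns=[f"s{j}" for j in range(6)])
        net1 = correlation_network(expr, DynaConfig(stringency=0.5))
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        net2 = correlation_network(expr[perm], DynaConfig(stringency=0.5))
        assert {frozenset(e[:2]) for e in net1.edges} == \
            {frozenset(e[:2]) for e in net2.edges}

    def test_edge_count_monotone_in_stringency(self):
        rng = np.random.default_rng(7)
        factor = rng.normal(size=8)
        expr = pd.DataFrame(
            rng.normal(size=(20, 1)) * factor
            + 0.3 * rng.normal(size=(20, 8)))
        counts = [len(correlation_network(expr, DynaConfig(stringency=s)).edges)
                  for s in (0.99, 0.9, 0.7, 0.5)]
        assert counts == sorted(counts)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match="2 genes"):
            correlation_network(pd.DataFrame([[1.0, 2.0, 3.0]]), DynaConfig())


class TestTrajectory:
    def test_skipped_windows_reported_missing_not_zero(self):
        meta = _meta([4, 5, 5, 7, 8, 8])
        cfg = DynaConfig()
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(5, 6)),
                            columns=[f"s{i}" for i in range(6)])
        windows = build_windows(meta, cfg)
        nets = wt.dyna_networks(expr, meta, cfg)
        series = wt.complexity_trajectory(nets, windows)
        skipped = series.loc[series["window"] == "d6-7", "complexity"]
        assert skipped.isna().all()
        built = series.loc[series["window"] == "d4-5", "complexity"]
        assert built.notna().all()

    def test_identical_strata_give_identical_series(self):
        days = [4, 4, 5, 5, 6, 6]
        meta_h = _meta(days, outcome="healed")
        meta_f = _meta(days, outcome="failed")
        meta_f.index = [f"f{i}" for i in range(6)]
        meta_f["sample_id"] = meta_f.index
        meta = pd.concat([meta_h, meta_f])
        rng = np.random.default_rng(3)
        block = rng.normal(size=(8, 6))
        expr = pd.DataFrame(np.hstack([block, block]),
                            columns=list(meta_h["sample_id"])
                            + list(meta_f["sample_id"]))
        cfg = DynaConfig(stringency=0.8)
        nets = wt.dyna_networks(expr, meta, cfg)
        series = wt.complexity_trajectory(nets, build_windows(meta, cfg))
        piv = series.pivot(index="window", columns="stratum",
                           values="complexity")
        np.testing.assert_allclose(piv["healed"], piv["failed"])
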