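import json

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import funconn as fc
from funconn.synthetic import (CohortSpec, PlantedNetworkSpec,
                               default_coupling, graph_to_covariance,
                               make_planted_graph, sample_cohort,
                               sample_morphometry, write_cohort)


class TestPlantedGraph:
    def test_degenerate_probabilities_give_two_triangles(self):
        spec = PlantedNetworkSpec(n_nodes=6, n_modules=2, p_within=1.0,
                                  p_between=0.0, seed=1)
        g, modules = make_planted_graph(spec)
        expected = np.zeros((6, 6), dtype=int)
        expected[:3, :3] = 1 - np.eye(3)
        expected[3:, 3:] = 1 - np.eye(3)
        np.testing.assert_array_equal(g.adjacency, expected)
        np.testing.assert_array_equal(modules, [0, 0, 0, 1, 1, 1])

    def test_planted_partition_beats_random_partitions(self):
        """Q of the planted partition exceeds Q of 100 random partitions."""
        spec = PlantedNetworkSpec(seed=1)
        g, modules = make_planted_graph(spec)
        G = g.to_networkx()
        comms = [set(np.nonzero(modules == m)[0].tolist())
                 for m in range(spec.n_modules)]
        q_planted = nx.community.modularity(G, comms)
        rng = np.random.default_rng(0)
        for _ in range(100):
            perm = rng.permutation(spec.n_nodes)
            rand_comms = [set(perm[np.nonzero(modules == m)[0]].tolist())
                          for m in range(spec.n_modules)]
            assert q_planted > nx.community.modularity(G, rand_comms)

    def test_determinism(self):
        spec = PlantedNetworkSpec(seed=42, hub_nodes=(3, 50))
        g1, m1 = make_planted_graph(spec)
        g2, m2 = make_planted_graph(spec)
        np.testing.assert_array_equal(g1.adjacency, g2.adjacency)
        np.testing.assert_array_equal(m1, m2)

    def test_hub_degree_exceeds_two_sd(self):
        spec = PlantedNetworkSpec(seed=5, hub_nodes=(7, 91, 23))
        g, _ = make_planted_graph(spec)
        deg = g.degrees()
        threshold = deg.mean() + 2 * deg.std()
        for h in spec.hub_nodes:
            assert deg[h] >= threshold

    def test_infeasible_hub_names_node(self):
        spec = PlantedNetworkSpec(n_nodes=20, n_modules=2, p_within=0.06,
                                  p_between=0.0, hub_nodes=(4,), seed=0)
        with pytest.raises(ValueError, match="node 4"):
            make_planted_graph(spec)

    @pytest.mark.parametrize("kwargs", [
        dict(p_within=0.3, p_between=0.4),       # between >= within
        dict(n_nodes=10, n_modules=6),            # too many modules
        dict(hub_nodes=(200,)),                   # hub index out of range
        dict(ar_coeff=1.0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PlantedNetworkSpec(**kwargs)


class TestGraphToCovariance:
    def test_empty_adjacency_identity(self):
        cov = graph_to_covariance(np.zeros((4, 4)), 0.3)
        np.testing.assert_allclose(cov, np.eye(4), atol=1e-12)

    def test_single_edge_closed_form(self):
        n, c = 5, 0.4
        adj = np.zeros((n, n))
        adj[0, 1] = adj[1, 0] = 1
        cov = graph_to_covariance(adj, c)
        corr = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert corr[0, 1] == pytest.approx(c)  # 2x2 block inverse
        off = corr - np.eye(n)
        off[0, 1] = off[1, 0] = 0
        assert np.max(np.abs(off)) == 0.0

    def test_zero_coupling_identity(self):
        adj = 1 - np.eye(3)  # K3
        np.testing.assert_allclose(graph_to_covariance(adj, 0.0), np.eye(3),
                                   atol=1e-12)

    def test_connected_pairs_correlate_more(self):
        spec = PlantedNetworkSpec(seed=3)
        g, _ = make_planted_graph(spec)
        cov = graph_to_covariance(g.adjacency,
                                  default_coupling(g.adjacency))
        corr = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        edge = g.adjacency.astype(bool)
        non_edge = ~edge & ~np.eye(spec.n_nodes, dtype=bool)
        assert np.abs(corr[edge]).mean() > np.abs(corr[non_edge]).mean()

    def test_excessive_coupling_instructs_smaller(self):
        adj = 1 - np.eye(6)
        with pytest.raises(ValueError, match="smaller coupling"):
            graph_to_covariance(adj, 0.5)


class TestSampleCohort:
    def test_determinism(self):
        net = PlantedNetworkSpec(n_nodes=20, n_modules=2, p_within=0.5,
                                 p_between=0.05, seed=9)
        cohort = CohortSpec(n_per_group=(3, 3), n_timepoints=50)
        s1, m1, t1 = sample_cohort(net, cohort)
        s2, m2, t2 = sample_cohort(net, cohort)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.data, b.data)
        assert m1.equals(m2)
        assert json.dumps(t1, sort_keys=True) == json.dumps(t2,
                                                            sort_keys=True)

    def test_group_effect_lowers_group_b_clustering(self):
        net = PlantedNetworkSpec(n_nodes=40, n_modules=4, p_within=0.5,
                                 p_between=0.05, seed=21)
        cohort = CohortSpec(n_per_group=(8, 8), n_timepoints=200,
                            group_effect=0.5)
        series, manifest, _ = sample_cohort(net, cohort)
        cs = {}
        for grp in ("A", "B"):
            vals = []
            for s in series:
                if not s.subject_id.startswith(grp):
                    continue
                am = fc.correlation_matrix(s)
                vals.append(fc.clustering_coefficient(
                    fc.binarize_at_density(am, 0.2))[0])
            cs[grp] = np.mean(vals)
        assert cs["B"] < cs["A"]

    def test_white_noise_limit_lag1_autocorr(self):
        net = PlantedNetworkSpec(n_nodes=15, n_modules=3, p_within=0.5,
                                 p_between=0.05, ar_coeff=0.0, seed=2)
        cohort = CohortSpec(n_per_group=(4, 4), n_timepoints=400)
        series, _, _ = sample_cohort(net, cohort)
        acs = []
        for s in series:
            x = s.data - s.data.mean(axis=0)
            num = (x[1:] * x[:-1]).sum(axis=0)
            den = (x * x).sum(axis=0)
            acs.extend(num / den)
        assert abs(np.mean(acs)) < 3 / np.sqrt(400)

    def test_ar_coeff_preserves_marginal_covariance(self):
        """AR(1) is scaled so lag-0 covariance equals the planted one."""
        net0 = PlantedNetworkSpec(n_nodes=10, n_modules=2, p_within=0.8,
                                  p_between=0.1, ar_coeff=0.0, seed=4)
        net7 = PlantedNetworkSpec(n_nodes=10, n_modules=2, p_within=0.8,
                                  p_between=0.1, ar_coeff=0.7, seed=4)
        cohort = CohortSpec(n_per_group=(1, 1), n_timepoints=20_000)
        s0, _, _ = sample_cohort(net0, cohort)
        s7, _, _ = sample_cohort(net7, cohort)
        r0 = np.corrcoef(s0[0].data, rowvar=False)
        r7 = np.corrcoef(s7[0].data, rowvar=False)
        iu = np.triu_indices(10, 1)
        # same population correlations; AR(1) widens the sampling noise
        assert np.abs(r0[iu] - r7[iu]).mean() < 0.05

    def test_short_series_warns(self):
        net = PlantedNetworkSpec(n_nodes=30, n_modules=3, p_within=0.5,
                                 p_between=0.05, seed=3)
        cohort = CohortSpec(n_per_group=(1, 1), n_timepoints=20)
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            sample_cohort(net, cohort)

    def test_manifest_structure(self):
        net = PlantedNetworkSpec(n_nodes=16, n_modules=2, p_within=0.6,
                                 p_between=0.05, seed=6)
        cohort = CohortSpec(n_per_group=(4, 6), n_timepoints=40,
                            genotype_split=(0.5, 0.5))
        series, manifest, truth = sample_cohort(net, cohort)
        assert list(manifest["group"]) == ["A"] * 4 + ["B"] * 6
        assert (manifest.loc[manifest.group == "A", "genotype"]
                .tolist().count("S")) == 2
        assert all(s.roi_labels == series[0].roi_labels for s in series)
        assert set(manifest.columns) >= {"subject_id", "group", "genotype",
                                         "bmi", "stai"}

    def test_edge_recovery_long_series(self):
        """Thresholding a long-series subject recovers >= 80% of edges."""
        net = PlantedNetworkSpec(seed=8)
        cohort = CohortSpec(n_per_group=(1, 1), n_timepoints=5000)
        series, _, truth = sample_cohort(net, cohort)
        adj = np.array(truth["adjacency_a"])
        n = adj.shape[0]
        density = adj.sum() / (n * (n - 1))
        am = fc.correlation_matrix(series[0])
        g = fc.binarize_at_density(am, density)
        recovered = (g.adjacency & adj).sum() / adj.sum()
        assert recovered >= 0.80


class TestExchangeability:
    def test_zero_effects_make_groups_exchangeable(self):
        """KS test on each global metric across 100 null replicates."""
        dists = {m: {"A": [], "B": []}
                 for m in ("C", "L", "E", "Q", "r", "sigma")}
        for rep in range(100):
            net = PlantedNetworkSpec(n_nodes=20, n_modules=2, p_within=0.6,
                                     p_between=0.1, seed=5000 + rep)
            cohort = CohortSpec(n_per_group=(3, 3), n_timepoints=80,
                                group_effect=0.0, genotype_effect=0.0)
            series, manifest, _ = sample_cohort(net, cohort)
            for s, grp in zip(series, manifest["group"]):
                am = fc.correlation_matrix(s)
                g = fc.binarize_at_density(am, 0.3)
                prof = fc.metric_profile(g, n_null=2, n_rewires_per_edge=3,
                                         seed=rep, modularity_restarts=2)
                for m, v in prof.globals_dict().items():
                    if np.isfinite(v):
                        dists[m][grp].append(v)
        failures = 0
        for m, d in dists.items():
            p = stats.ks_2samp(d["A"], d["B"]).pvalue
            failures += (p <= 0.01)
        assert failures <= 1


class TestMorphometry:
    def _truth(self, seed=0, **cohort_kwargs):
        net = PlantedNetworkSpec(n_nodes=40, n_modules=4, p_within=0.5,
                                 p_between=0.05, hub_nodes=(3,), seed=seed)
        cohort = CohortSpec(n_per_group=(4, 4), n_timepoints=50,
                            hub_nodes_b=(17,), **cohort_kwargs)
        _, _, truth = sample_cohort(net, cohort)
        return cohort, truth

    def test_noiseless_case_exact_regression(self):
        cohort, truth = self._truth(noise_sd=0.0, volume_coupling=-1.0)
        morph = sample_morphometry(truth, cohort)
        vol = morph.pivot_table(index="node", columns="group",
                                values="volume")
        labels = truth["roi_labels"]
        dv = (vol["A"] - vol["B"]).loc[labels].to_numpy()
        dk = np.array(truth["degree_diff_a_minus_b"])
        res = stats.linregress(dk, dv)
        assert res.rvalue ** 2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(-1.0)

    def test_zero_coupling_slope_ci_covers_zero(self):
        covered = 0
        for rep in range(50):
            cohort, truth = self._truth(seed=100 + rep, volume_coupling=0.0,
                                        noise_sd=1.0)
            morph = sample_morphometry(truth, cohort)
            vol = morph.pivot_table(index="node", columns="group",
                                    values="volume")
            labels = truth["roi_labels"]
            dv = (vol["A"] - vol["B"]).loc[labels].to_numpy()
            dk = np.array(truth["degree_diff_a_minus_b"])
            res = stats.linregress(dk, dv)
            half = 1.96 * res.stderr
            covered += (res.slope - half <= 0 <= res.slope + half)
        assert covered >= 45

    def test_determinism(self):
        cohort, truth = self._truth()
        m1 = sample_morphometry(truth, cohort)
        m2 = sample_morphometry(truth, cohort)
        assert m1.equals(m2)


def test_write_cohort_roundtrip(tmp_path, small_cohort):
    _, _, series, manifest, truth = small_cohort
    out = write_cohort(tmp_path / "cohort", series, manifest, truth)
    assert (out / "manifest.csv").exists()
    assert (out / "ground_truth.json").exists()
    study = fc.ConnectomeStudy.from_cohort_dir(out)
    assert len(study.series) == len(series)
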