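import numpy as np
import pandas as pd
import pytest

import ssmnet as sn
from ssmnet.metabolic_network import (GraphMetricsTable, assortativity, binarize,
                                      bootstrap_graphs, characteristic_path_length,
                                      clustering_coefficient, compare_global_metrics,
                                      edge_changes, eigenvector_centrality,
                                      extract_nodes, global_metrics,
                                      icc_absolute_single, matrix_concordance,
                                      mean_degree, node_activity,
                                      permutation_edge_pvalues,
                                      rewire_degree_preserving)


# ---------------------------------------------------------------------------
# node extraction

class TestExtractNodes:
    def test_planted_pattern_nodes_recovered_at_zero_noise(self, small_inputs):
        spec, mask, atlas, modules, truth = small_inputs
        quiet = truth.replace(noise_sd=0.0, global_scale_sd=0.0,
                              node_jitter_scale={"control": 0.0, "patient": 0.0},
                              inter_module_corr={"control": 1.0, "patient": 1.0})
        coh = sn.simulate_cohort(spec, quiet, seed=2)
        res = sn.derive_pattern(coh.raw, coh.is_patient)
        nodes = extract_nodes(res.model, coh.atlas, coh.mask)
        assert sorted(nodes.labels) == sorted(truth.pattern_parcels)
        pol = dict(zip(nodes.labels, nodes.table["polarity"]))
        for lab in truth.pattern_parcels:
            expect = "hypo" if truth.module_of_parcel[lab] == "frontotemporal" else "hyper"
            assert pol[lab] == expect

    def test_hand_z_oracle_on_synthetic_weight_profile(self, small_inputs):
        spec, mask, atlas, modules, truth = small_inputs
        lab = mask.flatten(atlas.labels)
        profile = {1: 5.0, 2: 5.0, 3: 5.0, 4: -5.0, 5: -5.0, 6: 0.0, 7: 0.0, 8: 0.0}
        weights = np.zeros(mask.n_voxels)
        for l, w in profile.items():
            weights[lab == l] = w
        weights /= np.linalg.norm(weights)
        model = sn.PatternModel(weights=weights, gmp=np.zeros(mask.n_voxels),
                                selected_pcs=(0,), logit_coefs={0: 1.0},
                                logit_intercept=0.0, hc_ref_mean=0.0, hc_ref_sd=1.0)
        nodes = extract_nodes(model, atlas, mask)
        vals = np.array([profile[l] for l in sorted(profile)])
        z = (vals - vals.mean()) / vals.std(ddof=1)  # hand z-computation oracle
        expected = {l for l, zz in zip(sorted(profile), z) if abs(zz) > 1}
        assert set(nodes.labels) == expected

    def test_degenerate_equal_weights_rejected(self, small_inputs):
        spec, mask, atlas, modules, truth = small_inputs
        model = sn.PatternModel(weights=np.ones(mask.n_voxels) / np.sqrt(mask.n_voxels),
                                gmp=np.zeros(mask.n_voxels), selected_pcs=(0,),
                                logit_coefs={0: 1.0}, logit_intercept=0.0,
                                hc_ref_mean=0.0, hc_ref_sd=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            extract_nodes(model, atlas, mask)


class TestNodeActivity:
    def test_constant_scan_gives_unit_activities(self, small_inputs):
        spec, mask, atlas, modules, truth = small_inputs
        raw = np.full((3, mask.n_voxels), 4.2)
        act = node_activity(raw, atlas, mask, labels=[1, 2, 3])
        np.testing.assert_allclose(act, 1.0, atol=1e-12)

    def test_subject_rescaling_leaves_activity_unchanged(self, small_cohort):
        coh = small_cohort
        labels = coh.truth.pattern_parcels[:3]
        act_a = node_activity(coh.raw, coh.atlas, coh.mask, labels)
        scaled = coh.raw.copy()
        scaled[1] *= 9.9
        act_b = node_activity(scaled, coh.atlas, coh.mask, labels)
        np.testing.assert_allclose(act_a, act_b, atol=1e-12)

    def test_matches_per_voxel_oracle(self, small_cohort):
        coh = small_cohort
        labels = coh.truth.pattern_parcels[:4]
        lab = coh.mask.flatten(coh.atlas.labels)
        act = node_activity(coh.raw, coh.atlas, coh.mask, labels)
        ref = coh.raw[:, lab == coh.atlas.reference_label].mean(axis=1)
        for j, l in enumerate(labels):  # brute-force voxel-list oracle
            expected = coh.raw[:, lab == l].mean(axis=1) / ref
            assert np.abs(act[:, j] - expected).max() < 1e-12


# ---------------------------------------------------------------------------
# bootstrap graphs

class TestBootstrapGraphs:
    def test_collinear_nodes_give_unit_median_correlation(self, rng):
        base = rng.standard_normal(30)
        activity = np.column_stack([base, 2 * base, rng.standard_normal(30)])
        g = bootstrap_graphs(activity, n_boot=50, seed=0)
        assert g.median_matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_nodes_median_near_zero(self, rng):
        activity = rng.standard_normal((50, 6))
        g = bootstrap_graphs(activity, n_boot=100, seed=1)
        off = g.median_matrix[np.triu_indices(6, 1)]
        se = 1 / np.sqrt(50 - 3)  # Fisher-z sampling scale at n=50
        assert np.abs(off).mean() < 0.15
        assert np.abs(off).max() < 4 * se

    def test_symmetric_unit_diagonal_bounded(self, rng):
        activity = rng.standard_normal((20, 5))
        g = bootstrap_graphs(activity, n_boot=40, seed=2)
        for m in (g.r, g.median_matrix, *g.bootstrap_stack[:5]):
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-12)
            assert np.nanmax(np.abs(m)) <= 1 + 1e-12

    def test_seed_determinism(self, rng):
        activity = rng.standard_normal((25, 4))
        a = bootstrap_graphs(activity, n_boot=30, seed=5)
        b = bootstrap_graphs(activity, n_boot=30, seed=5)
        np.testing.assert_array_equal(a.bootstrap_stack, b.bootstrap_stack)


# ---------------------------------------------------------------------------
# eigenvector centrality

class TestEigenvectorCentrality:
    def test_star_center_leaf_ratio(self):
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 0.9
        np.fill_diagonal(A, 1.0)
        c = eigenvector_centrality(A, threshold=0.5)
        assert c[0] / c[1] == pytest.approx(np.sqrt(3), abs=1e-10)

    def test_complete_graph_equal_centralities(self):
        A = np.full((4, 4), 0.8)
        np.fill_diagonal(A, 1.0)
        c = eigenvector_centrality(A, threshold=0.5)
        np.testing.assert_allclose(c, 0.5, atol=1e-10)

    def test_matches_power_iteration_oracle(self, rng):
        W = np.abs(rng.standard_normal((9, 9)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        c = eigenvector_centrality(W, threshold=0.2)
        A = np.where((np.abs(W) > 0.2) & ~np.eye(9, dtype=bool), np.abs(W), 0.0)
        from scipy.sparse.csgraph import connected_components
        n_comp, comp = connected_components(A > 0, directed=False)
        if n_comp == 1:
            v = rng.random(9) + 0.1
            for _ in range(500):  # independent power-iteration oracle
                v = A @ v
                v /= np.linalg.norm(v)
            assert np.abs(c - v).max() < 1e-8

    def test_permutation_equivariance(self, rng):
        W = np.abs(rng.standard_normal((7, 7)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        perm = rng.permutation(7)
        c = eigenvector_centrality(W, threshold=0.3)
        c_perm = eigenvector_centrality(W[np.ix_(perm, perm)], threshold=0.3)
        np.testing.assert_allclose(c_perm, c[perm], atol=1e-10)

    def test_empty_graph_all_zero(self):
        A = np.eye(5)
        c = eigenvector_centrality(A, threshold=0.9)
        np.testing.assert_array_equal(c, 0.0)


# ---------------------------------------------------------------------------
# edge gain / loss

class TestEdgeChanges:
    def test_identical_groups_give_empty_set(self, rng):
        X = rng.standard_normal((40, 6))
        ec = edge_changes(X, X.copy(), seed=0, n_perm=200, n_boot=50)
        assert len(ec.changes) == 0

    def test_planted_decorrelation_detected_as_loss(self, rng):
        n = 40
        shared = rng.standard_normal(n)
        hc = np.column_stack([shared + 0.3 * rng.standard_normal(n),
                              shared + 0.3 * rng.standard_normal(n),
                              rng.standard_normal(n)])
        pat = rng.standard_normal((n, 3))
        ec = edge_changes(hc, pat, seed=1, n_perm=1000, n_boot=100)
        hit = ec.changes[(ec.changes["i"] == 0) & (ec.changes["j"] == 1)]
        assert len(hit) == 1
        assert hit.iloc[0]["direction"] == "loss"
        assert hit.iloc[0]["p_perm"] < 0.05

    def test_sub_threshold_correlation_not_a_candidate(self):
        # |r| = .55 vs .1: fails the |r| > .6 gate regardless of delta
        n = 500
        rng = np.random.default_rng(7)
        z = rng.standard_normal(n)
        a = np.column_stack([z, 0.55 * z + np.sqrt(1 - 0.55**2) * rng.standard_normal(n)])
        b = np.column_stack([rng.standard_normal(n), rng.standard_normal(n)])
        ec = edge_changes(a, b, seed=2, n_perm=100, n_boot=20)
        assert len(ec.candidates) == 0

    def test_listed_edges_satisfy_all_gates(self, rng):
        n = 30
        shared = rng.standard_normal(n)
        hc = np.column_stack([shared, shared + 0.1 * rng.standard_normal(n),
                              rng.standard_normal(n), rng.standard_normal(n)])
        pat = rng.standard_normal((n, 4))
        ec = edge_changes(hc, pat, seed=3)
        for _, row in ec.changes.iterrows():
            assert max(abs(row["r_hc"]), abs(row["r_patient"])) > 0.6
            assert abs(row["delta_r"]) > 0.4
            assert row["p_perm"] < 0.05
            assert row["bootstrap_confirmed"]

    def test_permutation_pvalues_match_direct_oracle(self, rng):
        # small-n oracle: recompute the permutation distribution directly
        A = rng.standard_normal((8, 3))
        B = rng.standard_normal((8, 3))
        pv = permutation_edge_pvalues(A, B, n_perm=300, seed=11)
        X = np.vstack([A, B])
        obs = np.abs(np.corrcoef(A.T) - np.corrcoef(B.T))
        rng2 = np.random.default_rng(123)
        count = np.zeros((3, 3))
        for _ in range(3000):
            idx = rng2.permutation(16)
            d = np.abs(np.corrcoef(X[idx[:8]].T) - np.corrcoef(X[idx[8:]].T))
            count += d >= obs
        oracle = (count + 1) / 3001
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(pv[iu], oracle[iu], atol=0.06)


# ---------------------------------------------------------------------------
# graph metrics

class TestGraphMetricClosedForms:
    def test_complete_graph_k4(self):
        K4 = ~np.eye(4, dtype=bool)
        assert mean_degree(K4) == 3.0
        assert clustering_coefficient(K4) == pytest.approx(1.0, abs=1e-12)
        L, frac = characteristic_path_length(K4)
        assert L == pytest.approx(1.0, abs=1e-12) and frac == 0.0

    def test_k4_normalized_metrics_are_unity(self):
        R = np.full((4, 4), 0.9)
        np.fill_diagonal(R, 1.0)
        gm = global_metrics(np.array([R]), thresholds=(0.3,), n_null=10, seed=0)
        row = gm.table.iloc[0]
        assert row["clustering_norm"] == pytest.approx(1.0, abs=1e-8)
        assert row["path_norm"] == pytest.approx(1.0, abs=1e-8)
        assert row["small_worldness"] == pytest.approx(1.0, abs=1e-8)

    def test_path_graph_p4(self):
        P4 = np.zeros((4, 4), bool)
        for i in range(3):
            P4[i, i + 1] = P4[i + 1, i] = True
        L, _ = characteristic_path_length(P4)
        assert L == pytest.approx(5 / 3, abs=1e-12)
        assert clustering_coefficient(P4) == pytest.approx(0.0, abs=1e-12)

    def test_star_assortativity_is_minus_one(self):
        S = np.zeros((5, 5), bool)
        S[0, 1:] = S[1:, 0] = True
        assert assortativity(S) == pytest.approx(-1.0, abs=1e-10)

    def test_small_worldness_identity(self, rng):
        R = rng.uniform(-1, 1, (10, 10))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        gm = global_metrics(np.array([R]), thresholds=(0.3, 0.4), n_null=10, seed=1)
        ok = gm.table.dropna(subset=["small_worldness"])
        np.testing.assert_allclose(ok["small_worldness"],
                                   ok["clustering_norm"] / ok["path_norm"], atol=1e-10)


class TestGraphMetricsAgainstNetworkx:
    def test_random_graphs_match_networkx(self, rng):
        import networkx as nx

        for _ in range(5):
            A = rng.random((12, 12)) < 0.3
            A = np.triu(A, 1)
            A = A | A.T
            if not A.any():
                continue
            G = nx.from_numpy_array(A.astype(int))
            assert clustering_coefficient(A) == pytest.approx(
                nx.average_clustering(G), abs=1e-10)
            paths = [d for _, dd in nx.all_pairs_shortest_path_length(G)
                     for u, d in dd.items() if d > 0]
            L, _ = characteristic_path_length(A)
            assert L == pytest.approx(np.mean(paths), abs=1e-10)
            if len(set(A.sum(1))) > 1:
                assert assortativity(A) == pytest.approx(
                    nx.degree_assortativity_coefficient(G), abs=1e-8)


class TestRewiring:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_degree_sequence_exactly_preserved(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((14, 14)) < 0.3
        A = np.triu(A, 1)
        A = A | A.T
        B = rewire_degree_preserving(A, rng)
        np.testing.assert_array_equal(A.sum(axis=1), B.sum(axis=1))
        assert not np.diag(B).any()
        np.testing.assert_array_equal(B, B.T)

    def test_component_partition_respected(self, rng):
        # two cliques stay two cliques' worth of components under swaps
        from scipy.sparse.csgraph import connected_components

        A = np.zeros((10, 10), bool)
        A[:5, :5] = ~np.eye(5, dtype=bool)
        A[5:, 5:] = ~np.eye(5, dtype=bool)
        B = rewire_degree_preserving(A, rng)
        _, comp = connected_components(B, directed=False)
        assert len(set(comp[:5]) & set(comp[5:])) == 0


class TestCompareGlobalMetrics:
    def _table(self, rng, shift, group, n_units=10):
        rows = []
        for u in range(n_units):
            base = rng.standard_normal() * 0.5
            for t in (0.3, 0.4, 0.5):
                rows.append({"group": group, "iteration": u, "threshold": t,
                             "m": base + shift + 0.2 * t + 0.1 * rng.standard_normal()})
        return GraphMetricsTable(pd.DataFrame(rows), thresholds=(0.3, 0.4, 0.5))

    def test_matches_pingouin_mixed_anova_oracle(self, rng):
        import pingouin as pg

        ta = self._table(rng, 0.0, "A")
        tb = self._table(rng, 0.4, "B", n_units=12)
        res = compare_global_metrics(ta, tb, "m")
        df = pd.concat([ta.table.assign(subj=ta.table["iteration"]),
                        tb.table.assign(subj=tb.table["iteration"] + 100)])
        aov = pg.mixed_anova(df, dv="m", within="threshold", between="group",
                             subject="subj").set_index("Source")
        assert res.f_group == pytest.approx(aov.loc["group", "F"], abs=1e-8)
        assert res.p_group == pytest.approx(aov.loc["group", "p_unc"], abs=1e-8)
        assert res.f_threshold == pytest.approx(aov.loc["threshold", "F"], abs=1e-8)
        assert res.f_interaction == pytest.approx(aov.loc["Interaction", "F"], abs=1e-8)

    def test_null_groups_give_uniformish_pvalues(self, rng):
        # KS check of p-value uniformity under identical generative groups
        from scipy import stats as ss

        ps = []
        for _ in range(200):
            ta = self._table(rng, 0.0, "A", n_units=8)
            tb = self._table(rng, 0.0, "B", n_units=8)
            ps.append(compare_global_metrics(ta, tb, "m").p_group)
        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_undefined_metric_everywhere_rejected(self, rng):
        ta = self._table(rng, 0.0, "A")
        tb = self._table(rng, 0.0, "B")
        ta.table["m"] = np.nan
        tb.table["m"] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            compare_global_metrics(ta, tb, "m")


# ---------------------------------------------------------------------------
# intraclass correlation

class TestICC:
    def test_identical_matrices_give_unit_icc(self, rng):
        m = rng.standard_normal((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        res = matrix_concordance([m, m.copy(), m.copy()])
        assert res.icc == pytest.approx(1.0, abs=1e-10)

    def test_variance_components_recovery(self, rng):
        obj = rng.standard_normal(500)
        data = obj[:, None] + rng.standard_normal((500, 3))
        res = icc_absolute_single(data)
        assert res.icc == pytest.approx(0.5, abs=0.07)

    def test_matches_pingouin_icc2_oracle(self, rng):
        import pingouin as pg

        data = rng.standard_normal((6, 3)) + rng.standard_normal(6)[:, None]
        mine = icc_absolute_single(data)
        df = pd.DataFrame({"targets": np.repeat(range(6), 3),
                           "raters": list(range(3)) * 6,
                           "scores": data.ravel()})
        icc = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        row = icc[icc["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert mine.icc == pytest.approx(row["ICC"], abs=1e-10)

    def test_too_few_pairs_rejected(self, rng):
        m = np.eye(2)
        with pytest.raises(ValueError):
            matrix_concordance([m, m])
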