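import numpy as np
import pandas as pd
import pytest

from adipoptm.io import IntensityMatrix
from adipoptm.network import (WeightedCoabundanceNetwork,
                              adjacency_from_correlation, adjacency_matrix,
                              build_feature_space, detect_modules, kme_gs,
                              merge_modules, module_eigengene,
                              module_trait_statistics, prune_by_kme,
                              select_key_drivers, topological_overlap)

from conftest import small_matrix


def tom_bruteforce(a):
    """Triple-loop reference for the topological overlap matrix."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n)
                         if u != i and u != j)
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            tom[i, j] = (shared + a[i, j]) / denom if denom > 0 else 0.0
    return tom


def random_adjacency(rng, n=20):
    r = rng.uniform(-1, 1, (n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    return adjacency_from_correlation(r, beta=6, signed=True)


class TestAdjacency:
    def test_perfect_correlation_maps_to_one(self):
        for signed in (True, False):
            assert adjacency_from_correlation(1.0, 17, signed) == 1.0

    def test_signed_anticorrelation_maps_to_zero(self):
        assert adjacency_from_correlation(-1.0, 17, True) == 0.0
        assert adjacency_from_correlation(-1.0, 17, False) == 1.0

    def test_soft_power_value(self):
        assert adjacency_from_correlation(0.0, 17, True) == pytest.approx(
            0.5 ** 17, rel=1e-12)

    def test_monotone_in_correlation(self):
        r = np.linspace(-1, 1, 201)
        a = adjacency_from_correlation(r, 17, True)
        assert np.all(np.diff(a) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjacency_from_correlation(1.5)


class TestTopologicalOverlap:
    def test_fully_connected_triangle(self):
        a = np.ones((3, 3))
        tom = topological_overlap(a)
        # shared = 1, k = 2 each: (1 + 1) / (2 + 1 - 1) = 1
        assert np.allclose(tom, 1.0)

    def test_empty_network(self):
        tom = topological_overlap(np.eye(4))
        assert np.allclose(tom, np.eye(4))

    def test_matches_bruteforce_on_random_matrices(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = random_adjacency(rng)
            assert np.max(np.abs(topological_overlap(a) - tom_bruteforce(a))) < 1e-10

    def test_asymmetry_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)

    def test_out_of_range_entries_rejected(self):
        a = np.eye(2)
        a[0, 1] = a[1, 0] = 1.7
        with pytest.raises(ValueError, match="0, 1"):
            topological_overlap(a)


class TestEigengene:
    def test_identical_profiles(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        sub = pd.DataFrame(np.tile(profile, (6, 1)))
        eig, varex = module_eigengene(sub)
        assert varex == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)
        # orientation: positively correlated with the module features
        assert np.corrcoef(eig, profile)[0, 1] > 0

    def test_rank_one_anticorrelated_pair(self):
        p = np.array([1.0, 2.0, 3.0, 4.0])
        sub = pd.DataFrame([p, -p])
        eig, varex = module_eigengene(sub)
        assert varex == pytest.approx(1.0)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sub = pd.DataFrame(rng.normal(size=(8, 6)))
            eig, varex = module_eigengene(sub)
            z = sub.to_numpy()
            z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1,
                                                            keepdims=True)
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            assert min(np.linalg.norm(eig - vt[0]),
                       np.linalg.norm(eig + vt[0])) < 1e-10
            assert varex == pytest.approx(s[0] ** 2 / np.sum(s ** 2), rel=1e-10)

    def test_constant_rows_excluded_with_warning(self):
        sub = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        log = []
        eig, _ = module_eigengene(sub, warnings_out=log)
        assert log and "constant" in log[0]

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            module_eigengene(pd.DataFrame([[1.0, 2.0]]))


def planted_blocks(rng, sizes, n_samples=12, noise=0.3):
    rows, labels = [], []
    patterns = []
    for b, size in enumerate(sizes):
        pattern = rng.normal(size=n_samples)
        for prev in patterns:  # orthogonalize so blocks stay uncorrelated
            pattern = pattern - (pattern @ prev) / (prev @ prev) * prev
        pattern /= pattern.std()
        patterns.append(pattern)
        for _ in range(size):
            rows.append(pattern + rng.normal(0, noise, n_samples))
            labels.append(b)
    index = [f"F{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=index), pd.Series(labels, index=index)


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(20)
        data, truth = planted_blocks(rng, [60, 60])
        tom = topological_overlap(adjacency_matrix(data, beta=17))
        labels = detect_modules(tom, min_module=50)
        assert set(labels) <= set(["turquoise", "blue", "grey"])
        for block in (0, 1):
            block_labels = labels[truth.index[truth == block]]
            assert block_labels.nunique() == 1
            assert block_labels.iloc[0] != "grey"
        assert (labels[truth.index[truth == 0]].iloc[0]
                != labels[truth.index[truth == 1]].iloc[0])

    def test_small_block_goes_grey(self):
        rng = np.random.default_rng(21)
        data, truth = planted_blocks(rng, [60, 10])
        tom = topological_overlap(adjacency_matrix(data, beta=17))
        labels = detect_modules(tom, min_module=50)
        assert (labels[truth.index[truth == 1]] == "grey").all()

    def test_deterministic(self):
        rng = np.random.default_rng(22)
        data, _ = planted_blocks(rng, [60, 55])
        tom = topological_overlap(adjacency_matrix(data, beta=6))
        l1 = detect_modules(tom)
        l2 = detect_modules(tom)
        pd.testing.assert_series_equal(l1, l2)

    def test_too_few_features_all_grey(self):
        rng = np.random.default_rng(23)
        data, _ = planted_blocks(rng, [10])
        tom = topological_overlap(adjacency_matrix(data, beta=6))
        log = []
        labels = detect_modules(tom, min_module=50, warnings_out=log)
        assert (labels == "grey").all() and log

    def test_oversized_cluster_recut(self):
        rng = np.random.default_rng(24)
        data, truth = planted_blocks(rng, [80, 80], noise=0.25)
        tom = topological_overlap(adjacency_matrix(data, beta=6))
        labels = detect_modules(tom, min_module=50, max_module=100)
        sizes = labels[labels != "grey"].value_counts()
        assert (sizes <= 100).all()
        assert len(sizes) >= 2


class TestMergeModules:
    def test_identical_eigengenes_merged(self):
        rng = np.random.default_rng(25)
        pattern = rng.normal(size=8)
        data = pd.DataFrame(
            [pattern + rng.normal(0, 0.05, 8) for _ in range(20)],
            index=[f"F{i}" for i in range(20)])
        labels = pd.Series(["m1"] * 10 + ["m2"] * 10, index=data.index)
        merged = merge_modules(data, labels, merge_cut=0.3)
        assert merged.nunique() == 1

    def test_distant_modules_not_merged(self):
        rng = np.random.default_rng(26)
        p1 = rng.normal(size=8)
        p2 = rng.normal(size=8)  # independent pattern: diss ~1 >> 0.3
        data = pd.DataFrame(
            [p1 + rng.normal(0, 0.05, 8) for _ in range(10)]
            + [p2 + rng.normal(0, 0.05, 8) for _ in range(10)],
            index=[f"F{i}" for i in range(20)])
        labels = pd.Series(["m1"] * 10 + ["m2"] * 10, index=data.index)
        merged = merge_modules(data, labels, merge_cut=0.3)
        assert merged.nunique() == 2

    def test_partition_independent_of_input_order(self):
        rng = np.random.default_rng(27)
        base = rng.normal(size=8)
        patterns = [base, base + rng.normal(0, 0.35, 8),
                    base + rng.normal(0, 0.35, 8)]
        rows, labs = [], []
        for i, p in enumerate(patterns):
            for _ in range(8):
                rows.append(p + rng.normal(0, 0.05, 8))
                labs.append(f"m{i}")
        data = pd.DataFrame(rows, index=[f"F{i:02d}" for i in range(24)])
        labels = pd.Series(labs, index=data.index)
        merged_fwd = merge_modules(data, labels, merge_cut=0.6)
        perm = list(rng.permutation(data.index))
        merged_rev = merge_modules(data.loc[perm], labels.loc[perm],
                                   merge_cut=0.6)
        fwd = merged_fwd.groupby(merged_fwd).groups
        rev = merged_rev.groupby(merged_rev).groups
        assert {frozenset(v) for v in fwd.values()} == \
               {frozenset(v) for v in rev.values()}


class TestTraitStatistics:
    def test_eigengene_equal_to_trait(self):
        trait = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], dtype=float)
        eigs = pd.DataFrame([(trait - trait.mean()) / np.linalg.norm(trait - trait.mean())],
                            index=["m1"])
        stats_ = module_trait_statistics(eigs, trait)
        assert stats_.at["m1", "r"] == pytest.approx(1.0)
        assert stats_.at["m1", "p"] < 1e-9

    def test_orthogonal_eigengene(self):
        trait = np.array([0.0, 0, 1, 1, 2, 2])
        orth = np.array([1.0, -1, 1, -1, 1, -1])
        stats_ = module_trait_statistics(pd.DataFrame([orth / np.linalg.norm(orth)],
                                                      index=["m1"]), trait)
        assert stats_.at["m1", "r"] == pytest.approx(0.0, abs=1e-12)
        assert stats_.at["m1", "p"] == pytest.approx(1.0)

    def test_constant_trait_rejected(self):
        eigs = pd.DataFrame([[0.5, 0.5, -0.5, -0.5]], index=["m1"])
        with pytest.raises(ValueError, match="constant"):
            module_trait_statistics(eigs, np.ones(4))

    def test_planted_positive_module_strongly_correlated(self):
        """A single planted trait-tracking module yields eigengene-trait
        r > 0.9 at p < 0.001."""
        from adipoptm.simulate import SimulationConfig, generate_dataset
        cfg = SimulationConfig(n_proteins=200,
                               module_spec=(("m1", 60, +1, 1.5),),
                               module_orth_scale=0.0, noise_sd=0.5,
                               missing_low_quantile=0.0,
                               sporadic_missing_rate=0.0,
                               n_genesets=3, geneset_size_range=(3, 5),
                               geneset_amplitude=0.0, seed=31)
        ds = generate_dataset(cfg)
        members = [f for f, m in ds.truth.module_of.items() if m == "m1"
                   and f.startswith("PROT:")]
        sub = ds.proteome.values.loc[[f.split(":", 1)[1] for f in members]]
        eig, _ = module_eigengene(sub)
        trait = ds.design["time_code"].to_numpy(float)
        stats_ = module_trait_statistics(pd.DataFrame([eig], index=["m1"]),
                                         trait)
        assert stats_.at["m1", "r"] > 0.9
        assert stats_.at["m1", "p"] < 0.001


class TestKmeGs:
    def test_feature_equal_to_eigengene_and_trait(self):
        trait = np.array([0.0, 0, 1, 1, 2, 2])
        rng = np.random.default_rng(28)
        data = pd.DataFrame(rng.normal(size=(5, 6)),
                            index=[f"F{i}" for i in range(5)])
        data.loc["F0"] = trait
        eig = (trait - trait.mean())
        eig /= np.linalg.norm(eig)
        eigs = pd.DataFrame([eig], index=["m1"])
        kme, kme_p, gs, gs_p = kme_gs(data, eigs, trait)
        assert kme.at["F0", "m1"] == pytest.approx(1.0)
        assert gs["F0"] == pytest.approx(1.0)

    def test_constant_feature_flagged_nan(self):
        trait = np.array([0.0, 1, 2, 0, 1, 2])
        data = pd.DataFrame([[7.0] * 6], index=["F0"])
        eigs = pd.DataFrame([np.ones(6) / np.sqrt(6)], index=["m1"])
        kme, _, gs, _ = kme_gs(data, eigs, trait)
        assert np.isnan(kme.at["F0", "m1"]) and np.isnan(gs["F0"])

    def test_planted_features_peak_at_own_module(self, dataset, processed,
                                                 fitted_network):
        net = fitted_network
        truth = dataset.truth.module_of.reindex(net.kme_.index)
        checked = 0
        for feature in net.kme_.index:
            if truth[feature] == "grey":
                continue
            detected = net.labels_[feature]
            if detected == "grey":
                continue
            # signed membership: own-module kME is the largest *signed* kME
            assert net.kme_.loc[feature].idxmax() == detected
            checked += 1
        assert checked > 200


class TestKeyDrivers:
    def make_setup(self):
        rng = np.random.default_rng(29)
        trait = np.repeat([0.0, 1, 2], 3)
        data = pd.DataFrame(rng.normal(size=(120, 9)),
                            index=[f"PROT:P{i:03d}" for i in range(120)])
        # module of 100 features tracking the trait
        for i in range(100):
            data.iloc[i] = trait * 2 + rng.normal(0, 0.4, 9)
        labels = pd.Series(["mod"] * 100 + ["grey"] * 20, index=data.index)
        eig, _ = module_eigengene(data.iloc[:100])
        eigs = pd.DataFrame([eig], index=["mod"])
        kme, _, gs, _ = kme_gs(data, eigs, trait)
        tom = topological_overlap(adjacency_matrix(data, beta=6))
        return data, labels, kme, gs, tom

    def test_top30_from_module_of_100(self):
        data, labels, kme, gs, tom = self.make_setup()
        kd = select_key_drivers(labels, kme, gs, tom, "mod")
        assert len(kd.nodes) == 30
        assert list(kd.nodes["rank"]) == list(range(1, 31))
        assert (kd.nodes["layer"] == "proteome").all()

    def test_perfect_feature_ranks_first(self):
        data, labels, kme, gs, tom = self.make_setup()
        kme.loc["PROT:P007", "mod"] = 1.0
        gs["PROT:P007"] = 1.0
        kd = select_key_drivers(labels, kme, gs, tom, "mod")
        assert kd.nodes.index[0] == "PROT:P007"

    def test_edges_rescaled_and_flagged(self):
        data, labels, kme, gs, tom = self.make_setup()
        kd = select_key_drivers(labels, kme, gs, tom, "mod",
                                edge_emphasis_threshold=0.5)
        assert len(kd.edges) == 30 * 29 // 2
        assert kd.edges["weight"].between(0, 1).all()
        assert (kd.edges["emphasized"] == (kd.edges["weight"] >= 0.5)).all()

    def test_tie_break_lexicographic(self):
        data, labels, kme, gs, tom = self.make_setup()
        kme.loc[:, "mod"] = 0.5
        gs.loc[:] = 0.5
        kd = select_key_drivers(labels, kme, gs, tom, "mod", n_key_drivers=5)
        members = sorted(labels.index[labels == "mod"], key=str)
        assert list(kd.nodes.index) == members[:5]

    def test_small_module_returns_all_with_warning(self):
        data, labels, kme, gs, tom = self.make_setup()
        labels[:] = "grey"
        labels.iloc[:7] = "tiny"
        kme["tiny"] = kme["mod"]
        log = []
        kd = select_key_drivers(labels, kme, gs, tom, "tiny",
                                warnings_out=log)
        assert len(kd.nodes) == 7 and log


class TestFeatureSpace:
    def test_concatenation_and_prefixes(self):
        prot = small_matrix(np.ones((3, 2)), features=["A", "B", "C"])
        ack = small_matrix(np.ones((2, 2)), features=["A_K1", "B_K2"])
        pp = small_matrix(np.ones((1, 2)), features=["A_S3"])
        combined = build_feature_space(prot, ack, pp)
        assert combined.shape == (6, 2)
        assert list(combined.index[:3]) == ["PROT:A", "PROT:B", "PROT:C"]
        assert "ACK:A_K1" in combined.index and "PP:A_S3" in combined.index

    def test_duplicate_ids_across_layers_disambiguated(self):
        prot = small_matrix(np.ones((1, 2)), features=["X_K1"])
        ack = small_matrix(np.zeros((1, 2)), features=["X_K1"])
        pp = small_matrix(np.ones((1, 2)), features=["Y_S1"])
        combined = build_feature_space(prot, ack, pp)
        assert combined.index.is_unique

    def test_missing_values_rejected(self):
        prot = small_matrix([[1.0, np.nan]], features=["A"])
        ack = small_matrix(np.ones((1, 2)), features=["A_K1"])
        pp = small_matrix(np.ones((1, 2)), features=["A_S1"])
        with pytest.raises(ValueError, match="missing"):
            build_feature_space(prot, ack, pp)

    def test_sample_mismatch_rejected(self):
        prot = small_matrix(np.ones((1, 2)), features=["A"])
        ack = small_matrix(np.ones((1, 2)), features=["A_K1"],
                           samples=["X", "Y"])
        pp = small_matrix(np.ones((1, 2)), features=["A_S1"])
        with pytest.raises(ValueError, match="sample"):
            build_feature_space(prot, ack, pp)


class TestEstimator:
    def test_deterministic_fit(self, processed):
        X, trait = processed["network_input"], processed["trait"]
        n1 = WeightedCoabundanceNetwork().fit(X, trait)
        n2 = WeightedCoabundanceNetwork().fit(X, trait)
        pd.testing.assert_series_equal(n1.labels_, n2.labels_)
        pd.testing.assert_frame_equal(n1.eigengenes_, n2.eigengenes_)
        pd.testing.assert_frame_equal(n1.module_trait_, n2.module_trait_)

    def test_sklearn_params_round_trip(self):
        net = WeightedCoabundanceNetwork(soft_power=6, merge_cut=0.2)
        params = net.get_params()
        assert params["soft_power"] == 6
        clone = WeightedCoabundanceNetwork(**params)
        assert clone.get_params() == params

    def test_eigengenes_unit_norm_and_trait_bounds(self, fitted_network):
        net = fitted_network
        norms = np.linalg.norm(net.eigengenes_.to_numpy(), axis=1)
        assert np.allclose(norms, 1.0)
        assert net.module_trait_["r"].abs().le(1.0).all()

    def test_module_sizes_within_bounds(self, fitted_network):
        sizes = fitted_network.labels_.value_counts().drop("grey",
                                                           errors="ignore")
        assert (sizes >= 50).all() and (sizes <= 500).all()
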