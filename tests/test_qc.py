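import numpy as np
import pandas as pd
import pytest

from orthomapper import (
    ClusterLabeling,
    ConversionPolicy,
    ConversionWarning,
    SimulationDesign,
    TableDesign,
    ValidationError,
    adjusted_rand_index,
    biotype_retention,
    cluster_observations,
    concordance_report,
    convert_matrix,
    gene_mapping_rate,
    per_observation_efficiency,
    pseudobulk_efficiency,
    rand_index,
    simulate_counts,
    simulate_marker_groups,
    simulate_ortholog_table,
)
from tests.conftest import make_matrix, make_table, random_instance
from tests.oracles import pair_enumeration_rand


def labeling(labels):
    return ClusterLabeling([f"c{i}" for i in range(len(labels))], list(labels))


class TestEfficiency:
    def test_identity_conversion_is_100_percent(self):
        X = make_matrix(["Aa", "Bb"], [[1, 2], [3, 4]])
        res = convert_matrix(X, make_table([("Aa", "AA"), ("Bb", "BB")]))
        assert pseudobulk_efficiency(X, res.converted) == 100.0
        assert np.all(per_observation_efficiency(X, res.converted) == 100.0)

    def test_half_the_counts_unmapped_gives_50_percent(self):
        X = make_matrix(["Aa", "Zz"], [[3, 2], [4, 1]])  # equal feature totals
        res = convert_matrix(X, make_table([("Aa", "AA")], ["Zz"]))
        assert pseudobulk_efficiency(X, res.converted) == 50.0

    def test_empty_source_matrix_errors(self):
        X = make_matrix(["A"], [[0, 0]])
        Y = make_matrix(["B"], [[0, 0]])
        with pytest.raises(ValidationError, match="empty source"):
            pseudobulk_efficiency(X, Y)

    def test_zero_count_observation_is_undefined_not_zero(self):
        X = make_matrix(["Aa", "Zz"], [[2, 0], [0, 0]])
        res = convert_matrix(X, make_table([("Aa", "AA")], ["Zz"]))
        with pytest.warns(ConversionWarning, match="undefined"):
            eff = per_observation_efficiency(X, res.converted)
        assert eff[0] == 100.0 and np.isnan(eff[1])

    def test_observation_with_only_unmapped_counts_is_0_percent(self):
        X = make_matrix(["Aa", "Zz"], [[2, 0], [0, 5]])
        res = convert_matrix(X, make_table([("Aa", "AA")], ["Zz"]))
        eff = per_observation_efficiency(X, res.converted)
        assert eff.tolist() == [100.0, 0.0]

    def test_matches_dense_oracle_on_random_instances(self, rng):
        from orthomapper import NoFeaturesMappedError

        for _ in range(20):
            X, table = random_instance(rng, max_genes=25, max_obs=10)
            try:
                res = convert_matrix(X, table)
            except NoFeaturesMappedError:
                continue
            xd, yd = X.counts.toarray(), res.converted.counts.toarray()
            if xd.sum() == 0:
                continue
            assert pseudobulk_efficiency(X, res.converted) == pytest.approx(
                100.0 * yd.sum() / xd.sum()
            )
            with np.errstate(invalid="ignore"), pytest.warns() if (
                xd.sum(axis=0) == 0
            ).any() else np.errstate():
                eff = per_observation_efficiency(X, res.converted)
            expected = 100.0 * yd.sum(axis=0) / np.where(
                xd.sum(axis=0) == 0, np.nan, xd.sum(axis=0)
            )
            assert np.allclose(eff, expected, equal_nan=True)

    def test_pseudobulk_is_count_weighted_mean_of_per_obs(self, rng):
        X, table = random_instance(rng, max_genes=30, max_obs=12)
        from orthomapper import NoFeaturesMappedError

        try:
            res = convert_matrix(X, table)
        except NoFeaturesMappedError:
            pytest.skip("degenerate instance")
        if X.total() == 0:
            pytest.skip("degenerate instance")
        weights = X.obs_totals().astype(float)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            eff = per_observation_efficiency(X, res.converted)
        ok = ~np.isnan(eff)
        assert pseudobulk_efficiency(X, res.converted) == pytest.approx(
            float(np.sum(eff[ok] * weights[ok]) / X.total())
        )


class TestMappingRate:
    def test_simple_fractions(self):
        table = make_table([("A", "H1"), ("B", "H2"), ("C", "H3")], ["D"])
        assert gene_mapping_rate(table, ["A", "B", "C", "D"]) == 75.0
        assert gene_mapping_rate(table, ["A", "B"]) == 100.0

    def test_designed_unmapped_fraction_recovered(self):
        design = TableDesign(
            n_one2one=30, n_one2many=5, n_many2many_blocks=1, block_size=5,
            n_unmapped=40, seed=3,
        )
        feats = [f"Gene{i:03d}" for i in range(design.n_consumed)]
        table, fates = simulate_ortholog_table(design, feats)
        p = sum(1 for f in fates.values() if f == "unmapped") / len(feats)
        assert gene_mapping_rate(table, feats) == 100.0 * (1 - p)


class TestBiotypeRetention:
    def test_protein_coding_kept_lncrna_lost(self):
        X = make_matrix(["Aa", "Bb"], [[1], [2]])
        meta = pd.DataFrame(
            {"biotype": ["protein_coding", "lncRNA"]}, index=["Aa", "Bb"]
        )
        res = convert_matrix(
            X, make_table([("Aa", "AA")], ["Bb"]), ConversionPolicy()
        )
        table = biotype_retention(X, res, meta).set_index("biotype")
        assert table.loc["protein_coding", "percent"] == 100.0
        assert table.loc["lncRNA", "percent"] == 0.0

    def test_no_metadata_pools_unknown_matching_mapping_rate(self):
        X = make_matrix(["Aa", "Bb", "Cc", "Dd"], [[1], [1], [1], [1]])
        t = make_table([("Aa", "AA"), ("Bb", "BB"), ("Cc", "CC")], ["Dd"])
        res = convert_matrix(X, t)
        table = biotype_retention(X, res)
        assert list(table["biotype"]) == ["unknown"]
        assert table["percent"].iloc[0] == gene_mapping_rate(t, X.feature_ids)

    def test_matches_bruteforce_tally(self, rng):
        from orthomapper import NoFeaturesMappedError

        X, t = random_instance(rng, max_genes=30, max_obs=5)
        biotypes = rng.choice(["protein_coding", "lncRNA", "pseudogene"], X.n_features)
        meta = pd.Series(biotypes, index=X.feature_ids)
        try:
            res = convert_matrix(X, t)
        except NoFeaturesMappedError:
            pytest.skip("degenerate instance")
        table = biotype_retention(X, res, meta).set_index("biotype")
        for bt in set(biotypes):
            members = [f for f, b in zip(X.feature_ids, biotypes) if b == bt]
            kept = sum(1 for f in members if res.plan.fates[f].status == "kept")
            assert table.loc[bt, "n_in"] == len(members)
            assert table.loc[bt, "n_retained"] == kept


class TestRandIndex:
    def test_identical_labelings_are_1(self):
        L = labeling([1, 1, 2, 2, 3])
        assert rand_index(L, L) == 1.0
        assert adjusted_rand_index(L, L) == 1.0

    def test_worked_example_one_block_vs_two(self):
        L1 = labeling([0, 0, 0, 0])
        L2 = labeling([1, 1, 2, 2])
        assert rand_index(L1, L2) == pytest.approx(2 / 6)

    def test_all_singletons_agree(self):
        L1 = labeling([0, 1, 2, 3])
        L2 = labeling(["w", "x", "y", "z"])
        assert rand_index(L1, L2) == 1.0

    def test_matches_pair_enumeration_on_small_random_labelings(self, rng):
        for _ in range(120):
            n = int(rng.integers(2, 13))
            l1 = rng.integers(0, 4, size=n).tolist()
            l2 = rng.integers(0, 4, size=n).tolist()
            assert rand_index(labeling(l1), labeling(l2)) == pytest.approx(
                pair_enumeration_rand(l1, l2)
            )

    def test_symmetry_and_label_renaming_invariance(self, rng):
        l1 = rng.integers(0, 3, size=40).tolist()
        l2 = rng.integers(0, 3, size=40).tolist()
        a, b = labeling(l1), labeling(l2)
        renamed = labeling([f"x{v}" for v in l1])
        for fn in (rand_index, adjusted_rand_index):
            assert fn(a, b) == pytest.approx(fn(b, a))
            assert fn(renamed, b) == pytest.approx(fn(a, b))

    def test_ari_zero_when_one_side_constant(self):
        L1 = labeling([0] * 6)
        L2 = labeling([0, 0, 1, 1, 2, 2])
        assert adjusted_rand_index(L1, L2) == 0.0

    def test_obs_alignment_and_errors(self):
        L1 = ClusterLabeling(["a", "b", "c"], [1, 1, 2])
        L2 = ClusterLabeling(["c", "a", "b"], [2, 1, 1])  # same partition, reordered
        assert rand_index(L1, L2) == 1.0
        L3 = ClusterLabeling(["a", "b", "zzz"], [1, 1, 2])
        with pytest.raises(ValidationError, match="zzz"):
            rand_index(L1, L3)
        with pytest.raises(ValidationError, match="at least 2"):
            rand_index(ClusterLabeling(["a"], [1]), ClusterLabeling(["a"], [1]))


class TestClustering:
    PARAMS = dict(n_top_genes=120, n_components=10, k_neighbors=10, resolution=0.8)

    def test_recovers_well_separated_groups(self):
        X, labels = simulate_counts(
            SimulationDesign(
                n_genes=200, n_cells=120, n_groups=3, de_fraction=0.4,
                lfc_scale=4.0, nb_dispersion=50.0, seed=11,
            )
        )
        found = cluster_observations(X, seed=0, **self.PARAMS)
        truth = ClusterLabeling(X.obs_ids, labels)
        assert adjusted_rand_index(found, truth) == 1.0

    def test_same_seed_same_labels(self):
        X, _ = simulate_counts(
            SimulationDesign(n_genes=120, n_cells=60, n_groups=2, seed=5)
        )
        a = cluster_observations(X, seed=3, **self.PARAMS)
        b = cluster_observations(X, seed=3, **self.PARAMS)
        assert a.labels == b.labels

    def test_bijective_renaming_preserves_labels(self):
        X, _ = simulate_counts(
            SimulationDesign(n_genes=150, n_cells=80, n_groups=3, seed=6)
        )
        table = make_table([(f, f.upper()) for f in X.feature_ids])
        res = convert_matrix(X, table)
        a = cluster_observations(X, seed=0, **self.PARAMS)
        b = cluster_observations(res.converted, seed=0, **self.PARAMS)
        assert a.labels == b.labels
        assert rand_index(a, b) == 1.0

    def test_too_few_observations_error(self):
        X, _ = simulate_counts(SimulationDesign(n_genes=30, n_cells=8, n_groups=2, seed=0))
        with pytest.raises(ValidationError, match="k_neighbors"):
            cluster_observations(X, k_neighbors=10)


class TestConcordance:
    PARAMS = dict(n_top_genes=120, n_components=10, k_neighbors=10, seed=0)

    def test_bijective_conversion_concordance_is_1(self):
        X, _ = simulate_counts(
            SimulationDesign(n_genes=150, n_cells=80, n_groups=3, seed=8)
        )
        res = convert_matrix(X, make_table([(f, f.upper()) for f in X.feature_ids]))
        rep = concordance_report(X, res, **self.PARAMS)
        assert rep["rand_index"] == 1.0
        assert rep["adjusted_rand_index"] == 1.0
        assert rep["n_clusters_pre"] == rep["n_clusters_post"]

    def test_dropping_group_markers_degrades_concordance(self):
        # groups are separable only through their private marker blocks;
        # dropping the blocks of grp0 and grp1 forces those groups to merge
        X, labels, markers = simulate_marker_groups(
            n_base_genes=120, n_markers_per_group=25, n_groups=3, n_cells=150, seed=9
        )
        lost = set(markers["grp0"]) | set(markers["grp1"])
        pairs = [(f, f.upper()) for f in X.feature_ids if f not in lost]
        res = convert_matrix(X, make_table(pairs, sorted(lost)))
        rep = concordance_report(X, res, **self.PARAMS)
        assert rep["adjusted_rand_index"] < 1.0

    def test_report_consistent_with_direct_indices(self):
        X, _ = simulate_counts(
            SimulationDesign(n_genes=100, n_cells=60, n_groups=2, seed=10)
        )
        res = convert_matrix(X, make_table([(f, f.upper()) for f in X.feature_ids]))
        rep = concordance_report(X, res, **self.PARAMS)
        pre = cluster_observations(X, **self.PARAMS)
        post = cluster_observations(res.converted, **self.PARAMS)
        assert rep["rand_index"] == rand_index(pre, post)
        assert rep["adjusted_rand_index"] == adjusted_rand_index(pre, post)
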