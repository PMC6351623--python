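import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix, make_meta
from dripseq import diffexpr
from dripseq.counting import CountMatrix
from dripseq.diffexpr import SizeFactors, size_factors_median_of_ratios
from dripseq.intron_dr import (
    cluster_fold_changes,
    coa_library_clustering,
    correspondence_analysis,
    discretize_quantiles,
    dr_test,
    restrict_to_nonde,
    union_dr,
)
from dripseq.synthetic_data import (
    dr_benchmark_scenario,
    shifted_mass_scenario,
    simulate_annotation,
    simulate_counts,
)


def unit_sf(libs):
    return SizeFactors(pd.Series(1.0, index=list(libs)), "total_count")


class TestDrTest:
    def test_constant_intron_not_dr(self):
        cm = make_matrix(np.full((1, 6), 30))
        res = dr_test(cm, unit_sf(cm.library_ids), "c", "m")
        assert res.loc["f0", "log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert not res.loc["f0", "significant"]

    def test_eightfold_retention_detected_with_direction(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(60, size=(30, 6))
        hit = np.hstack([rng.poisson(60, size=(1, 3)),
                         rng.poisson(480, size=(1, 3))])
        cm = make_matrix(np.vstack([base, hit]))
        res = dr_test(cm, unit_sf(cm.library_ids), "c", "m")
        assert res.loc["f30", "significant"]
        assert res.loc["f30", "direction"] == "more_retained"

    def test_library_mismatch_is_hard_error(self):
        cm = make_matrix(np.full((1, 6), 30))
        sf = SizeFactors(pd.Series(1.0, index=["other_1", "other_2"]),
                         "total_count")
        with pytest.raises(ValueError, match="do not cover"):
            dr_test(cm, sf, "c", "m")

    def test_gene_factors_recover_truth_under_global_retention_shift(self):
        # mutant retains every intron 4x more; gene depth unchanged.
        sc = shifted_mass_scenario(seed=5)
        genes, introns = simulate_annotation(sc)
        gcm, icm, truth = simulate_counts(sc, genes, introns)
        kept, _ = diffexpr.low_count_filter(gcm)
        gene_sf = size_factors_median_of_ratios(gcm.subset_features(kept))
        ikept, _ = diffexpr.low_count_filter(icm)
        isub = icm.subset_features(ikept)
        res_gene = dr_test(isub, gene_sf, "ku70", "shifted")
        res_sub = dr_test(isub, size_factors_median_of_ratios(isub),
                          "ku70", "shifted")
        bias_gene = (res_gene["log2fc"] - 2.0).mean()
        bias_sub = (res_sub["log2fc"] - 2.0).mean()
        assert abs(bias_gene) <= 0.2
        assert abs(bias_sub) > 1.0  # subset normalization absorbs the shift

    def test_invariant_to_joint_library_rescaling(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(500, size=(20, 6))
        cm = make_matrix(counts)
        sf = unit_sf(cm.library_ids)
        res1 = dr_test(cm, sf, "c", "m")
        scaled = counts.copy()
        scaled[:, 2] *= 2
        s2 = pd.Series(1.0, index=cm.library_ids)
        s2.iloc[2] = 2.0
        cm2 = make_matrix(scaled)
        res2 = dr_test(cm2, SizeFactors(s2 / np.exp(np.mean(np.log(s2))),
                                        "total_count"), "c", "m")
        # exact in the Poisson limit; NB re-weighting leaves a small residual
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=0.05)


class TestUnionDr:
    def _result(self, introns, sig, lfc=1.0):
        df = pd.DataFrame({"log2fc": lfc, "significant": False},
                          index=introns)
        df.loc[sig, "significant"] = True
        return df

    def test_empty_union(self):
        res = {m: self._result(["a", "b"], []) for m in ["m1", "m2"]}
        union, fc = union_dr(res)
        assert union == [] and fc.empty

    def test_single_mutant_significance_included(self):
        res = {"m1": self._result(["a", "b"], []),
               "m2": self._result(["a", "b"], ["b"])}
        union, fc = union_dr(res)
        assert union == ["b"]

    def test_set_union_across_mutants(self):
        res = {"m1": self._result(["a", "b", "c"], ["a", "b"]),
               "m2": self._result(["a", "b", "c"], ["b", "c"])}
        union, fc = union_dr(res)
        assert union == ["a", "b", "c"]
        assert list(fc.columns) == ["m1", "m2"]
        assert fc.attrs["significant"].loc["a", "m2"] == False  # noqa: E712

    def test_mismatched_universes_rejected(self):
        res = {"m1": self._result(["a"], []), "m2": self._result(["b"], [])}
        with pytest.raises(ValueError, match="different intron universes"):
            union_dr(res)


class TestRestrictToNonDe:
    def _gene_de(self, status_map):
        return pd.DataFrame({"status": pd.Series(status_map)})

    def test_ns_host_kept_de_host_dropped(self):
        hosts = pd.Series({"i1": "g1", "i2": "g2", "i3": "g3"})
        gene_de = self._gene_de({"g1": "ns", "g2": "up", "g3": "filtered"})
        kept = restrict_to_nonde(["i1", "i2", "i3"], hosts, gene_de)
        assert kept == ["i1"]  # filtered hosts cannot be certified non-DE

    def test_unknown_host_is_hard_error(self):
        hosts = pd.Series({"i1": "g1"})
        gene_de = self._gene_de({"g1": "ns"})
        with pytest.raises(KeyError):
            restrict_to_nonde(["iX"], hosts, gene_de)
        with pytest.raises(KeyError):
            restrict_to_nonde(["i1"], pd.Series({"i1": "gX"}), gene_de)

    def test_constructed_truth_table(self):
        # 10 DR introns, 4 in DE genes -> 6 survive
        hosts = pd.Series({f"i{k}": f"g{k}" for k in range(10)})
        status = {f"g{k}": "ns" for k in range(10)}
        for k in (0, 3, 5, 7):
            status[f"g{k}"] = "up" if k % 2 == 0 else "down"
        kept = restrict_to_nonde([f"i{k}" for k in range(10)], hosts,
                                 self._gene_de(status))
        assert len(kept) == 6

    def test_retains_true_dr_introns_when_genes_not_de(self):
        sc = dr_benchmark_scenario(seed=21, direction="up")
        genes, introns = simulate_annotation(sc)
        gcm, icm, truth = simulate_counts(sc, genes, introns)
        kept, _ = diffexpr.low_count_filter(gcm)
        sf = size_factors_median_of_ratios(gcm.subset_features(kept))
        gene_de = diffexpr.de_analysis(gcm, "ku70", "mut", size_factors=sf)
        ikept, _ = diffexpr.low_count_filter(icm)
        res = dr_test(icm.subset_features(ikept), sf, "ku70", "mut")
        called = [i for i in res.index[res["significant"]]]
        hosts = pd.Series({i.intron_id: i.gene_id for i in introns})
        surviving = restrict_to_nonde(called, hosts, gene_de)
        true_called = set(called) & truth.true_dr("mut")
        assert len(set(surviving) & true_called) >= 0.95 * len(true_called)


class TestClusterFoldChanges:
    def test_identical_rows_merge_first_at_zero(self):
        fc = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]],
                          index=["a", "b", "c"], columns=["m1", "m2"])
        rows, cols = cluster_fold_changes(fc)
        first = rows.linkage[0]
        merged = {rows.labels[int(first[0])], rows.labels[int(first[1])]}
        assert merged == {"a", "b"}
        assert first[2] == pytest.approx(0.0)

    def test_hand_distance_matrix_first_merge(self):
        fc = pd.DataFrame([[0.0, 0.0], [0.0, 3.0], [4.0, 0.0]],
                          index=["a", "b", "c"], columns=["m1", "m2"])
        rows, _ = cluster_fold_changes(fc)
        first = rows.linkage[0]
        merged = {rows.labels[int(first[0])], rows.labels[int(first[1])]}
        assert merged == {"a", "b"}
        assert first[2] == pytest.approx(3.0)

    def test_sign_flipped_mutants_merge_last(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 2, size=20)
        fc = pd.DataFrame(
            {"m1": base, "m2": base + rng.normal(0, 0.1, 20), "m3": -base},
            index=[f"i{k}" for k in range(20)])
        _, cols = cluster_fold_changes(fc)
        last = cols.linkage[-1]
        # the final merge joins m3 against the (m1, m2) cluster
        singles = {int(last[0]), int(last[1])} & {0, 1, 2}
        assert {cols.labels[i] for i in singles} == {"m3"}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        fc = pd.DataFrame(rng.normal(size=(8, 3)),
                          index=[f"i{k}" for k in range(8)],
                          columns=["m1", "m2", "m3"])
        rows1, _ = cluster_fold_changes(fc)
        perm = fc.sample(frac=1.0, random_state=1)
        rows2, _ = cluster_fold_changes(perm)
        assert rows1.order == rows2.order


class TestCoaClustering:
    def test_duplicated_libraries_have_zero_distance(self):
        rng = np.random.default_rng(11)
        col = rng.poisson(30, size=200)
        counts = pd.DataFrame({"a": col, "b": col, "c": rng.poisson(30, 200)})
        meta = pd.DataFrame({"strain": ["s1", "s1", "s2"],
                             "replicate": ["1", "2", "1"]},
                            index=["a", "b", "c"])
        cm = CountMatrix(counts, pd.Series(1000, index=counts.index), meta)
        coords, _ = coa_library_clustering(cm)
        d = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_identical_columns_all_distances_zero(self):
        col = np.arange(1, 51)
        counts = pd.DataFrame({f"l{i}": col for i in range(4)})
        meta = pd.DataFrame({"strain": "s", "replicate": "1"},
                            index=counts.columns)
        cm = CountMatrix(counts, pd.Series(1000, index=counts.index), meta)
        coords, clustering = coa_library_clustering(cm)
        if coords.shape[1]:
            assert np.allclose(coords.to_numpy(), coords.to_numpy()[0], atol=1e-9)

    def test_single_library_trivial_output(self):
        counts = pd.DataFrame({"only": [1, 2, 3]})
        meta = pd.DataFrame({"strain": "s", "replicate": "1"}, index=["only"])
        cm = CountMatrix(counts, pd.Series(1000, index=counts.index), meta)
        coords, clustering = coa_library_clustering(cm)
        assert clustering.order == ["only"]

    def test_replicates_cluster_by_strain_under_strong_effects(self):
        from scipy.cluster import hierarchy

        from dripseq.synthetic_data import SimulationScenario, StrainEffects

        strains = {"ku70": StrainEffects()}
        for name in ["upf1", "upf2", "mago", "y14"]:
            strains[name] = StrainEffects(de_fraction=0.5, de_log2_mean=3.0,
                                          de_log2_sd=0.3)
        sc = SimulationScenario(seed=13, n_genes=300, dispersion=0.01,
                                strains=strains)
        genes, introns = simulate_annotation(sc)
        gcm, _, _ = simulate_counts(sc, genes, introns)
        coords, clustering = coa_library_clustering(gcm)
        labels = hierarchy.fcluster(clustering.linkage, t=5,
                                    criterion="maxclust")
        by_strain = {}
        for lib, lab in zip(clustering.labels, labels):
            by_strain.setdefault(lib.rsplit("_", 1)[0], set()).add(lab)
        assert all(len(v) == 1 for v in by_strain.values())
        assert len(set.union(*by_strain.values())) == 5


class TestDiscretize:
    def test_zeros_form_their_own_level(self):
        counts = pd.DataFrame({"a": [0, 1, 5, 10, 50, 100]})
        levels = discretize_quantiles(counts)
        assert levels.loc[0, "a"] == 0
        assert levels.loc[1, "a"] >= 1
        assert levels["a"].max() <= 5

    def test_five_levels_over_nonzero_entries(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame({"a": rng.integers(1, 1000, size=500)})
        levels = discretize_quantiles(counts)
        assert set(levels["a"].unique()) == {1, 2, 3, 4, 5}

    def test_all_zero_table(self):
        counts = pd.DataFrame({"a": [0, 0]})
        assert (discretize_quantiles(counts) == 0).all().all()


def test_correspondence_analysis_reproduces_chi2_distances_structure():
    # two identical columns collapse onto the same point
    tbl = pd.DataFrame({"a": [5, 1, 3], "b": [5, 1, 3], "c": [1, 6, 2]})
    coords = correspondence_analysis(tbl)
    assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-12)
    assert not np.allclose(coords.loc["a"], coords.loc["c"], atol=1e-6)
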