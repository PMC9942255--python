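import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import AffinityPropagation

from spscreen import (
    CorrelationAPSelector,
    affinity_propagation_cluster,
    build_final_feature_set,
    correlation_partition,
    drop_invariant_features,
    select_cluster_representatives,
)
from spscreen.selection import Cluster, _similarity_matrix

from .oracles import affinity_propagation_bruteforce


def two_group_matrix(rng, n_rows=40, sizes=(3, 3), noise=0.01) -> pd.DataFrame:
    cols = {}
    for g, size in enumerate(sizes):
        base = rng.normal(size=n_rows)
        for i in range(size):
            cols[f"g{g}_{i}"] = base + rng.normal(0, noise, n_rows)
    return pd.DataFrame(cols)


class TestInvariantDrop:
    def test_constant_column_dropped(self, rng):
        df = pd.DataFrame({"var": rng.normal(size=10), "const": np.ones(10)})
        out, dropped = drop_invariant_features(df)
        assert dropped == ["const"] and list(out.columns) == ["var"]

    def test_varying_matrix_untouched(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        out, dropped = drop_invariant_features(df)
        assert dropped == [] and out.equals(df)


class TestCorrelationPartition:
    def test_duplicated_pair_is_redundant(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        independent, redundant = correlation_partition(df)
        assert sorted(redundant) == ["a", "b"] and independent == ["c"]

    def test_orthogonal_columns_all_independent(self):
        df = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        independent, redundant = correlation_partition(df)
        assert redundant == [] and sorted(independent) == ["a", "b"]

    def test_anticorrelation_counts_via_absolute_value(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=30)})
        _, redundant = correlation_partition(df)
        assert sorted(redundant) == ["a", "b"]

    def test_constant_column_directs_to_invariant_drop(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="drop_invariant_features"):
            correlation_partition(df)


class TestAffinityPropagation:
    def test_single_feature_is_its_own_exemplar(self, rng):
        df = pd.DataFrame({"only": rng.normal(size=10)})
        clusters = affinity_propagation_cluster(df)
        assert clusters == [Cluster(members=("only",), exemplar="only")]

    def test_identical_columns_collapse_to_one_cluster(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({f"c{i}": x for i in range(4)})
        clusters = affinity_propagation_cluster(df)
        assert len(clusters) == 1 and len(clusters[0].members) == 4

    @pytest.mark.parametrize("sizes", [(3, 3), (3, 4, 3)])
    def test_matches_sklearn_reference_on_separated_groups(self, rng, sizes):
        df = two_group_matrix(rng, sizes=sizes)
        clusters = affinity_propagation_cluster(df)
        pts = ((df - df.mean()) / df.std(ddof=0)).T.to_numpy()
        ref = AffinityPropagation(damping=0.5, random_state=0).fit(pts)
        ref_exemplars = sorted(df.columns[ref.cluster_centers_indices_])
        assert sorted(c.exemplar for c in clusters) == ref_exemplars
        # membership agrees too
        ref_members = {
            tuple(sorted(df.columns[ref.labels_ == k])) for k in range(len(ref_exemplars))
        }
        assert {tuple(sorted(c.members)) for c in clusters} == ref_members

    def test_matches_bruteforce_exemplar_objective_on_tiny_instances(self, rng):
        for trial in range(5):
            local = np.random.default_rng(trial)
            df = two_group_matrix(local, n_rows=12, sizes=(3, 3), noise=0.05)
            clusters = affinity_propagation_cluster(df)
            S = _similarity_matrix(df)
            pref = np.median(S)
            np.fill_diagonal(S, pref)
            best = affinity_propagation_bruteforce(S)
            assert sorted(c.exemplar for c in clusters) == sorted(df.columns[list(best)])


class TestRepresentatives:
    def make_clusters(self):
        return [
            Cluster(members=("a1", "a2"), exemplar="a1"),
            Cluster(members=tuple(f"b{i}" for i in range(7)), exemplar="b0"),
            Cluster(members=("c1",), exemplar="c1"),
        ]

    def test_default_takes_one_exemplar_per_cluster(self):
        assert select_cluster_representatives(self.make_clusters()) == ["a1", "b0", "c1"]

    def test_take_all_override_keeps_whole_cluster(self):
        reps = select_cluster_representatives(self.make_clusters(), overrides={"b0": "all"})
        assert len(reps) == 9 and all(f"b{i}" in reps for i in range(7))

    def test_extra_member_override(self):
        reps = select_cluster_representatives(self.make_clusters(), overrides={"a1": ["a2"]})
        assert reps == ["a1", "a2", "b0", "c1"]

    def test_unknown_feature_in_override_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            select_cluster_representatives(self.make_clusters(), overrides={"zz": "all"})

    def test_empty_cluster_list(self):
        assert select_cluster_representatives([]) == []


class TestFinalSet:
    def test_independent_features_plus_dummies_pass_through(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        dummies = [f"-3_{aa}" for aa in "ACDEF"]
        reduced, report = build_final_feature_set(df, dummies=dummies)
        assert len(report.final_set) == 10
        assert report.clusters == [] and report.representatives == []

    def test_duplicated_pair_collapses_to_one_representative(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-6, 40), "c": rng.normal(size=40)})
        reduced, report = build_final_feature_set(df)
        assert report.retained_low_corr == ["c"]
        assert len(report.representatives) == 1
        assert set(report.final_set) == {"c", report.representatives[0]}

    def test_every_feature_is_accounted_for(self, rng):
        df = two_group_matrix(rng, sizes=(3, 3))
        df["independent"] = rng.normal(size=len(df))
        df["constant"] = 1.0
        _, report = build_final_feature_set(df)
        clustered = {m for c in report.clusters for m in c.members}
        accounted = set(report.dropped_invariant) | set(report.retained_low_corr) | clustered
        assert accounted == set(df.columns)

    def test_no_retained_pair_exceeds_the_threshold(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"f{i}" for i in range(8)])
        df["f8"] = df["f0"] + rng.normal(0, 0.1, 60)  # strong correlate
        reduced, report = build_final_feature_set(df)
        corr = reduced[report.retained_low_corr].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.7

    def test_dummy_overlap_with_features_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            build_final_feature_set(df, dummies=["a"])

    def test_report_serializes_to_json(self, tmp_path, rng):
        df = two_group_matrix(rng)
        _, report = build_final_feature_set(df)
        report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").read_text().startswith("{")


class TestSelectorEstimator:
    def test_transform_returns_selected_columns_with_dummy_passthrough(self, rng):
        df = two_group_matrix(rng)
        df["solo"] = rng.normal(size=len(df))
        df["-1_A"] = rng.integers(0, 2, len(df)).astype(float)
        selector = CorrelationAPSelector().fit(df)
        out = selector.transform(df)
        assert "-1_A" in out.columns and "solo" in out.columns
        assert list(out.columns) == selector.selected_features_

    def test_representative_mapping_resolves_clustered_features(self, rng):
        df = two_group_matrix(rng)
        selector = CorrelationAPSelector().fit(df)
        for cluster in selector.report_.clusters:
            for member in cluster.members:
                assert selector.report_.representative_of(member) == cluster.exemplar
        assert selector.report_.representative_of("nonexistent") is None

    def test_get_set_params_round_trip(self):
        selector = CorrelationAPSelector(corr_threshold=0.5)
        params = selector.get_params()
        assert params["corr_threshold"] == 0.5
        selector.set_params(corr_threshold=0.9)
        assert selector.corr_threshold == 0.9
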