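"""Profile ingestion, envelope separation, UPGMA clustering, and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fluxspan.panels import DECREASED_IN_PATIENT, INCREASED_IN_PATIENT, PLASMA_METABOLITES
from fluxspan.profiles import (
    ProfileTable,
    load_profiles,
    pca_scores,
    separating_sets,
    two_way_cluster,
    write_profiles,
)


def make_table(values, samples=None, metabolites=None, groups=None) -> ProfileTable:
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    metabolites = metabolites or [f"m{j}" for j in range(values.shape[1])]
    groups = groups or {s: "other" for s in samples}
    return ProfileTable(pd.DataFrame(values, index=samples, columns=metabolites), groups)


class TestIngestion:
    def test_small_table_loads(self, tmp_path):
        (tmp_path / "p.tsv").write_text("\tm1\tm2\tm3\ns1\t1\t2\t3\ns2\t4\t5\t6\n")
        (tmp_path / "g.tsv").write_text("sample\tgroup\ns1\tcontrol\ns2\tpatient_pre\n")
        table = load_profiles(tmp_path / "p.tsv", tmp_path / "g.tsv")
        assert table.data.shape == (2, 3)
        assert table.groups == {"s1": "control", "s2": "patient_pre"}

    def test_missing_cell_drops_metabolite_with_warning(self, tmp_path):
        (tmp_path / "p.tsv").write_text("\tm1\tm2\ns1\t1\t\ns2\t4\t5\n")
        (tmp_path / "g.tsv").write_text("sample\tgroup\ns1\tcontrol\ns2\tcontrol\n")
        with pytest.warns(UserWarning, match="m2"):
            table = load_profiles(tmp_path / "p.tsv", tmp_path / "g.tsv")
        assert table.metabolites == ["m1"]

    def test_negative_concentration_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("\tm1\ns1\t-1\n")
        (tmp_path / "g.tsv").write_text("sample\tgroup\ns1\tcontrol\n")
        with pytest.raises(ValueError, match="negative"):
            load_profiles(tmp_path / "p.tsv", tmp_path / "g.tsv")

    def test_sample_without_group_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("\tm1\ns1\t1\ns2\t2\n")
        (tmp_path / "g.tsv").write_text("sample\tgroup\ns1\tcontrol\n")
        with pytest.raises(ValueError, match="s2"):
            load_profiles(tmp_path / "p.tsv", tmp_path / "g.tsv")

    def test_write_read_round_trip(self, tmp_path):
        table = make_table([[1.0, 2.5], [0.5, 4.0]])
        write_profiles(table, tmp_path / "p.tsv", tmp_path / "g.tsv")
        back = load_profiles(tmp_path / "p.tsv", tmp_path / "g.tsv")
        assert np.array_equal(back.data.values, table.data.values)
        assert back.groups == dict(table.groups)


class TestSeparatingSets:
    def test_recovers_the_printed_group_structure(self):
        """A fixture realizing the published relations: patient strictly above
        controls on the ketone-side pair, strictly below on seven amino-type
        metabolites."""
        metabolites = list(PLASMA_METABOLITES)
        rng = np.random.default_rng(11)
        controls = rng.uniform(1.0, 2.0, size=(7, len(metabolites)))
        patient = rng.uniform(1.2, 1.8, size=(2, len(metabolites)))
        for j, name in enumerate(metabolites):
            if name in INCREASED_IN_PATIENT:
                patient[:, j] = rng.uniform(2.5, 3.0, size=2)
            elif name in DECREASED_IN_PATIENT:
                patient[:, j] = rng.uniform(0.1, 0.5, size=2)
        samples = [f"c{i}" for i in range(7)] + ["p1", "p2"]
        table = make_table(np.vstack([controls, patient]), samples=samples, metabolites=metabolites)
        groups = separating_sets(table, [f"c{i}" for i in range(7)], ["p1", "p2"])
        assert groups.high_set == frozenset(INCREASED_IN_PATIENT)
        assert groups.low_set == frozenset(DECREASED_IN_PATIENT)

    def test_identical_groups_give_empty_sets(self):
        table = make_table([[1, 2], [1, 2], [1, 2], [1, 2]])
        groups = separating_sets(table, ["s0", "s1"], ["s2", "s3"])
        assert groups.high_set == frozenset() and groups.low_set == frozenset()

    def test_overlapping_groups_rejected(self):
        table = make_table([[1], [2]])
        with pytest.raises(ValueError, match="overlap"):
            separating_sets(table, ["s0"], ["s0"])

    @settings(max_examples=30, deadline=None)
    @given(values=arrays(np.float64, (6, 10), elements=st.floats(0.0, 100.0)))
    def test_matches_exhaustive_minmax_oracle(self, values):
        table = make_table(values)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        groups = separating_sets(table, a, b)
        high, low = set(), set()
        for j, name in enumerate(table.metabolites):  # brute-force scan
            va = [values[i, j] for i in range(3)]
            vb = [values[i, j] for i in range(3, 6)]
            if min(vb) > max(va):
                high.add(name)
            if max(vb) < min(va):
                low.add(name)
        assert groups.high_set == frozenset(high)
        assert groups.low_set == frozenset(low)

    def test_invariant_to_sample_and_metabolite_order(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 10, size=(6, 8))
        table = make_table(values)
        ref = separating_sets(table, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        perm_rows = ["s4", "s0", "s5", "s2", "s1", "s3"]
        perm_cols = list(np.array(table.metabolites)[rng.permutation(8)])
        shuffled = ProfileTable(table.data.loc[perm_rows, perm_cols], table.groups)
        out = separating_sets(shuffled, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert out == ref

    def test_enlarging_reference_group_only_shrinks_sets(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 10, size=(8, 12))
        table = make_table(values)
        b = ["s6", "s7"]
        small = separating_sets(table, ["s0", "s1"], b)
        large = separating_sets(table, ["s0", "s1", "s2", "s3", "s4", "s5"], b)
        assert large.high_set <= small.high_set
        assert large.low_set <= small.low_set


def brute_force_upgma(D: np.ndarray):
    """Reference UPGMA: average of all pairwise inter-cluster distances."""
    clusters = {i: [i] for i in range(D.shape[0])}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append((set(clusters[a]) | set(clusters[b]), d))
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    return merges


class TestClustering:
    def test_duplicate_rows_merge_first_at_zero_height(self):
        table = make_table([[1, 2, 3], [1, 2, 3], [9, 9, 9]])
        merges = two_way_cluster(table).sample_merges()
        left, right, height = merges[0]
        assert left | right == {"s0", "s1"}
        assert height == pytest.approx(0.0, abs=1e-12)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            two_way_cluster(make_table([[1, 2]]))

    def test_heights_match_brute_force_upgma(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(2)
        values = rng.uniform(0, 5, size=(6, 4))
        table = make_table(values)
        result = two_way_cluster(table, norm="infinity")
        D = squareform(pdist(values, "chebyshev"))
        expected = brute_force_upgma(D)
        got = result.sample_merges()
        label_to_idx = {s: i for i, s in enumerate(table.samples)}
        for (left, right, height), (members, ref_height) in zip(got, expected):
            assert {label_to_idx[s] for s in left | right} == members
            assert height == pytest.approx(ref_height, abs=1e-9)

    def test_merge_heights_are_nondecreasing_and_leaves_partition(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.uniform(0, 5, size=(7, 5)))
        merges = two_way_cluster(table).sample_merges()
        heights = [h for _, _, h in merges]
        assert heights == sorted(heights)
        final_left, final_right, _ = merges[-1]
        assert final_left | final_right == set(table.samples)

    def test_planted_outlier_pair_merges_first_then_outlier_joins_last(self):
        """Deterministic planted structure: two near-identical shifted samples
        cohere before touching anything else, and a strongly deviating sample
        joins the tree last — the qualitative two-group topology the study's
        dendrogram shows."""
        rng = np.random.default_rng(1)
        base = np.ones((4, 6)) + rng.uniform(0, 0.2, size=(4, 6))
        pre1 = np.full(6, 6.0)
        pre2 = np.full(6, 6.1)  # coherent pair, far from controls
        nf = np.full(6, 13.0)  # strongest deviation of all: joins last
        values = np.vstack([base, pre1, pre2, nf])
        samples = ["c0", "c1", "c2", "c3", "p1", "p2", "nf"]
        merges = two_way_cluster(make_table(values, samples=samples)).sample_merges()
        first_pre_merge = next(m for m in merges if {"p1", "p2"} & (m[0] | m[1]))
        assert first_pre_merge[0] | first_pre_merge[1] == {"p1", "p2"}
        last = merges[-1]
        assert frozenset({"nf"}) in (last[0], last[1])

    def test_newick_serialization_contains_all_leaves(self):
        table = make_table(np.random.default_rng(0).uniform(0, 1, (4, 3)))
        nwk = two_way_cluster(table).sample_newick()
        assert nwk.endswith(";") and all(s in nwk for s in table.samples)


class TestPca:
    def test_rank_one_data_puts_all_variance_on_pc1(self):
        values = np.ones((5, 4))
        values[:, 2] = [1, 2, 3, 4, 5]
        table = make_table(values)
        scores = pca_scores(table, 2)
        assert scores.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_scores_preserve_pairwise_distances(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 5, size=(6, 10))
        table = make_table(values)
        k = 5  # full rank for 6 samples
        scores = pca_scores(table, k).scores.values
        from scipy.spatial.distance import pdist

        centered = values - values.mean(axis=0)
        assert np.allclose(pdist(scores), pdist(centered), atol=1e-8)

    def test_duplicate_samples_land_on_identical_coordinates(self):
        values = np.vstack([[1, 2, 3], [1, 2, 3], [4, 5, 6], [0, 1, 0]])
        scores = pca_scores(make_table(values), 2).scores.values
        assert np.allclose(scores[0], scores[1], atol=1e-10)

    def test_k_out_of_range_rejected(self):
        table = make_table(np.ones((3, 4)) + np.eye(3, 4))
        with pytest.raises(ValueError, match="out of range"):
            pca_scores(table, 3)

    def test_explained_variance_fractions_are_valid(self):
        rng = np.random.default_rng(12)
        table = make_table(rng.uniform(0, 5, size=(8, 6)))
        evr = pca_scores(table, 4).explained_variance_ratio
        assert all(0 <= f <= 1 for f in evr)
        assert list(evr) == sorted(evr, reverse=True)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 5, size=(6, 5))
        a = pca_scores(make_table(values), 3)
        b = pca_scores(make_table(values), 3)
        assert np.array_equal(a.scores.values, b.scores.values)
        for col in a.loadings.columns:
            loading = a.loadings[col].values
            assert loading[np.argmax(np.abs(loading))] > 0
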