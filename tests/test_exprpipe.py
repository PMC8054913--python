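import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organodyn.exprpipe import (
    DROPPED,
    ClusterAssignment,
    FuzzyClusterModel,
    TemporalProfileSet,
    TpmMatrix,
    assign_clusters,
    compute_tpm,
    correlation_map,
    detect_shifts,
    enrich_terms,
    filter_abundance,
    filter_dynamic,
    filter_replicate_consistency,
    fuzzy_cmeans,
    intersect_tf,
    most_variable_genes,
    pca_projection,
    read_gmt,
    term_shift_graph,
    write_gmt,
    zscale_profiles,
)
from conftest import make_count_matrix


def _meta(samples):
    return [
        {"sample": s, "species": sp, "day": d, "replicate": r}
        for s, sp, d, r in samples
    ]


def _tpm_matrix(tpm: pd.DataFrame, meta_rows) -> TpmMatrix:
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return TpmMatrix(tpm=tpm, log2_tpm=np.log2(tpm + 1), sample_meta=meta)


class TestComputeTpm:
    def test_single_gene_takes_whole_sample(self):
        cm = make_count_matrix(
            {"s1": [7]},
            _meta([("s1", "human", 3, 1)]),
            {0: 500.0},
        )
        tm = compute_tpm(cm)
        assert tm.tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_length_normalization_hand_computed(self):
        cm = make_count_matrix(
            {"s1": [10, 10]},
            _meta([("s1", "human", 3, 1)]),
            {0: 1000.0, 1: 2000.0},
        )
        tm = compute_tpm(cm)
        assert tm.tpm["s1"].tolist() == pytest.approx([666666.666667, 333333.333333])

    def test_columns_sum_to_one_million(self, toy_counts):
        tm = compute_tpm(toy_counts)
        assert np.allclose(tm.tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_sample_names_offender(self):
        cm = make_count_matrix(
            {"ok": [5, 5], "dead": [0, 0]},
            _meta([("ok", "human", 3, 1), ("dead", "human", 5, 1)]),
            {0: 1000.0, 1: 1000.0},
        )
        with pytest.raises(ZeroDivisionError, match="dead"):
            compute_tpm(cm)


class TestZScale:
    def _profiles(self, values_by_day):
        tpm = pd.DataFrame(
            {f"h_d{d}_r1": [2.0**v - 1] for d, v in values_by_day.items()}
        )
        meta = _meta([(f"h_d{d}_r1", "human", d, 1) for d in values_by_day])
        tm = _tpm_matrix(tpm, meta)
        return zscale_profiles(tm)

    def test_linear_profile(self):
        prof = self._profiles({1: 1.0, 2: 2.0, 3: 3.0})
        assert prof.z.iloc[0].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_profile_flagged_zero(self):
        prof = self._profiles({1: 5.0, 2: 5.0, 3: 5.0})
        assert prof.z.iloc[0].tolist() == [0.0, 0.0, 0.0]
        assert bool(prof.constant.iloc[0])

    def test_hand_computed_skewed_profile(self):
        prof = self._profiles({1: 0.0, 2: 0.0, 3: 6.0})
        assert prof.z.iloc[0].tolist() == pytest.approx(
            [-0.57735, -0.57735, 1.154701], abs=1e-6
        )

    def test_rows_have_zero_mean_unit_sd(self, toy_counts):
        prof = zscale_profiles(compute_tpm(toy_counts))
        live = prof.z.loc[~prof.constant]
        assert np.allclose(live.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(live.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_mean_level_averages_replicates_first(self, toy_counts):
        prof = zscale_profiles(compute_tpm(toy_counts), level="mean")
        reps = prof.z.index.get_level_values("replicate").unique()
        assert list(reps) == ["mean"]


class TestVarianceAndProjections:
    def test_most_variable_returns_all_when_n_is_gene_count(self, toy_counts):
        tm = compute_tpm(toy_counts)
        assert set(most_variable_genes(tm, 4)) == set(toy_counts.genes)

    def test_most_variable_ranks_planted_variances(self):
        tpm = pd.DataFrame(
            {
                "s1": [100.0, 100.0, 100.0],
                "s2": [110.0, 180.0, 400.0],
            },
            index=["g1", "g2", "g3"],
        )
        tm = _tpm_matrix(tpm, _meta([("s1", "h", 3, 1), ("s2", "h", 5, 1)]))
        assert most_variable_genes(tm, 2) == ["g3", "g2"]

    def test_correlation_identical_and_negated_profiles(self):
        z = pd.DataFrame(
            {"a": [1.0, 0.0, -1.0], "b": [1.0, 0.0, -1.0], "c": [-1.0, 0.0, 1.0]}
        )
        corr = correlation_map(z)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_correlation_zero_variance_column_is_nan(self):
        z = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        corr = correlation_map(z)
        assert math.isnan(corr.loc["a", "flat"])
        assert corr.loc["flat", "flat"] == 1.0

    def test_pca_rank_one_input(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        mat = pd.DataFrame(
            {f"s{i}": (i + 1) * base for i in range(4)}
        )
        scores, evr = pca_projection(mat, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_pca_duplicate_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(30, 3)), columns=["s1", "s2", "s3"])
        mat["s4"] = mat["s1"]
        scores, _ = pca_projection(mat, 2)
        assert np.allclose(scores.loc["s1"], scores.loc["s4"])


def _two_species_tpm(gene_tpm: dict):
    """gene -> {species: {day: [per-replicate TPM]}} laid out as a TpmMatrix."""
    samples = []
    data = {}
    any_gene = next(iter(gene_tpm.values()))
    for sp in any_gene:
        for day in any_gene[sp]:
            for r, _ in enumerate(any_gene[sp][day], start=1):
                name = f"{sp}_d{day}_r{r}"
                samples.append((name, sp, day, r))
                data[name] = [gene_tpm[g][sp][day][r - 1] for g in gene_tpm]
    tpm = pd.DataFrame(data, index=list(gene_tpm))
    return _tpm_matrix(tpm, _meta(samples))


class TestAbundanceFilter:
    def test_brute_force_agreement_on_designed_patterns(self):
        days, reps = (3, 5, 10), 2
        gene_tpm = {
            "allhigh": {sp: {d: [50.0, 60.0] for d in days} for sp in ("h", "g")},
            "zero": {sp: {d: [0.0, 0.0] for d in days} for sp in ("h", "g")},
            "one_rep_low": {
                "h": {d: [50.0, 60.0] for d in days},
                "g": {3: [50.0, 5.0], 5: [60.0, 6.0], 10: [70.0, 7.0]},
            },
            "peak_only": {
                sp: {3: [1.0, 2.0], 5: [30.0, 40.0], 10: [1.0, 2.0]}
                for sp in ("h", "g")
            },
        }
        tm = _two_species_tpm(gene_tpm)
        report = filter_abundance(tm, threshold=10.0)

        survivors_oracle = set()
        for g, per_sp in gene_tpm.items():
            ok = all(
                any(per_sp[sp][d][r] > 10.0 for d in days)
                for sp in per_sp
                for r in range(reps)
            )
            if ok:
                survivors_oracle.add(g)
        assert set(report.genes_out) == survivors_oracle
        assert survivors_oracle == {"allhigh", "peak_only"}


class TestDynamicFilter:
    def test_flat_gene_removed_and_doubling_kept(self):
        days = (3, 5)
        gene_tpm = {
            "flat": {sp: {d: [100.0, 100.0] for d in days} for sp in ("h", "g")},
            "doubles_in_h": {
                "h": {3: [100.0, 100.0], 5: [200.0, 200.0]},
                "g": {3: [100.0, 100.0], 5: [100.0, 100.0]},
            },
        }
        tm = _two_species_tpm(gene_tpm)
        report = filter_dynamic(tm, fc=1.5)
        assert set(report.genes_out) == {"doubles_in_h"}

    def test_brute_force_with_pseudocount_straddling_threshold(self):
        days = (3, 5, 10)
        rng = np.random.default_rng(4)
        gene_tpm = {
            f"g{i}": {
                sp: {d: list(rng.uniform(5, 40, size=2)) for d in days}
                for sp in ("h", "g")
            }
            for i in range(12)
        }
        tm = _two_species_tpm(gene_tpm)
        report = filter_dynamic(tm, fc=1.5)

        oracle = set()
        for g, per_sp in gene_tpm.items():
            for sp in per_sp:
                means = {d: np.mean(per_sp[sp][d]) for d in days}
                for d1, d2 in itertools.combinations(days, 2):
                    hi, lo = max(means[d1], means[d2]), min(means[d1], means[d2])
                    if (hi + 1.0) / (lo + 1.0) > 1.5:
                        oracle.add(g)
        assert set(report.genes_out) == oracle


class TestConsistencyFilter:
    def _profiles(self, z_by_row):
        idx = pd.MultiIndex.from_tuples(
            list(z_by_row), names=["gene", "species", "replicate"]
        )
        z = pd.DataFrame(list(z_by_row.values()), index=idx, columns=[3, 5])
        return TemporalProfileSet(
            z=z, constant=pd.Series(False, index=idx), level="replicate"
        )

    def test_identical_replicates_have_zero_discordance(self):
        rows = {
            ("g1", sp, r): [1.0, -1.0] for sp in ("h", "g") for r in (1, 2, 3)
        }
        report = filter_replicate_consistency(self._profiles(rows), cutoff=6.0)
        assert report.genes_out == ("g1",)

    def test_hand_summed_pairwise_differences(self):
        # replicates offset by (0, 1, 2) at both timepoints:
        # pairs (0-1)^2+(0-2)^2+(1-2)^2 = 1+4+1 = 6 per timepoint, D = 12
        rows = {}
        for sp in ("h", "g"):
            for r, off in zip((1, 2, 3), (0.0, 1.0, 2.0)):
                rows[("g1", sp, r)] = [off, off]
        prof = self._profiles(rows)
        from organodyn.exprpipe import replicate_discordance

        disc = replicate_discordance(prof)
        assert disc.loc[("g1", "h"), "D"] == pytest.approx(12.0)
        report = filter_replicate_consistency(prof, cutoff=6.0)
        assert report.genes_out == ()

    def test_discordance_in_one_species_removes_gene(self):
        rows = {}
        for r in (1, 2, 3):
            rows[("g1", "h", r)] = [1.0, -1.0]
        for r, off in zip((1, 2, 3), (0.0, 2.0, 4.0)):
            rows[("g1", "g", r)] = [off, -off]
        report = filter_replicate_consistency(self._profiles(rows), cutoff=6.0)
        assert report.genes_out == ()


def _profile_set_from_array(X, genes, species=("h",), reps=(1,)):
    idx = pd.MultiIndex.from_tuples(
        [(g, sp, r) for g in genes for sp in species for r in reps],
        names=["gene", "species", "replicate"],
    )
    z = pd.DataFrame(X, index=idx, columns=range(X.shape[1]))
    return TemporalProfileSet(
        z=z, constant=pd.Series(False, index=idx), level="replicate"
    )


class TestFuzzyCMeans:
    def test_k1_collapses_to_plain_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        prof = _profile_set_from_array(X, [f"g{i}" for i in range(20)])
        model = fuzzy_cmeans(prof, k=1, seed=0)
        assert np.allclose(model.membership.to_numpy(), 1.0)
        assert np.allclose(model.centroids[0], X.mean(axis=0), atol=1e-9)

    def test_recovers_well_separated_clouds(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.1, size=(25, 2)), rng.normal(5, 0.1, size=(25, 2))]
        )
        prof = _profile_set_from_array(X, [f"g{i}" for i in range(50)])
        model = fuzzy_cmeans(prof, k=2, seed=3)
        hard = model.hard_labels().to_numpy()
        # oracle: nearest centroid by brute force
        d = ((X[:, None, :] - model.centroids[None]) ** 2).sum(-1)
        assert np.array_equal(hard, d.argmin(axis=1))
        # and the hard partition equals the planted one
        assert len(set(hard[:25])) == 1 and len(set(hard[25:])) == 1
        assert hard[0] != hard[-1]

    def test_memberships_row_normalized_and_objective_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        prof = _profile_set_from_array(X, [f"g{i}" for i in range(60)])
        model = fuzzy_cmeans(prof, k=4, seed=0)
        assert np.allclose(model.membership.sum(axis=1), 1.0, atol=1e-9)
        hist = np.array(model.objective_history)
        assert np.all(np.diff(hist) <= 1e-8 * hist[0])

    def test_profile_coincident_with_centroid_gets_unit_membership(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [4.0, 4.0], [4.0, 4.0]])
        prof = _profile_set_from_array(X, [f"g{i}" for i in range(5)])
        model = fuzzy_cmeans(prof, k=2, seed=0)
        u = model.membership.to_numpy()
        assert np.allclose(u.max(axis=1), 1.0, atol=1e-9)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        prof = _profile_set_from_array(X, [f"g{i}" for i in range(40)])
        m1 = fuzzy_cmeans(prof, k=3, seed=9)
        m2 = fuzzy_cmeans(prof, k=3, seed=9)
        pd.testing.assert_frame_equal(m1.membership, m2.membership)


def _model_with_labels(labels_by_gene_species, k=8):
    """Build a FuzzyClusterModel whose argmax labels match the given map."""
    rows, idx = [], []
    for (gene, sp), labels in labels_by_gene_species.items():
        for r, lab in enumerate(labels, start=1):
            u = np.full(k, 0.01)
            u[lab] = 1.0
            rows.append(u / u.sum())
            idx.append((gene, sp, r))
    membership = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(idx, names=["gene", "species", "replicate"]),
        columns=range(k),
    )
    return FuzzyClusterModel(
        k=k, m=2.0, centroids=np.zeros((k, 3)), membership=membership,
        objective_history=(0.0,), n_iter=1, converged=True, seed=0,
    )


class TestAssignmentAndShifts:
    @pytest.mark.parametrize(
        "labels,expected",
        [((3, 3, 5), 3), ((1, 2, 3), DROPPED), ((4, 4, 4), 4), ((2, 5, 5), 5)],
    )
    def test_majority_rule(self, labels, expected):
        model = _model_with_labels({("g1", "h"): labels})
        assign = assign_clusters(model)
        assert assign.table.loc[("g1", "h"), "assigned"] == expected

    def test_shift_classification_cases(self):
        model = _model_with_labels(
            {
                ("g1", "g"): (3, 3, 4),  # disjoint from h -> robust + assigned
                ("g1", "h"): (1, 1, 2),
                ("g2", "g"): (2, 2, 5),  # shares label 2 -> assigned only
                ("g2", "h"): (1, 1, 2),
                ("g3", "g"): (6, 6, 1),  # same majority -> neither
                ("g3", "h"): (6, 6, 6),
                ("g4", "g"): (1, 2, 3),  # dropped in g -> not evaluated
                ("g4", "h"): (5, 5, 5),
            }
        )
        shifts = detect_shifts(assign_clusters(model))
        assert shifts.robust_shift == {"g1"}
        assert shifts.assigned_shift == {"g1", "g2"}
        assert shifts.evaluated == {"g1", "g2", "g3"}

    @settings(max_examples=200, deadline=None)
    @given(
        la=st.lists(st.integers(0, 7), min_size=3, max_size=3),
        lb=st.lists(st.integers(0, 7), min_size=3, max_size=3),
    )
    def test_robust_shifts_are_assigned_shifts(self, la, lb):
        model = _model_with_labels({("g1", "h"): tuple(la), ("g1", "g"): tuple(lb)})
        shifts = detect_shifts(assign_clusters(model))
        assert shifts.robust_shift <= shifts.assigned_shift


def _hypergeom_tail_oracle(k, N, K, n):
    """Exhaustive enumeration of P(overlap >= k)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    ) / total


class TestEnrichment:
    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(0)
        for N in (8, 15, 25):
            universe = [f"g{i}" for i in range(N)]
            for _ in range(5):
                K = int(rng.integers(1, N))
                n = int(rng.integers(1, N))
                term = set(rng.choice(universe, size=K, replace=False))
                cluster = set(rng.choice(universe, size=n, replace=False))
                res = enrich_terms(cluster, {"t": term}, universe, correction="none")
                k = len(term & cluster)
                expected = _hypergeom_tail_oracle(k, N, K, n)
                assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:5])
        res = enrich_terms(term, {"t": term}, universe, correction="none")
        assert res["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_overlap_at_expectation_is_not_called(self):
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:10])
        cluster = set(universe[8:12])  # overlap 2 = n*K/N = 4*10/20
        res = enrich_terms(cluster, {"t": term}, universe)
        assert res["p"].iloc[0] >= 0.39
        assert not res["enriched"].iloc[0]

    def test_term_outside_universe_skipped(self):
        universe = ["g1", "g2", "g3"]
        res = enrich_terms(["g1"], {"ghost": {"x1", "x2"}}, universe)
        assert len(res) == 0

    def test_bh_adjustment_never_below_raw_p(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(40)]
        terms = {
            f"t{j}": set(rng.choice(universe, size=8, replace=False))
            for j in range(6)
        }
        cluster = set(rng.choice(universe, size=10, replace=False))
        res = enrich_terms(cluster, terms, universe)
        assert (res["adjusted_p"] >= res["p"] - 1e-12).all()


class TestTermShiftGraph:
    @staticmethod
    def _enr(rows):
        return pd.DataFrame(rows, columns=["cluster", "term", "enriched"])

    def test_no_exclusive_terms_gives_empty_graph(self):
        a = self._enr([(1, "t1", True)])
        b = self._enr([(1, "t1", True)])
        g = term_shift_graph(a, b)
        assert g.graph.number_of_edges() == 0
        assert g.shared == {"t1": (1,)}

    def test_single_exclusive_term_single_arc(self):
        a = self._enr([(4, "t1", True)])
        b = self._enr([(6, "t1", True)])
        g = term_shift_graph(a, b)
        assert g.heaviest_arc() == (4, 6, 1)
        assert g.graph[4][6]["terms"] == ["t1"]

    def test_weights_count_terms_per_arc(self):
        a = self._enr([(4, f"t{i}", True) for i in range(3)] + [(2, "x", True)])
        b = self._enr([(6, f"t{i}", True) for i in range(3)] + [(5, "x", True)])
        g = term_shift_graph(a, b)
        assert g.graph[4][6]["weight"] == 3
        assert g.heaviest_arc() == (4, 6, 3)


class TestSmallUtilities:
    def test_tf_intersection_identities(self):
        assert intersect_tf({"a", "b", "c"}, {"b", "c", "d"}, {"c"}) == ["c"]
        assert intersect_tf({"a"}, {"b"}, {"c"}) == []
        assert intersect_tf({"a"}, {"a"}, set()) == []

    def test_gmt_round_trip(self, tmp_path):
        term_map = {"t1": frozenset({"g1", "g2"}), "t2": frozenset({"g3"})}
        path = tmp_path / "sets.gmt"
        write_gmt(term_map, path)
        assert read_gmt(path) == term_map
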