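import numpy as np
import pytest
from scipy import stats

from modesign.analysis import (
    HypervolumeSpec,
    ecdf,
    effective_dimension_pca,
    hypervolume,
    hypervolume_exact,
    hypervolume_monte_carlo,
    interface_ddE,
    logit_effective_dimension,
    native_recovery,
    net_charge_count,
    normalized_similarity,
    per_position_entropy,
    percentile_similarity_to_set,
    posthoc_front_baseline,
    raw_similarity,
    representative_sequence,
    similarity_matrix,
    spectral_embedding,
)
from modesign.core import Population, SequenceIndividual, make_problem

from conftest import random_front


def pop_of(*seqs):
    return Population([SequenceIndividual(s) for s in seqs])


def problem_for(wt):
    n = len(wt)
    positions = tuple(range(1, n + 1))
    return make_problem(
        ("s",), positions, {"s": {p: (("A", p),) for p in positions}}, wt
    )


class TestRecovery:
    def test_wild_type_population_scores_one(self):
        prob = problem_for("ACDE")
        _, mean = native_recovery(pop_of("ACDE", "ACDE"), prob)
        assert mean == 1.0

    def test_single_mismatch_fraction(self):
        wt = "A" * 36
        prob = problem_for(wt)
        fracs, _ = native_recovery(pop_of("A" * 35 + "C"), prob)
        assert fracs[0] == pytest.approx(35 / 36)

    def test_disjoint_alphabet_scores_zero(self):
        prob = problem_for("AAAA")
        _, mean = native_recovery(pop_of("CCCC", "WWWW"), prob)
        assert mean == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            native_recovery(pop_of("AC"), problem_for("ACDE"))


class TestEntropy:
    def test_constant_column_zero(self):
        H = per_position_entropy(["AC", "AC", "AC"])
        np.testing.assert_allclose(H, 0.0)

    def test_uniform_composition_hits_ln20(self):
        from modesign.core import AMINO_ACIDS

        H = per_position_entropy(list(AMINO_ACIDS))
        assert H[0] == pytest.approx(np.log(20), abs=1e-12)

    def test_two_point_column(self):
        H = per_position_entropy(["A", "A", "C", "C"])
        assert H[0] == pytest.approx(np.log(2))

    def test_bounds_hold_on_random_populations(self):
        rng = np.random.default_rng(0)
        from modesign.core import AMINO_ACIDS

        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 10)) for _ in range(50)]
        H = per_position_entropy(seqs)
        assert np.all(H >= 0) and np.all(H <= np.log(20) + 1e-12)

    def test_ecdf_is_a_right_continuous_step_to_one(self):
        v, p = ecdf(np.array([3.0, 1.0, 2.0]))
        assert v.tolist() == [1.0, 2.0, 3.0]
        assert p.tolist() == [pytest.approx(1 / 3), pytest.approx(2 / 3), 1.0]


class TestSimilarity:
    def test_self_similarity_normalizes_to_one(self):
        for s in ("ACDE", "WWWW", "KRKR"):
            assert normalized_similarity(s, s) == pytest.approx(1.0)

    def test_raw_blosum_entry(self):
        assert raw_similarity("AA", "AA") == pytest.approx(4.0)

    def test_symmetry(self):
        assert normalized_similarity("ACDE", "WYKR") == pytest.approx(
            normalized_similarity("WYKR", "ACDE")
        )

    def test_matrix_matches_pairwise_function(self):
        seqs = ["ACDE", "ACDF", "WYKR"]
        S = similarity_matrix(seqs)
        for i in range(3):
            for j in range(3):
                assert S[i, j] == pytest.approx(
                    normalized_similarity(seqs[i], seqs[j])
                )


class TestSpectralEmbedding:
    def make_clustered(self):
        rng = np.random.default_rng(0)
        base = {
            0: "AAAAAAAAAA", 1: "WWWWWWWWWW", 2: "KKKKKKKKKK",
        }
        seqs, labels = [], []
        from modesign.core import AMINO_ACIDS

        for c, proto in base.items():
            for _ in range(10):
                s = list(proto)
                i = rng.integers(10)
                s[i] = rng.choice(list(AMINO_ACIDS))
                seqs.append("".join(s))
                labels.append(c)
        return seqs, np.array(labels)

    def test_separates_synthetic_clusters(self):
        from sklearn.metrics import silhouette_score

        seqs, labels = self.make_clustered()
        emb = spectral_embedding(similarity_matrix(seqs), 2)
        assert silhouette_score(emb, labels) > 0.5

    def test_duplicates_coincide(self):
        seqs = ["ACDE"] * 3 + ["WYKR"] * 3
        emb = spectral_embedding(similarity_matrix(seqs), 1)
        assert np.ptp(emb[:3, 0]) < 1e-8

    def test_permutation_equivariance_up_to_sign(self):
        seqs, _ = self.make_clustered()
        S = similarity_matrix(seqs)
        perm = np.random.default_rng(1).permutation(len(seqs))
        a = spectral_embedding(S, 1)[:, 0]
        b = spectral_embedding(S[np.ix_(perm, perm)], 1)[:, 0]
        aligned = b if np.dot(a[perm], b) >= 0 else -b
        np.testing.assert_allclose(a[perm], aligned, atol=1e-6)

    def test_disconnected_graph_reports_components(self):
        S = np.eye(4)
        with pytest.raises(ValueError, match="components"):
            spectral_embedding(S, 1, floor=0.0)


def grid_hypervolume(points, ref, n=400):
    """Rasterization oracle: fraction of a fine grid over [min, ref]
    dominated by the point set."""
    points = np.asarray(points, float)
    lo = points.min(axis=0)
    d = points.shape[1]
    axes = [np.linspace(lo[k], ref[k], n, endpoint=False)
            + (ref[k] - lo[k]) / (2 * n) for k in range(d)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
    hit = np.zeros(len(mesh), bool)
    for p in points:
        hit |= np.all(mesh >= p, axis=1)
    return hit.mean() * np.prod(ref - lo)


class TestHypervolume:
    def test_single_point_rectangle(self):
        hv = hypervolume_exact(np.array([[1.0, 1.0]]), np.array([4.0, 4.0]))
        assert hv == pytest.approx(9.0)

    def test_two_point_inclusion_exclusion(self):
        hv = hypervolume_exact(
            np.array([[1.0, 3.0], [3.0, 1.0]]), np.array([4.0, 4.0])
        )
        assert hv == pytest.approx(5.0)

    def test_empty_set_is_zero(self):
        spec = HypervolumeSpec(reference=np.array([4.0, 4.0]))
        assert hypervolume(np.empty((0, 2)), spec) == 0.0

    def test_non_contributing_points_add_nothing(self):
        base = np.array([[1.0, 1.0]])
        with_junk = np.vstack([base, [[5.0, 5.0]], [[2.0, 2.0]]])
        ref = np.array([4.0, 4.0])
        assert hypervolume_exact(with_junk, ref) == pytest.approx(
            hypervolume_exact(base, ref)
        )

    @pytest.mark.parametrize("d", [2, 3])
    def test_matches_grid_oracle(self, d):
        rng = np.random.default_rng(d)
        ref = np.full(d, 4.0)
        for _ in range(3):
            P = rng.uniform(0, 3.5, size=(5, d))
            exact = hypervolume_exact(P, ref)
            approx = grid_hypervolume(P, ref, n=200 if d == 2 else 60)
            assert exact == pytest.approx(approx, rel=0.05)

    def test_monotone_under_point_addition(self):
        rng = np.random.default_rng(0)
        ref = np.full(3, 4.0)
        for _ in range(10):
            P = rng.uniform(0, 3.5, size=(6, 3))
            hv_all = hypervolume_exact(P, ref)
            hv_sub = hypervolume_exact(P[:4], ref)
            assert hv_all >= hv_sub - 1e-12

    def test_higher_dimensional_slicing(self):
        # box [1,4]^5 from a single point: volume 3^5
        P = np.ones((1, 5))
        assert hypervolume_exact(P, np.full(5, 4.0)) == pytest.approx(3.0**5)

    def test_monte_carlo_tracks_exact(self):
        rng = np.random.default_rng(7)
        errs = []
        for seed in range(30):
            P = random_front(rng, 3, 3)
            ref = np.full(3, 4.0)
            e = hypervolume_exact(P, ref)
            if e <= 0:
                continue
            m = hypervolume_monte_carlo(P, ref, rng=seed)
            errs.append(abs(m - e) / e)
        assert np.quantile(errs, 0.95) <= 0.1


class TestPosthocBaseline:
    def test_degenerate_population(self):
        res = posthoc_front_baseline(
            ["AAAA"] * 10, np.ones((10, 2)), n_resamples=10
        )
        assert np.all(res.front_entropies == 0)
        assert np.all(res.baseline_entropies == 0)

    def test_front_equal_population_gives_identical_ecdf(self):
        rng = np.random.default_rng(0)
        seqs = ["ACDE", "WYKR", "AAAA"]
        F = random_front(rng, 3, 2)
        res = posthoc_front_baseline(seqs, F, n_resamples=5)
        assert sorted(res.front_indices) == [0, 1, 2]
        np.testing.assert_allclose(
            np.sort(np.unique(res.baseline_entropies)),
            np.sort(np.unique(res.front_entropies)),
        )

    def test_biased_front_detected_by_ks(self):
        # front members all share one letter at every position; the rest of
        # the population is diverse
        rng = np.random.default_rng(1)
        from modesign.core import AMINO_ACIDS

        front_seqs = ["A" * 8] * 10
        other = ["".join(rng.choice(list(AMINO_ACIDS), 8)) for _ in range(40)]
        seqs = front_seqs + other
        F = np.empty((50, 2))
        F[:10] = np.column_stack(
            [np.linspace(0, 1, 10), np.linspace(1, 0, 10)]
        )
        F[10:] = rng.uniform(2, 3, size=(40, 2))
        res = posthoc_front_baseline(seqs, F, n_resamples=50, rng=0)
        ks = stats.ks_2samp(
            res.front_entropies, res.baseline_entropies,
            alternative="greater",
        )
        assert ks.pvalue < 0.01
        assert res.front_entropies.mean() < res.baseline_entropies.mean()


class TestPercentileSimilarity:
    def test_query_in_refs(self):
        assert percentile_similarity_to_set("ACDE", ["ACDE"]) == pytest.approx(1.0)

    def test_constant_reference_set(self):
        v = percentile_similarity_to_set("ACDE", ["WYKR"] * 100)
        assert v == pytest.approx(normalized_similarity("ACDE", "WYKR"))

    def test_matches_sorted_interpolation_oracle(self):
        rng = np.random.default_rng(0)
        from modesign.core import AMINO_ACIDS

        refs = ["".join(rng.choice(list(AMINO_ACIDS), 6)) for _ in range(20)]
        query = "ACDEFG"
        sims = sorted(normalized_similarity(query, r) for r in refs)
        # linear interpolation at the 95th percentile of 20 order statistics
        h = 0.95 * 19
        expected = sims[19] * (h - 18) + sims[18] * (19 - h)
        assert percentile_similarity_to_set(query, refs) == pytest.approx(expected)

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            percentile_similarity_to_set("ACDE", [])


@pytest.mark.parametrize(
    "seq,expected", [("KKRR", 4), ("KDRE", 0), ("AAAA", 0), ("DDEE", -4)]
)
def test_net_charge_count(seq, expected):
    assert net_charge_count(seq) == expected


class TestRepresentativeSequence:
    def test_uniform_population(self):
        pop = pop_of("ACDE", "ACDE")
        assert representative_sequence(pop, "consensus") == "ACDE"
        assert representative_sequence(pop) == "ACDE"

    def test_hand_counted_consensus_and_nearest(self):
        pop = pop_of("AAC", "AAC", "ACC")
        assert representative_sequence(pop, "consensus") == "AAC"
        assert representative_sequence(pop) == "AAC"

    def test_column_tie_breaks_alphabetically(self):
        pop = pop_of("C", "A")
        assert representative_sequence(pop, "consensus") == "A"


class TestEffectiveDimensionPCA:
    def test_points_on_a_line(self):
        t = np.linspace(0, 1, 20)
        X = np.outer(t, np.array([1.0, 2.0, -1.0, 0.5, 3.0]))
        ratios, dim = effective_dimension_pca(X)
        assert dim == 1
        assert ratios[0] == pytest.approx(1.0)

    def test_isotropic_cloud_ratios(self):
        X = np.random.default_rng(0).normal(size=(500, 3))
        ratios, _ = effective_dimension_pca(X)
        assert np.all(np.abs(ratios - 1 / 3) < 0.05)

    def test_duplicated_axis_counts_once(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        b = rng.normal(size=200) * 0.01
        X = np.column_stack([a, a, b])
        ratios, dim = effective_dimension_pca(X)
        assert dim == 1

    def test_zero_variance(self):
        _, dim = effective_dimension_pca(np.ones((5, 3)))
        assert dim == 0


class TestLogitEffectiveDimension:
    def test_identical_vectors_one_cluster(self):
        v = np.tile(np.random.default_rng(0).normal(size=20), (4, 1))
        assert logit_effective_dimension(v, 0.8) == 1

    def test_two_orthogonal_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        group = np.vstack(
            [a + 0.01 * rng.normal(size=20) for _ in range(3)]
            + [b + 0.01 * rng.normal(size=20) for _ in range(3)]
        )
        assert logit_effective_dimension(group, 0.8) == 2

    def test_threshold_above_one_gives_singletons(self):
        v = np.tile(np.random.default_rng(0).normal(size=20), (4, 1))
        assert logit_effective_dimension(v, 1.0 + 1e-9) == 4

    def test_constant_vector_names_the_culprit(self):
        v = np.vstack([np.ones(20), np.random.default_rng(0).normal(size=20)])
        with pytest.raises(ValueError, match="flat_state"):
            logit_effective_dimension(v, 0.8, labels=["flat_state", "ok"])


class TestInterfaceDDE:
    def test_identical_inputs_give_zero(self):
        e = lambda x: float(sum(x))
        assert interface_ddE(e, [3], ([1], [2]), [3], ([1], [2])) == 0.0

    def test_additive_energy_has_no_interface(self):
        # E[C:P] = E[C] + E[P] always => ddE = 0 for any mutation
        e = lambda x: float(sum(x))
        assert interface_ddE(
            e, [10, 5], ([10], [5]), [8, 2], ([8], [2])
        ) == 0.0

    def test_single_contact_change(self):
        # toy contact energy: complexes carry an extra interface term
        def e(x):
            total = sum(x["parts"])
            total += x.get("interface", 0.0)
            return float(total)

        mut_c = {"parts": [1, 2], "interface": 3.0}
        wt_c = {"parts": [1, 2], "interface": 2.0}
        parts = ({"parts": [1]}, {"parts": [2]})
        assert interface_ddE(e, mut_c, parts, wt_c, parts) == pytest.approx(1.0)

    def test_energy_failure_propagates_with_label(self):
        def e(x):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="complex_mut"):
            interface_ddE(e, [1], ([1],), [1], ([1],))
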