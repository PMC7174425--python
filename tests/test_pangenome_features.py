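import itertools

import numpy as np
import pytest

from panarch import (
    GenePresenceMatrix,
    GeneAccumulation,
    PartitionThresholds,
    chao_lower_bound,
    classify_openness,
    compute_feature_set,
    core_nucleotide_diversity,
    fit_curve,
    functional_distance,
    genome_fluidity,
    normalized_sizes,
    partition_sizes,
    rarefaction,
)
from panarch.errors import AlignmentError
from panarch.pangenome_features import CurveFitResults

from conftest import random_matrix


def _matrix_from_counts(n_genomes, cluster_counts, species="sp"):
    """One cluster per entry, carried by the first `count` genomes."""
    P = np.zeros((n_genomes, len(cluster_counts)), dtype=bool)
    for j, c in enumerate(cluster_counts):
        P[:c, j] = True
    return GenePresenceMatrix(species, [f"g{i}" for i in range(n_genomes)],
                              [f"c{j}" for j in range(len(cluster_counts))], P)


class TestPartitionSizes:
    def test_frequency_rules(self):
        # 10 genomes: one cluster in all (core), one in 1/10 (cloud+unique)
        m = _matrix_from_counts(10, [10, 1])
        s = partition_sizes(m)
        assert (s.core, s.cloud, s.unique) == (1, 1, 1)
        assert s.core + s.shell + s.cloud == s.pangenome

    def test_extended_core_is_shell_not_core(self):
        # 19/20 genomes: f=0.95 > 0.90 so extended core, but not core; 0.15<=0.95<1 so shell
        m = _matrix_from_counts(20, [20, 19])
        s = partition_sizes(m)
        assert s.core == 1
        assert s.extended_core == 2
        assert s.shell == 1
        assert s.cloud == 0

    def test_partition_sums_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = random_matrix(rng)
            s = partition_sizes(m)
            assert s.core + s.shell + s.cloud == s.pangenome == m.n_clusters
            assert s.core <= s.extended_core <= s.pangenome
            assert s.unique <= max(s.cloud, s.unique)  # unique within cloud for n>=7

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            PartitionThresholds(extended_core_min=0.1, cloud_max=0.5)


class TestRarefaction:
    def test_identical_genomes_flat_curves(self):
        m = _matrix_from_counts(5, [5] * 7)
        c = rarefaction(m, n_perm=5, seed=0)
        assert np.allclose(c.pan_mean, 7) and np.allclose(c.core_mean, 7)

    def test_final_point_is_pangenome_size(self, toy_matrix):
        c = rarefaction(toy_matrix, n_perm=10, seed=1)
        assert c.pan_mean[-1] == toy_matrix.n_clusters

    def test_exhaustive_toy_enumeration(self, toy_matrix):
        c = rarefaction(toy_matrix, exhaustive=True)
        assert c.n_permutations == 6
        assert c.pan_mean[0] == pytest.approx((3 + 3 + 2) / 3)
        # brute-force oracle over all orderings
        P = toy_matrix.presence
        pans = []
        for order in itertools.permutations(range(3)):
            seen = np.zeros(P.shape[1], bool)
            row = []
            for g in order:
                seen |= P[g]
                row.append(seen.sum())
            pans.append(row)
        assert np.allclose(c.pan_mean, np.mean(pans, axis=0))

    def test_monotonicity_and_new_genes_identity(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, n_genomes=5, n_clusters=20)
        c = rarefaction(m, n_perm=20, seed=9)
        assert (np.diff(c.pan_mean) >= -1e-12).all()
        assert (np.diff(c.core_mean) <= 1e-12).all()
        assert c.pan_mean[0] == pytest.approx(c.core_mean[0])
        assert np.allclose(c.new_genes_mean[1:], np.diff(c.pan_mean))

    def test_seed_reproducibility(self, toy_matrix):
        a = rarefaction(toy_matrix, n_perm=7, seed=5)
        b = rarefaction(toy_matrix, n_perm=7, seed=5)
        assert np.array_equal(a.pan_mean, b.pan_mean)


class TestCurveFits:
    N = np.arange(1, 51, dtype=float)

    def test_power_law_recovery(self):
        fit = GeneAccumulation(self.N, 200 * self.N ** 0.3 + 1500, "pan_power_law").fit()
        assert fit.converged
        assert fit.exponent == pytest.approx(0.3, rel=1e-3)
        assert fit.k == pytest.approx(200, rel=1e-3)
        assert fit.c == pytest.approx(1500, rel=1e-3)

    def test_new_genes_decay_recovery(self):
        fit = GeneAccumulation(self.N, 300 * self.N ** -1.5, "new_genes_decay").fit()
        assert fit.alpha == pytest.approx(1.5, rel=1e-3)
        assert fit.k == pytest.approx(300, rel=1e-3)

    def test_core_exp_decay_recovery(self):
        fit = GeneAccumulation(self.N, 2000 * np.exp(-0.3 * self.N) + 1500, "core_exp_decay").fit()
        assert fit.exponent == pytest.approx(0.3, rel=1e-3)
        assert fit.c == pytest.approx(1500, rel=1e-3)

    def test_flat_curve_is_saturated(self):
        fit = GeneAccumulation(self.N, np.full(50, 4000.0), "pan_power_law").fit()
        assert fit.exponent <= 0
        assert fit.openness == "closed"

    def test_fit_curve_from_rarefaction(self):
        rng = np.random.default_rng(21)
        m = random_matrix(rng, n_genomes=8, n_clusters=40)
        curves = rarefaction(m, n_perm=10, seed=2)
        fit = fit_curve(curves, "pan_power_law")
        assert fit.model == "pan_power_law"
        assert fit.rss >= 0

    @pytest.mark.parametrize(
        "model,exponent,expected",
        [
            ("pan_power_law", 0.3, "open"),
            ("pan_power_law", -0.05, "closed"),
            ("pan_power_law", 0.0, "closed"),
            ("pan_power_law", 1.5, "undefined"),
            ("new_genes_decay", 1.2, "closed"),
            ("new_genes_decay", 0.7, "open"),
            ("new_genes_decay", 1.0, "undefined"),
        ],
    )
    def test_openness_rules(self, model, exponent, expected):
        fit = CurveFitResults(model, 1.0, 0.0, exponent, True, 0.0, 10)
        assert classify_openness(fit) == expected

    def test_unconverged_is_undefined(self):
        fit = CurveFitResults("pan_power_law", 1.0, 0.0, 0.5, False, 0.0, 10)
        assert classify_openness(fit) == "undefined"


class TestFluidity:
    def test_identical_genomes_zero(self):
        assert genome_fluidity(_matrix_from_counts(4, [4] * 6)) == 0.0

    def test_disjoint_genomes_one(self):
        P = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], bool)
        m = GenePresenceMatrix("sp", ["a", "b"], list("wxyz"), P)
        assert genome_fluidity(m) == 1.0

    def test_toy_value(self, toy_matrix):
        assert genome_fluidity(toy_matrix) == pytest.approx(23 / 45)

    def test_zero_gene_genome_rejected(self):
        P = np.array([[1, 1], [0, 0], [1, 0]], bool)
        m = GenePresenceMatrix("sp", ["a", "b", "c"], ["x", "y"], P)
        with pytest.raises(ValueError):
            genome_fluidity(m)


class TestChao:
    def test_closed_form(self):
        # S_obs=10, Q1=4, Q2=2 -> 10 + 16/4 = 14
        m = _matrix_from_counts(5, [1] * 4 + [2] * 2 + [3] * 4)
        assert chao_lower_bound(m) == 14.0

    def test_no_singletons(self):
        m = _matrix_from_counts(5, [2, 3, 5])
        assert chao_lower_bound(m) == 3.0

    def test_q2_zero_bias_corrected(self):
        m = _matrix_from_counts(5, [1, 1, 1, 3])
        assert chao_lower_bound(m) == 4 + 3 * 2 / 2


class TestNormalizedSizes:
    def test_single_subset_equals_plain_sizes(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, n_genomes=9, n_clusters=30)
        core, pan = normalized_sizes(m, k=9)
        assert core == m.presence.all(axis=0).sum()
        assert pan == m.n_clusters

    def test_identical_genomes(self):
        m = _matrix_from_counts(10, [10] * 12)
        assert normalized_sizes(m, seed=0) == (12.0, 12.0)

    def test_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, n_genomes=10, n_clusters=40)
        # C(10,9)=10 <= 30 draws -> exhaustive; oracle enumerates directly
        core, pan = normalized_sizes(m, k=9, n_draws=30, seed=1)
        cores, pans = [], []
        for idx in itertools.combinations(range(10), 9):
            sub = m.presence[list(idx)]
            cores.append(sub.all(axis=0).sum())
            pans.append(sub.any(axis=0).sum())
        assert core == pytest.approx(np.mean(cores))
        assert pan == pytest.approx(np.mean(pans))

    def test_seed_invariance_when_exhaustive(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, n_genomes=10, n_clusters=25)
        assert normalized_sizes(m, seed=1) == normalized_sizes(m, seed=999)

    def test_too_few_genomes(self, toy_matrix):
        with pytest.raises(ValueError, match="at least"):
            normalized_sizes(toy_matrix)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        assert core_nucleotide_diversity({"a": "ACGT" * 25, "b": "ACGT" * 25}) == 0.0

    def test_single_pair_proportion(self):
        s = "A" * 100
        t = "C" + "A" * 99
        assert core_nucleotide_diversity({"a": s, "b": t}) == pytest.approx(0.01)

    def test_three_sequences_mean_of_pairs(self):
        seqs = {"a": "AAAA", "b": "AAAC", "c": "AACC"}
        # pairs: ab 1/4, ac 2/4, bc 1/4
        assert core_nucleotide_diversity(seqs) == pytest.approx((0.25 + 0.5 + 0.25) / 3)

    def test_gaps_excluded_pairwise(self):
        seqs = {"a": "A-AA", "b": "AAAC", "c": "AAAA"}
        # ab: sites 1,3,4 -> 1/3 diff; ac: 0/3; bc: 1/4
        assert core_nucleotide_diversity(seqs) == pytest.approx((1 / 3 + 0 + 0.25) / 3)

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            core_nucleotide_diversity({"a": "ACGT", "b": "ACG"})

    def test_sitewise_alternative_in_range(self):
        rng = np.random.default_rng(5)
        seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), 50)) for i in range(4)}
        v = core_nucleotide_diversity(seqs, method="sitewise")
        assert 0 <= v <= 1


class TestFunctionalDistance:
    def test_identical_and_disjoint(self):
        assert functional_distance({"a": {"x"}, "b": {"x"}}) == 0.0
        assert functional_distance({"a": {"x"}, "b": {"y"}}) == 1.0

    def test_hand_value(self):
        # pairs: AB 1 - 1/3 = 2/3, AC 1 - 2/3 = 1/3, BC 1 - 2/3 = 1/3
        d = functional_distance({"A": {"x", "y"}, "B": {"y", "z"}, "C": {"x", "y", "z"}})
        assert d == pytest.approx(4 / 9)

    def test_empty_set_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            d = functional_distance({"a": {"x"}, "b": {"x"}, "c": set()})
        assert d == 0.0
        assert any("without annotations" in r.message for r in caplog.records)


class TestFeatureSet:
    def test_degenerate_identical_genomes(self):
        m = _matrix_from_counts(10, [10] * 20)
        aln = {g: "ACGT" * 10 for g in m.genome_ids}
        annot = {g: {"og1", "og2"} for g in m.genome_ids}
        fs = compute_feature_set(m, alignment=aln, annotations=annot, seed=0)
        assert fs.fluidity == 0.0
        assert fs.core_nt_diversity == 0.0
        assert fs.cloud_size == 0
        assert fs.core_size == fs.pangenome_size == 20
        assert fs.functional_distance == 0.0

    def test_invariants_on_random_matrices(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            m = random_matrix(rng, n_genomes=int(rng.integers(4, 7)),
                              n_clusters=int(rng.integers(8, 16)))
            fs = compute_feature_set(m, seed=int(rng.integers(1 << 30)))
            assert fs.core_size + fs.shell_size + fs.cloud_size == fs.pangenome_size
            assert fs.chao_lower_bound >= fs.pangenome_size
            assert 0 <= fs.fluidity <= 1
            assert fs.mean_genome_size <= fs.pangenome_size

    def test_synthetic_open_pangenome(self):
        from panarch import simulate_pangenome

        m = simulate_pangenome("sp", core_size=300, accessory_pool=500,
                               novel_influx=30, n_genomes=15, seed=4)
        fs = compute_feature_set(m, seed=1)
        assert fs.gamma_pan is not None and 0 < fs.gamma_pan <= 1
        assert fs.openness == "open"
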