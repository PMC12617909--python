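import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgcna.io import BipartiteAssociations, DrugRecord, SequenceRecord
from mgcna.views import (
    ALL_VIEWS,
    KMER_DIM,
    KMER_VOCAB,
    FingerprintSet,
    build_view_bundle,
    cosine_similarity_view,
    gipk_bandwidth,
    gipk_view,
    kmer_feature_matrix,
    kmer_features,
    maccs_fingerprints,
    tanimoto_view,
    threshold_view,
)

seq_strategy = st.text(alphabet="ACGUT", min_size=3, max_size=30)


class TestKmerFeatures:
    def test_vocabulary_is_84_dimensional(self):
        assert KMER_DIM == 4 + 16 + 64
        assert len(kmer_features(SequenceRecord("m", "ACGUACGUACGU"))) == 84

    def test_homopolymer_hits_single_entry_per_block(self):
        v = kmer_features(SequenceRecord("m", "AAA"))
        expected = np.zeros(84)
        for w in ("A", "AA", "AAA"):
            expected[KMER_VOCAB.index(w)] = 1.0
        np.testing.assert_allclose(v, expected)

    def test_permutation_sequence_uniform_monomers(self):
        v = kmer_features(SequenceRecord("m", "ACGU"))
        np.testing.assert_allclose(v[:4], 0.25)  # U counted as T

    @given(seq=seq_strategy)
    @settings(deadline=None, max_examples=50)
    def test_each_k_block_is_a_frequency_distribution(self, seq):
        v = kmer_features(SequenceRecord("m", seq))
        assert v.min() >= 0
        for sl in (slice(0, 4), slice(4, 20), slice(20, 84)):
            assert v[sl].sum() == pytest.approx(1.0)

    def test_brute_force_count_oracle(self):
        seq = "ACGGUACGGA"
        v = kmer_features(SequenceRecord("m", seq))
        s = seq.replace("U", "T")
        for w in ("A", "CG", "ACG", "GGA"):
            count = sum(1 for i in range(len(s) - len(w) + 1)
                        if s[i : i + len(w)] == w)
            k = len(w)
            assert v[KMER_VOCAB.index(w)] == pytest.approx(
                count / (len(s) - k + 1))


class TestCosineView:
    def test_hand_computed_example(self):
        # x_i=(1,1,0,...), x_j=(1,0,0,...): cos = 1/sqrt(2)
        from mgcna.views import KmerFeatureMatrix

        x = np.zeros((2, 84))
        x[0, :2] = 1.0
        x[1, 0] = 1.0
        sim = cosine_similarity_view(KmerFeatureMatrix(("a", "b"), x))
        assert sim.matrix[0, 1] == pytest.approx(0.7071067811865475)

    def test_identical_and_orthogonal_vectors(self):
        from mgcna.views import KmerFeatureMatrix

        x = np.zeros((3, 84))
        x[0, 0] = x[1, 0] = 1.0  # identical
        x[2, 1] = 1.0  # orthogonal to both
        sim = cosine_similarity_view(KmerFeatureMatrix(("a", "b", "c"), x))
        assert sim.matrix[0, 1] == pytest.approx(1.0)
        assert sim.matrix[0, 2] == pytest.approx(0.0)

    def test_zero_norm_vector_names_entity(self):
        from mgcna.views import KmerFeatureMatrix

        x = np.zeros((2, 84))
        x[0, 0] = 1.0
        with pytest.raises(ValueError, match="b"):
            cosine_similarity_view(KmerFeatureMatrix(("a", "b"), x))


class TestGipk:
    def test_two_row_closed_form(self):
        # rows (1,0,0) and (1,1,0): gamma = 1/1.5, sim = exp(-2/3)
        assoc = BipartiteAssociations(
            ["a", "b"], ["g1", "g2", "g3"], {("a", "g1"), ("b", "g1"), ("b", "g2")})
        sim = gipk_view(assoc, "mirna_gene")
        assert sim.matrix[0, 1] == pytest.approx(np.exp(-2.0 / 3.0))
        assert sim.matrix[0, 1] == pytest.approx(0.513417, abs=1e-6)

    def test_identical_profiles_give_unit_similarity(self):
        assoc = BipartiteAssociations(
            ["a", "b"], ["g1", "g2"], {("a", "g1"), ("b", "g1")})
        assert gipk_view(assoc, "x").matrix[0, 1] == pytest.approx(1.0)

    def test_all_zero_profile_matrix_rejected(self):
        assoc = BipartiteAssociations(["a", "b"], ["g1"], set())
        with pytest.raises(ValueError, match="bandwidth"):
            gipk_view(assoc, "x")

    def test_brute_force_oracle_random_profiles(self, rng):
        """exp(-gamma ||IP_i - IP_j||^2) recomputed elementwise by loops."""
        for _ in range(5):
            profiles = (rng.random((5, 8)) < 0.4).astype(float)
            if profiles.sum() == 0:
                profiles[0, 0] = 1.0
            rows = [f"r{i}" for i in range(5)]
            cols = [f"c{j}" for j in range(8)]
            pairs = {(rows[i], cols[j]) for i, j in zip(*np.nonzero(profiles))}
            sim = gipk_view(BipartiteAssociations(rows, cols, pairs), "x")
            gamma = 1.0 / np.mean((profiles**2).sum(axis=1))
            for i in range(5):
                for j in range(5):
                    expected = 1.0 if i == j else np.exp(
                        -gamma * ((profiles[i] - profiles[j]) ** 2).sum())
                    assert sim.matrix[i, j] == pytest.approx(expected, abs=1e-10)

    def test_column_permutation_invariance(self, rng):
        profiles = (rng.random((5, 8)) < 0.5).astype(float)
        profiles[0, 0] = 1.0
        rows = [f"r{i}" for i in range(5)]

        def build(p):
            cols = [f"c{j}" for j in range(p.shape[1])]
            pairs = {(rows[i], cols[j]) for i, j in zip(*np.nonzero(p))}
            return gipk_view(BipartiteAssociations(rows, cols, pairs), "x").matrix

        perm = rng.permutation(8)
        np.testing.assert_allclose(build(profiles), build(profiles[:, perm]),
                                   atol=1e-12)

    def test_gamma_prime_must_be_positive(self):
        with pytest.raises(ValueError):
            gipk_bandwidth(np.ones((2, 2)), gamma_prime=0.0)


ASPIRIN = "CC(=O)OC1=CC=CC=C1C(=O)O"
CAFFEINE = "CN1C=NC2=C1C(=O)N(C(=O)N2C)C"


class TestMaccs:
    def test_fingerprint_has_167_bits(self):
        fps = maccs_fingerprints([DrugRecord("aspirin", ASPIRIN)])
        assert fps.bits.shape == (1, 167)

    def test_deterministic_for_same_smiles(self):
        fps = maccs_fingerprints(
            [DrugRecord("a", CAFFEINE), DrugRecord("b", CAFFEINE)])
        np.testing.assert_array_equal(fps.bits[0], fps.bits[1])

    def test_unparseable_smiles_names_drug(self):
        with pytest.raises(ValueError, match="badDrug"):
            maccs_fingerprints([DrugRecord("badDrug", "C((")])


class TestTanimoto:
    @staticmethod
    def _fps(*bitsets):
        bits = np.zeros((len(bitsets), 167))
        for i, s in enumerate(bitsets):
            bits[i, list(s)] = 1.0
        return FingerprintSet(tuple(f"d{i}" for i in range(len(bitsets))), bits)

    def test_set_arithmetic_example(self):
        sim = tanimoto_view(self._fps({1, 2, 3}, {2, 3, 4}))
        assert sim.matrix[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint_sets(self):
        sim = tanimoto_view(self._fps({1, 2}, {1, 2}, {5, 6}))
        assert sim.matrix[0, 1] == pytest.approx(1.0)
        assert sim.matrix[0, 2] == pytest.approx(0.0)

    def test_all_zero_fingerprints(self):
        sim = tanimoto_view(self._fps(set(), set()))
        assert sim.matrix[0, 1] == 0.0
        assert sim.matrix[0, 0] == 1.0


class TestThreshold:
    def test_equality_maps_to_edge(self):
        from mgcna.views import SimilarityView

        m = np.array([[1.0, 0.7], [0.7, 1.0]])
        sim = SimilarityView(("a", "b"), m, "x")
        assert threshold_view(sim, 0.7).matrix[0, 1] == 1.0
        assert threshold_view(sim, 0.7 + 1e-9).matrix[0, 1] == 0.0

    def test_zero_threshold_gives_complete_graph(self, rng):
        from mgcna.views import SimilarityView

        m = rng.random((4, 4))
        m = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(m, 1.0)
        sim = SimilarityView(tuple("abcd"), m, "x")
        assert threshold_view(sim, 0.0).matrix.min() == 1.0

    def test_monotone_in_theta(self, rng):
        from mgcna.views import SimilarityView

        m = rng.random((6, 6))
        m = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(m, 1.0)
        sim = SimilarityView(tuple("abcdef"), m, "x")
        prev = threshold_view(sim, 0.0).matrix
        for th in (0.2, 0.4, 0.6, 0.8, 1.0):
            cur = threshold_view(sim, th).matrix
            assert (cur <= prev).all()
            prev = cur

    def test_out_of_range_theta_rejected(self):
        from mgcna.views import SimilarityView

        sim = SimilarityView(("a",), np.ones((1, 1)), "x")
        with pytest.raises(ValueError):
            threshold_view(sim, 1.5)


class TestViewBundle:
    def test_all_views_present_with_full_inputs(self, tiny_dataset):
        b = build_view_bundle(tiny_dataset.sequences, tiny_dataset.fingerprints,
                              tiny_dataset.mga, tiny_dataset.dga, tiny_dataset.mda)
        assert set(b.mirna_views) | set(b.drug_views) == set(ALL_VIEWS)

    def test_subset_configuration(self, tiny_dataset):
        b = build_view_bundle(tiny_dataset.sequences, tiny_dataset.fingerprints,
                              None, None, tiny_dataset.mda,
                              include=["mirna_seq", "drug_struct"])
        assert set(b.mirna_views) == {"mirna_seq"}
        assert set(b.drug_views) == {"drug_struct"}

    def test_mda_views_depend_only_on_training_positives(self, tiny_dataset):
        """Removing a held-out pair from the full set leaves the bundle
        byte-identical when the training subset is unchanged."""
        pairs = sorted(tiny_dataset.mda.pairs)
        train = set(pairs[:-4])  # last 4 pairs act as the held-out fold
        train_mda = tiny_dataset.mda.subset_pairs(train)
        b1 = build_view_bundle(tiny_dataset.sequences, tiny_dataset.fingerprints,
                               tiny_dataset.mga, tiny_dataset.dga, train_mda)
        b2 = build_view_bundle(tiny_dataset.sequences, tiny_dataset.fingerprints,
                               tiny_dataset.mga, tiny_dataset.dga, train_mda)
        for name in b1.mirna_views:
            assert b1.mirna_views[name].matrix.tobytes() == \
                b2.mirna_views[name].matrix.tobytes()

    def test_missing_sequence_for_mda_entity_is_error(self, tiny_dataset):
        with pytest.raises(ValueError, match="missing sequences"):
            build_view_bundle(tiny_dataset.sequences[:-1],
                              tiny_dataset.fingerprints,
                              tiny_dataset.mga, tiny_dataset.dga,
                              tiny_dataset.mda)

    def test_entity_without_gene_links_gets_zero_profile_row(self, tiny_dataset):
        mga = tiny_dataset.mga
        lonely = tiny_dataset.mirna_ids[0]
        stripped = BipartiteAssociations(
            mga.row_ids, mga.col_ids,
            {(m, g) for m, g in mga.pairs if m != lonely})
        b = build_view_bundle(tiny_dataset.sequences, tiny_dataset.fingerprints,
                              stripped, tiny_dataset.dga, tiny_dataset.mda,
                              include=["mirna_gene", "drug_gene"])
        sim = b.mirna_views["mirna_gene"]
        assert sim.entity_ids[0] == lonely
        assert sim.matrix.shape[0] == len(tiny_dataset.mirna_ids)

    def test_entity_permutation_equivariance(self, tiny_dataset):
        """Reordering the input entities permutes every view identically."""
        ds = tiny_dataset
        b1 = build_view_bundle(ds.sequences, ds.fingerprints, ds.mga, ds.dga,
                               ds.mda, include=["mirna_seq", "drug_struct"])
        perm = np.arange(len(ds.mirna_ids))[::-1]
        seqs = [ds.sequences[i] for i in perm]
        mda_perm = BipartiteAssociations(
            [ds.mirna_ids[i] for i in perm], list(ds.drug_ids), set(ds.mda.pairs))
        b2 = build_view_bundle(seqs, ds.fingerprints, None, None, mda_perm,
                               include=["mirna_seq", "drug_struct"])
        np.testing.assert_array_equal(
            b2.mirna_views["mirna_seq"].matrix,
            b1.mirna_views["mirna_seq"].matrix[np.ix_(perm, perm)])


@given(st.data())
@settings(deadline=None, max_examples=25)
def test_similarity_views_symmetric_unit_diagonal_bounded(data):
    """Structural invariants of every similarity kind on random inputs."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    n = data.draw(st.integers(3, 7))
    seqs = [SequenceRecord(f"m{i}", "".join(
        rng.choice(list("ACGU"), size=rng.integers(5, 15))))
        for i in range(n)]
    sim_cos = cosine_similarity_view(kmer_feature_matrix(seqs))
    profiles = (rng.random((n, 6)) < 0.5).astype(float)
    profiles[0, 0] = 1.0
    rows = [f"r{i}" for i in range(n)]
    cols = [f"c{j}" for j in range(6)]
    sim_gipk = gipk_view(BipartiteAssociations(
        rows, cols, {(rows[i], cols[j]) for i, j in zip(*np.nonzero(profiles))}),
        "x")
    bits = np.zeros((n, 167))
    bits[:, :20] = (rng.random((n, 20)) < 0.5)
    sim_tan = tanimoto_view(FingerprintSet(tuple(rows), bits))
    for sim in (sim_cos, sim_gipk, sim_tan):
        m = sim.matrix
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert m.min() >= 0.0 and m.max() <= 1.0
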