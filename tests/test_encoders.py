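import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurostack.encoders import (
    ALPHABET21,
    AAIndexTable,
    EmbeddingTable,
    GGapConfig,
    N_GGAP_BINS,
    count_ggap_pairs,
    default_aaindex_table,
    encode_aaindex,
    encode_ggap,
    encode_onehot,
    encode_word2vec,
    ggap_bin_index,
    train_word2vec,
)
from neurostack.io_formats import AA_ALPHABET, PAD_CHAR, pad_sequence

peptides = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=100)


class TestOneHot:
    def test_single_residue_then_pad(self):
        mat = encode_onehot(pad_sequence("A")).values
        expected_row0 = np.zeros(20)
        expected_row0[0] = 1.0
        np.testing.assert_array_equal(mat[0], expected_row0)
        np.testing.assert_array_equal(mat[1:], np.full((99, 20), 0.05))

    def test_shape_and_row_sums(self):
        mat = encode_onehot(pad_sequence("ACDEFGHIKLMNPQRSTVWY")).values
        assert mat.shape == (100, 20)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0)  # basis rows and 0.05 rows

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(peptides)
    def test_column_sums_equal_residue_counts(self, seq):
        mat = encode_onehot(pad_sequence(seq)).values
        n_pad = 100 - len(seq)
        counts = np.array([seq.count(aa) for aa in AA_ALPHABET])
        np.testing.assert_allclose(mat.sum(axis=0), counts + 0.05 * n_pad)


class TestAAIndex:
    def test_shape_and_accession_count(self):
        table = default_aaindex_table()
        assert table.n_properties == 14
        assert encode_aaindex(pad_sequence("ACD")).values.shape == (100, 14)

    def test_pad_rows_are_column_means(self):
        table = default_aaindex_table()
        mat = encode_aaindex(pad_sequence("ACD"), table).values
        np.testing.assert_allclose(mat[3:], np.tile(table.values.mean(axis=0), (97, 1)))

    def test_positionality(self):
        a = encode_aaindex(pad_sequence("ACDEFG")).values
        b = encode_aaindex(pad_sequence("ACDWYV")).values
        np.testing.assert_array_equal(a[:3], b[:3])
        assert not np.array_equal(a[3], b[3])

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            AAIndexTable(accession_ids=("X1",), values=np.zeros((19, 1)))


class TestGGap:
    def test_bin_space_excludes_pure_pad_pair(self):
        assert N_GGAP_BINS == 21 * 21 - 1 == 440
        with pytest.raises(ValueError):
            ggap_bin_index(PAD_CHAR, PAD_CHAR)

    def test_two_residue_example_g0(self):
        counts = count_ggap_pairs(pad_sequence("AA"), GGapConfig(g=0))
        expected = np.zeros(440, dtype=int)
        expected[ggap_bin_index("A", "A")] = 1
        expected[ggap_bin_index("A", PAD_CHAR)] = 1
        np.testing.assert_array_equal(counts, expected)  # 97 (B,B) pairs discarded

    def test_full_length_sequence_conserves_99_pairs(self):
        seq = ("ACDEFGHIKL" * 10)
        counts = count_ggap_pairs(pad_sequence(seq), GGapConfig(g=0))
        assert counts.sum() == 99

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(peptides, st.integers(min_value=0, max_value=4))
    def test_conservation_against_brute_force(self, seq, g):
        padded = pad_sequence(seq)
        counts = count_ggap_pairs(padded, GGapConfig(g=g))
        # independent oracle: enumerate every position pair directly
        s = padded.residues
        brute = {}
        for i in range(100 - g - 1):
            pair = (s[i], s[i + g + 1])
            brute[pair] = brute.get(pair, 0) + 1
        n_bb = brute.pop((PAD_CHAR, PAD_CHAR), 0)
        assert counts.sum() == (100 - g - 1) - n_bb
        for (a, b), c in brute.items():
            assert counts[ggap_bin_index(a, b)] == c

    def test_count_onehot_rows(self):
        mat = encode_ggap(pad_sequence("AA")).values
        assert mat.shape == (440, 10)
        row = mat[ggap_bin_index("A", "A")]
        np.testing.assert_array_equal(row, np.eye(10)[0])
        # count 0 rows are all-zero
        assert mat[ggap_bin_index("C", "D")].sum() == 0

    def test_counts_above_cap_clip_to_cap(self):
        # 'A'*26: 25 adjacent (A,A) pairs, brute-force verifiable
        padded = pad_sequence("A" * 26)
        counts = count_ggap_pairs(padded, GGapConfig(g=0))
        assert counts[ggap_bin_index("A", "A")] == 25
        mat = encode_ggap(padded).values
        np.testing.assert_array_equal(mat[ggap_bin_index("A", "A")], np.eye(10)[9])

    def test_invalid_gap_config(self):
        with pytest.raises(ValueError):
            GGapConfig(g=-1)
        with pytest.raises(ValueError):
            GGapConfig(g=99)


class TestWord2Vec:
    def test_coverage_and_dimension(self, motif_arrays):
        padded, _ = motif_arrays
        table = train_word2vec(padded[:30], d=8, epochs=10, seed=0)
        assert set(table.token_vectors) == set(ALPHABET21)
        assert all(v.shape == (8,) for v in table.token_vectors.values())

    def test_deterministic_for_fixed_seed(self, motif_arrays):
        padded, _ = motif_arrays
        a = train_word2vec(padded[:20], d=8, epochs=10, seed=5)
        b = train_word2vec(padded[:20], d=8, epochs=10, seed=5)
        np.testing.assert_array_equal(a.matrix(), b.matrix())

    def test_disjoint_languages_separate_in_embedding_space(self):
        # two residue "languages" that never co-occur within a sequence
        rng = np.random.default_rng(42)
        group1, group2 = "ACDEF", "KLMNP"
        corpus = []
        for i in range(60):
            letters = group1 if i % 2 == 0 else group2
            seq = "".join(rng.choice(list(letters), size=40))
            corpus.append(pad_sequence(seq))
        table = train_word2vec(corpus, d=16, epochs=100, seed=1)

        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

        vecs = {t: table.token_vectors[t] for t in group1 + group2}
        intra, inter = [], []
        for a in group1 + group2:
            for b in group1 + group2:
                if a >= b:
                    continue
                same = (a in group1) == (b in group1)
                (intra if same else inter).append(cos(vecs[a], vecs[b]))
        assert np.mean(intra) > np.mean(inter)

    def test_empty_corpus_and_cbow_rejected(self):
        with pytest.raises(ValueError):
            train_word2vec([], d=4)
        with pytest.raises(NotImplementedError):
            train_word2vec([pad_sequence("ACDEF")], d=4, algorithm="cbow")

    def test_lookup_semantics_with_hand_built_table(self):
        vecs = {t: np.zeros(2) for t in ALPHABET21}
        vecs["A"] = np.array([1.0, 2.0])
        vecs[PAD_CHAR] = np.array([3.0, 4.0])
        table = EmbeddingTable(token_vectors=vecs, d=2)
        mat = encode_word2vec(pad_sequence("A"), table).values
        assert mat.shape == (100, 2)
        np.testing.assert_array_equal(mat[0], [1.0, 2.0])
        np.testing.assert_array_equal(mat[1], [3.0, 4.0])

    def test_identical_sequences_identical_matrices(self, motif_arrays):
        padded, _ = motif_arrays
        table = train_word2vec(padded[:10], d=4, epochs=5, seed=0)
        a = encode_word2vec(padded[0], table).values
        b = encode_word2vec(padded[0], table).values
        np.testing.assert_array_equal(a, b)


def test_encoders_are_pure_functions():
    padded = pad_sequence("ACDWYV")
    for enc in (encode_onehot, encode_aaindex, encode_ggap):
        np.testing.assert_array_equal(enc(padded).values, enc(padded).values)
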