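"""Feature encoding: vocabularies, bit matrices, similarity matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddiconv.features import (
    BitMatrix,
    DrugFeatureTable,
    build_vocabulary,
    encode_bit_matrix,
    read_bit_matrix,
    read_feature_table,
    read_similarity_matrix,
    similarity_matrix,
    write_bit_matrix,
    write_feature_table,
    write_similarity_matrix,
)
from conftest import random_bit_matrix


def brute_force_jaccard(values: np.ndarray) -> np.ndarray:
    """Set-arithmetic reference: |a & b| / |a | b| over all row pairs."""
    n = values.shape[0]
    sets = [set(np.flatnonzero(row)) for row in values]
    out = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            union = sets[i] | sets[k]
            out[i, k] = len(sets[i] & sets[k]) / len(union) if union else 0.0
    return out


def brute_force_cosine(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            denom = np.linalg.norm(values[i]) * np.linalg.norm(values[k])
            out[i, k] = float(values[i] @ values[k]) / denom if denom else 0.0
    return out


class TestVocabulary:
    def test_sorted_union(self, toy_table):
        vocab = build_vocabulary(toy_table, "substructure")
        assert vocab.tokens == ("a", "b", "c")
        assert vocab.size == 3

    def test_empty_token_sets_give_empty_vocabulary(self):
        table = DrugFeatureTable(drugs=["d1", "d2"], modalities=["target"], tokens={})
        vocab = build_vocabulary(table, "target")
        assert vocab.size == 0
        bits = encode_bit_matrix(table, vocab)
        assert bits.values.shape == (2, 0)

    def test_unknown_modality_names_valid_ones(self, toy_table):
        with pytest.raises(ValueError, match="substructure"):
            build_vocabulary(toy_table, "pathway")


class TestBitMatrix:
    def test_membership_encoding(self, toy_table):
        vocab = build_vocabulary(toy_table, "substructure")
        bits = encode_bit_matrix(toy_table, vocab)
        np.testing.assert_array_equal(bits.values, [[1, 1, 0], [0, 1, 1], [0, 0, 0]])

    def test_row_sums_equal_token_set_sizes(self):
        rng = np.random.default_rng(7)
        drugs = [f"d{i}" for i in range(50)]
        universe = [f"tok{j}" for j in range(40)]
        tokens = {}
        for d in drugs:
            chosen = frozenset(t for t in universe if rng.random() < 0.2)
            if chosen:
                tokens[(d, "m")] = chosen
        table = DrugFeatureTable(drugs=drugs, modalities=["m"], tokens=tokens)
        bits = encode_bit_matrix(table, build_vocabulary(table, "m"))
        expected = [len(table.token_set(d, "m")) for d in drugs]
        np.testing.assert_array_equal(bits.values.sum(axis=1), expected)

    def test_unknown_tokens_warn_not_fail(self, toy_table, caplog):
        vocab = build_vocabulary(toy_table, "substructure")
        bigger = DrugFeatureTable(
            drugs=["dX"],
            modalities=["substructure"],
            tokens={("dX", "substructure"): frozenset({"a", "zz_new"})},
        )
        with caplog.at_level("WARNING"):
            bits = encode_bit_matrix(bigger, vocab)
        np.testing.assert_array_equal(bits.values, [[1, 0, 0]])
        assert any("ignored" in r.message for r in caplog.records)


class TestSimilarity:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([[1, 1, 0], [0, 1, 1]], 1 / 3),
            ([[1, 0, 1], [1, 0, 1]], 1.0),
            ([[1, 0, 0], [0, 1, 1]], 0.0),
        ],
    )
    def test_jaccard_known_pairs(self, rows, expected):
        bits = BitMatrix(drugs=["x", "y"], modality="m", values=np.array(rows))
        sim = similarity_matrix(bits, "jaccard")
        assert sim.values[0, 1] == pytest.approx(expected)

    def test_empty_vs_empty_is_zero(self):
        bits = BitMatrix(drugs=["x", "y"], modality="m", values=np.zeros((2, 3), dtype=int))
        for metric in ("jaccard", "cosine"):
            sim = similarity_matrix(bits, metric)
            assert sim.values[0, 1] == 0.0
            assert sim.values[0, 0] == 0.0  # empty drug has no unit diagonal

    @pytest.mark.parametrize("metric", ["jaccard", "cosine"])
    def test_matches_brute_force(self, metric):
        rng = np.random.default_rng(11)
        oracle = brute_force_jaccard if metric == "jaccard" else brute_force_cosine
        for _ in range(10):
            values = random_bit_matrix(rng, 30, 20)
            bits = BitMatrix(drugs=[f"d{i}" for i in range(30)], modality="m", values=values)
            sim = similarity_matrix(bits, metric)
            np.testing.assert_allclose(sim.values, oracle(values), atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_range_symmetry_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        n, v = int(rng.integers(2, 15)), int(rng.integers(1, 12))
        values = random_bit_matrix(rng, n, v, 0.4)
        for metric in ("jaccard", "cosine"):
            sim = similarity_matrix(
                BitMatrix(drugs=[f"d{i}" for i in range(n)], modality="m", values=values), metric
            ).values
            assert np.all(sim >= 0) and np.all(sim <= 1)
            np.testing.assert_array_equal(sim, sim.T)
            nonempty = values.sum(axis=1) > 0
            np.testing.assert_allclose(np.diag(sim)[nonempty], 1.0, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        values = random_bit_matrix(rng, 12, 9)
        drugs = [f"d{i}" for i in range(12)]
        sim = similarity_matrix(BitMatrix(drugs=drugs, modality="m", values=values), "jaccard")
        perm = rng.permutation(12)
        sim_p = similarity_matrix(
            BitMatrix(drugs=[drugs[i] for i in perm], modality="m", values=values[perm]), "jaccard"
        )
        np.testing.assert_allclose(sim_p.values, sim.values[np.ix_(perm, perm)], atol=1e-12)

    def test_unknown_metric(self):
        bits = BitMatrix(drugs=["x"], modality="m", values=np.ones((1, 1), dtype=int))
        with pytest.raises(ValueError, match="jaccard"):
            similarity_matrix(bits, "tanimoto")


class TestRoundTrips:
    def test_feature_table(self, toy_table, tmp_path):
        path = tmp_path / "features.tsv"
        write_feature_table(toy_table, path)
        loaded = read_feature_table(path)
        # d3 has no tokens so it is not representable in the long format
        assert loaded.drugs == ["d1", "d2"]
        for d in loaded.drugs:
            for m in loaded.modalities:
                assert loaded.token_set(d, m) == toy_table.token_set(d, m)

    def test_bit_and_similarity_matrices(self, toy_table, tmp_path):
        vocab = build_vocabulary(toy_table, "substructure")
        bits = encode_bit_matrix(toy_table, vocab)
        write_bit_matrix(bits, vocab, tmp_path / "bits.tsv")
        bits2, vocab2 = read_bit_matrix(tmp_path / "bits.tsv", "substructure")
        np.testing.assert_array_equal(bits2.values, bits.values)
        assert vocab2.tokens == vocab.tokens

        sim = similarity_matrix(bits)
        write_similarity_matrix(sim, tmp_path / "sim.tsv")
        sim2 = read_similarity_matrix(tmp_path / "sim.tsv", "substructure")
        np.testing.assert_allclose(sim2.values, sim.values, atol=1e-12)
        assert sim2.drugs == sim.drugs
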