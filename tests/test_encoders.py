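"""One-hot and k-mer encodings: dimensions, layouts, cross-encoder oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseusite import (
    EncodingSpec,
    RnaSequenceRecord,
    SequenceDataset,
    default_encodings,
    encode,
    encode_kmer,
    encode_onehot,
    kmer_index,
)
from pseusite.encoders import all_kmers
from pseusite.simulate import default_specs, generate


def _ds(*seqs: str) -> SequenceDataset:
    return SequenceDataset(
        [RnaSequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)], center_check=False
    )


@pytest.mark.parametrize(
    "kmer,expected",
    [("A", 0), ("U", 3), ("AC", 1), ("UUU", 63), ("GAU", 2 * 16 + 0 + 3)],
)
def test_kmer_index(kmer, expected):
    assert kmer_index(kmer) == expected


def test_kmer_index_bijective_and_matches_enumeration():
    for k in (1, 2, 3):
        kmers = all_kmers(k)
        assert sorted(kmers) == kmers  # lexicographic A<C<G<U order
        assert [kmer_index(m) for m in kmers] == list(range(4**k))


def test_kmer_index_rejects_invalid():
    with pytest.raises(ValueError):
        kmer_index("AXU")


def test_onehot_canonical_single_bases():
    fm = encode_onehot(_ds("A", "C", "G", "U"), k=1)
    assert np.array_equal(fm.values, np.eye(4))


def test_onehot_concatenates_position_blocks():
    fm = encode_onehot(_ds("ACGU"), k=1)
    assert fm.values.shape == (1, 16)
    expected = np.concatenate([np.eye(4)[i] for i in range(4)])
    assert np.array_equal(fm.values[0], expected)
    assert fm.values.sum() == 4  # row sum = λ-k+1


@pytest.mark.parametrize(
    "lam,k,expected",
    [(21, 1, 84), (21, 2, 320), (21, 3, 1216), (31, 1, 124), (31, 2, 480), (31, 3, 1856)],
)
def test_onehot_dimension_formula(lam, k, expected):
    """n_features = 4^k (λ−k+1) for every benchmark window length and k."""
    ds = generate(default_specs(n_pos=2, n_neg=2, seed=0)[
        "human-like" if lam == 21 else "yeast-like"
    ])
    fm = encode_onehot(ds, k)
    assert fm.n_features == expected == 4**k * (lam - k + 1)
    # every 4^k block one-hot, row sums exact
    blocks = fm.values.reshape(len(ds), lam - k + 1, 4**k)
    assert np.array_equal(blocks.sum(axis=2), np.ones((len(ds), lam - k + 1)))


def test_kmer_hand_examples():
    fm = encode_kmer(_ds("AAAA"), k=1)
    assert np.array_equal(fm.values[0], [1, 0, 0, 0])
    fm2 = encode_kmer(_ds("ACGU"), k=2)
    expected = np.zeros(16)
    for m in ("AC", "CG", "GU"):
        expected[kmer_index(m)] = 1 / 3
    assert np.allclose(fm2.values[0], expected)


def test_k_larger_than_window_rejected():
    with pytest.raises(ValueError):
        encode_kmer(_ds("ACG"), k=4)


@pytest.mark.parametrize("spec", default_encodings(), ids=lambda s: s.name)
def test_rows_and_blocks_on_synthetic_windows(spec):
    ds = generate(default_specs(n_pos=15, n_neg=15, seed=2)["human-like"])
    fm = encode(ds, spec)
    if spec.scheme == "kmer":
        assert fm.values.shape == (30, 4**spec.k)
        assert np.allclose(fm.values.sum(axis=1), 1.0, atol=1e-12)
        assert (fm.values >= 0).all()
    else:
        assert set(np.unique(fm.values)) <= {0.0, 1.0}
        assert np.allclose(fm.values.sum(axis=1), ds.window_length - spec.k + 1)


@pytest.mark.parametrize("k", [1, 2, 3])
def test_cross_encoder_consistency(k):
    """k-mer frequencies equal block-summed one-hot counts / (λ−k+1)."""
    ds = generate(default_specs(n_pos=20, n_neg=20, seed=9)["yeast-like"])
    lam = ds.window_length
    onehot = encode_onehot(ds, k).values.reshape(len(ds), lam - k + 1, 4**k)
    from_onehot = onehot.sum(axis=1) / (lam - k + 1)
    assert np.allclose(from_onehot, encode_kmer(ds, k).values, atol=1e-12)


@given(st.permutations(list(range(8))))
@settings(max_examples=20, deadline=None)
def test_permutation_equivariance(perm):
    ds = generate(default_specs(n_pos=4, n_neg=4, seed=1)["human-like"])
    permuted = ds.subset(perm)
    for spec in (EncodingSpec("onehot", 2), EncodingSpec("kmer", 3)):
        full = encode(ds, spec).values
        assert np.array_equal(encode(permuted, spec).values, full[perm])


def test_feature_names_match_layout():
    fm = encode_onehot(_ds("ACGU"), k=2)
    assert fm.feature_names[0] == "pos1_AA"
    assert fm.feature_names[kmer_index("AC")] == "pos1_AC"
    assert len(fm.feature_names) == fm.n_features
    assert encode_kmer(_ds("ACGU"), k=1).feature_names == ["A", "C", "G", "U"]
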