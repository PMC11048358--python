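"""Sequence feature encodings: one-hot of k-nucleotides and k-mer frequencies.

Two complementary views of a λ-nt window are used, each for k = 1, 2, 3:

* **One-hot of k-nucleotides** — position-resolved: each of the λ−k+1
  overlapping k-mers becomes a 4^k indicator block, giving a
  4^k·(λ−k+1)-dimensional binary vector.  This preserves *where* a
  nucleotide preference occurs (e.g. A/U enrichment at +1 next to Ψ sites).
* **K-mer frequency** — position-free: the 4^k overlapping k-mer counts,
  normalised by λ−k+1 so every row is a probability vector.  Dividing by the
  window length makes 21-nt and 31-nt datasets commensurable.

Columns follow lexicographic A<C<G<U order throughout; the one-hot layout is
position-major (blocks of 4^k per position).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io import SequenceDataset

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SCHEMES = ("onehot", "kmer")


@dataclass(frozen=True)
class EncodingSpec:
    """One of the six feature representations: scheme in {onehot, kmer}, k in {1,2,3}."""

    scheme: str
    k: int

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.k not in (1, 2, 3):
            raise ValueError(f"k must be in {{1,2,3}}, got {self.k}")

    @property
    def name(self) -> str:
        return f"{self.scheme}_k{self.k}"

    @classmethod
    def parse(cls, name: str) -> "EncodingSpec":
        scheme, _, k = name.partition("_k")
        return cls(scheme, int(k))


def default_encodings() -> list[EncodingSpec]:
    """The six representations, one-hot first, k ascending within scheme."""
    return [EncodingSpec(s, k) for s in SCHEMES for k in (1, 2, 3)]


@dataclass
class FeatureMatrix:
    """A numeric view of a dataset under one encoding."""

    values: np.ndarray  # n_sequences x n_features
    spec: EncodingSpec
    feature_names: list[str]
    window_length: int

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def kmer_index(kmer: str) -> int:
    """Base-4 rank of a k-mer with A=0, C=1, G=2, U=3, most significant first."""
    idx = 0
    for ch in kmer:
        if ch not in _BASE_INDEX:
            raise ValueError(f"invalid nucleotide {ch!r} in k-mer {kmer!r}")
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic (= kmer_index) order."""
    return ["".join(p) for p in product(BASES, repeat=k)]


def _codes(dataset: SequenceDataset) -> np.ndarray:
    """Integer codes (n x λ) for the dataset's sequences."""
    lam = dataset.window_length
    flat = np.frombuffer("".join(dataset.sequences).encode(), dtype=np.uint8)
    codes = np.empty(flat.shape, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        codes[flat == ord(base)] = i
    return codes.reshape(len(dataset), lam)


def _kmer_codes(dataset: SequenceDataset, k: int) -> np.ndarray:
    """Ranks of the λ−k+1 overlapping k-mers per sequence (n x (λ−k+1))."""
    lam = dataset.window_length
    if not 1 <= k <= lam:
        raise ValueError(f"k must satisfy 1 <= k <= window length {lam}, got {k}")
    codes = _codes(dataset)
    n_pos = lam - k + 1
    out = np.zeros((len(dataset), n_pos), dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[:, j : j + n_pos]
    return out


def encode_onehot(dataset: SequenceDataset, k: int) -> FeatureMatrix:
    """Position-major one-hot of overlapping k-mers: 4^k·(λ−k+1) binary columns."""
    lam = dataset.window_length
    ranks = _kmer_codes(dataset, k)
    n, n_pos = ranks.shape
    width = 4**k
    values = np.zeros((n, n_pos * width), dtype=np.float64)
    cols = np.arange(n_pos) * width + ranks
    values[np.arange(n)[:, None], cols] = 1.0
    names = [f"pos{p + 1}_{km}" for p in range(n_pos) for km in all_kmers(k)]
    return FeatureMatrix(values, EncodingSpec("onehot", k), names, lam)


def encode_kmer(dataset: SequenceDataset, k: int) -> FeatureMatrix:
    """Overlapping k-mer frequencies: 4^k columns, each row summing to 1."""
    lam = dataset.window_length
    ranks = _kmer_codes(dataset, k)
    n, n_pos = ranks.shape
    width = 4**k
    counts = np.zeros((n, width), dtype=np.float64)
    for i in range(n):
        counts[i] = np.bincount(ranks[i], minlength=width)
    return FeatureMatrix(counts / n_pos, EncodingSpec("kmer", k), all_kmers(k), lam)


def encode(dataset: SequenceDataset, spec: EncodingSpec) -> FeatureMatrix:
    if spec.scheme == "onehot":
        return encode_onehot(dataset, spec.k)
    return encode_kmer(dataset, spec.k)


def to_tsv(matrix: FeatureMatrix, path: str, ids: list[str] | None = None) -> None:
    """Export a feature matrix as headered TSV for inspection."""
    import pandas as pd

    frame = pd.DataFrame(matrix.values, columns=matrix.feature_names, index=ids)
    frame.to_csv(path, sep="\t", index=ids is not None, index_label="id" if ids else None)
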