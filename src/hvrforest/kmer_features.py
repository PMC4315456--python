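"""Normalized k-mer frequency vectors, the classifier's input representation.

A sequence of length L contributes L-k+1 overlapping windows (step 1).  Each
window containing only A/C/G/T increments the count of its k-mer; windows
touching any other symbol are excluded from both the numerator and the
denominator.  The frequency of a k-mer is its count divided by the number of
valid windows, so a non-degenerate vector sums to 1.  K-mers are plain
(non-canonical): no reverse-complement collapsing, so the full 4^k feature
space is enumerated (256 features at the working size k=4) and orientation
of the input reads matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_BASE_CODE[ord("a")] = 0
_BASE_CODE[ord("c")] = 1
_BASE_CODE[ord("g")] = 2
_BASE_CODE[ord("t")] = 3

K_MIN, K_MAX = 2, 8


def feature_space_size(k: int) -> int:
    """Number of distinct k-mers over {A,C,G,T}: 4^k (256 for k=4)."""
    if int(k) != k or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    return 4 ** int(k)


def kmer_names(k: int) -> list[str]:
    """All k-mers in lexicographic order over A<C<G<T (the column order)."""
    feature_space_size(k)
    return ["".join(p) for p in product("ACGT", repeat=int(k))]


@dataclass
class FeatureVector:
    k: int
    values: np.ndarray  # length 4^k, lexicographic k-mer order
    valid_kmer_count: int


def _window_indices(sequence: str, k: int) -> tuple[np.ndarray, int]:
    """Lexicographic index of each valid window; also the valid-window count."""
    n = len(sequence)
    if n < k:
        return np.empty(0, dtype=np.int64), 0
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii", "replace"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid] @ powers, int(valid.sum())


def kmer_frequencies(sequence: str, k: int) -> FeatureVector:
    """Normalized k-mer frequency vector of one sequence.

    A sequence shorter than k (or with no window free of ambiguity symbols)
    yields the all-zero vector with valid_kmer_count 0 rather than an error,
    so degenerate reads flow through batch featurization.
    """
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k must lie in [{K_MIN},{K_MAX}], got {k}")
    idx, n_valid = _window_indices(sequence, k)
    counts = np.bincount(idx, minlength=4 ** k).astype(float)
    values = counts / n_valid if n_valid > 0 else counts
    return FeatureVector(k, values, n_valid)


def resolve_subset(k: int, variable_subset: Sequence[str] | str = "all") -> list[str]:
    """Validate a variable subset and return it in stable lexicographic order."""
    names = kmer_names(k)
    if isinstance(variable_subset, str):
        if variable_subset != "all":
            raise ValueError("variable_subset must be 'all' or a k-mer collection")
        return names
    subset = {s.upper() for s in variable_subset}
    valid = set(names)
    bad = subset - valid
    if bad:
        raise ValueError(f"subset contains non-{k}-mer tokens: {sorted(bad)[:5]}")
    return [m for m in names if m in subset]


def featurize_batch(
    sequences: Iterable[str],
    k: int,
    variable_subset: Sequence[str] | str = "all",
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix (rows follow input order) and its column k-mers.

    Columns are restricted to `variable_subset` *after* normalization over
    all valid windows — frequencies are not renormalized to the subset, so a
    restricted row sums to the fraction of k-mer mass the subset captures.
    """
    columns = resolve_subset(k, variable_subset)
    rows = [kmer_frequencies(s, k).values for s in sequences]
    full = np.vstack(rows) if rows else np.empty((0, 4 ** k))
    if len(columns) == 4 ** k:
        return full, columns
    names = kmer_names(k)
    col_idx = [names.index(c) for c in columns]
    return full[:, col_idx], columns


def write_feature_table(
    matrix: np.ndarray, columns: Sequence[str], ids: Sequence[str], path
) -> None:
    """Debug/interop export: TSV with k-mer column headers, one row per id."""
    import pandas as pd

    pd.DataFrame(matrix, index=list(ids), columns=list(columns)).to_csv(
        path, sep="\t", index_label="id"
    )
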