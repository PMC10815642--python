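"""Consensus sequences and pairwise percent-difference distances.

Distances are uncorrected p-distances obtained by counting mismatched
columns between two aligned sequences, with pairwise deletion of columns
where either sequence has a gap or an ambiguity symbol, expressed as a
percentage of the comparable columns.  Between-group distances are the
mean of all cross pairs, which is what populates the inter-locus grid of
the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "consensus",
    "p_difference",
    "pairwise_matrix",
    "pair_table",
    "between_group_distance",
]

# Symbols excluded from comparisons (pairwise deletion).
_EXCLUDED = {
    "nt": b"-N?",
    "aa": b"-X?",
}


def _encode(seqs: list[str]) -> np.ndarray:
    if not seqs:
        raise ValueError("empty sequence set")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    if 0 in lengths:
        raise ValueError("zero-length alignment")
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def _valid_mask(arr: np.ndarray, level: str) -> np.ndarray:
    excluded = np.frombuffer(_EXCLUDED[level], dtype=np.uint8)
    return ~np.isin(arr, excluded)


def _match_valid(
    a: np.ndarray, b: np.ndarray, level: str
) -> tuple[np.ndarray, np.ndarray]:
    """Cross tables of (matching columns, comparable columns) via one-hot
    products — O(symbols * n * m * L) in BLAS rather than a Python loop."""
    va = _valid_mask(a, level).astype(np.float64)
    vb = _valid_mask(b, level).astype(np.float64)
    valid = va @ vb.T
    match = np.zeros_like(valid)
    symbols = np.union1d(np.unique(a), np.unique(b))
    excluded = np.frombuffer(_EXCLUDED[level], dtype=np.uint8)
    for s in symbols:
        if s in excluded:
            continue
        xa = (a == s).astype(np.float64)
        xb = (b == s).astype(np.float64)
        match += xa @ xb.T
    return match, valid


def p_difference(a: str, b: str, level: str = "aa") -> float:
    """Percent difference between two aligned sequences.

    ``100 * mismatches / comparable``, where comparable columns are those
    in which neither sequence carries a gap/ambiguity symbol.
    """
    if len(a) != len(b):
        raise ValueError("sequences have unequal lengths")
    arr = _encode([a, b])
    valid = _valid_mask(arr, level)
    both = valid[0] & valid[1]
    n = int(both.sum())
    if n == 0:
        raise ValueError("no comparable columns between sequences")
    mismatches = int((arr[0, both] != arr[1, both]).sum())
    return 100.0 * mismatches / n


def consensus(seqs: list[str], level: str = "aa") -> tuple[str, list[tuple[int, str]]]:
    """Per-column modal non-gap residue, with tie/all-gap flags.

    Ties are broken by fixed residue-alphabet (ASCII) order; an all-gap
    column yields ``-``.  Returns ``(consensus, flags)`` where flags are
    ``(column, reason)`` pairs.
    """
    if len(seqs) < 2:
        raise ValueError("consensus requires at least 2 sequences")
    arr = _encode(seqs)
    valid = _valid_mask(arr, level)
    out: list[str] = []
    flags: list[tuple[int, str]] = []
    for j in range(arr.shape[1]):
        col = arr[valid[:, j], j]
        if col.size == 0:
            out.append("-")
            flags.append((j, "all-gap"))
            continue
        states, counts = np.unique(col, return_counts=True)
        best = counts.max()
        winners = states[counts == best]
        out.append(chr(int(winners.min())))
        if winners.size > 1:
            flags.append((j, "tie"))
    return "".join(out), flags


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise percent differences."""

    labels: list[str]
    values: np.ndarray
    level: str = "aa"
    region: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if self.values.min() < -1e-9 or self.values.max() > 100.0 + 1e-9:
            raise ValueError("percent differences must lie in [0, 100]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_matrix(
    labels: list[str],
    seqs: list[str],
    level: str = "aa",
    region: str = "",
) -> DistanceMatrix:
    """All-pairs percent-difference matrix for an aligned sequence set."""
    if len(labels) != len(seqs):
        raise ValueError("labels and sequences differ in number")
    arr = _encode(seqs)
    match, valid = _match_valid(arr, arr, level)
    if (valid == 0).any():
        raise ValueError("a sequence pair has no comparable columns")
    values = 100.0 * (valid - match) / valid
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DistanceMatrix(list(labels), values, level=level, region=region)


def pair_table(dm: DistanceMatrix) -> pd.DataFrame:
    """Long-format table of unordered pairs (the boxplot distribution)."""
    rows = []
    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                {
                    "a": dm.labels[i],
                    "b": dm.labels[j],
                    "region": dm.region,
                    "level": dm.level,
                    "percent_difference": dm.values[i, j],
                }
            )
    return pd.DataFrame(rows)


def between_group_distance(
    seqs_a: list[str], seqs_b: list[str], level: str = "aa"
) -> float:
    """Mean percent difference over all |A| x |B| cross pairs."""
    if not seqs_a or not seqs_b:
        raise ValueError("between-group distance requires non-empty sets")
    arr_a = _encode(seqs_a)
    arr_b = _encode(seqs_b)
    if arr_a.shape[1] != arr_b.shape[1]:
        raise ValueError("groups are not aligned to common columns")
    match, valid = _match_valid(arr_a, arr_b, level)
    if (valid == 0).any():
        raise ValueError("a cross pair has no comparable columns")
    return float(np.mean(100.0 * (valid - match) / valid))
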