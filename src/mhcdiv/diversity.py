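"""Per-site amino-acid variability: frequencies, conservation, Shannon H.

Shannon diversity is computed per alignment column as
``H = -sum_i p_i * log2(p_i)`` over the observed residues (gaps excluded
by default, the Protein Variability Server convention), so H ranges from
0 for an invariant column to log2(20) ~ 4.32 bits for a column showing
all twenty residues uniformly.  Region summaries are plain arithmetic
means of column H; pocket summaries average the columns assigned to each
of the six peptide-binding pockets A-F.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteProfile",
    "site_profiles",
    "mean_H",
    "pocket_H",
    "conservation_table",
    "load_pocket_map",
    "example_pocket_map",
    "synthetic_pocket_map",
]

POCKET_LABELS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class SiteProfile:
    """Residue composition of one alignment column."""

    column: int
    counts: dict[str, int]

    @property
    def n_effective(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n_effective
        return {res: c / n for res, c in self.counts.items()}

    @property
    def modal_residue(self) -> str:
        # ties broken by residue-alphabet order for determinism
        return min(self.counts, key=lambda r: (-self.counts[r], r))

    @property
    def conservation(self) -> float:
        n = self.n_effective
        if n == 0:
            return float("nan")
        return max(self.counts.values()) / n

    @property
    def H(self) -> float:
        n = self.n_effective
        if n == 0:
            return 0.0
        p = np.array(list(self.counts.values()), dtype=float) / n
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())


def site_profiles(
    seqs: Sequence[str],
    gap_chars: str = "-",
    gap_as_symbol: bool = False,
) -> list[SiteProfile]:
    """One :class:`SiteProfile` per column of an aligned amino-acid set.

    Gap characters are excluded from counts and from ``n_effective``
    unless ``gap_as_symbol`` is set, in which case ``-`` is treated as a
    21st residue symbol.
    """
    if len(seqs) < 2:
        raise ValueError("site profiles require at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    if 0 in lengths:
        raise ValueError("zero-length alignment")
    arr = np.array([list(s) for s in seqs], dtype="U1")
    profiles: list[SiteProfile] = []
    skip = set() if gap_as_symbol else set(gap_chars)
    for j in range(arr.shape[1]):
        states, counts = np.unique(arr[:, j], return_counts=True)
        cc = {
            str(s): int(c) for s, c in zip(states, counts) if str(s) not in skip
        }
        profiles.append(SiteProfile(column=j, counts=cc))
    return profiles


def mean_H(
    profiles: Sequence[SiteProfile], positions: Iterable[int] | None = None
) -> float:
    """Arithmetic mean of column H over a set of 0-based columns."""
    if positions is None:
        positions = range(len(profiles))
    positions = list(positions)
    if not positions:
        raise ValueError("empty position set")
    for p in positions:
        if p < 0 or p >= len(profiles):
            raise ValueError(f"position {p} outside column range")
    return float(np.mean([profiles[p].H for p in positions]))


def pocket_H(
    profiles: Sequence[SiteProfile], pocket_map: Mapping[str, Sequence[int]]
) -> dict[str, float]:
    """Per-pocket mean H; pocket positions are 1-based PBR columns."""
    out: dict[str, float] = {}
    for pocket, positions in pocket_map.items():
        cols = [p - 1 for p in positions]
        if not cols:
            raise ValueError(f"pocket {pocket!r} has no valid position")
        out[pocket] = mean_H(profiles, cols)
    return out


def conservation_table(
    profiles: Sequence[SiteProfile],
    bins: Sequence[float] = (1.00, 0.95, 0.90, 0.70, 0.50, 0.30),
) -> pd.DataFrame:
    """Per-column conservation rates binned as in a conservation heat map.

    ``bins`` are descending thresholds; a column fully conserved is
    labelled ``100``, otherwise the enclosing interval (e.g. a modal
    frequency of 0.93 falls in ``90-95``).
    """
    edges = sorted(set(bins), reverse=True)
    if edges[0] != 1.0:
        raise ValueError("bins must start at 1.0 (the 100% class)")

    def label(v: float) -> str:
        if v >= 1.0:
            return "100"
        for hi, lo in zip(edges, edges[1:]):
            if lo <= v < hi:
                return f"{int(round(lo * 100))}-{int(round(hi * 100))}"
        return f"<{int(round(edges[-1] * 100))}"

    rows = []
    for prof in profiles:
        rows.append(
            {
                "position": prof.column + 1,
                "modal_residue": prof.modal_residue if prof.counts else "-",
                "conservation": prof.conservation,
                "bin": label(prof.conservation) if prof.counts else "gap",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pocket maps
# ---------------------------------------------------------------------------


def _validate_pocket_map(data: Mapping[str, Sequence[int]]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for pocket, positions in data.items():
        if pocket not in POCKET_LABELS:
            raise ValueError(f"pocket label {pocket!r} not in A-F")
        pos = [int(p) for p in positions]
        if not pos or any(p < 1 for p in pos):
            raise ValueError(f"pocket {pocket!r}: positions must be 1-based and non-empty")
        out[pocket] = pos
    return out


def load_pocket_map(path: str | Path) -> dict[str, list[int]]:
    """Load a pocket → 1-based-position map from a JSON file."""
    with open(path) as fh:
        return _validate_pocket_map(json.load(fh))


def _bundled(name: str) -> dict[str, list[int]]:
    text = resources.files("mhcdiv.data").joinpath(name).read_text()
    return _validate_pocket_map(json.loads(text))


def example_pocket_map() -> dict[str, list[int]]:
    """Partial pocket map with the peptide-binding positions reported for
    HLA-derived structures (A: 6, 58, 158; B: 6; D: 158; F: 83, 122, 145).
    A full map must be supplied by the user for real analyses."""
    return _bundled("pockets_hla_example.json")


def synthetic_pocket_map() -> dict[str, list[int]]:
    """Full A-F pocket assignment used with the synthetic generator.

    The residue sets are synthetic: they are loosely modelled on the HLA
    groove (pocket positions concentrated in the alpha1/alpha2 helices,
    with position 6 shared between pockets A and B and position 158
    between A and D) but are NOT an experimentally determined map."""
    return _bundled("pockets_synthetic.json")
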