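"""Representative-allele selection per allelic group.

Classical MHC nomenclature clusters alleles into 2- or 3-digit allelic
groups that act as sequence-similarity bins.  The dataset-construction
procedure selects, for each group, the allele with the lowest similarity
to the alleles of all *other* groups (phase 1), and for loci with fewer
groups than the target panel size pads the panel with additional alleles
from the redundant groups, each chosen to minimise similarity to the
alleles already selected (phase 2).

"Lowest similarity" is operationalised as the lowest MEAN pairwise
identity (identical non-gap columns over columns where neither sequence
has a gap); a ``score="min"`` variant uses the minimum identity instead.
Ties are broken lexicographically on the raw allele name and flagged in
the provenance, so selection is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .allele_io import AlleleRecord

__all__ = [
    "GroupedAlleles",
    "RepresentativeSet",
    "group_alleles",
    "mean_cross_group_identity",
    "select_representatives",
]


def _identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("sequences have unequal lengths")
    same = comparable = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y:
            same += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return same / comparable


def mean_cross_group_identity(candidate: str, others: Sequence[str]) -> float:
    """Mean pairwise identity of ``candidate`` against each of ``others``."""
    if not others:
        raise ValueError("no comparison sequences supplied")
    return float(np.mean([_identity(candidate, o) for o in others]))


def _aggregate(candidate: str, others: Sequence[str], score: str) -> float:
    if not others:
        raise ValueError("no comparison sequences supplied")
    idents = [_identity(candidate, o) for o in others]
    if score == "mean":
        return float(np.mean(idents))
    if score == "min":
        return float(np.min(idents))
    raise ValueError(f"unknown score {score!r} (expected 'mean' or 'min')")


@dataclass
class GroupedAlleles:
    """Alleles of one locus, keyed by allelic group id (as printed)."""

    locus: str
    groups: dict[str, list[AlleleRecord]]

    def __post_init__(self) -> None:
        for gid, records in self.groups.items():
            if not records:
                raise ValueError(f"group {gid!r} is empty")
            for rec in records:
                if rec.name.locus != self.locus:
                    raise ValueError(
                        f"record {rec.name.raw} does not belong to locus {self.locus}"
                    )
                if rec.name.group != gid:
                    raise ValueError(
                        f"record {rec.name.raw} filed under group {gid!r}"
                    )

    @property
    def n_alleles(self) -> int:
        return sum(len(v) for v in self.groups.values())


def group_alleles(records: Iterable[AlleleRecord]) -> list[GroupedAlleles]:
    """Partition records into per-locus :class:`GroupedAlleles`."""
    by_locus: dict[str, dict[str, list[AlleleRecord]]] = {}
    for rec in records:
        by_locus.setdefault(rec.name.locus, {}).setdefault(rec.name.group, []).append(rec)
    out = []
    for locus in sorted(by_locus):
        groups = {
            gid: sorted(v, key=lambda r: r.name.raw)
            for gid, v in sorted(by_locus[locus].items(), key=lambda kv: (len(kv[0]), kv[0]))
        }
        out.append(GroupedAlleles(locus=locus, groups=groups))
    return out


@dataclass
class RepresentativeSet:
    """Selected panel with per-allele provenance."""

    locus: str
    chosen: list[AlleleRecord]
    #: (allele, group, phase, selection score, tie_break_applied)
    provenance: list[tuple[str, str, int, float, bool]] = field(default_factory=list)


def _seq_getter_default(rec: AlleleRecord) -> str:
    return rec.protein if rec.protein is not None else rec.sequence("nt")


def select_representatives(
    grouped: GroupedAlleles,
    target: int = 20,
    score: str = "mean",
    seq_getter: Callable[[AlleleRecord], str] | None = None,
    columns: Sequence[int] | None = None,
    allow_subsample: bool = False,
) -> RepresentativeSet:
    """Two-phase representative selection for one locus.

    Phase 1 picks, per allelic group, the member minimising the aggregate
    cross-group identity against all alleles of all other groups.  When
    the locus has fewer groups than ``target``, phase 2 repeatedly adds,
    from the remaining pool, the allele minimising the aggregate identity
    to the already-chosen panel until the target is reached or the pool
    is exhausted.  ``columns`` restricts the comparison to the given
    0-based columns (e.g. the PBR columns of the region under study).

    ``target`` below the number of groups is refused unless
    ``allow_subsample`` is set, in which case the ``target`` phase-1
    representatives with the lowest scores are kept.
    """
    getter = seq_getter or _seq_getter_default

    def seq_of(rec: AlleleRecord) -> str:
        s = getter(rec)
        if columns is not None:
            s = "".join(s[i] for i in columns)
        return s

    gids = sorted(grouped.groups, key=lambda g: (len(g), g))
    if target < len(gids) and not allow_subsample:
        raise ValueError(
            f"target {target} below the {len(gids)} allelic groups of "
            f"{grouped.locus}; pass allow_subsample=True to subsample"
        )

    seqs = {
        rec.name.raw: seq_of(rec)
        for records in grouped.groups.values()
        for rec in records
    }

    chosen: list[AlleleRecord] = []
    provenance: list[tuple[str, str, int, float, bool]] = []

    # Phase 1: one representative per group, lowest cross-group identity.
    phase1: list[tuple[AlleleRecord, str, float, bool]] = []
    for gid in gids:
        members = sorted(grouped.groups[gid], key=lambda r: r.name.raw)
        others = [
            seqs[rec.name.raw]
            for other_gid in gids
            if other_gid != gid
            for rec in grouped.groups[other_gid]
        ]
        if not others:  # single-group locus: pick lexicographically first
            best, best_score, tie = members[0], float("nan"), len(members) > 1
        else:
            scored = [
                (_aggregate(seqs[rec.name.raw], others, score), rec.name.raw, rec)
                for rec in members
            ]
            scored.sort(key=lambda t: (t[0], t[1]))
            best_score, _, best = scored[0]
            tie = len(scored) > 1 and scored[1][0] == best_score
        phase1.append((best, gid, best_score, tie))

    if allow_subsample and target < len(gids):
        phase1.sort(key=lambda t: (t[2], t[0].name.raw))
        phase1 = sorted(phase1[:target], key=lambda t: (len(t[1]), t[1]))

    for rec, gid, sc, tie in phase1:
        chosen.append(rec)
        provenance.append((rec.name.raw, gid, 1, sc, tie))

    # Phase 2: pad from redundant groups up to the target panel size.
    if len(chosen) < target:
        chosen_names = {rec.name.raw for rec in chosen}
        pool = sorted(
            (
                rec
                for records in grouped.groups.values()
                for rec in records
                if rec.name.raw not in chosen_names
            ),
            key=lambda r: r.name.raw,
        )
        while len(chosen) < target and pool:
            panel = [seqs[rec.name.raw] for rec in chosen]
            scored = [
                (_aggregate(seqs[rec.name.raw], panel, score), rec.name.raw, rec)
                for rec in pool
            ]
            scored.sort(key=lambda t: (t[0], t[1]))
            best_score, _, best = scored[0]
            tie = len(scored) > 1 and scored[1][0] == best_score
            chosen.append(best)
            provenance.append((best.name.raw, best.name.group, 2, best_score, tie))
            pool = [rec for rec in pool if rec.name.raw != best.name.raw]

    return RepresentativeSet(locus=grouped.locus, chosen=chosen, provenance=provenance)
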