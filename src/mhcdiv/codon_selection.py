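"""Nei-Gojobori synonymous/nonsynonymous analysis of coding alignments.

Implements the counting method of Nei & Gojobori (1986): fractional
synonymous (s) and nonsynonymous (n) site counts per codon obtained by
enumerating the nine single-nucleotide neighbours (mutations to stop
codons excluded from numerator and denominator), pathway-averaged
observed differences for codon pairs differing at 1-3 positions, and the
Jukes-Cantor correction ``d = -(3/4) ln(1 - 4p/3)`` applied to the
proportions pS = Sd/S and pN = Nd/N.  Ka/Ks > 1 is the positive-selection
signal expected in the peptide-binding region of classical MHC genes.

The polymorphic-site classifier implements the Table-3-style reading of
"synonymous/nonsynonymous sites": variable nucleotide columns classified
by the protein-level effect of the observed changes relative to the
consensus codon, not NG86 potential-site sums (which are reported
separately by :func:`pairwise_kaks`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_io import RegionSpec

__all__ = [
    "GENETIC_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonSiteCounts",
    "PairwiseKaKs",
    "PolymorphicSiteClass",
    "codon_site_counts",
    "pairwise_kaks",
    "mean_pairwise_kaks",
    "classify_polymorphic_sites",
    "shared_nonsyn_sites",
    "domain_kaks_summary",
]

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

#: Standard genetic code, codon -> one-letter amino acid ('*' = stop).
GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))


@dataclass(frozen=True)
class CodonSiteCounts:
    """Fractional synonymous/nonsynonymous site counts of one codon."""

    codon: str
    s: float
    n: float


def _site_counts_uncached(codon: str) -> CodonSiteCounts:
    if codon not in GENETIC_CODE or codon in STOP_CODONS:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = GENETIC_CODE[codon]
    s = n = 0.0
    for pos in range(3):
        syn = non = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue  # NG86: nonsense changes excluded entirely
            if GENETIC_CODE[alt] == aa:
                syn += 1
            else:
                non += 1
        total = syn + non  # >= 1 for every sense codon
        s += syn / total
        n += non / total
    return CodonSiteCounts(codon, s, n)


_SITE_COUNTS: dict[str, CodonSiteCounts] = {}


def codon_site_counts(codon: str) -> CodonSiteCounts:
    """NG86 site counts: per position, the fraction of non-stop
    single-nucleotide changes that are synonymous, summed over the three
    positions (so s + n == 3 for every sense codon)."""
    codon = codon.upper()
    hit = _SITE_COUNTS.get(codon)
    if hit is None:
        hit = _site_counts_uncached(codon)
        _SITE_COUNTS[codon] = hit
    return hit


# ---------------------------------------------------------------------------
# Pathway-averaged differences and pairwise Ka/Ks
# ---------------------------------------------------------------------------

_PATHWAYS: dict[tuple[str, str], tuple[float, float]] = {}


def _pathway_sd_nd(ca: str, cb: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over all mutational
    pathways; pathways passing through a stop codon are excluded.  If
    every pathway crosses a stop (cannot occur between sense codons in
    the standard code, kept as a safeguard) stop steps count as
    nonsynonymous and all pathways are used."""
    key = (ca, cb)
    hit = _PATHWAYS.get(key)
    if hit is not None:
        return hit
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = ca
        s = n = 0
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                n += 1
            elif GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        return float(s), float(n)

    paths = [r for order in permutations(positions) if (r := walk(order, False))]
    if not paths:  # pragma: no cover - unreachable for the standard code
        paths = [walk(order, True) for order in permutations(positions)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    _PATHWAYS[key] = (sd, nd)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """JC correction; None when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class PairwiseKaKs:
    """NG86 + Jukes-Cantor Ka/Ks summary for one sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def Ks(self) -> float | None:
        return _jukes_cantor(self.pS)

    @property
    def Ka(self) -> float | None:
        return _jukes_cantor(self.pN)

    @property
    def ratio(self) -> float:
        """Ka/Ks; inf when Ks == 0 and Ka > 0, nan when undefined."""
        ka, ks = self.Ka, self.Ks
        if ka is None or ks is None:
            return float("nan")
        if ks == 0.0:
            return float("inf") if ka > 0 else float("nan")
        return ka / ks


def _clean_codons(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("sequences have unequal lengths")
    if len(a) % 3 != 0:
        raise ValueError(f"alignment length {len(a)} is not a multiple of 3")
    pairs = []
    au, bu = a.upper(), b.upper()
    ok = set("ACGT")
    for i in range(0, len(a), 3):
        ca, cb = au[i : i + 3], bu[i : i + 3]
        if set(ca) <= ok and set(cb) <= ok and ca not in STOP_CODONS and cb not in STOP_CODONS:
            pairs.append((ca, cb))
    return pairs


def pairwise_kaks(a: str, b: str) -> PairwiseKaKs:
    """NG86 Ka/Ks between two codon-aligned CDS sequences.

    Codon columns containing gaps, ambiguity symbols or stop codons are
    dropped pairwise.  S and N are averaged over the two sequences; Sd
    and Nd are pathway-averaged over all stop-free mutational pathways.
    """
    pairs = _clean_codons(a, b)
    if not pairs:
        raise ValueError("no comparable codon columns")
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        xa = codon_site_counts(ca)
        xb = codon_site_counts(cb)
        S += (xa.s + xb.s) / 2.0
        N += (xa.n + xb.n) / 2.0
        if ca != cb:
            sd, nd = _pathway_sd_nd(ca, cb)
            Sd += sd
            Nd += nd
    return PairwiseKaKs(S=S, N=N, Sd=Sd, Nd=Nd, n_codons=len(pairs))


def mean_pairwise_kaks(
    seqs: Sequence[str], per_allele: bool = False
) -> tuple[float, int, int]:
    """Mean Ka/Ks over all unordered pairs of an aligned CDS set.

    Pairs whose ratio is undefined (Ks == 0 or uncorrectable proportions)
    are excluded and counted.  Returns ``(mean_ratio, n_used, n_excluded)``;
    the mean is nan when no pair is informative.  With ``per_allele`` the
    mean is taken per allele (each allele against all others) first and
    then averaged — the alternative reading of "averaging the ratios for
    each allele".
    """
    n = len(seqs)
    ratios = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            r = pairwise_kaks(seqs[i], seqs[j]).ratio
            ratios[i, j] = ratios[j, i] = r
    iu = np.triu_indices(n, k=1)
    flat = ratios[iu]
    usable = np.isfinite(flat)
    n_used, n_excluded = int(usable.sum()), int((~usable).sum())
    if n_used == 0:
        return float("nan"), 0, n_excluded
    if per_allele:
        per = []
        for i in range(n):
            row = np.delete(ratios[i], i)
            row = row[np.isfinite(row)]
            if row.size:
                per.append(row.mean())
        return float(np.mean(per)), n_used, n_excluded
    return float(flat[usable].mean()), n_used, n_excluded


# ---------------------------------------------------------------------------
# Polymorphic-site classification and shared nonsynonymous sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolymorphicSiteClass:
    """Effect classification of one variable nucleotide column."""

    column: int  # 0-based nucleotide column
    klass: str  # synonymous | nonsynonymous | mixed | invariant
    contributing: tuple[int, ...] = ()  # sequence indices with non-consensus base

    @property
    def position(self) -> int:
        """1-based nucleotide position."""
        return self.column + 1


def _modal_codon(codons: list[str]) -> str:
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    return min(counts, key=lambda c: (-counts[c], c))


def classify_polymorphic_sites(
    seqs: Sequence[str],
) -> tuple[list[PolymorphicSiteClass], dict[str, float]]:
    """Classify every variable nucleotide column by protein-level effect.

    The consensus codon of each codon column is the modal observed codon
    (ties alphabetical).  A variable nucleotide column is *synonymous*
    when every observed alternative base, substituted in isolation into
    the consensus codon, preserves the encoded amino acid; *nonsynonymous*
    when every such change alters it (changes creating a stop codon count
    as nonsynonymous); *mixed* when both kinds occur.  Mixed sites count
    toward the nonsynonymous tally (reported separately too).
    """
    if len(seqs) < 2:
        raise ValueError("classification requires at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences have unequal lengths")
    if L % 3 != 0:
        raise ValueError(f"alignment length {L} is not codon-aligned")

    ok = set("ACGT")
    upper = [s.upper() for s in seqs]
    sites: list[PolymorphicSiteClass] = []
    n_syn = n_non = n_mixed = n_var = 0
    for cc in range(L // 3):
        codons = [s[3 * cc : 3 * cc + 3] for s in upper]
        valid_idx = [k for k, c in enumerate(codons) if set(c) <= ok]
        if not valid_idx:
            for off in range(3):
                sites.append(PolymorphicSiteClass(3 * cc + off, "invariant"))
            continue
        cons = _modal_codon([codons[k] for k in valid_idx])
        cons_aa = GENETIC_CODE[cons]
        for off in range(3):
            col = 3 * cc + off
            observed = {codons[k][off] for k in valid_idx}
            if len(observed) < 2:
                sites.append(PolymorphicSiteClass(col, "invariant"))
                continue
            n_var += 1
            syn = non = False
            for base in sorted(observed - {cons[off]}):
                alt = cons[:off] + base + cons[off + 1 :]
                if alt in STOP_CODONS or GENETIC_CODE[alt] != cons_aa:
                    non = True
                else:
                    syn = True
            if syn and non:
                klass = "mixed"
                n_mixed += 1
            elif non:
                klass = "nonsynonymous"
                n_non += 1
            else:
                klass = "synonymous"
                n_syn += 1
            contributing = tuple(
                k for k in valid_idx if codons[k][off] != cons[off]
            )
            sites.append(PolymorphicSiteClass(col, klass, contributing))

    nonsyn_total = n_non + n_mixed  # mixed counts toward nonsynonymous
    summary = {
        "n_sites": float(L),
        "n_variable": float(n_var),
        "n_synonymous": float(n_syn),
        "n_nonsynonymous": float(nonsyn_total),
        "n_mixed": float(n_mixed),
        "pct_variable": 100.0 * n_var / L,
        "pct_synonymous": 100.0 * n_syn / L,
        "pct_nonsynonymous": 100.0 * nonsyn_total / L,
        "syn_nonsyn_ratio": (n_syn / nonsyn_total) if nonsyn_total else float("nan"),
    }
    return sites, summary


def shared_nonsyn_sites(
    classified: Mapping[str, Sequence[PolymorphicSiteClass]],
    include_mixed: bool = True,
) -> list[int]:
    """1-based positions classed nonsynonymous in EVERY member locus.

    All loci must be on a common coordinate frame (equal column counts).
    """
    if not classified:
        raise ValueError("no loci supplied")
    frames = {max(s.column for s in sites) for sites in classified.values()}
    if len(frames) != 1:
        raise ValueError("loci are not on a common coordinate frame")
    wanted = {"nonsynonymous"} | ({"mixed"} if include_mixed else set())
    shared: set[int] | None = None
    for sites in classified.values():
        positions = {s.position for s in sites if s.klass in wanted}
        shared = positions if shared is None else shared & positions
    return sorted(shared or ())


def domain_kaks_summary(
    seqs: Sequence[str],
    spec: RegionSpec | None = None,
    per_allele: bool = False,
) -> pd.DataFrame:
    """Per-domain mean pairwise Ka/Ks table for a PBR codon alignment.

    ``spec`` defaults to the PBR coordinate frame (alpha1 codons [0, 90),
    alpha2 [90, 182)).  Pairs with Ks == 0 or uncorrectable proportions
    are excluded from the mean and counted; a mean ratio above 1 is
    flagged as the positive-selection signal.
    """
    spec = spec or RegionSpec.pbr_only()
    rows = []
    for label, start, end in spec.intervals:
        cols = range(3 * start, 3 * end)
        sub = ["".join(s[i] for i in cols) for s in seqs]
        mean_ratio, n_used, n_excluded = mean_pairwise_kaks(sub, per_allele=per_allele)
        rows.append(
            {
                "domain": label,
                "n_pairs_used": n_used,
                "n_pairs_excluded": n_excluded,
                "mean_kaks": mean_ratio,
                "positive_selection": bool(np.isfinite(mean_ratio) and mean_ratio > 1.0),
                "no_informative_pairs": n_used == 0,
            }
        )
    return pd.DataFrame(rows)
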