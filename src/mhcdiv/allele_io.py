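"""Allele sequence I/O, MHC nomenclature parsing and region partitioning.

This module is the bookkeeping layer of the pipeline: it reads IPD-style
FASTA files whose headers carry allele designations (``HLA-A*02:01``,
``BoLA-1*049:01``), enforces the loss-of-function filter that removes
coding sequences with premature stop codons, translates CDS records, and
maps alignment columns onto named gene regions — the peptide-binding
region (PBR; the alpha1/alpha2 domains encoded by exons 2 and 3, 546 nt /
182 codon columns in the default eight-exon class I gene model) versus the
remaining, more constrained exons.

All region coordinates are 0-based, half-open and expressed in codon
units; helpers convert from the 1-based amino-acid and nucleotide
positions conventional in the MHC literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SPECIES_BY_PREFIX",
    "AlleleParseError",
    "PrematureStopError",
    "AlleleName",
    "AlleleRecord",
    "RegionSpec",
    "parse_allele_name",
    "translate_cds",
    "read_alleles",
    "write_alleles",
    "write_drop_log",
    "partition_region",
    "pbr_aa_position_to_column",
    "pbr_nt_position_to_codon",
]

#: Species tags inferred from the locus prefix of an allele designation.
SPECIES_BY_PREFIX = {
    "SLA": "pig",
    "BoLA": "cattle",
    "Patr": "chimpanzee",
    "HLA": "human",
    "Ovar": "sheep",
    "Oana": "platypus",  # outgroup loci emitted by the synthetic generator
}


class AlleleParseError(ValueError):
    """Raised when a string is not a valid MHC allele designation."""


class PrematureStopError(ValueError):
    """Raised when a CDS translates with an internal stop codon."""


@dataclass(frozen=True)
class AlleleName:
    """Parsed MHC allele designation, e.g. ``BoLA-2*03:01``.

    ``group`` is the first colon-delimited numeric field after ``*`` and
    identifies the allelic group, kept exactly as printed (two or three
    digits — BoLA uses three).  ``protein`` is the second field when
    present; any further fields are preserved verbatim in ``extra`` so
    that parsing followed by re-serialisation is the identity.
    """

    locus: str
    group: str
    protein: str = ""
    extra: tuple[str, ...] = ()

    @property
    def raw(self) -> str:
        fields = [self.group]
        if self.protein:
            fields.append(self.protein)
        fields.extend(self.extra)
        return f"{self.locus}*{':'.join(fields)}"

    @property
    def species(self) -> str:
        prefix = self.locus.split("-")[0]
        return SPECIES_BY_PREFIX.get(prefix, "unknown")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.raw


def parse_allele_name(raw: str) -> AlleleName:
    """Parse an allele designation into (locus, group, protein).

    The designation must contain exactly one ``*`` separating the locus
    from the colon-delimited numeric fields; the first field (the allelic
    group) must be non-empty and numeric.
    """
    if raw.count("*") != 1:
        raise AlleleParseError(
            f"allele designation {raw!r} must contain exactly one '*'"
        )
    locus, _, rest = raw.partition("*")
    if not locus:
        raise AlleleParseError(f"allele designation {raw!r} has an empty locus")
    fields = rest.split(":")
    group = fields[0]
    if not group or not group.isdigit():
        raise AlleleParseError(
            f"allele designation {raw!r} has a missing or non-numeric "
            "allelic-group field"
        )
    protein = fields[1] if len(fields) > 1 else ""
    return AlleleName(locus=locus, group=group, protein=protein, extra=tuple(fields[2:]))


# Codon translations are cached; biopython's standard table is the source.
_CODON_AA: dict[str, str] = {}


def _codon_aa(codon: str) -> str:
    aa = _CODON_AA.get(codon)
    if aa is None:
        aa = str(Seq(codon).translate())
        _CODON_AA[codon] = aa
    return aa


def translate_cds(cds: str) -> str:
    """Translate a codon-aligned CDS with the standard genetic code.

    A terminal stop codon is stripped; an internal stop raises
    :class:`PrematureStopError`.  Fully gapped codons translate to ``-``;
    codons whose ambiguity cannot be resolved (e.g. ``NNT``) translate to
    ``X``, while family-ambiguous codons that still determine the residue
    (e.g. ``GGN``) are resolved.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    out: list[str] = []
    up = cds.upper()
    for i in range(0, len(up), 3):
        codon = up[i : i + 3]
        if codon == "---":
            out.append("-")
        elif "-" in codon:
            out.append("X")
        else:
            out.append(_codon_aa(codon))
    if out and out[-1] == "*":
        out.pop()
    protein = "".join(out)
    stop = protein.find("*")
    if stop != -1:
        raise PrematureStopError(f"internal stop codon at codon {stop + 1}")
    return protein


@dataclass
class AlleleRecord:
    """One named allele with its CDS and/or protein sequence."""

    name: AlleleName
    cds: str | None = None
    protein: str | None = None
    aligned: bool = False
    description: str = ""

    def sequence(self, level: str = "aa") -> str:
        """Return the requested sequence level (``"nt"`` or ``"aa"``)."""
        if level == "nt":
            if self.cds is None:
                raise ValueError(f"{self.name.raw}: no CDS available")
            return self.cds
        if self.protein is not None:
            return self.protein
        if self.cds is None:
            raise ValueError(f"{self.name.raw}: no sequence available")
        return translate_cds(self.cds)


def read_alleles(
    path: str | Path,
    expect_cds: bool = True,
    aligned: bool = False,
) -> tuple[list[AlleleRecord], list[tuple[str, str]]]:
    """Read an allele FASTA, applying the loss-of-function filter.

    Headers must begin with an allele designation token; free text after
    the first whitespace is kept as the record description.  CDS entries
    that fail translation (premature internal stop, incomplete codon) are
    dropped — never silently kept — and reported in the returned drop log
    as ``(allele, reason)`` pairs.  Duplicate designations are an error.
    """
    raw_records = list(SeqIO.parse(str(path), "fasta"))
    if not raw_records:
        raise ValueError(f"{path}: empty FASTA")
    ids = [r.id for r in raw_records]
    seen: set[str] = set()
    dupes = sorted({i for i in ids if i in seen or seen.add(i)})
    if dupes:
        raise ValueError(f"{path}: duplicate allele names: {', '.join(dupes)}")

    kept: list[AlleleRecord] = []
    dropped: list[tuple[str, str]] = []
    for rec in raw_records:
        name = parse_allele_name(rec.id)
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id) :].strip()
        if not expect_cds:
            kept.append(
                AlleleRecord(name, protein=seq, aligned=aligned, description=desc)
            )
            continue
        if not aligned and "-" in seq:
            raise ValueError(f"{rec.id}: gap characters in unaligned CDS input")
        bad = set(seq) - set("ACGTN-")
        if bad:
            raise ValueError(
                f"{rec.id}: invalid CDS characters {''.join(sorted(bad))!r}"
            )
        if len(seq) % 3 != 0:
            dropped.append((rec.id, f"length {len(seq)} not a multiple of 3"))
            continue
        try:
            protein = translate_cds(seq)
        except PrematureStopError as exc:
            dropped.append((rec.id, str(exc)))
            continue
        kept.append(
            AlleleRecord(name, cds=seq, protein=protein, aligned=aligned, description=desc)
        )
    return kept, dropped


def write_alleles(records: Iterable[AlleleRecord], path: str | Path, level: str = "nt") -> None:
    """Write records as FASTA (header = allele designation)."""
    out = []
    for rec in records:
        seq = rec.cds if (level == "nt" and rec.cds is not None) else rec.sequence(level)
        out.append(SeqRecord(Seq(seq), id=rec.name.raw, description=rec.description))
    SeqIO.write(out, str(path), "fasta")


def write_drop_log(dropped: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write the loss-of-function drop log as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("allele\treason\n")
        for allele, reason in dropped:
            fh.write(f"{allele}\t{reason}\n")


# ---------------------------------------------------------------------------
# Region specifications
# ---------------------------------------------------------------------------

PBR_LABELS = ("PBR_alpha1", "PBR_alpha2")


@dataclass(frozen=True)
class RegionSpec:
    """Named half-open codon intervals over an alignment.

    Intervals are ``(label, codon_start, codon_end)`` with 0-based,
    half-open codon coordinates; labels beginning with ``PBR_`` form the
    peptide-binding region, everything else is non-PBR.  The bundled
    default (:meth:`default`) encodes an eight-exon class I gene model in
    which exons 2 and 3 span 90 + 92 = 182 codons (546 nt).
    """

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        spans: list[tuple[int, int]] = []
        for label, start, end in self.intervals:
            if label in seen:
                raise ValueError(f"duplicate region label {label!r}")
            seen.add(label)
            if start < 0 or end < start:
                raise ValueError(f"invalid interval for {label!r}: [{start}, {end})")
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("region intervals overlap")

    # -- basic geometry -----------------------------------------------------

    @property
    def n_codons(self) -> int:
        return max((end for _, _, end in self.intervals), default=0)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.intervals)

    @property
    def pbr_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l.startswith("PBR_"))

    @property
    def nonpbr_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if not l.startswith("PBR_"))

    def _resolve(self, which: str | Iterable[str]) -> tuple[str, ...]:
        if isinstance(which, str):
            if which == "PBR":
                return self.pbr_labels
            if which == "NONPBR":
                return self.nonpbr_labels
            if which in self.labels:
                return (which,)
            raise KeyError(f"unknown region label {which!r}")
        return tuple(which)

    def columns(self, which: str | Iterable[str] = "PBR") -> list[int]:
        """Codon columns of the named region(s), in alignment order."""
        wanted = set(self._resolve(which))
        cols: list[int] = []
        for label, start, end in sorted(self.intervals, key=lambda iv: iv[1]):
            if label in wanted:
                cols.extend(range(start, end))
        return cols

    def nt_columns(self, which: str | Iterable[str] = "PBR") -> list[int]:
        """Nucleotide columns of the named region(s)."""
        return [3 * c + k for c in self.columns(which) for k in range(3)]

    # -- bundled defaults ---------------------------------------------------

    @classmethod
    def default(cls) -> "RegionSpec":
        """Eight-exon class I gene model (362 codons, 546-nt PBR)."""
        sizes = [
            ("NONPBR_E1", 24),
            ("PBR_alpha1", 90),
            ("PBR_alpha2", 92),
            ("NONPBR_E4", 92),
            ("NONPBR_E5", 37),
            ("NONPBR_E6", 11),
            ("NONPBR_E7", 11),
            ("NONPBR_E8", 5),
        ]
        intervals = []
        pos = 0
        for label, n in sizes:
            intervals.append((label, pos, pos + n))
            pos += n
        return cls(tuple(intervals))

    @classmethod
    def pbr_only(cls) -> "RegionSpec":
        """PBR coordinate frame: alpha1 [0, 90), alpha2 [90, 182)."""
        return cls((("PBR_alpha1", 0, 90), ("PBR_alpha2", 90, 182)))

    # -- config file I/O ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(tuple((label, int(v[0]), int(v[1])) for label, v in data.items()))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {label: [start, end] for label, start, end in self.intervals},
                fh,
                sort_keys=False,
            )


def partition_region(
    seq: str,
    spec: RegionSpec,
    which: str | Iterable[str] = "PBR",
    nucleotide: bool | None = None,
) -> str:
    """Extract the named region(s) from an aligned sequence.

    ``nucleotide`` is inferred from the sequence length when omitted
    (``len == 3 * n_codons`` → nucleotide; ``len == n_codons`` → amino
    acid).  Column order is preserved; a spec interval reaching past the
    end of the sequence is an error.
    """
    if nucleotide is None:
        if len(seq) == 3 * spec.n_codons:
            nucleotide = True
        elif len(seq) == spec.n_codons:
            nucleotide = False
        else:
            raise ValueError(
                f"cannot infer sequence unit: length {len(seq)} matches neither "
                f"{spec.n_codons} codons nor {3 * spec.n_codons} nt"
            )
    cols = spec.nt_columns(which) if nucleotide else spec.columns(which)
    if cols and cols[-1] >= len(seq):
        raise ValueError(
            f"region spec exceeds alignment length ({cols[-1] + 1} > {len(seq)})"
        )
    return "".join(seq[i] for i in cols)


def pbr_aa_position_to_column(position: int) -> int:
    """1-based amino-acid position within the PBR → 0-based codon column."""
    if position < 1:
        raise ValueError("amino-acid positions are 1-based")
    return position - 1


def pbr_nt_position_to_codon(position: int) -> int:
    """1-based nucleotide position within the PBR → 0-based codon column."""
    if position < 1:
        raise ValueError("nucleotide positions are 1-based")
    return (position - 1) // 3
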