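"""Synthetic IPD-like allele families with known ground truth.

The generator realises the evolutionary setting the analysis expects —
a gene tree of classical MHC class I loci from several species with
known duplication ages, allelic groups per locus, a 546-nt peptide-
binding region (PBR) evolving with an elevated nonsynonymous rate and a
constrained non-PBR — so every pipeline stage can be exercised without
any database download, against a machine-readable truth record.

The sequence model is a codon-level acceptance-rejection scheme: along
each branch, mutation events arrive as a Poisson process at ``mu`` per
nucleotide per Myr (modulated by per-site rate multipliers, used to
plant pocket hot spots, and boosted by ``max(1, omega)`` where positive
selection accelerates change); each event picks a target nucleotide
with transition/transversion bias ``kappa``; events creating stop
codons are rejected outright; nonsynonymous events are accepted with
probability ``omega / max(1, omega)`` and synonymous events with
``1 / max(1, omega)``, so the realised substitution rates are
``mu * omega`` per nonsynonymous and ``mu`` per synonymous opportunity
and dN/dS tracks the configured omega on both sides of 1.  Allelic
groups are a star coalescent below each locus: groups split at
``group_age`` Mya and alleles within a group at ``allele_age`` Mya.

Everything is driven by a single seed; identical configurations produce
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .allele_io import AlleleRecord, RegionSpec, parse_allele_name, write_alleles
from .codon_selection import GENETIC_CODE

__all__ = [
    "DEFAULT_GENE_TREE",
    "DEFAULT_HOTSPOTS",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate",
    "evolve_on_tree",
    "truth_report",
    "read_truth",
]

#: Gene tree of 12 classical class I loci (pig, cattle, chimpanzee,
#: human) plus a platypus-like outgroup, with branch lengths in Myr.
#: Node ages mirror the published divergence-time estimates used as
#: ground truth: primate/artiodactyl 60.41, BoLA/SLA 35.34, BoLA crown
#: 16.33, BoLA-1/-3 15.39, SLA crown 6.70, MHC-A vs B/C 24.97, B vs C
#: 19.86, orthologous human/chimp locus splits at 6.0.
DEFAULT_GENE_TREE = (
    "(((SLA-1:6.7,(SLA-2:6.0,SLA-3:6.0):0.7):28.64,"
    "((BoLA-1:15.39,BoLA-3:15.39):0.94,BoLA-2:16.33):19.01):25.07,"
    "((HLA-A:6.0,Patr-A:6.0):18.97,"
    "((HLA-B:6.0,Patr-B:6.0):13.86,(HLA-C:6.0,Patr-C:6.0):13.86):5.11):35.44)"
    ":119.59,Oana-N:180.0;"
)
# The outgroup leaf joins the ingroup at 180 Mya; written as a two-child
# root so dendropy keeps the ingroup/outgroup split explicit.
DEFAULT_GENE_TREE = "(" + DEFAULT_GENE_TREE.rstrip(";") + ");"

#: Default per-site rate multipliers: the synthetic E-pocket positions
#: (1-based PBR amino-acid positions) evolve 3x faster, planting the
#: "pocket E most diverse" signal with known truth.
DEFAULT_HOTSPOTS = {97: 3.0, 114: 3.0, 147: 3.0, 152: 3.0, 156: 3.0}

_BASES = "TCAG"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

# codon index (16*b1 + 4*b2 + b3 over TCAG) -> amino-acid byte, 255 = stop
_AA_OF_CODON = np.zeros(64, dtype=np.uint8)
for _codon, _aa in GENETIC_CODE.items():
    _idx = 16 * _BASE_IDX[_codon[0]] + 4 * _BASE_IDX[_codon[1]] + _BASE_IDX[_codon[2]]
    _AA_OF_CODON[_idx] = 255 if _aa == "*" else ord(_aa)
_SENSE_IDX = np.flatnonzero(_AA_OF_CODON != 255)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    gene_tree: str = DEFAULT_GENE_TREE
    outgroup_label: str = "Oana-N"
    groups_per_locus: int = 20
    outgroup_groups: int = 2
    alleles_per_group: tuple[int, int] = (1, 3)
    group_age: float = 5.0  # Mya; must sit below the shallowest locus split
    allele_age: float = 0.5  # Mya
    regions: RegionSpec = field(default_factory=RegionSpec.default)
    omega_pbr: float = 2.0
    omega_nonpbr: float = 0.1
    #: PBR omega on gene-tree branches outside the locus subtrees: the
    #: elevated omega of the PBR is a within-locus allelic phenomenon,
    #: while long-term inter-locus divergence is dominated by purifying
    #: constraint.
    omega_pbr_ancestral: float = 0.2
    pbr_omega_by_species: dict[str, float] = field(default_factory=dict)
    kappa: float = 2.0
    mutation_rate: float = 5e-3  # mutations per nt per Myr, before selection
    #: 1-based PBR amino-acid position -> rate multiplier
    site_rate_multipliers: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HOTSPOTS)
    )

    def __post_init__(self) -> None:
        lo, hi = self.alleles_per_group
        if lo < 1 or hi < lo:
            raise ValueError("alleles_per_group must be (lo, hi) with 1 <= lo <= hi")
        if self.groups_per_locus < 1 or self.outgroup_groups < 1:
            raise ValueError("group counts must be >= 1")
        if not (0 < self.allele_age <= self.group_age):
            raise ValueError("need 0 < allele_age <= group_age")
        if min(self.omega_pbr, self.omega_nonpbr, self.omega_pbr_ancestral) < 0:
            raise ValueError("omega must be >= 0")
        if min(self.pbr_omega_by_species.values(), default=0.0) < 0:
            raise ValueError("omega must be >= 0")
        if self.mutation_rate < 0 or self.kappa <= 0:
            raise ValueError("mutation_rate >= 0 and kappa > 0 required")

    # -- config file I/O ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "alleles_per_group" in data:
            data["alleles_per_group"] = tuple(data["alleles_per_group"])
        if "regions" in data:
            data["regions"] = RegionSpec(
                tuple((l, int(v[0]), int(v[1])) for l, v in data["regions"].items())
            )
        if "site_rate_multipliers" in data:
            data["site_rate_multipliers"] = {
                int(k): float(v) for k, v in data["site_rate_multipliers"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "gene_tree": self.gene_tree,
            "outgroup_label": self.outgroup_label,
            "groups_per_locus": self.groups_per_locus,
            "outgroup_groups": self.outgroup_groups,
            "alleles_per_group": list(self.alleles_per_group),
            "group_age": self.group_age,
            "allele_age": self.allele_age,
            "regions": {l: [s, e] for l, s, e in self.regions.intervals},
            "omega_pbr": self.omega_pbr,
            "omega_nonpbr": self.omega_nonpbr,
            "omega_pbr_ancestral": self.omega_pbr_ancestral,
            "pbr_omega_by_species": dict(self.pbr_omega_by_species),
            "kappa": self.kappa,
            "mutation_rate": self.mutation_rate,
            "site_rate_multipliers": {
                int(k): float(v) for k, v in self.site_rate_multipliers.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SyntheticDataset:
    """Simulated allele records plus the machine-readable truth."""

    records: list[AlleleRecord]
    regions: RegionSpec
    truth: dict
    config: SimulationConfig

    def to_fasta(self, path: str | Path) -> None:
        write_alleles(self.records, path, level="nt")


# ---------------------------------------------------------------------------
# Core sequence evolution
# ---------------------------------------------------------------------------


class _BranchContext:
    """Per-branch event rates and acceptance probabilities.

    Positive selection (omega > 1) accelerates the regional event rate
    by ``max(1, omega)`` while the acceptance probabilities become
    ``omega / max(1, omega)`` for nonsynonymous and ``1 / max(1, omega)``
    for synonymous changes, so the realised per-site substitution rates
    are ``mu * omega`` (nonsynonymous) and ``mu`` (synonymous) and the
    realised dN/dS tracks omega on both sides of 1."""

    def __init__(self, mu: float, site_mult_nt: np.ndarray, omega: np.ndarray) -> None:
        omega = np.asarray(omega, dtype=float)
        boost = np.maximum(1.0, omega)
        self.p_non = omega / boost
        self.p_syn = 1.0 / boost
        mult = np.asarray(site_mult_nt, dtype=float) * np.repeat(boost, 3)
        total = float(mult.sum())
        self.total_rate = mu * total
        self.site_probs = mult / total if total > 0 else None


class _Evolver:
    """Shared per-simulation state for branch evolution."""

    def __init__(
        self,
        n_codons: int,
        mu: float,
        kappa: float,
        site_mult_nt: np.ndarray,
        rng: np.random.Generator,
    ) -> None:
        self.n_nt = 3 * n_codons
        self.mu = mu
        self.kappa = kappa
        self.rng = rng
        self.site_mult = np.asarray(site_mult_nt, dtype=float)
        if self.site_mult.shape != (self.n_nt,):
            raise ValueError("site multiplier array has wrong length")
        self.ts_threshold = kappa / (kappa + 2.0)

    def make_context(self, omega: np.ndarray) -> _BranchContext:
        return _BranchContext(self.mu, self.site_mult, omega)

    def root_sequence(self) -> np.ndarray:
        codons = self.rng.choice(_SENSE_IDX, size=self.n_nt // 3)
        seq = np.empty(self.n_nt, dtype=np.int64)
        seq[0::3] = codons // 16
        seq[1::3] = (codons // 4) % 4
        seq[2::3] = codons % 4
        return seq

    def evolve_branch(
        self, seq: np.ndarray, t: float, ctx: _BranchContext
    ) -> np.ndarray:
        seq = seq.copy()
        if ctx.total_rate <= 0 or t <= 0:
            return seq
        rng = self.rng
        p_syn, p_non = ctx.p_syn, ctx.p_non
        n_events = int(rng.poisson(ctx.total_rate * t))
        if n_events == 0:
            return seq
        sites = rng.choice(self.n_nt, size=n_events, p=ctx.site_probs)
        u_target = rng.random(n_events)
        u_accept = rng.random(n_events)
        thr = self.ts_threshold
        for k in range(n_events):
            i = int(sites[k])
            base = seq[i]
            u = u_target[k]
            if u < thr:
                new_base = base ^ 1  # transition partner (T<->C, A<->G)
            else:
                # the two transversion targets lie in the other base class
                first = 2 if base < 2 else 0
                new_base = first if (u - thr) / (1.0 - thr) < 0.5 else first + 1
            c = i // 3
            pos = i % 3
            j = 3 * c
            old_idx = 16 * seq[j] + 4 * seq[j + 1] + seq[j + 2]
            new_idx = old_idx + (new_base - base) * (16, 4, 1)[pos]
            new_aa = _AA_OF_CODON[new_idx]
            if new_aa == 255:  # stop codon: event rejected
                continue
            p = p_syn[c] if new_aa == _AA_OF_CODON[old_idx] else p_non[c]
            if u_accept[k] < p:
                seq[i] = new_base
        return seq


def _seq_to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def evolve_on_tree(
    newick: str,
    n_codons: int,
    mutation_rate: float,
    omega: float = 1.0,
    kappa: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Evolve a codon sequence along an arbitrary tree (uniform omega).

    Branch lengths are read as time units; the per-nucleotide event rate
    is ``mutation_rate`` per unit time.  Returns ``(leaf_labels, CDS)``
    in Newick leaf order.  This is the primitive behind :func:`simulate`
    and is handy for clock simulations on user-supplied trees.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(seed)
    ev = _Evolver(n_codons, mutation_rate, kappa, np.ones(3 * n_codons), rng)
    ctx = ev.make_context(np.full(n_codons, float(omega)))
    tree.seed_node._seq = ev.root_sequence()
    labels: list[str] = []
    seqs: list[str] = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node._seq = ev.evolve_branch(
                node.parent_node._seq, node.edge.length or 0.0, ctx
            )
        if node.is_leaf():
            labels.append(node.taxon.label)
            seqs.append(_seq_to_str(node._seq))
    return labels, seqs


# ---------------------------------------------------------------------------
# The IPD-style generator
# ---------------------------------------------------------------------------


def _species_of_locus(locus: str) -> str:
    return parse_allele_name(f"{locus}*01").species


def _site_multipliers(config: SimulationConfig) -> np.ndarray:
    mult = np.ones(3 * config.regions.n_codons)
    pbr_cols = config.regions.columns("PBR")
    for pos, m in config.site_rate_multipliers.items():
        if not 1 <= pos <= len(pbr_cols):
            raise ValueError(f"hotspot position {pos} outside the PBR")
        c = pbr_cols[pos - 1]
        mult[3 * c : 3 * c + 3] = m
    return mult


def _omega_array(config: SimulationConfig, species: str | None) -> np.ndarray:
    """Per-codon omega for a branch context: ``species`` names a
    within-locus branch; ``None`` is an ancestral inter-locus branch."""
    omega = np.full(config.regions.n_codons, config.omega_nonpbr)
    if species is None:
        pbr = config.omega_pbr_ancestral
    else:
        pbr = config.pbr_omega_by_species.get(species, config.omega_pbr)
    omega[config.regions.columns("PBR")] = pbr
    return omega


def _expand_locus(
    leaf: dendropy.Node, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[dendropy.Node, str]]:
    """Replace a locus leaf with its allelic-group star coalescent.

    Returns ``(leaf_node, allele_name)`` pairs for the new allele leaves.
    """
    locus = leaf.taxon.label
    is_outgroup = locus == config.outgroup_label
    n_groups = config.outgroup_groups if is_outgroup else config.groups_per_locus
    edge_len = leaf.edge.length or 0.0
    if edge_len < config.group_age:
        raise ValueError(
            f"locus {locus}: terminal branch ({edge_len} Myr) shorter than "
            f"group_age ({config.group_age} Myr)"
        )
    species = _species_of_locus(locus)
    leaf.taxon = None
    leaf.edge.length = edge_len - config.group_age
    pad = max(2, len(str(n_groups)))
    lo, hi = config.alleles_per_group
    alleles: list[tuple[dendropy.Node, str]] = []
    for g in range(1, n_groups + 1):
        gid = str(g).zfill(pad)
        k = 1 if is_outgroup else int(rng.integers(lo, hi + 1))
        group_node = dendropy.Node()
        leaf.add_child(group_node)
        group_node._ctx = species
        if k == 1:
            group_node.edge.length = config.group_age
            name = f"{locus}*{gid}:01"
            alleles.append((group_node, name))
        else:
            group_node.edge.length = config.group_age - config.allele_age
            for p in range(1, k + 1):
                tip = dendropy.Node()
                group_node.add_child(tip)
                tip.edge.length = config.allele_age
                tip._ctx = species
                name = f"{locus}*{gid}:{str(p).zfill(2)}"
                alleles.append((tip, name))
    return alleles


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate one synthetic allele-family dataset (fully seeded)."""
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.gene_tree, schema="newick")
    locus_leaves = list(tree.leaf_node_iter())
    loci = [leaf.taxon.label for leaf in locus_leaves]
    if len(set(loci)) != len(loci):
        raise ValueError("gene tree has duplicate locus labels")

    # truth: node ages of the gene tree before allele expansion
    depth_below: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depth_below[id(node)] = 0.0
        else:
            depth_below[id(node)] = max(
                depth_below[id(c)] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    node_ages = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = ",".join(sorted(l.taxon.label for l in node.leaf_iter()))
        node_ages.append({"clade": clade, "age_mya": depth_below[id(node)]})

    allele_leaves: list[tuple[dendropy.Node, str]] = []
    for leaf in locus_leaves:
        allele_leaves.extend(_expand_locus(leaf, config, rng))

    n_codons = config.regions.n_codons
    ev = _Evolver(
        n_codons, config.mutation_rate, config.kappa, _site_multipliers(config), rng
    )
    all_species = {_species_of_locus(locus) for locus in loci}
    contexts: dict[str | None, _BranchContext] = {
        None: ev.make_context(_omega_array(config, None))
    }
    for species in sorted(all_species | set(config.pbr_omega_by_species)):
        contexts[species] = ev.make_context(_omega_array(config, species))

    name_of = {id(node): name for node, name in allele_leaves}
    tree.seed_node._seq = ev.root_sequence()
    records: list[AlleleRecord] = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            ctx = contexts.get(getattr(node, "_ctx", None), contexts[None])
            node._seq = ev.evolve_branch(
                node.parent_node._seq, node.edge.length or 0.0, ctx
            )
        if node.is_leaf():
            name = name_of[id(node)]
            cds = _seq_to_str(node._seq)
            records.append(
                AlleleRecord(parse_allele_name(name), cds=cds, aligned=True)
            )

    truth = {
        "seed": config.seed,
        "node_ages": node_ages,
        "group_age": config.group_age,
        "allele_age": config.allele_age,
        "omega_pbr": config.omega_pbr,
        "omega_nonpbr": config.omega_nonpbr,
        "omega_pbr_ancestral": config.omega_pbr_ancestral,
        "pbr_omega_by_species": dict(config.pbr_omega_by_species),
        "kappa": config.kappa,
        "mutation_rate": config.mutation_rate,
        "hotspots": {int(k): float(v) for k, v in config.site_rate_multipliers.items()},
    }
    return SyntheticDataset(
        records=records, regions=config.regions, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# Truth record I/O
# ---------------------------------------------------------------------------


def truth_report(dataset: SyntheticDataset) -> pd.DataFrame:
    """Machine-readable truth as a (section, key, value) table."""
    rows: list[dict[str, object]] = []
    t = dataset.truth
    for scalar in (
        "seed",
        "group_age",
        "allele_age",
        "omega_pbr",
        "omega_nonpbr",
        "omega_pbr_ancestral",
        "kappa",
        "mutation_rate",
    ):
        rows.append({"section": "param", "key": scalar, "value": t[scalar]})
    for species, omega in sorted(t["pbr_omega_by_species"].items()):
        rows.append({"section": "omega_pbr_species", "key": species, "value": omega})
    for entry in t["node_ages"]:
        rows.append(
            {"section": "node_age", "key": entry["clade"], "value": entry["age_mya"]}
        )
    for pos, mult in sorted(t["hotspots"].items()):
        rows.append({"section": "hotspot", "key": str(pos), "value": mult})
    return pd.DataFrame(rows, columns=["section", "key", "value"])


def write_truth(dataset: SyntheticDataset, path: str | Path) -> None:
    truth_report(dataset).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"section": str, "key": str})
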