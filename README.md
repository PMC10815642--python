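# mhcdiv

Comparative diversity analysis of classical MHC class I genes.

Classical MHC class I molecules present intracellular peptides to CD8+
T-cells; their peptide-binding region (PBR, the alpha1/alpha2 domains
encoded by exons 2–3, 546 nt) is among the most polymorphic coding
sequence in mammals, while the remaining exons are strongly conserved.
`mhcdiv` is a library and pipeline for comparing that diversity within
and between species (pig *SLA*, cattle *BoLA*, chimpanzee *Patr*, human
*HLA*, and relatives) from IPD-style allele FASTA files:

- **allele_io** — nomenclature parsing (`BoLA-1*049:01`), the
  premature-stop (loss-of-function) filter, translation, and
  PBR/non-PBR partitioning of codon-aligned sequences;
- **repset** — representative-allele selection: one allele per allelic
  group with the lowest cross-group identity, padded from redundant
  groups for loci with few groups;
- **diversity** — per-column amino-acid frequencies, conservation
  rates, Shannon diversity `H = -Σ p_i log2 p_i` (bits), region and
  peptide-binding-pocket (A–F) summaries;
- **distance** — consensus sequences, pairwise percent differences
  (p-distance with pairwise deletion), between-group mean distances;
- **codon_selection** — Nei–Gojobori (1986) Ka/Ks with fractional site
  counts, mutational-pathway averaging and Jukes–Cantor correction,
  polymorphic-site classification, shared nonsynonymous sites;
- **phylo** — neighbor joining (Saitou–Nei Q criterion), column
  bootstrap with bipartition supports, outgroup rooting, Newick I/O;
- **chronology** — relative-rate divergence dating with a single
  age calibration (Mya);
- **stats_compare** — Student's t-test, one-/two-way ANOVA, Tukey HSD,
  with paralogous genes as experimental repeats;
- **synth** — a fully seeded codon-level simulator of IPD-like allele
  families (known gene-tree ages, allelic groups, per-region dN/dS,
  planted pocket hot spots) so the entire pipeline runs and is tested
  without any database download.

Real IPD data are not bundled; the synthetic generator defines the
default study conditions (see `docs/methods.md`).

## Worked example

```python
from mhcdiv import SimulationConfig, simulate, diversity, repset
from mhcdiv.allele_io import translate_cds

cfg = SimulationConfig(seed=7)           # 12 loci + outgroup, ~490 alleles
ds = simulate(cfg)
pbr = cfg.regions.columns("PBR")         # 182 codon columns (546 nt)

grouped = {g.locus: g for g in repset.group_alleles(ds.records)}
reps = repset.select_representatives(grouped["SLA-1"], target=20, columns=pbr,
                                     allow_subsample=True)
seqs = ["".join(translate_cds(r.cds)[i] for i in pbr) for r in reps.chosen]
profiles = diversity.site_profiles(seqs)
print(f"SLA-1 PBR mean H = {diversity.mean_H(profiles):.3f}")
print(f"pocket H: { {k: round(v, 2) for k, v in diversity.pocket_H(profiles, diversity.synthetic_pocket_map()).items()} }")
```

prints

```
SLA-1 PBR mean H = 0.536
pocket H: {'A': 0.4, 'B': 0.85, 'C': 0.61, 'D': 0.64, 'E': 0.95, 'F': 0.41}
```

i.e. a PBR averaging ~0.54 bits of per-site diversity across the
20-representative panel, with pocket E — where the generator plants 3×
rate hot spots — the most diverse pocket of this locus and values
comparable to those reported for real class I loci (roughly 0.1–0.4
bits for whole regions and 0.4–1.8 for individual pockets).

The same analysis end-to-end, from a shell:

```sh
mhcdiv pipeline --out results/run1 --seed 7
```

writes the dataset, representative panels with provenance, the
between-locus distance grid, Shannon/pocket/Ka-Ks tables, conservation
maps, bootstrapped PBR and non-PBR trees, a calibrated chronogram and
the group statistics — all plain TSV/Newick/JSON, byte-identical for a
fixed seed.

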