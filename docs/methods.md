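# Methods

`mhcdiv` re-implements, as a tested library, a comparative analysis of
intra- and inter-species diversity of classical MHC class I genes (pig
SLA, cattle BoLA, chimpanzee Patr, human HLA, with an Ovar/sheep-style
locus supported by the nomenclature layer).  This note records the
models and procedures as the package implements them, the defaults of
the synthetic generator, the numerical choices, and the limitations.

## Sequence model of the gene

Classical class I genes are modelled with eight exons.  The
peptide-binding region (PBR) is the alpha1 + alpha2 domains encoded by
exons 2 and 3; the bundled default region specification assigns them 90
and 92 codons (546 nt, 182 codon columns), with the remaining exons
(E1, E4–E8; 180 codons in the default layout) forming the non-PBR.
The nucleotide counts are taken as authoritative: descriptions of exon 2
as "89 amino acids" circulate in the literature but are inconsistent
with 270 nt, so the package works with 90 + 92 = 182 codon columns
throughout.  All region coordinates are 0-based, half-open, in codon
units; conversion helpers accept the 1-based amino-acid and nucleotide
positions conventional in MHC papers (e.g. "position 349" of the PBR is
nucleotide 349 counting from the start of exon 2, i.e. codon column
116).

## Allele nomenclature and filtering

Allele designations are `locus*group:protein[:...]`; the first numeric
field after `*` is the allelic group, kept exactly as printed (two or
three digits — truncating `049` to two characters would merge distinct
BoLA groups).  Coding sequences with loss-of-function features
(premature internal stop codons, incomplete terminal codons) are
excluded at ingestion and logged with the reason, never silently kept.

## Representative selection

For each locus, one allele per allelic group is selected: the member
with the lowest aggregate identity to the alleles of all other groups
(identity = identical non-gap columns / columns where neither sequence
is gapped, computed on the region under study).  The aggregate is the
mean by default; a `min` variant exists because the source procedure
does not define the aggregate, and the mean avoids the degeneracy of
`min` when any single distant allele exists.  When a locus has fewer
groups than the target panel size (default 20), the panel is padded
with additional alleles from the redundant groups, each minimising the
aggregate identity to the already-chosen panel.  Ties are broken
lexicographically on the raw allele name and flagged in the provenance;
selection is therefore a pure function of its inputs.

## Diversity and distances

Per-column Shannon diversity is `H = -sum p_i log2 p_i` over observed
residues, gaps excluded from counts (a flag treats `-` as a 21st
symbol); the maximum is log2 20 ≈ 4.32 bits.  Region and pocket
summaries are arithmetic means of column H.  Pocket membership ships as
a user-replaceable JSON file; the bundled `pockets_hla_example.json`
contains only the handful of peptide-binding positions with direct
literature support (A: 6, 58, 158; B: 6; D: 158; F: 83, 122, 145),
while `pockets_synthetic.json` is a full A–F assignment invented for
the synthetic pipeline (it is labelled synthetic and must not be used
for real data).

Distances are uncorrected p-distances — percent mismatched columns with
pairwise deletion of gap/ambiguity columns — at nucleotide or
amino-acid level; between-group distances are means over all cross
pairs.  No substitution-model correction is applied at this stage,
matching a counting-based workflow.

## Nei–Gojobori Ka/Ks

Site counts follow NG86: per codon position, the fraction of the
non-stop single-nucleotide changes that are synonymous, summed over the
three positions (mutations to stop codons are excluded from numerator
and denominator, so s + n = 3 for every sense codon).  Observed
differences for codon pairs differing at k positions are averaged over
the k! mutational pathways, excluding pathways through stop codons.
Proportions pS = Sd/S and pN = Nd/N receive the Jukes–Cantor correction
`d = -(3/4) ln(1 - 4p/3)`; p ≥ 3/4 is reported as NA.  Pairs with
Ks = 0 are excluded from mean ratios and counted.  The phrase
"averaging the Ka/Ks ratios at all sites for each allele" in
counting-based workflows is ambiguous; the default here is the mean
over all unordered allele pairs per domain, with a per-allele variant
(each allele against all others, then averaged) behind a flag.

The "synonymous/nonsynonymous site" counts of the substitution table
are *polymorphic-site classifications*, not NG86 potential-site sums:
a variable nucleotide column is classified by substituting each
observed alternative base in isolation into the consensus codon
(modal codon, ties alphabetical) — synonymous if every change preserves
the residue, nonsynonymous if every change alters it (changes creating
a stop count as nonsynonymous), mixed otherwise.  Mixed sites count
toward the nonsynonymous tally and are also reported separately.
Shared nonsynonymous sites across loci are the set intersection of
those positions on the common PBR coordinate frame, reported 1-based.

## Neighbor joining and bootstrap

NJ uses the Saitou–Nei criterion Q(i,j) = (n−2)d(i,j) − Σd(i,·) −
Σd(j,·), ties broken by the smallest index pair (documented for
reproducibility), standard branch-length formulas, and clamps negative
branch-length estimates to zero (counted on the tree object).  Additive
matrices are recovered exactly.  Trees feeding the pipeline are built
from amino-acid p-distances.  Bootstrap supports resample alignment
columns with replacement; each internal edge of the original tree is
scored by the percentage of non-degenerate replicates whose NJ tree
contains the same bipartition.  Replicates in which every sequence is
identical are skipped and counted.  Output can suppress supports below
50, the usual figure convention; the full support map is always
returned.

## Relative-rate dating

A deliberately simple relative-rate scheme stands in for ML-based
relative-time estimation.  For node u, `ell(u)` is the leaf-count-
weighted mean path length to its descendant leaves; the root lineage
has rate 1, a child lineage c of u inherits rate(c) = rate(u) ·
(e_c + ell(c)) / ell(u), and t(u) = ell(u) / rate(u), normalised so the
root is 1.  On ultrametric input this reproduces depths exactly;
rescaling branch lengths leaves relative times unchanged; times are
monotone from root to leaves.  A single calibration (an MRCA pinned to
an age in Mya) converts relative times to ages by one scalar.  PBR
columns are excluded from dating input to reduce selection-driven bias.
Because branch lengths come from distance trees, not ML, absolute dates
are indicative only: at the default problem size (10 non-PBR
representatives per locus, 180 aa columns) single Poisson realizations
on deep branches move date estimates by tens of percent, which the
synthetic truth makes visible.

## Group statistics

Paralogous genes of a species act as experimental repeats.  The
two-sample test is pooled-variance Student by default (Welch behind a
flag, since "Student's t-test" is the named procedure being emulated).
ANOVA is one-way, or additive two-way without interaction — the
paralog × pocket layout has one observation per cell, so an interaction
term is inestimable.  Tukey HSD uses the studentized-range distribution
at the pooled within-group df.  Degenerate inputs (all observations
equal) return F = 0, p = 1 by convention.

## The synthetic generator

The generator realises the study conditions end-to-end with known
truth.  Defaults:

- **Gene tree** (ultrametric, Myr): primate–artiodactyl split 60.41;
  BoLA–SLA 35.34; BoLA crown 16.33; BoLA-1/-3 15.39; SLA crown 6.70;
  MHC-A vs B/C 24.97; B vs C 19.86; human–chimp orthologous locus
  splits 6.0; platypus-like outgroup (`Oana-N`) at 180.
- **Allelic structure**: 20 groups per locus (2 for the outgroup),
  1–3 alleles per group, groups splitting as a star at 5.0 Mya (it must
  sit below the shallowest 6.0-Mya locus split) and alleles within a
  group at 0.5 Mya.
- **Sequence model**: 362 codons (546-nt PBR + 540-nt non-PBR);
  mutation rate mu = 5e-3 /nt/Myr; transition bias kappa = 2;
  omega_PBR = 2.0 within locus subtrees, omega_nonPBR = 0.1, and
  omega = 0.2 for the PBR on ancestral inter-locus branches — elevated
  PBR omega is modelled as a within-locus allelic phenomenon, while
  long-term inter-locus divergence is purifying-dominated (without
  this, 120-Myr paths at omega 2 drive between-locus PBR divergence
  toward saturation, unlike real class I loci).  Per-site rate
  multipliers plant 3× hot spots at the synthetic E-pocket positions,
  making pocket E the most diverse with known truth.

Selection is acceptance–rejection at codon level: events arrive as a
Poisson process at mu per nt per Myr, boosted by max(1, omega) in
regions under positive selection; events creating stops are rejected;
nonsynonymous events are accepted with probability omega / max(1,
omega) and synonymous events with 1 / max(1, omega).  Realised rates
are therefore mu·omega per nonsynonymous and mu per synonymous
opportunity, so the realised dN/dS tracks omega on both sides of 1 and
protein-level diversity is strictly increasing in omega.  Everything is
driven by one seed; identical configurations give byte-identical FASTA.

What the generator does *not* emulate: recombination and gene
conversion, indels, trans-species allele sharing (allelic lineages here
coalesce within their locus branch), rate variation beyond the planted
hot spots, and database artefacts (partial sequences, nomenclature
revisions).  Passing tests therefore demonstrate correctness of the
analysis machinery under a clean codon model, not robustness to those
real-data features.

The estimator-calibration check for the Ka/Ks machinery runs the
generator with kappa = 1: NG86 counting is only a consistent estimator
under equal mutation rates, and with transition bias the method is
biased by construction — a property of the method, not a defect of the
implementation.

## Problem sizes

The default end-to-end run simulates 4 species × 3 loci × 20 groups ×
1–3 alleles (~490 alleles plus the outgroup), selects 20-allele PBR and
10-allele non-PBR panels per locus, and uses 100 bootstrap replicates
for the pooled panels (~240 and ~122 taxa); the dedicated bootstrap
check uses 1000 replicates on a 6-taxon design.  Clock-recovery checks
use 20 replicates of 12-leaf ultrametric trees with 2000 amino-acid
columns; omega recovery uses 12-allele stars of 182 codons, 10
replicates per omega.

## Known limitations

- The polymorphic-site classifier attributes changes relative to the
  consensus codon; for columns where several codon positions vary
  jointly, attribution in isolation is an approximation.
- Dates are distance-based and carry no confidence intervals; only one
  calibration is supported.
- The representative-selection procedure reproduces the published
  construction only up to its unstated similarity aggregate and tie
  structure; both implemented readings are flagged in provenance.
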