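"""End-to-end analysis pipeline over a synthetic allele-family dataset.

Runs every stage on one simulated dataset: representative selection per
locus, between-locus distance grids, per-region Shannon diversity,
Nei-Gojobori substitution analysis with shared nonsynonymous sites,
bootstrapped neighbor-joining trees of the PBR and non-PBR panels, a
calibrated chronogram from the non-PBR panel, and the group-comparison
statistics.  All outputs are plain TSV/Newick/JSON files and are
byte-identical across runs with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    allele_io,
    chronology,
    codon_selection,
    distance,
    diversity,
    phylo,
    repset,
    stats_compare,
    synth,
)

__all__ = ["run_pipeline"]

_ARTIODACTYL = {"pig", "cattle", "sheep"}
_HOMINID = {"chimpanzee", "human"}
_FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _truth_age(truth: dict, leaf_a: str, leaf_b: str) -> float:
    """Age of the smallest true gene-tree clade containing both loci."""
    best = None
    for entry in truth["node_ages"]:
        leaves = set(entry["clade"].split(","))
        if leaf_a in leaves and leaf_b in leaves:
            if best is None or len(leaves) < best[0]:
                best = (len(leaves), entry["age_mya"])
    if best is None:
        raise KeyError(f"no clade containing {leaf_a} and {leaf_b}")
    return best[1]


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    config: synth.SimulationConfig | None = None,
    pbr_target: int = 20,
    nonpbr_target: int = 10,
    bootstrap_reps: int = 100,
) -> dict:
    """Run the full analysis on one synthetic dataset; returns a summary.

    ``seed`` overrides the configuration seed and also drives the
    bootstrap replicates, so the entire output directory is a pure
    function of (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = replace(config or synth.SimulationConfig(), seed=seed)
    dataset = synth.simulate(cfg)
    dataset.to_fasta(outdir / "dataset.fasta")
    synth.write_truth(dataset, outdir / "truth.tsv")
    cfg.to_yaml(outdir / "config.yaml")

    regions = cfg.regions
    pbr_aa_cols = regions.columns("PBR")
    nonpbr_aa_cols = regions.columns("NONPBR")
    pbr_subspec = allele_io.RegionSpec.pbr_only()
    alpha1_cols = list(range(0, 90))
    alpha2_cols = list(range(90, len(pbr_aa_cols)))

    for rec in dataset.records:
        rec.protein = allele_io.translate_cds(rec.cds)

    outgroup_locus = cfg.outgroup_label
    grouped_all = repset.group_alleles(dataset.records)
    loci = [g.locus for g in grouped_all if g.locus != outgroup_locus]
    grouped = {g.locus: g for g in grouped_all}
    species_of = {
        locus: allele_io.parse_allele_name(f"{locus}*01").species for locus in loci
    }

    # -- representative panels ---------------------------------------------
    pbr_reps: dict[str, repset.RepresentativeSet] = {}
    nonpbr_reps: dict[str, repset.RepresentativeSet] = {}
    prov_rows = []
    for locus in loci + [outgroup_locus]:
        g = grouped[locus]
        tgt_p = min(pbr_target, g.n_alleles)
        tgt_n = min(nonpbr_target, g.n_alleles)
        pbr_reps[locus] = repset.select_representatives(
            g, target=tgt_p, columns=pbr_aa_cols, allow_subsample=True
        )
        nonpbr_reps[locus] = repset.select_representatives(
            g, target=tgt_n, columns=nonpbr_aa_cols, allow_subsample=True
        )
        for panel, rs in (("PBR", pbr_reps[locus]), ("NONPBR", nonpbr_reps[locus])):
            for allele, gid, phase, score, tie in rs.provenance:
                prov_rows.append(
                    {
                        "locus": locus,
                        "panel": panel,
                        "allele": allele,
                        "group": gid,
                        "phase": phase,
                        "score": score,
                        "tie_break": tie,
                    }
                )
    _write(pd.DataFrame(prov_rows), outdir / "representatives.tsv")

    def panel_seqs(rs: repset.RepresentativeSet, cols, level="aa"):
        labels = [rec.name.raw for rec in rs.chosen]
        if level == "aa":
            seqs = ["".join(rec.protein[i] for i in cols) for rec in rs.chosen]
        else:
            nt_cols = [3 * c + k for c in cols for k in range(3)]
            seqs = ["".join(rec.cds[i] for i in nt_cols) for rec in rs.chosen]
        return labels, seqs

    # -- between-locus distance grid (Table 1 analogue) ---------------------
    rows = []
    for i, la in enumerate(loci):
        for lb in loci[i + 1 :]:
            for region, repsets, cols in (
                ("PBR", pbr_reps, pbr_aa_cols),
                ("NONPBR", nonpbr_reps, nonpbr_aa_cols),
            ):
                for level in ("aa", "nt"):
                    _, sa = panel_seqs(repsets[la], cols, level)
                    _, sb = panel_seqs(repsets[lb], cols, level)
                    rows.append(
                        {
                            "locus_a": la,
                            "locus_b": lb,
                            "region": region,
                            "level": level,
                            "mean_percent_difference": distance.between_group_distance(
                                sa, sb, level=level
                            ),
                        }
                    )
    table1 = pd.DataFrame(rows)
    _write(table1, outdir / "table1_between_group.tsv")

    # -- within-species pairwise distributions (Fig 1 analogue) -------------
    fig1_rows = []
    for species in sorted(set(species_of.values())):
        sp_loci = [l for l in loci if species_of[l] == species]
        for region, repsets, cols, levels in (
            ("PBR", pbr_reps, pbr_aa_cols, ("nt", "aa")),
            ("NONPBR", nonpbr_reps, nonpbr_aa_cols, ("aa",)),
        ):
            for level in levels:
                labels, seqs = [], []
                for l in sp_loci:
                    lab, sq = panel_seqs(repsets[l], cols, level)
                    labels += lab
                    seqs += sq
                dm = distance.pairwise_matrix(labels, seqs, level=level, region=region)
                tab = distance.pair_table(dm)
                tab.insert(0, "species", species)
                fig1_rows.append(tab)
    fig1 = pd.concat(fig1_rows, ignore_index=True)
    _write(fig1, outdir / "fig1_pairwise_long.tsv")

    # -- Shannon diversity (Table 2 analogue) -------------------------------
    t2_rows = []
    pocket_map = diversity.synthetic_pocket_map()
    t4_rows = []
    pocket_long = []
    profiles_pbr: dict[str, list] = {}
    for locus in loci:
        _, pbr_aa = panel_seqs(pbr_reps[locus], pbr_aa_cols, "aa")
        _, nonpbr_aa = panel_seqs(nonpbr_reps[locus], nonpbr_aa_cols, "aa")
        prof = diversity.site_profiles(pbr_aa)
        profiles_pbr[locus] = prof
        prof_non = diversity.site_profiles(nonpbr_aa)
        t2_rows.append(
            {
                "locus": locus,
                "species": species_of[locus],
                "H_pbr": diversity.mean_H(prof),
                "H_alpha1": diversity.mean_H(prof, alpha1_cols),
                "H_alpha2": diversity.mean_H(prof, alpha2_cols),
                "H_nonpbr": diversity.mean_H(prof_non),
            }
        )
        ph = diversity.pocket_H(prof, pocket_map)
        row = {"locus": locus, "species": species_of[locus]}
        row.update({f"pocket_{p}": ph[p] for p in sorted(ph)})
        t4_rows.append(row)
        for p, h in sorted(ph.items()):
            pocket_long.append(
                {"locus": locus, "species": species_of[locus], "pocket": p, "H": h}
            )
    table2 = pd.DataFrame(t2_rows)
    _write(table2, outdir / "table2_shannon.tsv")
    table4 = pd.DataFrame(t4_rows)
    _write(table4, outdir / "table4_pockets.tsv")

    # conservation maps (Fig 4/5 analogue, as tables)
    cons = []
    for locus in loci:
        tab = diversity.conservation_table(profiles_pbr[locus])
        tab.insert(0, "locus", locus)
        cons.append(tab)
    _write(pd.concat(cons, ignore_index=True), outdir / "conservation_pbr.tsv")

    # -- substitution analysis (Table 3 analogue) ---------------------------
    t3_rows = []
    classified: dict[str, list] = {}
    for locus in loci:
        _, pbr_nt = panel_seqs(pbr_reps[locus], pbr_aa_cols, "nt")
        sites, summary = codon_selection.classify_polymorphic_sites(pbr_nt)
        classified[locus] = sites
        dom = codon_selection.domain_kaks_summary(pbr_nt, pbr_subspec)
        dom = dom.set_index("domain")
        t3_rows.append(
            {
                "locus": locus,
                "species": species_of[locus],
                "n_variable": int(summary["n_variable"]),
                "pct_variable": summary["pct_variable"],
                "n_synonymous": int(summary["n_synonymous"]),
                "pct_synonymous": summary["pct_synonymous"],
                "n_nonsynonymous": int(summary["n_nonsynonymous"]),
                "pct_nonsynonymous": summary["pct_nonsynonymous"],
                "syn_nonsyn_ratio": summary["syn_nonsyn_ratio"],
                "kaks_alpha1": dom.loc["PBR_alpha1", "mean_kaks"],
                "kaks_alpha2": dom.loc["PBR_alpha2", "mean_kaks"],
            }
        )
    table3 = pd.DataFrame(t3_rows)
    _write(table3, outdir / "table3_kaks.tsv")

    shared_rows = []
    for species in sorted(set(species_of.values())):
        sp_loci = sorted(l for l in loci if species_of[l] == species)
        shared = codon_selection.shared_nonsyn_sites(
            {l: classified[l] for l in sp_loci}
        )
        shared_rows.append(
            {
                "scope": species,
                "loci": ",".join(sp_loci),
                "n_shared": len(shared),
                "positions": ",".join(map(str, shared)),
            }
        )
    shared_all = codon_selection.shared_nonsyn_sites(classified)
    shared_rows.append(
        {
            "scope": "all_species",
            "loci": ",".join(sorted(loci)),
            "n_shared": len(shared_all),
            "positions": ",".join(map(str, shared_all)),
        }
    )
    _write(pd.DataFrame(shared_rows), outdir / "shared_nonsyn.tsv")

    # -- phylogenies --------------------------------------------------------
    def pooled_panel(repsets, cols):
        labels, seqs = [], []
        for locus in loci:
            lab, sq = panel_seqs(repsets[locus], cols, "aa")
            labels += lab
            seqs += sq
        return labels, seqs

    def dist_fn(labels, seqs):
        return distance.pairwise_matrix(list(labels), list(seqs), level="aa")

    trees = {}
    for name, repsets, cols, tree_seed in (
        ("pbr", pbr_reps, pbr_aa_cols, seed + 1001),
        ("nonpbr", nonpbr_reps, nonpbr_aa_cols, seed + 1002),
    ):
        labels, seqs = pooled_panel(repsets, cols)
        boot = phylo.bootstrap_support(
            labels,
            seqs,
            dist_fn,
            n_reps=bootstrap_reps,
            seed=tree_seed,
            min_support_shown=50.0,
        )
        phylo.write_newick(boot.tree, str(outdir / f"tree_{name}.nwk"))
        trees[name] = boot

    # -- chronology ---------------------------------------------------------
    chron_labels, chron_seqs = pooled_panel(nonpbr_reps, nonpbr_aa_cols)
    out_lab, out_seq = panel_seqs(nonpbr_reps[outgroup_locus], nonpbr_aa_cols, "aa")
    chron_labels += out_lab
    chron_seqs += out_seq
    chron_tree = phylo.nj(dist_fn(chron_labels, chron_seqs))
    phylo.root_on_outgroup(chron_tree, out_lab[0])
    tt = chronology.relative_times(chron_tree)

    def first_rep(locus):
        return nonpbr_reps[locus].chosen[0].name.raw

    cal_pair = (first_rep("HLA-A"), first_rep("HLA-B"))
    cal_age = _truth_age(dataset.truth, "HLA-A", "HLA-B")
    chronology.calibrate(tt, cal_pair, cal_age)
    _write(tt.table(), outdir / "chronogram.tsv")
    phylo.write_newick(tt.tree, str(outdir / "chronogram.nwk"))

    est_primate_artiodactyl = tt.age(first_rep("HLA-A"), first_rep("BoLA-1"))
    est_bola_sla = tt.age(first_rep("BoLA-1"), first_rep("SLA-1"))

    # -- statistics ---------------------------------------------------------
    table2 = table2.assign(
        lineage=[
            "artiodactyl" if species_of[l] in _ARTIODACTYL else "hominid"
            for l in table2["locus"]
        ]
    )
    h_art = table2.loc[table2["lineage"] == "artiodactyl", "H_pbr"].tolist()
    h_hom = table2.loc[table2["lineage"] == "hominid", "H_pbr"].tolist()
    tt_res = stats_compare.t_test(h_art, h_hom)
    anova_species = stats_compare.anova(
        table2.rename(columns={"H_pbr": "value", "species": "factor1"})[
            ["value", "factor1"]
        ]
    )
    tukey_species = stats_compare.tukey_hsd(
        table2.rename(columns={"H_pbr": "value", "species": "factor1"})[
            ["value", "factor1"]
        ]
    )
    pocket_df = pd.DataFrame(pocket_long).rename(
        columns={"H": "value", "pocket": "factor1", "locus": "factor2"}
    )
    anova_pockets = stats_compare.anova(pocket_df, factors=2)
    tukey_pockets = stats_compare.tukey_hsd(pocket_df)

    stats_rows = [
        {
            "test": "t_pbrH_artiodactyl_vs_hominid",
            "statistic": tt_res.t,
            "df": tt_res.df,
            "p": tt_res.p,
        }
    ]
    for _, r in anova_species.iterrows():
        stats_rows.append(
            {"test": "anova_species_pbrH", "statistic": r["F"], "df": r["df_num"], "p": r["p"]}
        )
    for _, r in anova_pockets.iterrows():
        stats_rows.append(
            {
                "test": f"anova2_pockets_{r['factor']}",
                "statistic": r["F"],
                "df": r["df_num"],
                "p": r["p"],
            }
        )
    _write(pd.DataFrame(stats_rows), outdir / "stats_tests.tsv")
    _write(tukey_species, outdir / "tukey_species.tsv")
    _write(tukey_pockets, outdir / "tukey_pockets.tsv")

    pocket_means = (
        pd.DataFrame(pocket_long).groupby("pocket")["H"].mean().sort_index()
    )
    summary = {
        "n_alleles_simulated": len(dataset.records),
        "n_loci": len(loci),
        "mean_H_pbr": float(table2["H_pbr"].mean()),
        "mean_H_nonpbr": float(table2["H_nonpbr"].mean()),
        "mean_H_pbr_artiodactyl": float(np.mean(h_art)),
        "mean_H_pbr_hominid": float(np.mean(h_hom)),
        "t_test_p_artiodactyl_vs_hominid": tt_res.p,
        "mean_pct_variable_pbr": float(table3["pct_variable"].mean()),
        "mean_kaks_alpha1": float(table3["kaks_alpha1"].mean()),
        "mean_kaks_alpha2": float(table3["kaks_alpha2"].mean()),
        "pocket_mean_H": {p: float(h) for p, h in pocket_means.items()},
        "pocket_most_diverse": str(pocket_means.idxmax()),
        "pocket_least_diverse": str(pocket_means.idxmin()),
        "calibration_age_mya": cal_age,
        "est_primate_artiodactyl_mya": float(est_primate_artiodactyl),
        "est_bola_sla_mya": float(est_bola_sla),
        "true_primate_artiodactyl_mya": _truth_age(dataset.truth, "HLA-A", "BoLA-1"),
        "true_bola_sla_mya": _truth_age(dataset.truth, "BoLA-1", "SLA-1"),
        "bootstrap_replicates": bootstrap_reps,
        "bootstrap_skipped_pbr": trees["pbr"].n_skipped,
        "mean_between_locus_pbr_aa": float(
            table1.query("region == 'PBR' and level == 'aa'")[
                "mean_percent_difference"
            ].mean()
        ),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
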