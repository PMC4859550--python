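"""End-to-end orchestration of the comparative-evolution analysis.

The pipeline generates (or loads) per-species genomes, detects one-to-one
orthologs, builds codon alignments, profiles promoter AATTTT motifs,
fits codon models (two-ratio branch tests, free-ratio rates, branch-site
positive-selection scans), compares GO-category rates, computes CAI, and
optionally maps selected sites onto a structure. Every stage writes its
table under the output directory and the headline numbers end up in
``report.json``; the whole run is deterministic under the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from . import cai as cai_mod
from . import categories, codonmodel, orthology, promoters, simulate
from .codonmodel import CodonAlignment
from .simulate import SimulationConfig, build_genome_set, write_genome_set
from .trees import BranchClassTree, guide_tree

logger = logging.getLogger(__name__)


def summarize_counts(n_selected: int, n_total: int) -> float:
    """Percentage (one decimal, half-up): 90 of 2429 -> 3.7."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_selected <= n_total:
        raise ValueError("need 0 <= n_selected <= n_total")
    pct = Decimal(100 * n_selected) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    outdir: str
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    min_score: float = 50.0
    alpha: float = 0.05
    fold: float = 2.0
    posterior_threshold: float = 0.95
    n_starts: int = 1
    n_go_terms: int = 8
    pdb_path: str | None = None
    structure_chain: str = "A"
    structure_gene: str | None = None
    force: bool = False


@dataclass
class AnalysisReport:
    data: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _stage_done(out: Path, *files: str) -> bool:
    return all((out / f).exists() for f in files)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed
    report: dict = {"seed": rng_seed, "stages": {}}

    # -- stage: simulate ---------------------------------------------------
    sim = config.sim
    if sim.seed != rng_seed:
        sim = SimulationConfig(
            n_genes=sim.n_genes, codon_length=sim.codon_length, kappa=sim.kappa,
            omega_by_class=dict(sim.omega_by_class), codon_freqs=sim.codon_freqs,
            promoter_length=sim.promoter_length, window_size=sim.window_size,
            plant_prob=dict(sim.plant_prob),
            background_motif_policy=sim.background_motif_policy,
            bias_level=sim.bias_level, seed=rng_seed,
        )
    logger.info("stage=simulate seed=%d n_genes=%d codon_length=%d", rng_seed, sim.n_genes, sim.codon_length)
    gs = build_genome_set(sim, n_go_terms=config.n_go_terms)
    inputs = out / "inputs"
    if config.force or not _stage_done(inputs, "tree.nwk"):
        write_genome_set(gs, inputs)
    report["stages"]["simulate"] = {
        "n_species": len(gs.species),
        "n_genes": sim.n_genes,
        "codon_length": sim.codon_length,
    }
    tree = gs.tree

    # -- stage: orthology --------------------------------------------------
    from .genetic_code import translate

    proteomes = {
        sp: {
            gid: translate(aln.seqs[aln.taxa.index(sp)])
            for gid, aln in gs.alignments.items()
        }
        for sp in gs.species
    }
    reference = gs.species[0]
    logger.info("stage=orthology reference=%s min_score=%g", reference, config.min_score)
    clusters = orthology.rbh_star_clusters(proteomes, reference, config.min_score)
    clusters.to_tsv(out / "orthologs.tsv")
    report["stages"]["orthology"] = {
        "reference": reference,
        "n_clusters": len(clusters),
        "n_reference_genes": len(proteomes[reference]),
    }

    # -- stage: alignments from clusters ------------------------------------
    alignments: dict[str, CodonAlignment] = {}
    for cluster in clusters.clusters:
        gid = cluster[reference]
        aln = gs.alignments[gid]
        # taxa renamed species-wise for the tree
        alignments[gid] = CodonAlignment(
            list(gs.species),
            [aln.seqs[aln.taxa.index(sp)] for sp in gs.species],
        )

    # -- stage: promoter motifs ---------------------------------------------
    logger.info("stage=promoter_motifs length=%d window=%d", sim.promoter_length, sim.window_size)
    profiles = []
    for sp in gs.species:
        pset = promoters.extract_promoters(
            gs.contigs[sp], gs.genes[sp], gs.set_labels,
            length=sim.promoter_length, species=sp,
        )
        for label in ("CRP", "rRNA", "MRP"):
            profiles.append(
                promoters.window_motif_profile(
                    pset, window_size=sim.window_size,
                    n_windows=sim.n_windows, set_label=label,
                )
            )
    promoters.profile_table(profiles, sim.window_size).to_csv(
        out / "motif_profiles.tsv", sep="\t", index=False
    )
    promoters.plot_profiles(
        [p for p in profiles if p.set_label in ("CRP", "rRNA", "MRP")],
        out / "motif_profiles.png", sim.window_size,
    )
    mrp_profiles = [p for p in profiles if p.set_label == "MRP"]
    anova = promoters.compare_profiles(mrp_profiles)
    report["stages"]["promoter_motifs"] = {
        "mrp_rm_anova_F": anova.F if np.isfinite(anova.F) else None,
        "mrp_rm_anova_p": anova.p,
        "degenerate": anova.degenerate,
    }

    # -- stage: rates --------------------------------------------------------
    logger.info("stage=rates n_alignments=%d", len(alignments))
    concat = CodonAlignment.concatenate(list(alignments.values()))
    m0 = codonmodel.fit_model(
        concat, tree, "M0", n_starts=config.n_starts, seed=rng_seed,
        optimize_branch_lengths=True,
    )
    fitted_tree = m0.tree
    gene_rates = categories.gene_group_rates(
        alignments, fitted_tree, n_starts=config.n_starts, seed=rng_seed,
    )
    foldc = categories.fold_classification(gene_rates, fold=config.fold)
    cat = categories.category_omega(
        gs.go_map, alignments, fitted_tree, gene_rates=gene_rates,
        n_starts=config.n_starts, seed=rng_seed,
    )
    cat_tested = categories.category_enrichment_test(
        cat.table, cat.genome_q, alpha=config.alpha
    )
    cat_tested.to_csv(out / "category_rates.tsv", sep="\t", index=False)
    if len(cat_tested):
        categories.plot_category_scatter(cat_tested, out / "category_rates.png")
    report["stages"]["category_rates"] = {
        "genome_fg_omega": cat.genome_fg,
        "genome_bg_omega": cat.genome_bg,
        "genome_fg_faster_fraction": cat.genome_q,
        "n_categories_tested": int(len(cat_tested)),
        "n_categories_significant": int(cat_tested["significant"].sum())
        if len(cat_tested) else 0,
        "fold_fg_faster": foldc.n_fg_faster,
        "fold_bg_faster": foldc.n_bg_faster,
        "fold_fg_faster_pct": summarize_counts(foldc.n_fg_faster, foldc.n_analyzed)
        if foldc.n_analyzed else None,
        "fold_bg_faster_pct": summarize_counts(foldc.n_bg_faster, foldc.n_analyzed)
        if foldc.n_analyzed else None,
    }

    # -- stage: positive selection (branch-site) -----------------------------
    logger.info("stage=positive_selection alpha=%g posterior=%g", config.alpha, config.posterior_threshold)
    selected = []
    site_rows = []
    for i, (gid, aln) in enumerate(sorted(alignments.items())):
        null = codonmodel.fit_model(
            aln, fitted_tree, "branch-site-null",
            n_starts=config.n_starts, seed=rng_seed + i,
            optimize_branch_lengths=False,
        )
        alt = codonmodel.fit_model(
            aln, fitted_tree, "branch-site-alt",
            n_starts=config.n_starts, seed=rng_seed + i,
            optimize_branch_lengths=False, warm_start=null.params,
        )
        res = codonmodel.lrt(alt, null, df=1, alpha=config.alpha)
        if res.significant:
            selected.append(gid)
            for sp in codonmodel.site_posteriors(
                alt, aln, fitted_tree, threshold=config.posterior_threshold
            ):
                if sp.flagged:
                    from .genetic_code import CODON_TO_AA

                    residues = "/".join(
                        CODON_TO_AA.get(seq[3 * sp.site : 3 * sp.site + 3], "-")
                        for seq in aln.seqs
                    )
                    site_rows.append(
                        {
                            "gene": gid,
                            "site": sp.site + 1,
                            "posterior": round(sp.posterior, 4),
                            "residues": residues,
                        }
                    )
    with open(out / "selected_sites.tsv", "w") as fh:
        fh.write("gene\tsite\tposterior\tresidues\n")
        for row in site_rows:
            fh.write(
                f"{row['gene']}\t{row['site']}\t{row['posterior']}\t{row['residues']}\n"
            )
    n_total = len(alignments)
    report["stages"]["positive_selection"] = {
        "n_selected": len(selected),
        "n_orthologs": n_total,
        "selected_pct": summarize_counts(len(selected), n_total) if n_total else None,
        "selected_genes": selected,
        "n_flagged_sites": len(site_rows),
    }

    # -- stage: codon usage --------------------------------------------------
    logger.info("stage=codon_usage reference_set=CRP")
    cai_summary = {}
    for sp in gs.species:
        crp = [
            gs.alignments[g].seqs[gs.alignments[g].taxa.index(sp)]
            for g, label in gs.set_labels.items()
            if label == "CRP" and g in alignments
        ]
        if not crp:
            continue
        table = cai_mod.relative_adaptiveness(crp, reference_id=f"{sp}:CRP")
        values = {
            g: cai_mod.cai(gs.alignments[g].seqs[gs.alignments[g].taxa.index(sp)], table)
            for g in alignments
        }
        vals = [v for v in values.values() if v is not None]
        cai_summary[sp] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
    with open(out / "cai.tsv", "w") as fh:
        fh.write("species\tmean\tsd\n")
        for sp, s in cai_summary.items():
            fh.write(f"{sp}\t{s['mean']:.4f}\t{s['sd']:.4f}\n")
    report["stages"]["codon_usage"] = cai_summary

    # -- stage: structure (optional) ------------------------------------------
    if config.pdb_path:
        from . import structure as structure_mod

        model = structure_mod.read_structure(Path(config.pdb_path).read_text())
        chain = config.structure_chain
        sseq, snum = model.chain_sequence(chain)
        gid = config.structure_gene or (selected[0] if selected else None)
        if gid is not None:
            query = proteomes[reference][gid]
            sites = [r["site"] - 1 for r in site_rows if r["gene"] == gid]
            try:
                mapping = structure_mod.map_sites_to_structure(sites, query, sseq, snum)
                report["stages"]["structure"] = {
                    "gene": gid,
                    "identity": round(mapping.identity, 3),
                    "mapped": {str(k): v for k, v in mapping.mapped.items()},
                    "n_unmapped": len(mapping.unmapped),
                }
            except ValueError as exc:
                report["stages"]["structure"] = {"gene": gid, "error": str(exc)}

    rep = AnalysisReport(data=report)
    rep.to_json(out / "report.json")
    return rep
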