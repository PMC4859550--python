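"""GO-category evolutionary-rate comparison between branch groups.

For each GO term with more than five member orthologs, the member codon
alignments are concatenated and a free-ratio model fitted; the foreground
(Dekkera clade) and background rates are the medians of the per-branch dN/dS
within each branch class. Categories are tested for an excess of
foreground-faster genes with a two-sided exact binomial test against the
genome-wide proportion, Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .codonmodel import CodonAlignment, ModelFit, fit_branch_models
from .trees import BranchClassTree

logger = logging.getLogger(__name__)

MIN_CATEGORY_GENES = 6  # "more than 5" member orthologs

#: per-branch ω̂ at (or within 1%% of) this bound is treated as undefined
OMEGA_CEILING = 99.0


def branch_group_medians(fit: ModelFit) -> dict[int, float | None]:
    """Median per-branch ω within each branch class of a free-ratio fit.

    Branches whose ω̂ sits at the optimisation ceiling (the dS→0 pathology)
    or whose length is ~0 are excluded; a class with no usable branch gives
    None.
    """
    if fit.model != "free" or fit.branch_omegas is None:
        raise ValueError("free-ratio fit required")
    groups: dict[int, list[float]] = {}
    for i, b in enumerate(fit.tree.branches()):
        w = fit.branch_omegas[i]
        if w >= OMEGA_CEILING or b.length < 1e-5:
            continue
        groups.setdefault(b.branch_class, []).append(w)
    return {c: (float(np.median(v)) if v else None) for c, v in groups.items()} | {
        c: None for c in {b.branch_class for b in fit.tree.branches()} - set(groups)
    }


def gene_group_rates(
    alignments: dict[str, CodonAlignment],
    tree: BranchClassTree,
    *,
    n_starts: int = 1,
    seed: int = 0,
    optimize_branch_lengths: bool = False,
) -> dict[str, dict[int, float | None]]:
    """Per-gene foreground/background rates from free-ratio fits.

    With ``optimize_branch_lengths=False`` the lengths already on ``tree``
    are used (e.g. from a genome-wide concatenated M0 fit).
    """
    out = {}
    for i, (gene, aln) in enumerate(alignments.items()):
        if optimize_branch_lengths:
            fits = fit_branch_models(
                aln, tree, models=("free",), n_starts=n_starts, seed=seed + i
            )
        else:
            from .codonmodel import fit_model

            fits = {
                "free": fit_model(
                    aln, tree, "free", n_starts=n_starts, seed=seed + i,
                    optimize_branch_lengths=False,
                )
            }
        out[gene] = branch_group_medians(fits["free"])
    return out


@dataclass
class CategoryRateTable:
    table: pd.DataFrame  # go, n_genes, fg_omega, bg_omega, direction, k_fg_faster
    genome_fg: float | None
    genome_bg: float | None
    genome_q: float  # genome-wide proportion of fg-faster genes


def category_omega(
    go_map: dict[str, list[str]],
    alignments: dict[str, CodonAlignment],
    tree: BranchClassTree,
    gene_rates: dict[str, dict[int, float | None]] | None = None,
    *,
    min_genes: int = MIN_CATEGORY_GENES,
    fg_class: int = 1,
    bg_class: int = 0,
    n_starts: int = 1,
    seed: int = 0,
) -> CategoryRateTable:
    """Concatenated free-ratio rates per GO category plus the genome baseline."""
    by_term: dict[str, list[str]] = {}
    for gene, terms in go_map.items():
        if gene not in alignments:
            continue
        for t in terms:
            by_term.setdefault(t, []).append(gene)
    if gene_rates is None:
        gene_rates = gene_group_rates(alignments, tree, n_starts=n_starts, seed=seed)
    directed = {
        g: r
        for g, r in gene_rates.items()
        if r.get(fg_class) is not None and r.get(bg_class) is not None
    }
    n_fg_faster = sum(1 for r in directed.values() if r[fg_class] > r[bg_class])
    genome_q = n_fg_faster / len(directed) if directed else 0.5

    def concat_fit(genes: list[str], s: int) -> dict[int, float | None]:
        aln = CodonAlignment.concatenate([alignments[g] for g in genes])
        if all(set(seq) <= {"-", "N"} for seq in aln.seqs):
            raise ValueError("all-gap concatenation")
        fits = fit_branch_models(
            aln, tree, models=("free",), n_starts=n_starts, seed=s
        )
        return branch_group_medians(fits["free"])

    rows = []
    for term in sorted(by_term):
        genes = sorted(by_term[term])
        if len(genes) < min_genes:
            continue
        try:
            med = concat_fit(genes, seed + hash(term) % 10_000)
        except ValueError as exc:
            logger.warning("category %s skipped: %s", term, exc)
            continue
        fg, bg = med.get(fg_class), med.get(bg_class)
        members = [g for g in genes if g in directed]
        k = sum(1 for g in members if directed[g][fg_class] > directed[g][bg_class])
        rows.append(
            {
                "go": term,
                "n_genes": len(genes),
                "fg_omega": fg,
                "bg_omega": bg,
                "direction": (
                    "fg_faster" if (fg or 0) > (bg or 0) else "bg_faster"
                ),
                "n_directed": len(members),
                "k_fg_faster": k,
            }
        )
    genome_med = concat_fit(sorted(alignments), seed) if alignments else {}
    return CategoryRateTable(
        table=pd.DataFrame(
            rows,
            columns=[
                "go", "n_genes", "fg_omega", "bg_omega",
                "direction", "n_directed", "k_fg_faster",
            ],
        ),
        genome_fg=genome_med.get(fg_class),
        genome_bg=genome_med.get(bg_class),
        genome_q=genome_q,
    )


def category_enrichment_test(
    table: pd.DataFrame, genome_q: float, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided exact binomial test per category against the genome-wide
    foreground-faster proportion, with Benjamini–Hochberg adjustment."""
    table = table.copy()
    pvals = []
    for _, row in table.iterrows():
        n, k = int(row["n_directed"]), int(row["k_fg_faster"])
        if n == 0:
            pvals.append(np.nan)
            continue
        pvals.append(binomtest(k, n, genome_q, alternative="two-sided").pvalue)
    table["p"] = pvals
    mask = table["p"].notna()
    table["p_adj"] = np.nan
    if mask.any():
        table.loc[mask, "p_adj"] = multipletests(
            table.loc[mask, "p"].to_numpy(), method="fdr_bh"
        )[1]
    table["significant"] = table["p_adj"] < alpha
    return table[table["n_directed"] > 0].reset_index(drop=True)


@dataclass
class FoldClassification:
    n_fg_faster: int
    n_bg_faster: int
    n_analyzed: int

    @property
    def frac_fg_faster(self) -> float:
        return self.n_fg_faster / self.n_analyzed if self.n_analyzed else 0.0

    @property
    def frac_bg_faster(self) -> float:
        return self.n_bg_faster / self.n_analyzed if self.n_analyzed else 0.0


def fold_classification(
    gene_rates: dict[str, dict[int, float | None]],
    fold: float = 2.0,
    fg_class: int = 1,
    bg_class: int = 0,
) -> FoldClassification:
    """Count genes whose foreground rate exceeds ``fold`` × the background
    rate and vice versa; genes with an undefined group rate are excluded."""
    n_fg = n_bg = n = 0
    for rates in gene_rates.values():
        fg, bg = rates.get(fg_class), rates.get(bg_class)
        if fg is None or bg is None:
            continue
        n += 1
        if fg > fold * bg:
            n_fg += 1
        elif bg > fold * fg:
            n_bg += 1
    return FoldClassification(n_fg_faster=n_fg, n_bg_faster=n_bg, n_analyzed=n)


def read_go_map(path) -> dict[str, list[str]]:
    """Two-column TSV (gene, GO id), one row per pair."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, []).append(term)
    return out


def plot_category_scatter(table: pd.DataFrame, path) -> None:
    """Scatter of foreground vs background ω per category, coloured by
    direction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    for direction, color in (("fg_faster", "tab:red"), ("bg_faster", "tab:blue")):
        sub = table[table["direction"] == direction]
        ax.scatter(sub["bg_omega"], sub["fg_omega"], s=14, c=color, label=direction)
    lim = max(
        float(table[["fg_omega", "bg_omega"]].max().max() or 1.0) * 1.1, 0.1
    )
    ax.plot([0, lim], [0, lim], "k--", lw=0.7)
    ax.set_xlabel("background dN/dS")
    ax.set_ylabel("foreground dN/dS")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
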