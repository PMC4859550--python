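"""Promoter extraction and AATTTT motif window profiles.

Promoters are the 600 bp upstream of each gene's start codon, read 5'→3' on
the coding strand (the last base is adjacent to the ATG). The profile splits
the promoter into 12 ordered 50 bp windows counted outward from the start
codon (window 1 = 1–50 bp upstream) and reports, per gene set and species,
the percentage of genes with at least one AATTTT occurrence — or its reverse
complement AAATTT — starting in each window. Profiles across species are
compared with a repeated-measures ANOVA in which windows are the repeated
subjects and species the condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

from .genetic_code import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MOTIF = "AATTTT"


@dataclass
class PromoterRecord:
    gene: str
    set_label: str
    seq: str  # coding strand, 5'→3'; last base adjacent to ATG
    truncated: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class PromoterSet:
    species: str
    promoter_length: int
    records: list[PromoterRecord] = field(default_factory=list)

    def by_set(self, set_label: str) -> "PromoterSet":
        return PromoterSet(
            self.species,
            self.promoter_length,
            [r for r in self.records if r.set_label == set_label],
        )


def extract_promoters(
    genome: dict[str, str],
    gene_records,
    set_labels: dict[str, str] | None = None,
    length: int = 600,
    species: str = "",
) -> PromoterSet:
    """Extract upstream sequences for 1-based, inclusive gene coordinates.

    For '+' strand genes the promoter is bases [start-length, start-1]; for
    '-' strand genes the reverse complement of [end+1, end+length]. Regions
    beyond a contig edge are truncated and flagged; genes off-contig are
    skipped with a warning.
    """
    out = PromoterSet(species=species, promoter_length=length)
    labels = set_labels or {}
    for rec in gene_records:
        contig = genome.get(rec.contig)
        if contig is None:
            logger.warning("gene %s: contig %s not in genome; skipped", rec.gene, rec.contig)
            continue
        n = len(contig)
        if not (1 <= rec.start <= rec.end <= n):
            logger.warning("gene %s off contig bounds; skipped", rec.gene)
            continue
        truncated = False
        if rec.strand == "+":
            lo = rec.start - length  # 1-based
            if lo < 1:
                lo, truncated = 1, True
            seq = contig[lo - 1 : rec.start - 1]
        elif rec.strand == "-":
            hi = rec.end + length
            if hi > n:
                hi, truncated = n, True
            seq = reverse_complement(contig[rec.end : hi])
        else:
            logger.warning("gene %s: bad strand %r; skipped", rec.gene, rec.strand)
            continue
        out.records.append(
            PromoterRecord(
                gene=rec.gene,
                set_label=labels.get(rec.gene, "none"),
                seq=seq.upper(),
                truncated=truncated,
            )
        )
    return out


@dataclass
class MotifWindowProfile:
    species: str
    set_label: str
    percentages: np.ndarray  # index 0 = window 1 (nearest ATG), in [0, 100]
    denominators: np.ndarray  # genes whose promoter covers any base of the window
    hit_counts: np.ndarray  # genes with >= 1 match starting in the window
    occurrence_counts: np.ndarray  # raw occurrences per window (audit only)

    @property
    def n_windows(self) -> int:
        return len(self.percentages)


def motif_hit_windows(
    seq: str, motif: str, window_size: int, n_windows: int
) -> tuple[set[int], dict[int, int]]:
    """Windows (1-based, from the ATG outward) containing at least one match
    start of the motif or its reverse complement, plus per-window occurrence
    counts. A match is assigned to the window containing its 5'-most base."""
    La = len(seq)
    hits: set[int] = set()
    occ: dict[int, int] = {}
    for m in (motif, reverse_complement(motif)):
        start = seq.find(m)
        while start != -1:
            distance = La - start  # bp from ATG of the match's 5'-most base
            w = (distance + window_size - 1) // window_size
            if 1 <= w <= n_windows:
                hits.add(w)
                occ[w] = occ.get(w, 0) + 1
            start = seq.find(m, start + 1)
    return hits, occ


def window_motif_profile(
    promoters: PromoterSet,
    motif: str = DEFAULT_MOTIF,
    window_size: int = 50,
    n_windows: int = 12,
    set_label: str | None = None,
) -> MotifWindowProfile:
    """Per-window percentage of genes with the motif (or reverse complement).

    Truncated promoters enter a window's denominator only if they cover at
    least one of its bases, so the per-window denominators can differ.
    """
    if set(motif.upper()) - set("ACGT"):
        raise ValueError(f"motif must be ACGT only, got {motif!r}")
    if window_size * n_windows != promoters.promoter_length:
        raise ValueError("window_size × n_windows must equal the promoter length")
    motif = motif.upper()
    records = promoters.records
    if set_label is not None:
        records = [r for r in records if r.set_label == set_label]
    denom = np.zeros(n_windows, dtype=int)
    hit = np.zeros(n_windows, dtype=int)
    occ = np.zeros(n_windows, dtype=int)
    for rec in records:
        covered = min(n_windows, -(-rec.length // window_size))  # ceil
        denom[:covered] += 1
        wins, counts = motif_hit_windows(rec.seq, motif, window_size, n_windows)
        for w in wins:
            hit[w - 1] += 1
        for w, c in counts.items():
            occ[w - 1] += c
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * hit / np.maximum(denom, 1), 0.0)
    return MotifWindowProfile(
        species=promoters.species,
        set_label=set_label or "all",
        percentages=pct,
        denominators=denom,
        hit_counts=hit,
        occurrence_counts=occ,
    )


@dataclass
class RMAnovaResult:
    F: float
    p: float
    df_condition: int
    df_error: int
    degenerate: bool = False


def compare_profiles(profiles: list[MotifWindowProfile]) -> RMAnovaResult:
    """One-way repeated-measures ANOVA across species profiles.

    Windows are the subjects, species the within-subject condition; the error
    term is the species×window interaction. Identical profiles give F = 0,
    p = 1; a zero error stratum with non-zero condition variance is flagged
    degenerate (F = inf, p = 0).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    n_windows = {p.n_windows for p in profiles}
    if len(n_windows) != 1:
        raise ValueError(f"unequal window counts: {sorted(n_windows)}")
    X = np.vstack([p.percentages for p in profiles])  # (k species, n windows)
    k, n = X.shape
    grand = X.mean()
    ss_cond = n * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    if ss_cond <= 1e-12:
        return RMAnovaResult(F=0.0, p=1.0, df_condition=df_cond, df_error=df_err)
    if ss_err <= 1e-12:
        return RMAnovaResult(
            F=float("inf"), p=0.0, df_condition=df_cond, df_error=df_err, degenerate=True
        )
    F = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(f_dist.sf(F, df_cond, df_err))
    return RMAnovaResult(F=float(F), p=p, df_condition=df_cond, df_error=df_err)


def profile_table(profiles: list[MotifWindowProfile], window_size: int = 50):
    """Long-format audit table (one row per species/set/window)."""
    import pandas as pd

    rows = []
    for prof in profiles:
        for w in range(prof.n_windows):
            rows.append(
                {
                    "species": prof.species,
                    "set": prof.set_label,
                    "window": w + 1,
                    "window_start_bp": w * window_size + 1,
                    "window_end_bp": (w + 1) * window_size,
                    "n_genes": int(prof.denominators[w]),
                    "n_hit": int(prof.hit_counts[w]),
                    "n_occurrences": int(prof.occurrence_counts[w]),
                    "percentage": float(prof.percentages[w]),
                }
            )
    return pd.DataFrame(rows)


def plot_profiles(profiles: list[MotifWindowProfile], path, window_size: int = 50) -> None:
    """Line plot of motif percentage against distance to the start codon,
    one panel per species, one line per gene set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    species = sorted({p.species for p in profiles})
    fig, axes = plt.subplots(1, len(species), figsize=(4 * len(species), 3.2), squeeze=False)
    colors = {"CRP": "tab:blue", "rRNA": "tab:red", "MRP": "tab:green", "none": "0.6"}
    for ax, sp in zip(axes[0], species):
        for prof in profiles:
            if prof.species != sp:
                continue
            x = (np.arange(prof.n_windows) + 0.5) * window_size
            ax.plot(x, prof.percentages, marker="o", ms=3,
                    color=colors.get(prof.set_label, "0.3"), label=prof.set_label)
        ax.set_title(sp)
        ax.set_xlabel("distance to start codon (bp)")
        ax.set_ylabel("% genes with motif")
        ax.invert_xaxis()
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
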