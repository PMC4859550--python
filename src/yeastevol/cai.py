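"""Codon Adaptation Index (Sharp & Li construction).

Relative adaptiveness w of each codon is its count in a reference set of
highly expressed genes divided by the count of the most-used synonym
(zero-count codons get a 0.5 pseudo-count). A gene's CAI is the geometric
mean of w over its codons, excluding Met, Trp and stop codons, whose usage
carries no choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean, stdev

from .genetic_code import CODON_INDEX, STOP_CODONS, codons_of, synonymous_families

EXCLUDED_CODONS = frozenset({"ATG", "TGG"}) | STOP_CODONS


@dataclass
class AdaptivenessTable:
    weights: dict[str, float]  # sense codon -> w in (0, 1]
    reference_id: str = ""

    def __post_init__(self):
        for fam in synonymous_families().values():
            top = max(self.weights.get(c, 0.0) for c in fam)
            if abs(top - 1.0) > 1e-9:
                raise ValueError(
                    f"family {fam} must contain a codon with w = 1 (max is {top})"
                )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tw\n")
            for codon in sorted(self.weights):
                fh.write(f"{codon}\t{self.weights[codon]:.6g}\n")


def relative_adaptiveness(
    reference_genes: list[str], reference_id: str = ""
) -> AdaptivenessTable:
    """Adaptiveness table from codon counts of a reference CDS set."""
    if not reference_genes:
        raise ValueError("empty reference gene set")
    counts: dict[str, float] = {c: 0.0 for c in CODON_INDEX}
    for cds in reference_genes:
        for codon in codons_of(cds.upper()):
            if codon in counts:
                counts[codon] += 1.0
    weights: dict[str, float] = {}
    for fam in synonymous_families().values():
        top = max(counts[c] for c in fam)
        if top == 0:
            for c in fam:
                weights[c] = 1.0  # family unseen in the reference: uninformative
            continue
        for c in fam:
            weights[c] = (counts[c] if counts[c] > 0 else 0.5) / top
    return AdaptivenessTable(weights=weights, reference_id=reference_id)


def cai(gene: str, table: AdaptivenessTable) -> float | None:
    """Geometric mean of codon adaptiveness; None when the gene contains only
    excluded (Met/Trp/stop) codons."""
    log_sum = 0.0
    n = 0
    for codon in codons_of(gene.upper()):
        if codon in EXCLUDED_CODONS or codon not in table.weights:
            continue
        log_sum += math.log(table.weights[codon])
        n += 1
    if n == 0:
        return None
    return math.exp(log_sum / n)


@dataclass
class CaiZScore:
    gene_cai: float
    mean: float
    sd: float
    z: float | None = field(default=None)


def cai_zscore(gene_cai: float, genome_cais: list[float]) -> CaiZScore:
    """Standardise a gene's CAI against the genome distribution (sample sd).

    A zero spread (all genome CAIs identical) leaves z undefined (None).
    """
    if len(genome_cais) < 2:
        raise ValueError("need at least two genome CAI values")
    mu = mean(genome_cais)
    sd = stdev(genome_cais)
    z = (gene_cai - mu) / sd if sd > 0 else None
    return CaiZScore(gene_cai=gene_cai, mean=mu, sd=sd, z=z)
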