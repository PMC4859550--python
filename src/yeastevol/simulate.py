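"""Synthetic seven-taxon data with known ground truth.

Everything the pipeline consumes can be generated here: coding genes evolved
along the fixed guide tree under a GY94 codon model with branch-class ω,
promoters with set- and window-specific planted AATTTT motifs, genes with a
controllable level of codon-usage bias, and whole synthetic genomes (contig
per species, GFF3-style gene coordinates, set/GO labels).

Substitutions are simulated as a continuous-time Markov jump process per
branch (exponential waiting times), not by sampling from P(t), so that every
event is recorded in a ledger with its branch, site, codons and
synonymous/nonsynonymous flag — the ledger is what recovery tests check
against. Rate matrices are scaled to one expected substitution per codon per
unit branch length, the same convention the likelihood engine uses, so true
and fitted branch lengths are directly comparable.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codonmodel import CodonAlignment, build_rate_matrix
from .genetic_code import (
    CODON_INDEX,
    CODON_TO_AA,
    N_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    reverse_complement,
    synonymous_families,
)
from .trees import BranchClassTree, guide_tree

MOTIF = "AATTTT"
MOTIF_RC = reverse_complement(MOTIF)  # AAATTT

GENE_SETS = ("CRP", "rRNA", "MRP", "none")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome set.

    ``plant_prob`` maps (gene-set label, 1-based window index counted from the
    start codon outward) to the probability that exactly one motif is planted
    in that window of that gene's promoter.
    """

    n_genes: int = 60
    codon_length: int = 150
    kappa: float = 2.0
    omega_by_class: dict[int, float] = field(default_factory=lambda: {0: 0.2, 1: 0.2})
    codon_freqs: np.ndarray | None = None  # None = uniform over 61 sense codons
    promoter_length: int = 600
    window_size: int = 50
    plant_prob: dict[tuple[str, int], float] = field(default_factory=dict)
    background_motif_policy: str = "exclude"  # or "natural"
    bias_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.codon_freqs is None:
            self.codon_freqs = np.full(N_CODONS, 1.0 / N_CODONS)
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_CODONS,):
            raise ValueError(f"codon_freqs must have {N_CODONS} entries (stops excluded)")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_freqs must sum to 1")
        if (self.codon_freqs < 0).any():
            raise ValueError("codon_freqs must be non-negative")
        for w in self.omega_by_class.values():
            if w < 0:
                raise ValueError("omega values must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        for key, p in self.plant_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"plant_prob{key} must be in [0,1], got {p}")
        if not 0.0 <= self.bias_level <= 1.0:
            raise ValueError("bias_level must be in [0,1]")
        if self.background_motif_policy not in ("exclude", "natural"):
            raise ValueError("background_motif_policy must be 'exclude' or 'natural'")
        if self.promoter_length % self.window_size:
            raise ValueError("promoter_length must be divisible by window_size")

    @property
    def n_windows(self) -> int:
        return self.promoter_length // self.window_size

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a flat key=value config (INI with or without a section header).

        Dict-valued fields use flat keys: ``omega_class_0 = 0.2``,
        ``plant_prob_MRP_3 = 0.15`` (set label, window index), or
        ``plant_prob_MRP = 0.15`` to apply to every window.
        """
        text = Path(path).read_text()
        cp = configparser.ConfigParser()
        if not text.lstrip().startswith("["):
            text = "[sim]\n" + text
        cp.read_string(text)
        flat: dict[str, str] = {}
        for section in cp.sections():
            flat.update(cp.items(section))
        kwargs: dict = {}
        omega: dict[int, float] = {}
        plant: dict[tuple[str, int], float] = {}
        simple = {
            "n_genes": int, "codon_length": int, "kappa": float,
            "promoter_length": int, "window_size": int, "bias_level": float,
            "seed": int, "background_motif_policy": str,
        }
        n_windows = int(flat.get("promoter_length", 600)) // int(flat.get("window_size", 50))
        for key, raw in flat.items():
            if key in simple:
                kwargs[key] = simple[key](raw)
            elif key.startswith("omega_class_"):
                omega[int(key.rsplit("_", 1)[1])] = float(raw)
            elif key.startswith("plant_prob_"):
                rest = key[len("plant_prob_"):]
                parts = rest.rsplit("_", 1)
                if len(parts) == 2 and parts[1].isdigit():
                    plant[(_canon_set(parts[0]), int(parts[1]))] = float(raw)
                else:
                    for w in range(1, n_windows + 1):
                        plant[(_canon_set(rest), w)] = float(raw)
            else:
                raise ValueError(f"unknown config key {key!r}")
        if omega:
            kwargs["omega_by_class"] = omega
        if plant:
            kwargs["plant_prob"] = plant
        return cls(**kwargs)


def _canon_set(label: str) -> str:
    for s in GENE_SETS:
        if s.lower() == label.lower():
            return s
    raise ValueError(f"unknown gene set {label!r} (known: {GENE_SETS})")


# ---------------------------------------------------------------------------
# Codon alignment simulation (jump process with event ledger)
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionEvent:
    branch: int  # index into tree.branches()
    node: str | None  # name of the node below the branch (leaves only)
    site: int  # 0-based codon site
    from_codon: str
    to_codon: str
    synonymous: bool
    time: float  # time from the start of the branch


class _JumpSampler:
    """Per-ω-class sampler of the embedded jump chain of the scaled Q."""

    def __init__(self, pi: np.ndarray, kappa: float, omega: float,
                 scale: float | None = None):
        if scale is None:
            Q = build_rate_matrix(pi, kappa, omega, scale=True)
        else:
            from .codonmodel import rate_matrix_unscaled

            Q = rate_matrix_unscaled(pi, kappa, omega) / scale
        self.exit_rate = -np.diag(Q).copy()
        jump = Q.copy()
        np.fill_diagonal(jump, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump = jump / self.exit_rate[:, None]
        jump[self.exit_rate == 0] = 0.0
        self.jump_cdf = np.cumsum(jump, axis=1)


def simulate_codon_alignment(
    tree: BranchClassTree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CodonAlignment, list[SubstitutionEvent]]:
    """Evolve one gene along the tree; returns the leaf alignment and the
    full substitution ledger."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pi = config.codon_freqs
    if any(SENSE_CODONS[i] in STOP_CODONS for i in range(N_CODONS)):  # pragma: no cover
        raise ValueError("codon_freqs assigns mass to stop codons")
    branches = tree.branches()
    samplers: dict[int, _JumpSampler] = {}
    for b in branches:
        if b.branch_class not in config.omega_by_class:
            raise ValueError(
                f"branch class {b.branch_class} has no omega in omega_by_class"
            )
        if b.branch_class not in samplers:
            samplers[b.branch_class] = _JumpSampler(
                pi, config.kappa, config.omega_by_class[b.branch_class]
            )
        if b.length < 0:
            raise ValueError("branch lengths must be >= 0")
    branch_index = {id(b): i for i, b in enumerate(branches)}
    L = config.codon_length
    root_states = rng.choice(N_CODONS, size=L, p=pi)
    ledger: list[SubstitutionEvent] = []
    leaf_seqs: dict[str, np.ndarray] = {}

    def evolve(node, states: np.ndarray):
        for child in node.children:
            child_states = states.copy()
            sampler = samplers[child.branch_class]
            bi = branch_index[id(child)]
            t_branch = child.length
            if t_branch > 0:
                for site in range(L):
                    s = child_states[site]
                    t = 0.0
                    while True:
                        rate = sampler.exit_rate[s]
                        if rate <= 0:
                            break
                        t += rng.exponential(1.0 / rate)
                        if t >= t_branch:
                            break
                        u = rng.random()
                        s_new = int(np.searchsorted(sampler.jump_cdf[s], u))
                        ledger.append(
                            SubstitutionEvent(
                                branch=bi,
                                node=child.name,
                                site=site,
                                from_codon=SENSE_CODONS[s],
                                to_codon=SENSE_CODONS[s_new],
                                synonymous=CODON_TO_AA[SENSE_CODONS[s]]
                                == CODON_TO_AA[SENSE_CODONS[s_new]],
                                time=t,
                            )
                        )
                        s = s_new
                    child_states[site] = s
            if child.is_leaf:
                leaf_seqs[child.name] = child_states
            else:
                evolve(child, child_states)

    evolve(tree.root, root_states)
    taxa = tree.leaf_names()
    seqs = ["".join(SENSE_CODONS[s] for s in leaf_seqs[t]) for t in taxa]
    return CodonAlignment(taxa, seqs), ledger


def simulate_branch_site_alignment(
    tree: BranchClassTree,
    codon_length: int,
    *,
    kappa: float = 2.0,
    omega0: float = 0.2,
    omega2: float = 4.0,
    p0: float = 0.7,
    p1: float = 0.2,
    codon_freqs: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CodonAlignment, np.ndarray, list[SubstitutionEvent]]:
    """Evolve a gene under branch-site model A (the likelihood engine's exact
    generating process, including the shared mixture-rate branch scaling).

    Sites draw one of the four classes (0: ω0 everywhere; 1: neutral;
    2a/2b: ω2 on foreground branches) with proportions (p0, p1, p2a, p2b);
    returns the alignment, the true site-class vector (0,1,2,3) and the
    substitution ledger.
    """
    from .codonmodel import GY94Params, expected_rate, rate_matrix_unscaled

    rng = np.random.default_rng(seed)
    pi = (
        np.asarray(codon_freqs, dtype=float)
        if codon_freqs is not None
        else np.full(N_CODONS, 1.0 / N_CODONS)
    )
    params = GY94Params(kappa, pi, omega0=omega0, omega2=omega2, p0=p0, p1=p1)
    props = np.array([params.p0, params.p1, params.p2a, params.p2b])
    class_w = [  # site class -> (background ω, foreground ω)
        (omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2),
    ]
    rate = {
        w: expected_rate(pi, rate_matrix_unscaled(pi, kappa, w))
        for w in {w for pair in class_w for w in pair}
    }
    mix = {
        bc: float(sum(p * rate[class_w[c][bc]] for c, p in enumerate(props)))
        for bc in (0, 1)
    }
    samplers: dict[tuple[int, int], _JumpSampler] = {}
    for c in range(4):
        for bc in (0, 1):
            samplers[(c, bc)] = _JumpSampler(pi, kappa, class_w[c][bc], scale=mix[bc])
    site_classes = rng.choice(4, size=codon_length, p=props / props.sum())
    branches = tree.branches()
    branch_index = {id(b): i for i, b in enumerate(branches)}
    root_states = rng.choice(N_CODONS, size=codon_length, p=pi)
    ledger: list[SubstitutionEvent] = []
    leaf_seqs: dict[str, np.ndarray] = {}

    def evolve(node, states: np.ndarray):
        for child in node.children:
            child_states = states.copy()
            bi = branch_index[id(child)]
            for site in range(codon_length):
                sampler = samplers[(site_classes[site], child.branch_class)]
                s = int(child_states[site])
                t = 0.0
                while True:
                    r = sampler.exit_rate[s]
                    if r <= 0:
                        break
                    t += rng.exponential(1.0 / r)
                    if t >= child.length:
                        break
                    u = rng.random()
                    s_new = int(np.searchsorted(sampler.jump_cdf[s], u))
                    ledger.append(
                        SubstitutionEvent(
                            branch=bi, node=child.name, site=site,
                            from_codon=SENSE_CODONS[s], to_codon=SENSE_CODONS[s_new],
                            synonymous=CODON_TO_AA[SENSE_CODONS[s]]
                            == CODON_TO_AA[SENSE_CODONS[s_new]],
                            time=t,
                        )
                    )
                    s = s_new
                child_states[site] = s
            if child.is_leaf:
                leaf_seqs[child.name] = child_states
            else:
                evolve(child, child_states)

    evolve(tree.root, root_states)
    taxa = tree.leaf_names()
    seqs = ["".join(SENSE_CODONS[s] for s in leaf_seqs[t]) for t in taxa]
    return CodonAlignment(taxa, seqs), site_classes, ledger


# ---------------------------------------------------------------------------
# Promoter simulation
# ---------------------------------------------------------------------------


@dataclass
class PlantedMotif:
    gene: str
    window: int  # 1-based, window 1 adjacent to the start codon
    offset: int  # 0-based within the window, counted outward from the ATG side
    strand_form: str  # the 6-mer actually written (AATTTT or AAATTT)
    distance: int  # distance of the match start (5'-most base) to ATG, in bp


def _scan_motif_starts(seq: str) -> list[int]:
    """0-based string positions where AATTTT or AAATTT starts."""
    hits = []
    for m in (MOTIF, MOTIF_RC):
        start = seq.find(m)
        while start != -1:
            hits.append(start)
            start = seq.find(m, start + 1)
    return sorted(set(hits))


def simulate_promoters(
    gene_table: list[tuple[str, str]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[PlantedMotif]]:
    """Promoter sequences (coding strand, 5'→3', last base adjacent to ATG)
    with motifs planted per (gene set, window) probability.

    With ``background_motif_policy='exclude'`` the assembled promoter is
    rejection-sampled until its only motif occurrences are the planted ones,
    so the ledger is exhaustive by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for (set_label, _w) in config.plant_prob:
        if set_label not in GENE_SETS:
            raise ValueError(f"plant_prob references unknown gene set {set_label!r}")
    L = config.promoter_length
    W = config.window_size
    n_win = config.n_windows
    exclude = config.background_motif_policy == "exclude"
    promoters: dict[str, str] = {}
    ledger: list[PlantedMotif] = []
    nts = np.array(list("ACGT"))
    for gene, set_label in gene_table:
        chosen: list[tuple[int, str]] = []  # (window, 6-mer form)
        for w in range(1, n_win + 1):
            p = config.plant_prob.get((set_label, w), 0.0)
            if p > 0 and rng.random() < p:
                chosen.append((w, MOTIF if rng.random() < 0.5 else MOTIF_RC))
        plan: list[PlantedMotif] = []
        for _attempt in range(500):
            plan = []
            spans: list[tuple[int, int]] = []  # occupied distance intervals
            ok = True
            for w, form in chosen:
                lo = 5 if w == 1 else 0  # motif must fit inside the promoter
                for _draw in range(50):
                    offset = int(rng.integers(lo, W))
                    distance = (w - 1) * W + 1 + offset
                    if all(distance - 5 > b or distance < a for a, b in spans):
                        break
                else:
                    ok = False
                    break
                spans.append((distance - 5, distance))
                plan.append(PlantedMotif(gene, w, offset, form, distance))
            if not ok:
                continue
            seq = list("".join(rng.choice(nts, size=L)))
            planted_pos = []
            for pm in plan:
                pos = L - pm.distance  # match start in string coordinates
                seq[pos : pos + 6] = pm.strand_form
                planted_pos.append(pos)
            s = "".join(seq)
            hits = _scan_motif_starts(s)
            if not exclude:
                if set(planted_pos) <= set(hits):
                    break
            elif hits == sorted(planted_pos):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not assemble promoter for {gene}")
        promoters[gene] = s
        ledger.extend(plan)
    return promoters, ledger


# ---------------------------------------------------------------------------
# Codon-usage-biased genes
# ---------------------------------------------------------------------------


def simulate_biased_genes(
    reference_weights: dict[str, float],
    bias_level: float,
    n_genes: int,
    length: int,
    seed: int,
) -> list[str]:
    """Generate CDS with tunable codon bias relative to an adaptiveness table.

    Each codon position draws an amino acid uniformly, then with probability
    ``bias_level`` a maximum-weight (w = 1) codon of that family, otherwise a
    uniform draw within the family. bias_level = 1 therefore yields CAI = 1.
    """
    if not reference_weights:
        raise ValueError("empty adaptiveness table")
    if not 0.0 <= bias_level <= 1.0:
        raise ValueError("bias_level must be in [0,1]")
    rng = np.random.default_rng(seed)
    fams = synonymous_families()
    aas = sorted(fams)
    genes = []
    for _ in range(n_genes):
        codons = []
        for _pos in range(length):
            aa = aas[rng.integers(len(aas))]
            family = fams[aa]
            if rng.random() < bias_level:
                best = max(reference_weights.get(c, 0.0) for c in family)
                top = [c for c in family if reference_weights.get(c, 0.0) >= best]
                codons.append(top[rng.integers(len(top))])
            else:
                codons.append(family[rng.integers(len(family))])
        genes.append("".join(codons))
    return genes


# ---------------------------------------------------------------------------
# Whole genome sets
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    gene: str
    contig: str
    start: int  # 1-based inclusive CDS start
    end: int  # 1-based inclusive CDS end
    strand: str  # '+' or '-'


@dataclass
class SyntheticGenomeSet:
    species: list[str]
    contigs: dict[str, dict[str, str]]  # species -> contig name -> sequence
    genes: dict[str, list[GeneRecord]]  # species -> gene records
    set_labels: dict[str, str]  # gene base id -> CRP|rRNA|MRP|none
    go_map: dict[str, list[str]]  # gene base id -> GO ids
    alignments: dict[str, CodonAlignment]  # gene base id -> codon alignment
    substitutions: dict[str, list[SubstitutionEvent]]
    promoters: dict[str, dict[str, str]]  # species -> gene base id -> promoter
    planted: dict[str, list[PlantedMotif]]  # species -> planted motif ledger
    true_omega: dict[str, dict[int, float]]  # gene base id -> class -> ω
    tree: BranchClassTree
    config: SimulationConfig


def _default_set_labels(n_genes: int) -> list[str]:
    """Deterministic striping over CRP/rRNA/MRP/none, roughly 25% each."""
    return [GENE_SETS[i % 4] for i in range(n_genes)]


def build_genome_set(
    config: SimulationConfig,
    tree: BranchClassTree | None = None,
    set_labels: list[str] | None = None,
    omega_by_gene: dict[str, dict[int, float]] | None = None,
    n_go_terms: int = 8,
) -> SyntheticGenomeSet:
    """Assemble per-species single-contig genomes with promoters, CDS and
    ground-truth ledgers. Gene base ids (g0001, ...) are shared across
    species, giving the orthology ground truth."""
    rng = np.random.default_rng(config.seed)
    tree = tree or guide_tree()
    species = tree.leaf_names()
    labels = set_labels or _default_set_labels(config.n_genes)
    if len(labels) != config.n_genes:
        raise ValueError("set_labels length must equal n_genes")
    gene_ids = [f"g{i+1:04d}" for i in range(config.n_genes)]
    alignments: dict[str, CodonAlignment] = {}
    subs: dict[str, list[SubstitutionEvent]] = {}
    true_omega: dict[str, dict[int, float]] = {}
    for gid in gene_ids:
        gene_conf = config
        omega = (omega_by_gene or {}).get(gid, config.omega_by_class)
        if omega is not config.omega_by_class:
            gene_conf = SimulationConfig(
                n_genes=config.n_genes, codon_length=config.codon_length,
                kappa=config.kappa, omega_by_class=dict(omega),
                codon_freqs=config.codon_freqs,
                promoter_length=config.promoter_length,
                window_size=config.window_size, plant_prob=config.plant_prob,
                background_motif_policy=config.background_motif_policy,
                bias_level=config.bias_level, seed=config.seed,
            )
        aln, ledger = simulate_codon_alignment(tree, gene_conf, rng)
        alignments[gid] = aln
        subs[gid] = ledger
        true_omega[gid] = dict(omega)
    set_map = dict(zip(gene_ids, labels))
    go_map = {
        gid: sorted({f"GO:{(i % n_go_terms)+1:07d}", f"GO:{(i // 2 % n_go_terms)+1:07d}"})
        for i, gid in enumerate(gene_ids)
    }
    contigs: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneRecord]] = {}
    promoters: dict[str, dict[str, str]] = {}
    planted: dict[str, list[PlantedMotif]] = {}
    spacer = 100
    for sp in species:
        prom, ledger = simulate_promoters(list(set_map.items()), config, rng)
        promoters[sp] = prom
        planted[sp] = ledger
        parts: list[str] = []
        records: list[GeneRecord] = []
        pos = 0  # 0-based running offset
        contig_name = f"{sp}_chr1"
        for i, gid in enumerate(gene_ids):
            cds = alignments[gid].seqs[alignments[gid].taxa.index(sp)]
            strand = "+" if i % 2 == 0 else "-"
            if strand == "+":
                parts.append(prom[gid])
                start = pos + config.promoter_length + 1
                parts.append(cds)
                end = start + len(cds) - 1
                pos = end
            else:
                start = pos + 1
                parts.append(reverse_complement(cds))
                end = start + len(cds) - 1
                parts.append(reverse_complement(prom[gid]))
                pos = end + config.promoter_length
            parts.append("".join(np.random.default_rng(config.seed + i).choice(
                list("ACGT"), size=spacer)))
            pos += spacer
            records.append(GeneRecord(gid, contig_name, start, end, strand))
        contigs[sp] = {contig_name: "".join(parts)}
        genes[sp] = records
    return SyntheticGenomeSet(
        species=species, contigs=contigs, genes=genes, set_labels=set_map,
        go_map=go_map, alignments=alignments, substitutions=subs,
        promoters=promoters, planted=planted, true_omega=true_omega,
        tree=tree, config=config,
    )


# ---------------------------------------------------------------------------
# Writers (FASTA / GFF3 / TSV / JSON)
# ---------------------------------------------------------------------------


def write_genome_set(gs: SyntheticGenomeSet, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in gs.species:
        with open(out / f"{sp}.genome.fasta", "w") as fh:
            for contig, seq in gs.contigs[sp].items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(out / f"{sp}.genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for r in gs.genes[sp]:
                fh.write(
                    f"{r.contig}\tyeastevol\tgene\t{r.start}\t{r.end}\t.\t{r.strand}"
                    f"\t.\tID={r.gene}\n"
                )
        with open(out / f"{sp}.cds.fasta", "w") as fh:
            for gid, aln in gs.alignments.items():
                fh.write(f">{gid}\n{aln.seqs[aln.taxa.index(sp)]}\n")
        with open(out / f"{sp}.protein.fasta", "w") as fh:
            from .genetic_code import translate

            for gid, aln in gs.alignments.items():
                fh.write(f">{gid}\n{translate(aln.seqs[aln.taxa.index(sp)])}\n")
    with open(out / "gene_sets.tsv", "w") as fh:
        for gid, label in gs.set_labels.items():
            fh.write(f"{gid}\t{label}\n")
    with open(out / "go_map.tsv", "w") as fh:
        for gid, terms in gs.go_map.items():
            for term in terms:
                fh.write(f"{gid}\t{term}\n")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(gs.tree.to_newick() + "\n")
    truth = {
        "true_omega": {g: {str(c): w for c, w in m.items()} for g, m in gs.true_omega.items()},
        "bias_level": gs.config.bias_level,
        "planted_motifs": {
            sp: [
                {"gene": p.gene, "window": p.window, "offset": p.offset,
                 "form": p.strand_form, "distance": p.distance}
                for p in gs.planted[sp]
            ]
            for sp in gs.species
        },
        "n_substitutions": {g: len(v) for g, v in gs.substitutions.items()},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
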