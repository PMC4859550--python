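"""One-to-one ortholog detection by reciprocal best hits (RBH).

Protein pairs are scored with Smith–Waterman local alignment (BLOSUM62,
affine gaps) at desk scale; a pair (a, b) is an RBH when b is the unique
best hit of a and vice versa, at or above a score threshold. Clusters are
built reference-star style: every species is compared against one reference
species, and a cluster is kept only when every species contributes exactly
one unambiguous member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(matrix=None, gap_open: float = 11.0, gap_extend: float = 1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    # affine convention: a gap of length L costs gap_open + (L-1)*gap_extend
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _validate_protein(seq: str, which: str) -> str:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise ValueError(f"illegal residue {ch!r} at position {i} of {which}")
    return seq


def local_align_score(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Smith–Waterman local alignment score with affine gaps (>= 0)."""
    seq_a = _validate_protein(seq_a, "seq_a")
    seq_b = _validate_protein(seq_b, "seq_b")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return max(0.0, float(aligner.score(seq_a, seq_b)))


@dataclass
class SimilarityMatrix:
    species_a: str
    species_b: str
    genes_a: list[str]
    genes_b: list[str]
    scores: np.ndarray  # (len(genes_a), len(genes_b)), >= 0

    @classmethod
    def from_proteomes(
        cls,
        species_a: str,
        proteome_a: dict[str, str],
        species_b: str,
        proteome_b: dict[str, str],
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
    ) -> "SimilarityMatrix":
        genes_a, genes_b = list(proteome_a), list(proteome_b)
        aligner = _make_aligner(None, gap_open, gap_extend)
        scores = np.zeros((len(genes_a), len(genes_b)))
        seqs_a = [_validate_protein(proteome_a[g], g) for g in genes_a]
        seqs_b = [_validate_protein(proteome_b[g], g) for g in genes_b]
        for i, sa in enumerate(seqs_a):
            for j, sb in enumerate(seqs_b):
                scores[i, j] = max(0.0, float(aligner.score(sa, sb)))
        return cls(
            species_a=species_a, species_b=species_b,
            genes_a=genes_a, genes_b=genes_b, scores=scores,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(self.genes_b) + "\n")
            for i, g in enumerate(self.genes_a):
                fh.write(g + "\t" + "\t".join(f"{s:g}" for s in self.scores[i]) + "\n")


def reciprocal_best_hits(
    m_ab: SimilarityMatrix, min_score: float = 50.0
) -> list[tuple[str, str]]:
    """Pairs (gene_a, gene_b) that are mutual unique best hits at or above
    ``min_score``. Ties for best hit disqualify a gene (no unique best)."""
    S = m_ab.scores
    if S.size == 0:
        return []
    pairs = []
    for i in range(S.shape[0]):
        row = S[i]
        j = int(np.argmax(row))
        if row[j] < min_score:
            continue
        if (row == row[j]).sum() > 1:
            continue  # tied best hit: ambiguous
        col = S[:, j]
        if (col == col.max()).sum() > 1 or int(np.argmax(col)) != i:
            continue
        pairs.append((m_ab.genes_a[i], m_ab.genes_b[j]))
    return pairs


@dataclass
class OrthologClusterSet:
    reference_species: str
    clusters: list[dict[str, str]]  # species -> gene id; one gene per species

    def __len__(self) -> int:
        return len(self.clusters)

    def to_tsv(self, path) -> None:
        species = sorted({sp for c in self.clusters for sp in c})
        ref = self.reference_species
        species = [ref] + [s for s in species if s != ref]
        with open(path, "w") as fh:
            fh.write("\t".join(species) + "\n")
            for c in sorted(self.clusters, key=lambda c: c[ref]):
                fh.write("\t".join(c[s] for s in species) + "\n")


def one_to_one_clusters(
    rbh_by_species: dict[str, list[tuple[str, str]]],
    reference_species: str,
) -> OrthologClusterSet:
    """Build one-to-one clusters seeded on reference genes.

    ``rbh_by_species`` maps each non-reference species to its RBH pair list
    (reference gene, species gene). A cluster is retained only when every
    species contributes exactly one gene and no gene is claimed twice.
    """
    if not rbh_by_species:
        raise ValueError("reference species absent: no RBH pair lists given")
    ref_genes: set[str] = set()
    maps: dict[str, dict[str, str]] = {}
    used: dict[str, set[str]] = {}
    for sp, pairs in rbh_by_species.items():
        m: dict[str, str] = {}
        dropped: set[str] = set()
        for ref_g, sp_g in pairs:
            if ref_g in m and m[ref_g] != sp_g:
                dropped.add(ref_g)  # reference gene paired twice: ambiguous
            else:
                m[ref_g] = sp_g
        for g in dropped:
            m.pop(g, None)
        maps[sp] = m
        used[sp] = set()
        ref_genes.update(m)
    clusters = []
    for ref_g in sorted(ref_genes):
        cluster = {reference_species: ref_g}
        ok = True
        for sp, m in maps.items():
            if ref_g not in m or m[ref_g] in used[sp]:
                ok = False
                break
            cluster[sp] = m[ref_g]
        if ok:
            for sp in maps:
                used[sp].add(cluster[sp])
            clusters.append(cluster)
    return OrthologClusterSet(reference_species=reference_species, clusters=clusters)


def rbh_star_clusters(
    proteomes: dict[str, dict[str, str]],
    reference_species: str,
    min_score: float = 50.0,
) -> OrthologClusterSet:
    """Full RBH-star workflow: score every species against the reference,
    take RBH pairs, and assemble one-to-one clusters."""
    if reference_species not in proteomes:
        raise ValueError(f"reference species {reference_species!r} not in proteomes")
    rbh_by_species = {}
    for sp, prot in proteomes.items():
        if sp == reference_species:
            continue
        m = SimilarityMatrix.from_proteomes(
            reference_species, proteomes[reference_species], sp, prot
        )
        rbh_by_species[sp] = reciprocal_best_hits(m, min_score)
    return one_to_one_clusters(rbh_by_species, reference_species)
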