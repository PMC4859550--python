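"""Standard genetic code tables and codon bookkeeping.

The codon-model machinery works on the 61 sense codons of the standard
nuclear code (stop codons are excluded from the state space). Codons are
indexed alphabetically over the DNA alphabet ACGT; the index order is a
package-internal convention shared by the simulator and the likelihood
engine.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

#: The 61 sense codons in alphabetical order; positions define state indices.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

N_CODONS = len(SENSE_CODONS)  # 61

#: codon -> one-letter amino acid (sense codons only)
CODON_TO_AA: dict[str, str] = {c: _standard.forward_table[c] for c in SENSE_CODONS}

AA_INDEX: dict[str, int] = {
    aa: i for i, aa in enumerate(sorted(set(CODON_TO_AA.values())))
}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition (A<->G, C<->T)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def codon_diff(c1: str, c2: str) -> list[int]:
    """Positions (0-2) at which two codons differ."""
    return [k for k in range(3) if c1[k] != c2[k]]


def translate(cds: str) -> str:
    """Translate an in-frame CDS of sense codons to protein.

    Raises ValueError on internal stop codons or non-multiple-of-3 length.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            if i == len(cds) - 3:
                break  # trailing stop tolerated
            raise ValueError(f"internal stop codon {codon} at nt position {i}")
        if codon not in CODON_TO_AA:
            raise ValueError(f"unrecognized codon {codon!r} at nt position {i}")
        aas.append(CODON_TO_AA[codon])
    return "".join(aas)


def codons_of(cds: str) -> list[str]:
    """Split an in-frame CDS into codons (no validation beyond length)."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def synonymous_families() -> dict[str, list[str]]:
    """Amino acid -> list of its sense codons (synonymous family)."""
    fam: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        fam.setdefault(aa, []).append(codon)
    return fam


# Precomputed single-step structure of the 61-state codon graph, used by both
# the rate-matrix builder and the jump-process simulator.
def _single_step_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = codon_diff(ci, cj)
            if len(diff) != 1:
                continue
            k = diff[0]
            single[i, j] = True
            transition[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = CODON_TO_AA[ci] != CODON_TO_AA[cj]
    return single, transition, nonsyn


SINGLE_STEP, TRANSITION_STEP, NONSYN_STEP = _single_step_tables()

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
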