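"""Protein structure reading and mapping of selected sites onto residues.

Positively selected alignment sites are mapped to residue numbers of a
crystal structure by global alignment of the query protein against the
sequence derived from the structure's residues, and side-chain distances
(e.g. the glutamate carboxylate to arginine guanidinium contact in the
phosphoglycerate kinase substrate pocket) are measured as atom-pair minima.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

logger = logging.getLogger(__name__)

#: atoms carrying the side-chain charge, per residue type
CHARGE_GROUP_ATOMS = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "CB"})


@dataclass
class Residue:
    chain: str
    number: int  # author numbering (resSeq)
    name: str  # three-letter code
    atoms: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class StructureModel:
    residues: dict[tuple[str, int], Residue]

    def chains(self) -> list[str]:
        return sorted({chain for chain, _ in self.residues})

    def chain_residues(self, chain: str) -> list[Residue]:
        return [r for (c, _), r in sorted(self.residues.items()) if c == chain]

    def chain_sequence(self, chain: str) -> tuple[str, list[int]]:
        """One-letter sequence derived from residue names plus parallel
        author residue numbers."""
        res = self.chain_residues(chain)
        return "".join(seq1(r.name) for r in res), [r.number for r in res]


def read_structure(pdb_text: str) -> StructureModel:
    """Parse fixed-column PDB ATOM records (HETATM ignored).

    altLoc duplicates keep the highest-occupancy conformer; malformed lines
    are skipped with a warning; zero parsed atoms is an error.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("model", io.StringIO(pdb_text))
    residues: dict[tuple[str, int], Residue] = {}
    n_atoms = 0
    for model in structure:
        for chain in model:
            for res in chain:
                hetfield, resseq, _icode = res.get_id()
                if hetfield.strip():
                    continue  # HETATM / water
                key = (chain.id, resseq)
                rec = residues.setdefault(
                    key,
                    Residue(chain=chain.id, number=resseq, name=res.get_resname()),
                )
                for atom in res:
                    # Biopython's DisorderedAtom yields the highest-occupancy
                    # conformer by default
                    rec.atoms[atom.get_name()] = np.asarray(atom.get_coord(), float)
                    n_atoms += 1
        break  # first model only
    if n_atoms == 0:
        raise ValueError("no ATOM records parsed from PDB text")
    return StructureModel(residues=residues)


def _atom_coords(res: Residue, mode: str) -> np.ndarray:
    if mode == "charge":
        names = CHARGE_GROUP_ATOMS.get(res.name)
        if names is None:
            raise ValueError(
                f"residue {res.name}{res.number} has no defined charge group; "
                "use mode='sidechain'"
            )
        coords = [res.atoms[n] for n in names if n in res.atoms]
    elif mode == "sidechain":
        coords = [
            xyz
            for name, xyz in res.atoms.items()
            if name not in BACKBONE_ATOMS and not name.startswith("H")
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not coords:
        raise ValueError(f"no atoms pass the {mode} filter for {res.name}{res.number}")
    return np.vstack(coords)


def min_sidechain_distance(
    model: StructureModel,
    chain: str,
    res_a: int,
    res_b: int,
    mode: str = "charge",
) -> float:
    """Minimum Euclidean distance (Å) between the selected atom groups of two
    residues. ``mode='charge'`` restricts to the charged side-chain atoms
    (Glu/Asp carboxylate oxygens, Arg guanidinium nitrogens, ...);
    ``mode='sidechain'`` uses all side-chain atoms beyond Cβ."""
    if res_a == res_b:
        return 0.0
    try:
        ra = model.residues[(chain, res_a)]
    except KeyError:
        raise ValueError(f"residue {chain}:{res_a} not in structure") from None
    try:
        rb = model.residues[(chain, res_b)]
    except KeyError:
        raise ValueError(f"residue {chain}:{res_b} not in structure") from None
    A, B = _atom_coords(ra, mode), _atom_coords(rb, mode)
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    return float(d.min())


@dataclass
class SiteMapping:
    mapped: dict[int, int]  # query position (0-based) -> structure residue number
    unmapped: list[int]
    identity: float


def map_sites_to_structure(
    selected_sites: list[int],
    query_seq: str,
    structure_seq: str,
    residue_numbers: list[int] | None = None,
    min_identity: float = 0.30,
) -> SiteMapping:
    """Map 0-based positions of the query protein onto structure residue
    numbers via global pairwise alignment.

    ``structure_seq`` is the one-letter sequence derived from the structure's
    residues (see :meth:`StructureModel.chain_sequence`);
    ``residue_numbers`` gives the author numbering of those residues
    (defaults to 1..len). Refuses to map below ``min_identity`` aligned
    identity — the structure is probably the wrong protein.
    """
    if residue_numbers is None:
        residue_numbers = list(range(1, len(structure_seq) + 1))
    if len(residue_numbers) != len(structure_seq):
        raise ValueError("residue_numbers length must match structure_seq")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(query_seq.upper(), structure_seq.upper())[0]
    qpos_to_spos: dict[int, int] = {}
    matches = aligned = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for k in range(qe - qs):
            qpos_to_spos[qs + k] = ss + k
            aligned += 1
            if query_seq[qs + k].upper() == structure_seq[ss + k].upper():
                matches += 1
    identity = matches / aligned if aligned else 0.0
    if identity < min_identity:
        raise ValueError(
            f"alignment identity {identity:.2f} below {min_identity:.2f}: "
            "likely the wrong structure"
        )
    mapped, unmapped = {}, []
    for site in selected_sites:
        if site in qpos_to_spos:
            mapped[site] = residue_numbers[qpos_to_spos[site]]
        else:
            unmapped.append(site)
    return SiteMapping(mapped=mapped, unmapped=unmapped, identity=identity)


def write_pdb(model: StructureModel, path) -> None:
    """Write ATOM records (fixed columns, coordinates to 3 decimals)."""
    serial = 1
    with open(path, "w") as fh:
        for (chain, _num), res in sorted(model.residues.items()):
            for name, xyz in res.atoms.items():
                pad = name if len(name) == 4 else f" {name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {pad}{'':1s}{res.name:>3s} {chain}"
                    f"{res.number:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}\n"
                )
                serial += 1
        fh.write("END\n")
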