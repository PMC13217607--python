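"""Parsing of protein structure files into per-residue chains.

Each residue is reduced to a single representative coordinate: the alpha
carbon when present, otherwise the beta carbon, otherwise the centroid of
the residue's heavy atoms.  This keeps low-resolution structures with
missing backbone atoms usable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: one-letter codes of the 20 standard amino acids (alphabetical)
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


class CoordSource(str, Enum):
    ALPHA_CARBON = "alpha_carbon"
    BETA_CARBON = "beta_carbon"
    CENTROID = "centroid"


class StructureFormatError(ValueError):
    """Raised for unreadable or chain-less structure files."""


@dataclass
class ResidueRecord:
    position: int                  # 1-based index within the chain
    aa_code: str                   # one-letter symbol, 'X' for nonstandard
    coord: np.ndarray              # (3,) in Angstrom
    coord_source: CoordSource

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError("residue coordinate must be a finite 3-vector")
        if self.position < 1:
            raise ValueError("residue position must be >= 1")
        if self.aa_code not in STANDARD_AA + "X":
            raise ValueError(f"unknown amino-acid symbol {self.aa_code!r}")


@dataclass
class ProteinChain:
    structure_id: str
    chain_id: str
    sequence: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) != len(self.residues):
            raise ValueError("sequence length must match residue count")
        for i, (c, r) in enumerate(zip(self.sequence, self.residues)):
            if c != r.aa_code:
                raise ValueError(f"sequence/residue mismatch at index {i}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def name(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"

    def coords(self) -> np.ndarray:
        """(L, 3) array of representative residue coordinates."""
        return np.stack([r.coord for r in self.residues]) if self.residues \
            else np.zeros((0, 3))


def extract_residue_coordinate(atoms: dict[str, np.ndarray]
                               ) -> tuple[np.ndarray, CoordSource]:
    """Pick the representative coordinate of one residue.

    ``atoms`` maps atom names (e.g. ``"CA"``) to 3-vectors.  Preference
    order: CA, then CB, then the unweighted centroid of all heavy atoms
    given (hydrogens should not be passed in).
    """
    if not atoms:
        raise ValueError("residue has no atoms; cannot place it")
    if "CA" in atoms:
        return np.asarray(atoms["CA"], dtype=float), CoordSource.ALPHA_CARBON
    if "CB" in atoms:
        return np.asarray(atoms["CB"], dtype=float), CoordSource.BETA_CARBON
    coords = np.stack([np.asarray(v, dtype=float) for v in atoms.values()])
    return coords.mean(axis=0), CoordSource.CENTROID


def _residue_one_letter(name: str) -> str:
    return _THREE_TO_ONE.get(name.upper().strip(), "X")


def _is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    return res.name.upper() in _THREE_TO_ONE


def parse_structure(path: str | Path,
                    chain_filter: set[str] | None = None
                    ) -> list[ProteinChain]:
    """Parse a PDB (or mmCIF) file into one ``ProteinChain`` per chain.

    Only the first model is used.  Waters and non-amino-acid hetero
    groups are dropped; nonstandard amino acids are kept with code 'X'.
    Alternate locations resolve to the first occurrence per atom name.
    Residues are ordered by author numbering (with insertion codes) and
    renumbered 1..L internally.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such structure file: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureFormatError(f"{path} contains no models")

    structure_id = structure.name.strip() or path.stem
    model = structure[0]
    chains: list[ProteinChain] = []
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        entries = []  # ((author seqid, icode), residue)
        for res in chain:
            if res.is_water() or not _is_amino_acid(res):
                continue
            entries.append(((res.seqid.num, res.seqid.icode or " "), res))
        entries.sort(key=lambda e: e[0])
        residues: list[ResidueRecord] = []
        for (num, icode), res in entries:
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                if atom.name in atoms:   # keep first altloc encountered
                    continue
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if not atoms:
                logger.warning("skipping residue %s %s%s in chain %s: no atoms",
                               res.name, num, icode.strip(), chain.name)
                continue
            coord, source = extract_residue_coordinate(atoms)
            residues.append(ResidueRecord(position=len(residues) + 1,
                                          aa_code=_residue_one_letter(res.name),
                                          coord=coord, coord_source=source))
        if not residues:
            continue
        chains.append(ProteinChain(structure_id=structure_id,
                                   chain_id=chain.name,
                                   sequence="".join(r.aa_code for r in residues),
                                   residues=residues))
    if not chains:
        if chain_filter is not None:
            raise StructureFormatError(
                f"chain filter {sorted(chain_filter)} matched no chain in {path}")
        raise StructureFormatError(f"no polymer chain found in {path}")
    return chains


def write_chain_fasta(chains: list[ProteinChain], path: str | Path) -> None:
    """Write chains as FASTA with headers ``structureid_chainid``.

    Chains with empty sequences are skipped with a warning.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    if not chains:
        raise ValueError("no chains to write")
    records = []
    for chain in chains:
        if not chain.sequence:
            logger.warning("skipping empty chain %s", chain.name)
            continue
        records.append(SeqRecord(Seq(chain.sequence), id=chain.name,
                                 description=""))
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs."""
    from Bio.SeqIO import parse as seqio_parse

    return [(rec.id, str(rec.seq)) for rec in seqio_parse(str(path), "fasta")]
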