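"""Synthetic structure/annotation fixtures with planted catalytic motifs.

Chains are compact self-avoiding random walks with the canonical
~3.8 A consecutive C-alpha spacing.  Each synthetic enzyme class is
defined by a motif: a few residue identities planted at sequence
positions at least 10 apart but forced to be spatially adjacent
(pairwise within 6 A by default), mimicking catalytic residues that are
close in the fold yet distant in sequence.  The generator emits the
same PDB and TSV dialects the rest of the package consumes, so dataset
construction, training, attribution and catalytic evaluation are all
exercisable without any downloads.

Geometry is deliberately minimal: no secondary structure, no side
chains, no Ramachandran statistics.  The only systematic difference
between classes is the planted motif (identities + clustered geometry);
background composition is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .annotations import AnnotationInterval, ECNumber, write_interval_table
from .catalytic import CatalyticAnnotation, write_catalytic_table
from .structure_io import (STANDARD_AA, CoordSource, ProteinChain,
                           ResidueRecord)

#: consecutive C-alpha spacing (A)
BACKBONE_STEP = 3.8
#: minimum distance between non-consecutive residues (A)
MIN_CLASH_DISTANCE = 3.0
#: minimum sequence separation between planted motif residues
MOTIF_MIN_SEPARATION = 10

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class MotifSpec:
    class_label: str                        # synthetic EC-like code, 4 digits
    residue_identities: tuple[str, ...]     # e.g. ("S", "H", "D")
    max_pairwise_distance: float = 6.0

    @property
    def motif_size(self) -> int:
        return len(self.residue_identities)

    def __post_init__(self):
        if self.motif_size < 2:
            raise ValueError("motif needs at least two residues")
        if any(aa not in STANDARD_AA for aa in self.residue_identities):
            raise ValueError("motif identities must be standard amino acids")


@dataclass
class SyntheticDatasetSpec:
    n_chains_per_class: int = 20
    length_range: tuple[int, int] = (80, 120)
    motifs: tuple[MotifSpec, ...] = ()
    background_weights: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.motifs:
            raise ValueError("at least one motif class is required")
        min_len = self.length_range[0]
        for m in self.motifs:
            if min_len <= m.motif_size * 4:
                raise ValueError("chains too short for the motif")
        if self.background_weights is None:
            # motif identities are the class signal: the background samples
            # the remaining amino acids uniformly
            used = {aa for m in self.motifs for aa in m.residue_identities}
            rest = [aa for aa in STANDARD_AA if aa not in used]
            if not rest:
                raise ValueError("motifs exhaust the amino-acid alphabet")
            self.background_weights = {aa: 1.0 / len(rest) for aa in rest}


DEFAULT_MOTIFS = (
    MotifSpec("1.1.1.1", ("S", "H", "D")),     # serine-triad-like
    MotifSpec("2.1.1.1", ("C", "K", "E")),
    MotifSpec("3.1.1.1", ("R", "N", "Q")),
    MotifSpec("4.1.1.1", ("W", "Y", "M")),
)


def default_dataset_spec(n_classes: int = 3, n_chains_per_class: int = 20,
                         length_range: tuple[int, int] = (80, 120),
                         seed: int = 0) -> SyntheticDatasetSpec:
    if not 1 <= n_classes <= len(DEFAULT_MOTIFS):
        raise ValueError(f"n_classes must be in 1..{len(DEFAULT_MOTIFS)}")
    return SyntheticDatasetSpec(n_chains_per_class=n_chains_per_class,
                                length_range=length_range,
                                motifs=DEFAULT_MOTIFS[:n_classes], seed=seed)


# ---------------------------------------------------------------------------
# backbone geometry
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _confinement_radius(length: int) -> float:
    # compact-globule scaling: R grows with the cube root of chain length
    return max(4.0 * length ** (1.0 / 3.0), 12.0)


def _walk(length: int, rng: np.random.Generator,
          motif_positions: tuple[int, ...] = (),
          motif_radius: float = 3.0,
          max_restarts: int = 50) -> np.ndarray:
    """Self-avoiding walk, optionally steered through a motif ball.

    Residues at ``motif_positions`` (1-based) must land within
    ``motif_radius`` of the origin, which bounds their pairwise
    distances by ``2 * motif_radius``.
    """
    R = _confinement_radius(length)
    motif_set = set(motif_positions)
    future_motifs = sorted(motif_positions)
    n_tries = 240

    for _ in range(max_restarts):
        pts = np.empty((length, 3))
        start_r = motif_radius * 0.8 if 1 in motif_set else R * 0.5
        pts[0] = _random_unit(rng) * rng.uniform(0, start_r)
        ok = True
        i = 1
        backtracks = 0
        while i < length:
            pos = i + 1          # 1-based residue position being placed
            nxt = next((m for m in future_motifs if m >= pos), None)
            placed = False
            prev = pts[i - 1]
            for attempt in range(n_tries):
                if nxt is not None:
                    # steer toward a random point of the motif ball, with
                    # steering strength growing across failed attempts
                    target = _random_unit(rng) * rng.uniform(
                        0, motif_radius * 0.8)
                    aim = target - prev
                    norm = np.linalg.norm(aim)
                    aim = aim / norm if norm > 1e-9 else _random_unit(rng)
                    w = (0.2, 0.6, 0.95)[min(attempt // 80, 2)]
                    d_center = np.linalg.norm(prev)
                    budget = motif_radius + (nxt - pos) * BACKBONE_STEP
                    if d_center < budget - 2 * BACKBONE_STEP \
                            and pos not in motif_set:
                        w = 0.1  # plenty of slack: wander freely
                    direction = w * aim + (1 - w) * _random_unit(rng)
                    direction = direction / np.linalg.norm(direction)
                else:
                    direction = _random_unit(rng)
                cand = prev + BACKBONE_STEP * direction
                if np.linalg.norm(cand) > R:
                    continue
                if nxt is not None and np.linalg.norm(cand) > \
                        motif_radius + (nxt - pos) * BACKBONE_STEP:
                    continue
                if pos in motif_set and np.linalg.norm(cand) > motif_radius:
                    continue
                if i >= 2:
                    d = np.linalg.norm(pts[:i - 1] - cand, axis=1)
                    if d.min() < MIN_CLASH_DISTANCE:
                        continue
                pts[i] = cand
                placed = True
                break
            if placed:
                i += 1
            else:
                backtracks += 1
                if backtracks > 60:
                    ok = False
                    break
                i = max(1, i - 8)
        if ok:
            return pts
    raise RuntimeError(
        f"could not place a {length}-residue chain after {max_restarts} "
        f"restarts (motif positions {motif_positions})")


def generate_backbone(length: int, seed: int) -> np.ndarray:
    """Compact self-avoiding C-alpha trace with exact 3.8 A steps."""
    if length < 2:
        raise ValueError("length must be >= 2")
    return _walk(length, np.random.default_rng(seed))


def _choose_motif_positions(length: int, motif_size: int,
                            rng: np.random.Generator,
                            min_separation: int = MOTIF_MIN_SEPARATION
                            ) -> tuple[int, ...]:
    for _ in range(200):
        cand = np.sort(rng.choice(np.arange(1, length + 1), size=motif_size,
                                  replace=False))
        if np.all(np.diff(cand) >= min_separation):
            return tuple(int(p) for p in cand)
    raise RuntimeError("could not select separated motif positions")


def plant_motif(sequence: str, motif: MotifSpec, seed: int
                ) -> tuple[str, np.ndarray, tuple[int, ...]]:
    """Plant a spatially clustered motif into a chain.

    Returns ``(sequence, coords, positions)``: the sequence with the
    motif identities written at positions pairwise >= 10 apart, and
    coordinates rebuilt so those positions are mutually within
    ``motif.max_pairwise_distance`` while keeping the 3.8 A backbone
    step and self-avoidance.
    """
    length = len(sequence)
    if length <= motif.motif_size * (MOTIF_MIN_SEPARATION + 1):
        raise ValueError("chain too short to plant the motif")
    rng = np.random.default_rng(seed)
    positions = _choose_motif_positions(length, motif.motif_size, rng)
    coords = _walk(length, rng, motif_positions=positions,
                   motif_radius=motif.max_pairwise_distance / 2.0)
    seq = list(sequence)
    for pos, aa in zip(positions, motif.residue_identities):
        seq[pos - 1] = aa
    return "".join(seq), coords, positions


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    chains: list[ProteinChain]
    intervals: list[AnnotationInterval]
    catalytic: dict[str, CatalyticAnnotation]
    class_of: dict[str, ECNumber] = field(default_factory=dict)


def _chain_from_arrays(structure_id: str, sequence: str,
                       coords: np.ndarray) -> ProteinChain:
    residues = [ResidueRecord(position=i + 1, aa_code=aa, coord=coords[i],
                              coord_source=CoordSource.ALPHA_CARBON)
                for i, aa in enumerate(sequence)]
    return ProteinChain(structure_id=structure_id, chain_id="A",
                        sequence=sequence, residues=residues)


def generate_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate all chains, interval annotations and catalytic tables."""
    rng = np.random.default_rng(spec.seed)
    letters = sorted(spec.background_weights)
    weights = np.array([spec.background_weights[a] for a in letters])
    weights = weights / weights.sum()

    chains: list[ProteinChain] = []
    intervals: list[AnnotationInterval] = []
    catalytic: dict[str, CatalyticAnnotation] = {}
    class_of: dict[str, ECNumber] = {}
    idx = 0
    for motif in spec.motifs:
        ec = ECNumber.parse(motif.class_label)
        for _ in range(spec.n_chains_per_class):
            length = int(rng.integers(spec.length_range[0],
                                      spec.length_range[1] + 1))
            background = "".join(rng.choice(letters, size=length, p=weights))
            chain_seed = int(rng.integers(0, 2**31 - 1))
            sequence, coords, positions = plant_motif(background, motif,
                                                      chain_seed)
            structure_id = f"syn{idx:04d}"
            chain = _chain_from_arrays(structure_id, sequence, coords)
            chains.append(chain)
            intervals.append(AnnotationInterval(
                accession=chain.name, start=1, end=length, ec_numbers=[ec]))
            catalytic[chain.name] = CatalyticAnnotation(
                chain_ref=chain.name, positions=set(positions))
            class_of[chain.name] = ec
            idx += 1
    return SyntheticDataset(chains=chains, intervals=intervals,
                            catalytic=catalytic, class_of=class_of)


# ---------------------------------------------------------------------------
# file emission (PDB + TSV dialects shared with the parsing modules)
# ---------------------------------------------------------------------------

def write_chain_pdb(chain: ProteinChain, path: str | Path,
                    ca_only: bool = True) -> None:
    """Write a chain as a C-alpha-only PDB file."""
    structure = gemmi.Structure()
    structure.name = chain.structure_id
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain.chain_id)
    for res in chain.residues:
        gres = gemmi.Residue()
        gres.name = _ONE_TO_THREE.get(res.aa_code, "UNK")
        gres.seqid = gemmi.SeqId(res.position, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*res.coord)
        gres.add_atom(atom)
        gchain.add_residue(gres)
    model.add_chain(gchain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
    del ca_only  # only the representative atom is stored


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict:
    """Emit PDB files plus interval and catalytic TSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_dir = out_dir / "structures"
    pdb_dir.mkdir(exist_ok=True)
    pdb_paths = []
    for chain in dataset.chains:
        # file stem must equal the structure id so that re-parsing
        # reconstructs the same chain name (accession key)
        p = pdb_dir / f"{chain.structure_id}.pdb"
        write_chain_pdb(chain, p)
        pdb_paths.append(p)
    interval_path = out_dir / "intervals.tsv"
    write_interval_table(dataset.intervals, interval_path)
    catalytic_path = out_dir / "catalytic.tsv"
    write_catalytic_table(dataset.catalytic, catalytic_path)
    return {"structures": pdb_paths, "intervals": interval_path,
            "catalytic": catalytic_path}
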