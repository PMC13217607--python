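import numpy as np
import pytest

from enzgraph.embedders import EmbedderSpec, ReferenceEmbedder
from enzgraph.pipeline import dataset_from_tables, graphs_from_dataset
from enzgraph.simulate import default_dataset_spec, generate_dataset


def pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                  resseq: int, x: float, y: float, z: float,
                  altloc: str = " ", element: str = "C",
                  occupancy: float = 1.0) -> str:
    """One fixed-column ATOM record."""
    return (f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
            f"{0.0:6.2f}          {element:>2s}")


@pytest.fixture
def three_residue_pdb(tmp_path):
    """ALA-GLY-SER chain A, CA atoms only, 3.8 A apart on a line."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        pdb_atom_line(3, "CA", "SER", "A", 3, 7.6, 0.0, 0.0),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        "TER",
        pdb_atom_line(3, "CA", "SER", "B", 1, 20.0, 0.0, 0.0),
        pdb_atom_line(4, "CA", "TRP", "B", 2, 23.8, 0.0, 0.0),
        "END",
    ]
    path = tmp_path / "two_chain.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_synthetic():
    """2 classes x 6 chains of 50-60 residues; cached for the session."""
    spec = default_dataset_spec(n_classes=2, n_chains_per_class=6,
                                length_range=(50, 60), seed=123)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_graph_dataset(small_synthetic):
    labeled = dataset_from_tables(small_synthetic.chains,
                                  small_synthetic.intervals, min_positives=5)
    embedder = ReferenceEmbedder(EmbedderSpec(dim=8, seed=0))
    graphs = graphs_from_dataset(labeled, embedder)
    return labeled, graphs


def random_graph(rng: np.random.Generator, L: int, d: int):
    """Random binary symmetric zero-diagonal adjacency + features."""
    A = (rng.random((L, L)) < 0.4).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    H = rng.standard_normal((L, d))
    return H, A
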