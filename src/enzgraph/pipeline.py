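"""Glue between annotation tables, chains, graphs and the classifier.

These helpers standardize the steps every entry point (CLI, scripts,
tests) shares: mapping chains onto accession intervals, building the
labeled dataset, and assembling model-ready graphs.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .annotations import (AnnotationInterval, ChainMapping, LabeledDataset,
                          build_dataset, compute_overlap)
from .graphs import DEFAULT_CUTOFF, ProteinGraph, assemble_graph
from .structure_io import ProteinChain, parse_structure

logger = logging.getLogger(__name__)


def map_chains(chains: list[ProteinChain],
               intervals: list[AnnotationInterval],
               spans: dict[str, tuple[str, int, int]] | None = None
               ) -> list[ChainMapping]:
    """One ChainMapping per (chain, overlapping interval) pair.

    ``spans`` maps a chain name to ``(accession, start, end)`` in
    accession coordinates; when omitted, each chain is assumed to be
    its own accession covering positions 1..L (the convention used by
    the synthetic datasets).
    """
    by_accession: dict[str, list[AnnotationInterval]] = {}
    for iv in intervals:
        by_accession.setdefault(iv.accession, []).append(iv)
    mappings: list[ChainMapping] = []
    for chain in chains:
        if spans is None:
            accession, start, end = chain.name, 1, len(chain)
        else:
            if chain.name not in spans:
                logger.warning("no accession span for %s; skipped", chain.name)
                continue
            accession, start, end = spans[chain.name]
        for iv in by_accession.get(accession, []):
            length, fraction = compute_overlap((start, end), iv)
            if length == 0:
                continue
            mappings.append(ChainMapping(
                chain=chain, accession=accession, chain_start=start,
                chain_end=end, length_overlap=length,
                fraction_overlap=fraction,
                ec_numbers=list(iv.ec_numbers)))
    return mappings


def load_structures(structure_dir: str | Path) -> list[ProteinChain]:
    """Parse every .pdb/.cif file in a directory (sorted by name)."""
    structure_dir = Path(structure_dir)
    paths = sorted(p for p in structure_dir.iterdir()
                   if p.suffix.lower() in (".pdb", ".cif", ".ent"))
    chains: list[ProteinChain] = []
    for p in paths:
        chains.extend(parse_structure(p))
    return chains


def graphs_from_dataset(dataset: LabeledDataset, embedder,
                        cutoff: float = DEFAULT_CUTOFF
                        ) -> list[ProteinGraph]:
    return [assemble_graph(chain, embedder, cutoff=cutoff, target=y)
            for chain, y in dataset.items]


def dataset_from_tables(chains: list[ProteinChain],
                        intervals: list[AnnotationInterval],
                        min_positives: int = 5,
                        spans: dict[str, tuple[str, int, int]] | None = None,
                        cluster_representatives: set[str] | None = None
                        ) -> LabeledDataset:
    mappings = map_chains(chains, intervals, spans=spans)
    return build_dataset(mappings, min_positives=min_positives,
                         cluster_representatives=cluster_representatives)
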