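"""EC-number annotation handling and dataset assembly.

Enzyme Commission (EC) numbers form a four-level hierarchy
(class.subclass.sub-subclass.sub-sub-subclass).  Annotations arrive as
accession-level sequence intervals carrying EC numbers; chains are mapped
onto those intervals, filtered by overlap, and turned into multi-label
target vectors over a hierarchy-closed label space.  Temporal holdout
and iterative-stratification k-fold splitting are provided for
leakage-free evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import ProteinChain

logger = logging.getLogger(__name__)

#: minimum positives per class retained in the label space by default
DEFAULT_MIN_POSITIVES = 5


@dataclass(frozen=True, order=True)
class ECNumber:
    """A (possibly partial) EC number such as 3.4.11.10 or 3.4.-.-."""
    digits: tuple[int, ...]

    def __post_init__(self):
        if not 1 <= len(self.digits) <= 4:
            raise ValueError("EC number needs 1-4 components")
        if any(d < 1 for d in self.digits):
            raise ValueError("EC components must be >= 1")

    @property
    def level(self) -> int:
        return len(self.digits)

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        # stop at the first placeholder: "3.4.-.-" has level 2
        digits: list[int] = []
        for raw in text.strip().split("."):
            raw = raw.strip()
            if raw in ("", "-") or raw.startswith("n"):
                break
            digits.append(int(raw))
        if not digits:
            raise ValueError(f"cannot parse EC number {text!r}")
        return cls(tuple(digits))

    def ancestor(self, level: int) -> "ECNumber":
        if not 1 <= level <= self.level:
            raise ValueError("invalid ancestor level")
        return ECNumber(self.digits[:level])

    def ancestors(self) -> list["ECNumber"]:
        """All prefixes of this EC number, from level 1 up to self."""
        return [ECNumber(self.digits[:k]) for k in range(1, self.level + 1)]

    def __str__(self) -> str:
        parts = [str(d) for d in self.digits] + ["-"] * (4 - len(self.digits))
        return ".".join(parts)


@dataclass
class AnnotationInterval:
    accession: str
    start: int            # 1-based inclusive on the accession sequence
    end: int
    ec_numbers: list[ECNumber]

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("interval start must not exceed end")
        if not self.ec_numbers:
            raise ValueError("interval carries no EC number")


@dataclass
class ChainMapping:
    chain: ProteinChain
    accession: str
    chain_start: int
    chain_end: int
    length_overlap: int
    fraction_overlap: float
    ec_numbers: list[ECNumber]


def compute_overlap(chain_span: tuple[int, int],
                    interval: AnnotationInterval) -> tuple[int, float]:
    """Overlap between a chain's accession span and an annotation interval.

    Returns ``(length_overlap, fraction_overlap)`` where the fraction is
    relative to the chain span length, so a short chain fully contained
    in an interval scores 1.0.
    """
    cs, ce = chain_span
    if cs > ce:
        raise ValueError("inverted chain span")
    length = max(0, min(ce, interval.end) - max(cs, interval.start) + 1)
    return length, length / (ce - cs + 1)


def apply_inclusion_filter(mapping: ChainMapping) -> tuple[bool, str]:
    """Decide whether a chain/interval mapping enters the dataset.

    A mapping is excluded when the length overlap is below 100 residues
    *and* the fraction overlap is below 0.90 (short chains must be almost
    fully covered).  EC numbers annotated only to the 2nd digit are
    dropped; a mapping left without any EC is excluded.
    """
    if mapping.length_overlap < 100 and mapping.fraction_overlap < 0.90:
        return False, "overlap too small (<100 residues and <90% of chain)"
    deep = [ec for ec in mapping.ec_numbers if ec.level >= 3]
    if not deep:
        return False, "no EC annotated to at least the 3rd digit"
    mapping.ec_numbers = deep
    return True, "kept"


@dataclass
class LabelSpace:
    classes: list[ECNumber]
    min_positives: int = DEFAULT_MIN_POSITIVES
    _index: dict[ECNumber, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate classes in label space")
        self._index = {ec: i for i, ec in enumerate(self.classes)}

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, ec: ECNumber) -> bool:
        return ec in self._index

    def index(self, ec: ECNumber) -> int:
        return self._index[ec]

    def level_mask(self, level: int) -> np.ndarray:
        """Boolean mask over classes at one hierarchy level."""
        return np.array([ec.level == level for ec in self.classes])


def build_label_space(mappings: list[ChainMapping],
                      min_positives: int = DEFAULT_MIN_POSITIVES) -> LabelSpace:
    """Build the hierarchy-closed label space from filtered mappings.

    Each chain's EC numbers are expanded to all ancestors; classes with
    fewer than ``min_positives`` positive chains are dropped together
    with their descendants.  Ordering is lexicographic by digits.
    """
    if not mappings:
        raise ValueError("no mappings supplied")
    counts: dict[ECNumber, int] = {}
    for m in mappings:
        chain_classes = set()
        for ec in m.ec_numbers:
            chain_classes.update(ec.ancestors())
        for ec in chain_classes:
            counts[ec] = counts.get(ec, 0) + 1
    kept = {ec for ec, n in counts.items() if n >= min_positives}
    # descendants of a dropped class are dropped too (ancestor closure)
    kept = {ec for ec in kept
            if all(anc in kept for anc in ec.ancestors()[:-1])}
    return LabelSpace(classes=sorted(kept, key=lambda e: e.digits),
                      min_positives=min_positives)


def make_target_vector(ecs: list[ECNumber], space: LabelSpace) -> np.ndarray:
    """Binary target vector with ancestor closure over the label space."""
    y = np.zeros(len(space), dtype=np.int8)
    for ec in ecs:
        if ec not in space:
            logger.warning("EC %s not in label space; ignored", ec)
        for anc in ec.ancestors():
            if anc in space:
                y[space.index(anc)] = 1
    return y


@dataclass
class LabeledDataset:
    items: list[tuple[ProteinChain, np.ndarray]]
    label_space: LabelSpace

    def __post_init__(self):
        for chain, y in self.items:
            if len(y) != len(self.label_space):
                raise ValueError(f"target length mismatch for {chain.name}")

    def __len__(self) -> int:
        return len(self.items)

    def targets(self) -> np.ndarray:
        return np.stack([y for _, y in self.items])


def build_dataset(mappings: list[ChainMapping],
                  min_positives: int = DEFAULT_MIN_POSITIVES,
                  cluster_representatives: set[str] | None = None
                  ) -> LabeledDataset:
    """Filter mappings, build the label space, and emit target vectors.

    ``cluster_representatives`` optionally lists chain names retained
    after external sequence-identity clustering; other chains are
    dropped before label-space construction.
    """
    kept: list[ChainMapping] = []
    for m in mappings:
        if cluster_representatives is not None \
                and m.chain.name not in cluster_representatives:
            continue
        ok, reason = apply_inclusion_filter(m)
        if ok:
            kept.append(m)
        else:
            logger.info("excluded %s: %s", m.chain.name, reason)
    # merge mappings of the same chain (one per overlapping interval)
    merged: dict[str, ChainMapping] = {}
    for m in kept:
        prev = merged.get(m.chain.name)
        if prev is None:
            merged[m.chain.name] = m
        else:
            prev.ec_numbers = sorted(set(prev.ec_numbers) | set(m.ec_numbers))
    chain_mappings = list(merged.values())
    space = build_label_space(chain_mappings, min_positives=min_positives)
    items = [(m.chain, make_target_vector(m.ec_numbers, space))
             for m in chain_mappings]
    return LabeledDataset(items=items, label_space=space)


def temporal_split(old_annotations: dict[str, set[ECNumber]],
                   new_annotations: dict[str, set[ECNumber]],
                   chains: list[tuple[ProteinChain, str, list[ECNumber]]]
                   ) -> tuple[list, list]:
    """Split chains into train/test by annotation-release novelty.

    ``chains`` holds ``(chain, accession, ec_numbers)``.  ECs present in
    the old snapshot put a chain in the training set; ECs appearing only
    in the new snapshot define the test set, with previously known ECs
    removed from test labels to avoid leakage.
    """
    train, test = [], []
    for chain, accession, ecs in chains:
        old = old_annotations.get(accession)
        new = new_annotations.get(accession)
        if old is None and new is None:
            logger.warning("accession %s absent from both snapshots; skipped",
                           accession)
            continue
        old = old or set()
        new = new or set()
        known = [ec for ec in ecs if ec in old]
        novel = [ec for ec in ecs if ec in new and ec not in old]
        if known:
            train.append((chain, accession, known))
        if novel:
            test.append((chain, accession, novel))
    return train, test


def stratified_kfold(dataset: LabeledDataset, k: int, seed: int
                     ) -> list[np.ndarray]:
    """Iterative stratification of a multi-label dataset into k folds.

    Greedy second-order scheme: labels are processed from rarest to most
    frequent; each remaining item carrying the current label goes to the
    fold with the largest remaining demand for that label, ties broken
    by overall remaining capacity and then by seeded random draw.  For
    every class with at least ``k`` positives the per-fold positive
    counts deviate from the ideal ``total / k`` by at most one.
    """
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more folds than items")
    Y = dataset.targets().astype(bool)
    # randomized restarts: keep the assignment with the least residual
    # imbalance (usually the first attempt is already exact)
    best_fold_of, best_v = None, np.inf
    for attempt in range(8):
        fold_of = _stratify_once(Y, k, np.random.default_rng(seed + attempt))
        v = _violation(Y, fold_of, k)
        if v < best_v:
            best_fold_of, best_v = fold_of, v
        if best_v <= 1e-9:
            break
    return [np.sort(np.flatnonzero(best_fold_of == f)) for f in range(k)]


def _stratify_once(Y: np.ndarray, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    n = Y.shape[0]
    remaining = set(range(n))
    fold_of = np.full(n, -1, dtype=int)
    # desired number of items per fold (overall balance)
    fold_capacity = np.full(k, n / k)
    # desired positives per fold per class
    class_desire = np.tile(Y.sum(axis=0) / k, (k, 1)).T  # (classes, k)

    def assign(i: int, f: int) -> None:
        fold_of[i] = f
        remaining.discard(i)
        fold_capacity[f] -= 1
        class_desire[Y[i], f] -= 1

    while remaining:
        counts = Y[list(remaining)].sum(axis=0)
        active = np.where(counts > 0)[0]
        if active.size == 0:
            # label-free leftovers: spread by capacity
            for i in sorted(remaining):
                f = int(np.argmax(fold_capacity + rng.random(k) * 1e-9))
                assign(i, f)
            break
        label = active[np.argmin(counts[active])]
        items = sorted(i for i in remaining if Y[i, label])
        rng.shuffle(items)
        for i in items:
            desire = class_desire[label]
            best = np.flatnonzero(desire == desire.max())
            if len(best) > 1:
                cap = fold_capacity[best]
                best = best[np.flatnonzero(cap == cap.max())]
            f = int(rng.choice(best))
            assign(i, f)
    _rebalance_folds(Y, fold_of, k)
    return fold_of


def _violation(Y: np.ndarray, fold_of: np.ndarray, k: int) -> float:
    """Total per-class excess beyond one unit from the ideal fold count."""
    totals = Y.sum(axis=0)
    ideal = totals / k
    v = 0.0
    for f in range(k):
        counts = Y[fold_of == f].sum(axis=0)
        v += np.maximum(np.abs(counts - ideal) - 1.0, 0.0).sum()
    return float(v)


def _rebalance_folds(Y: np.ndarray, fold_of: np.ndarray, k: int,
                     max_passes: int = 50) -> None:
    """Greedy repair: move single items between folds while it reduces the
    amount by which any class's per-fold positive count deviates from its
    ideal by more than one."""
    n_classes = Y.shape[1]
    for _ in range(max_passes):
        current = _violation(Y, fold_of, k)
        if current <= 1e-9:
            return
        improved = False
        for j in range(n_classes):
            totals = Y[:, j].sum()
            if totals == 0:
                continue
            ideal = totals / k
            counts = np.array([Y[fold_of == f, j].sum() for f in range(k)])
            hi = int(np.argmax(counts))
            lo = int(np.argmin(counts))
            if counts[hi] - ideal <= 1.0 + 1e-9 \
                    and ideal - counts[lo] <= 1.0 + 1e-9:
                continue
            best_item, best_v = -1, current
            for i in np.flatnonzero((fold_of == hi) & Y[:, j].astype(bool)):
                fold_of[i] = lo
                v = _violation(Y, fold_of, k)
                fold_of[i] = hi
                if v < best_v - 1e-12:
                    best_item, best_v = int(i), v
            if best_item >= 0:
                fold_of[best_item] = lo
                improved = True
        if not improved:
            return


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_interval_table(path: str | Path) -> list[AnnotationInterval]:
    """Read a TSV with columns accession, start, end, ec (';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    intervals = []
    for row in df.itertuples(index=False):
        ecs = [ECNumber.parse(t) for t in str(row.ec).split(";") if t.strip()]
        intervals.append(AnnotationInterval(accession=row.accession,
                                            start=int(row.start),
                                            end=int(row.end),
                                            ec_numbers=ecs))
    return intervals


def write_interval_table(intervals: list[AnnotationInterval],
                         path: str | Path) -> None:
    rows = [{"accession": iv.accession, "start": iv.start, "end": iv.end,
             "ec": ";".join(str(ec) for ec in iv.ec_numbers)}
            for iv in intervals]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_snapshot_table(path: str | Path) -> dict[str, set[ECNumber]]:
    """Read a release snapshot TSV with columns accession, ec."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[ECNumber]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.accession, set()).add(ECNumber.parse(row.ec))
    return out


def write_fold_table(folds: list[np.ndarray], item_ids: list[str],
                     path: str | Path) -> None:
    rows = [{"item_id": item_ids[i], "fold": f}
            for f, idx in enumerate(folds) for i in idx]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
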