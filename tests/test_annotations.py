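import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzgraph.annotations import (AnnotationInterval, ChainMapping, ECNumber,
                                  LabeledDataset, apply_inclusion_filter,
                                  build_label_space, compute_overlap,
                                  make_target_vector, read_interval_table,
                                  read_snapshot_table, stratified_kfold,
                                  temporal_split, write_interval_table)
from enzgraph.structure_io import CoordSource, ProteinChain, ResidueRecord


def ec(text: str) -> ECNumber:
    return ECNumber.parse(text)


def dummy_chain(name="c1", length=5):
    residues = [ResidueRecord(i + 1, "A", np.array([3.8 * i, 0.0, 0.0]),
                              CoordSource.ALPHA_CARBON) for i in range(length)]
    return ProteinChain(structure_id=name, chain_id="A",
                        sequence="A" * length, residues=residues)


def mapping(length_overlap, fraction_overlap, ecs):
    return ChainMapping(chain=dummy_chain(), accession="P1", chain_start=1,
                        chain_end=200, length_overlap=length_overlap,
                        fraction_overlap=fraction_overlap,
                        ec_numbers=[ec(e) for e in ecs])


class TestECNumber:
    def test_parse_and_render(self):
        assert ec("3.4.11.10").digits == (3, 4, 11, 10)
        assert ec("3.4.-.-").level == 2
        assert str(ec("3.4")) == "3.4.-.-"

    def test_ancestors(self):
        assert [str(a) for a in ec("1.2.3.4").ancestors()] == \
            ["1.-.-.-", "1.2.-.-", "1.2.3.-", "1.2.3.4"]

    def test_invalid(self):
        with pytest.raises(ValueError):
            ec("-.-.-.-")


class TestComputeOverlap:
    @pytest.mark.parametrize("span,interval,expected", [
        ((1, 200), (1, 200), (200, 1.0)),
        ((51, 150), (1, 100), (50, 0.5)),
        ((1, 50), (60, 100), (0, 0.0)),
    ])
    def test_examples(self, span, interval, expected):
        iv = AnnotationInterval("P1", interval[0], interval[1],
                                [ec("1.1.1.1")])
        assert compute_overlap(span, iv) == expected

    def test_inverted_span(self):
        iv = AnnotationInterval("P1", 1, 10, [ec("1.1.1.1")])
        with pytest.raises(ValueError):
            compute_overlap((10, 1), iv)


class TestInclusionFilter:
    def test_long_overlap_kept(self):
        kept, _ = apply_inclusion_filter(mapping(120, 0.50, ["1.1.1.1"]))
        assert kept

    def test_short_but_covered_kept(self):
        kept, _ = apply_inclusion_filter(mapping(80, 0.95, ["3.4.11.10"]))
        assert kept

    def test_short_and_uncovered_excluded(self):
        kept, _ = apply_inclusion_filter(mapping(80, 0.50, ["3.4.11.10"]))
        assert not kept

    def test_shallow_ec_only_excluded(self):
        kept, _ = apply_inclusion_filter(mapping(150, 0.99, ["3.4"]))
        assert not kept

    def test_shallow_ec_dropped_deep_kept(self):
        m = mapping(150, 0.99, ["3.4", "3.4.11.10"])
        kept, _ = apply_inclusion_filter(m)
        assert kept
        assert [str(e) for e in m.ec_numbers] == ["3.4.11.10"]

    @given(length=st.integers(0, 300), fraction=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_overlap(self, length, fraction):
        """Increasing either overlap never flips kept -> excluded."""
        base, _ = apply_inclusion_filter(mapping(length, fraction,
                                                 ["1.1.1.1"]))
        grown, _ = apply_inclusion_filter(
            mapping(min(length + 50, 300), min(fraction + 0.2, 1.0),
                    ["1.1.1.1"]))
        assert grown or not base


class TestLabelSpace:
    def test_ancestor_closure(self):
        space = build_label_space([mapping(120, 1.0, ["1.2.3.4"])],
                                  min_positives=1)
        assert [str(c) for c in space.classes] == \
            ["1.-.-.-", "1.2.-.-", "1.2.3.-", "1.2.3.4"]

    def test_min_positives_prunes_branch(self):
        ms = [mapping(120, 1.0, ["1.1.1.1"]),
              mapping(120, 1.0, ["1.1.1.1"]),
              mapping(120, 1.0, ["2.7.11.1"])]
        space = build_label_space(ms, min_positives=2)
        assert [str(c) for c in space.classes] == \
            ["1.-.-.-", "1.1.-.-", "1.1.1.-", "1.1.1.1"]

    def test_min_positives_zero_keeps_all(self):
        ms = [mapping(120, 1.0, ["1.1.1.1"]), mapping(120, 1.0, ["2.7.11.1"])]
        space = build_label_space(ms, min_positives=0)
        assert len(space) == 8

    def test_empty_error(self):
        with pytest.raises(ValueError):
            build_label_space([], min_positives=1)


class TestTargetVector:
    def test_ancestor_closure(self):
        space = build_label_space([mapping(120, 1.0, ["1.2.3.4"])],
                                  min_positives=1)
        y = make_target_vector([ec("1.2.3.4")], space)
        assert y.tolist() == [1, 1, 1, 1]

    def test_unknown_ec_ignored(self):
        space = build_label_space([mapping(120, 1.0, ["1.2.3.4"])],
                                  min_positives=1)
        assert make_target_vector([ec("6.1.1.1")], space).sum() == 0

    def test_shared_ancestor_set_once(self):
        ms = [mapping(120, 1.0, ["1.1.1.1"]), mapping(120, 1.0, ["1.2.3.4"])]
        space = build_label_space(ms, min_positives=1)
        y = make_target_vector([ec("1.1.1.1"), ec("1.2.3.4")], space)
        assert y[space.index(ec("1"))] == 1
        assert y.sum() == 7  # 1 + two disjoint deep branches


class TestTemporalSplit:
    def test_leakage_removed(self):
        old = {"P1": {ec("1.1.1.1")}}
        new = {"P1": {ec("1.1.1.1"), ec("2.7.11.1")}}
        chains = [(dummy_chain(), "P1", [ec("1.1.1.1"), ec("2.7.11.1")])]
        train, test = temporal_split(old, new, chains)
        assert [str(e) for e in test[0][2]] == ["2.7.11.1"]
        assert [str(e) for e in train[0][2]] == ["1.1.1.1"]

    def test_new_accession_goes_to_test(self):
        new = {"P2": {ec("3.2.1.4")}}
        chains = [(dummy_chain(), "P2", [ec("3.2.1.4")])]
        train, test = temporal_split({}, new, chains)
        assert not train and len(test) == 1

    def test_unchanged_accession_train_only(self):
        old = {"P1": {ec("1.1.1.1")}}
        chains = [(dummy_chain(), "P1", [ec("1.1.1.1")])]
        train, test = temporal_split(old, old, chains)
        assert len(train) == 1 and not test

    def test_per_accession_label_disjointness(self):
        old = {"P1": {ec("1.1.1.1")}}
        new = {"P1": {ec("1.1.1.1"), ec("2.7.11.1"), ec("3.2.1.4")}}
        chains = [(dummy_chain(), "P1",
                   [ec("1.1.1.1"), ec("2.7.11.1"), ec("3.2.1.4")])]
        train, test = temporal_split(old, new, chains)
        assert not set(map(str, train[0][2])) & set(map(str, test[0][2]))


def make_dataset(Y: np.ndarray) -> LabeledDataset:
    space = build_label_space(
        [mapping(120, 1.0, [f"{j + 1}.1.1.1"]) for j in range(Y.shape[1])],
        min_positives=0)
    # keep only the level-4 classes to match Y's columns
    deep = [c for c in space.classes if c.level == 4]
    from enzgraph.annotations import LabelSpace
    space = LabelSpace(deep, min_positives=0)
    items = [(dummy_chain(f"c{i}"), Y[i].astype(np.int8))
             for i in range(Y.shape[0])]
    return LabeledDataset(items=items, label_space=space)


class TestStratifiedKFold:
    def test_single_class_divisible(self):
        ds = make_dataset(np.ones((10, 1)))
        folds = stratified_kfold(ds, k=5, seed=0)
        assert all(len(f) == 2 for f in folds)

    def test_partition(self):
        rng = np.random.default_rng(3)
        ds = make_dataset((rng.random((23, 4)) < 0.3).astype(int))
        folds = stratified_kfold(ds, k=4, seed=1)
        merged = np.concatenate(folds)
        assert sorted(merged.tolist()) == list(range(23))

    def test_two_class_balance(self):
        Y = np.zeros((10, 2), dtype=int)
        Y[:6, 0] = 1
        Y[6:, 1] = 1
        ds = make_dataset(Y)
        folds = stratified_kfold(ds, k=2, seed=0)
        for f in folds:
            assert Y[f, 0].sum() == 3
            assert Y[f, 1].sum() == 2

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        ds = make_dataset((rng.random((30, 5)) < 0.25).astype(int))
        a = stratified_kfold(ds, k=5, seed=42)
        b = stratified_kfold(ds, k=5, seed=42)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_k_too_large(self):
        ds = make_dataset(np.ones((3, 1)))
        with pytest.raises(ValueError):
            stratified_kfold(ds, k=5, seed=0)


class TestTables:
    def test_interval_round_trip(self, tmp_path):
        ivs = [AnnotationInterval("P1", 1, 100,
                                  [ec("1.1.1.1"), ec("2.7.11.1")]),
               AnnotationInterval("P2", 5, 60, [ec("3.2.1.4")])]
        path = tmp_path / "iv.tsv"
        write_interval_table(ivs, path)
        back = read_interval_table(path)
        assert [(v.accession, v.start, v.end) for v in back] == \
            [("P1", 1, 100), ("P2", 5, 60)]
        assert [str(e) for e in back[0].ec_numbers] == \
            ["1.1.1.1", "2.7.11.1"]

    def test_snapshot_table(self, tmp_path):
        path = tmp_path / "snap.tsv"
        path.write_text("accession\tec\nP1\t1.1.1.1\nP1\t2.7.11.1\n")
        snap = read_snapshot_table(path)
        assert snap["P1"] == {ec("1.1.1.1"), ec("2.7.11.1")}
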