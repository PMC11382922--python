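"""Sample-table I/O, PU masking, undersampling and vertical partitioning."""

import numpy as np
import pandas as pd
import pytest

from pufedboost.data import (
    DataError,
    ParameterError,
    PartitionError,
    SampleTable,
    WorkingLabels,
    load_feature_table,
    mask_positive_labels,
    undersample_balance,
    vertical_split,
    write_feature_table,
)

from conftest import make_table


def _labeled_table(n_pos, n_neg, seed=0, d=3):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    features = pd.DataFrame(
        rng.standard_normal((n, d)),
        columns=[f"f{i}" for i in range(d)],
        index=[f"R{i}" for i in range(n)],
    )
    y = np.array([1] * n_pos + [0] * n_neg, dtype=np.int8)
    return SampleTable(features=features, s=np.zeros(n, dtype=np.int8), y=y)


class TestSampleTable:
    def test_flag_on_negative_rejected(self):
        features = pd.DataFrame({"f0": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(DataError, match="s=1 but y!=1"):
            SampleTable(features=features, s=np.array([1, 0]), y=np.array([0, 1]))

    def test_duplicate_ids_rejected(self):
        features = pd.DataFrame({"f0": [0.0, 1.0]}, index=["a", "a"])
        with pytest.raises(DataError, match="duplicate sample id"):
            SampleTable(features=features, s=np.zeros(2))

    def test_non_finite_rejected(self):
        features = pd.DataFrame({"f0": [0.0, np.nan]}, index=["a", "b"])
        with pytest.raises(DataError, match="non-finite"):
            SampleTable(features=features, s=np.zeros(2))


class TestCsvRoundTrip:
    def test_small_fixture_shape(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,f1,f2,f3,y\nA,1,2,3,1\nB,4,5,6,0\nC,7,8,9,1\nD,1,1,1,0\n"
        )
        table = load_feature_table(path, label_col="y")
        assert table.features.shape == (4, 3)
        assert table.sample_ids == ["A", "B", "C", "D"]
        assert table.y.tolist() == [1, 0, 1, 0]

    def test_round_trip_is_identity(self, tmp_path):
        table = make_table(n=25, d=4, seed=11)
        path = tmp_path / "rt.csv"
        write_feature_table(table, path)
        back = load_feature_table(path, label_col="y", flag_col="s")
        pd.testing.assert_frame_equal(
            back.features, table.features, check_names=False
        )
        assert np.array_equal(back.s, table.s)
        assert np.array_equal(back.y, table.y)
        assert back.sample_ids == [str(i) for i in table.sample_ids]

    def test_duplicate_id_in_file(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("sample_id,f1\nA,1\nA,2\n")
        with pytest.raises(DataError, match="duplicate sample id"):
            load_feature_table(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,f1,f2\nA,1,2\nB,oops,3\n")
        with pytest.raises(DataError, match=r"'B'.*'f1'"):
            load_feature_table(path)

    def test_missing_named_column(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,f1\nA,1\n")
        with pytest.raises(DataError, match="missing named column"):
            load_feature_table(path, label_col="label")


class TestMasking:
    def test_exact_count_among_positives(self):
        table = _labeled_table(10, 10)
        masked = mask_positive_labels(table, 0.2, seed=5)
        assert masked.s.sum() == 2
        assert np.all(masked.y[masked.s == 1] == 1)

    def test_deterministic(self):
        table = _labeled_table(10, 10)
        a = mask_positive_labels(table, 0.3, seed=9)
        b = mask_positive_labels(table, 0.3, seed=9)
        assert np.array_equal(a.s, b.s)

    def test_corpus_scale_count(self):
        # 20% of the 665 positives left after balancing → 133 labeled positives
        table = _labeled_table(665, 665, d=1)
        masked = mask_positive_labels(table, 0.2, seed=0)
        assert masked.s.sum() == 133

    @pytest.mark.parametrize("seed", range(10))
    def test_never_flags_a_negative(self, seed):
        table = _labeled_table(13, 17, seed=seed)
        masked = mask_positive_labels(table, 0.4, seed=seed)
        assert not np.any((masked.s == 1) & (masked.y == 0))

    def test_fraction_out_of_range(self):
        table = _labeled_table(5, 5)
        with pytest.raises(ParameterError):
            mask_positive_labels(table, 1.2, seed=0)

    def test_no_positives_rejected(self):
        table = _labeled_table(0, 5)
        with pytest.raises(DataError):
            mask_positive_labels(table, 0.2, seed=0)


class TestUndersampling:
    def test_corpus_counts(self):
        table = _labeled_table(665, 2575, d=1)
        balanced = undersample_balance(table, seed=1)
        assert int(balanced.y.sum()) == 665
        assert int((balanced.y == 0).sum()) == 665

    def test_balanced_input_unchanged(self):
        table = _labeled_table(40, 40)
        balanced = undersample_balance(table, seed=1)
        assert balanced.n_samples == 80

    def test_minority_kept_whole(self):
        table = _labeled_table(100, 7)
        balanced = undersample_balance(table, seed=2)
        assert int(balanced.y.sum()) == 7
        neg_ids_in = set(np.asarray(table.sample_ids)[table.y == 0])
        neg_ids_out = set(np.asarray(balanced.sample_ids)[balanced.y == 0])
        assert neg_ids_out == neg_ids_in

    def test_row_order_preserved(self):
        table = _labeled_table(30, 10)
        balanced = undersample_balance(table, seed=3)
        original_order = {sid: i for i, sid in enumerate(table.sample_ids)}
        positions = [original_order[sid] for sid in balanced.sample_ids]
        assert positions == sorted(positions)

    def test_one_class_rejected(self):
        table = _labeled_table(5, 0)
        with pytest.raises(DataError):
            undersample_balance(table, seed=0)


class TestVerticalSplit:
    def test_bookkeeping(self):
        table = make_table(n=10, d=10, seed=0)
        assignment = {f"f{i}": 0 if i < 4 else 1 for i in range(10)}
        part = vertical_split(table, assignment)
        assert part.guest.features.shape[1] == 4
        assert part.hosts[0].features.shape[1] == 6
        assert set(part.guest.features.columns).isdisjoint(part.hosts[0].features.columns)

    def test_unassigned_feature_rejected(self):
        table = make_table(n=5, d=3)
        with pytest.raises(PartitionError, match="unassigned"):
            vertical_split(table, {"f0": 0, "f1": 1})

    def test_unknown_feature_rejected(self):
        table = make_table(n=5, d=2)
        with pytest.raises(PartitionError, match="unknown"):
            vertical_split(table, {"f0": 0, "f1": 1, "ghost": 1})

    def test_empty_guest_warns_not_fails(self):
        table = make_table(n=5, d=2)
        with pytest.warns(UserWarning, match="no features"):
            part = vertical_split(table, {"f0": 1, "f1": 1})
        assert part.guest.features.shape[1] == 0

    def test_reassembly_is_identity(self):
        table = make_table(n=15, d=8, seed=7)
        rng = np.random.default_rng(4)
        assignment = {f: int(p) for f, p in zip(table.feature_names, rng.integers(0, 3, 8))}
        assignment[table.feature_names[0]] = 0
        part = vertical_split(table, assignment)
        rebuilt = part.concat_features()
        assert set(rebuilt.columns) == set(table.feature_names)
        pd.testing.assert_frame_equal(
            rebuilt[table.feature_names], table.features, check_names=False
        )

    def test_host_view_carries_no_labels(self):
        table = make_table(n=5, d=2)
        part = vertical_split(table, {"f0": 0, "f1": 1})
        assert not hasattr(part.hosts[0], "s")
        assert not hasattr(part.hosts[0], "y")


class TestWorkingLabels:
    def test_observed_positive_invariant(self):
        with pytest.raises(DataError, match="observed positives"):
            WorkingLabels(y_tilde=np.array([0, 1]), observed=np.array([True, False]))

    def test_from_flags_treats_unlabeled_as_negative(self):
        wl = WorkingLabels.from_flags(np.array([1, 0, 0, 1]))
        assert wl.y_tilde.tolist() == [1, 0, 0, 1]
        assert wl.observed.tolist() == [True, False, False, True]
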