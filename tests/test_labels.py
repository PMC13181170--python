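"""Binding counts, threshold pruning, mean binarization, sample weights."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tasselect.affinity import AffinityMatrix
from tasselect.labels import (
    BindingCountTable,
    LabelBuildError,
    ThresholdSet,
    binarize_by_column_mean,
    build_training_table,
    compute_sample_weights,
    count_bindings,
    prune_sparse_thresholds,
    split_train_test,
)


def matrix_from(values, smiles=None):
    values = np.asarray(values, dtype=float)
    ligs = [f"L{i}" for i in range(values.shape[0])]
    prots = [f"P{j}" for j in range(values.shape[1])]
    smi = {l: smiles[i] for i, l in enumerate(ligs)} if smiles else {}
    return AffinityMatrix(ligs, prots, values, smi)


class TestCountBindings:
    def test_single_row_enumeration(self):
        m = matrix_from([[6.5, 7.2, 8.6]])
        t = count_bindings(m, ThresholdSet((7.0, 8.5)))
        np.testing.assert_array_equal(t.counts, [[2, 1]])

    def test_all_below_min_threshold(self):
        m = matrix_from(np.full((4, 5), 5.0))
        t = count_bindings(m, ThresholdSet((7.0, 8.0)))
        assert (t.counts == 0).all()

    def test_exceedance_is_strict(self):
        m = matrix_from([[7.0, 7.0001]])
        t = count_bindings(m, ThresholdSet((7.0,)))
        np.testing.assert_array_equal(t.counts, [[1]])

    def test_missing_cells_never_counted(self):
        m = matrix_from([[np.nan, 9.0], [9.0, np.nan]])
        t = count_bindings(m, ThresholdSet((7.0,)))
        np.testing.assert_array_equal(t.counts, [[1], [1]])

    def test_matches_nested_loop_oracle(self, rng):
        vals = rng.uniform(4, 11, size=(20, 10))
        vals[rng.random((20, 10)) < 0.3] = np.nan
        taus = (6.0, 7.0, 8.0, 9.0)
        t = count_bindings(matrix_from(vals), ThresholdSet(taus))
        for i in range(20):
            for k, tau in enumerate(taus):
                expected = sum(
                    1 for j in range(10)
                    if not np.isnan(vals[i, j]) and vals[i, j] > tau
                )
                assert t.counts[i, k] == expected

    def test_counts_non_increasing_in_threshold(self, rng):
        vals = rng.uniform(3, 12, size=(50, 20))
        t = count_bindings(matrix_from(vals))
        assert (np.diff(t.counts, axis=1) <= 0).all()


class TestPruning:
    def _table(self, zero_fracs, n=100):
        counts = np.zeros((n, len(zero_fracs)), dtype=int)
        for j, zf in enumerate(zero_fracs):
            counts[int(round(zf * n)):, j] = 1
        taus = tuple(7.0 + 0.5 * j for j in range(len(zero_fracs)))
        return BindingCountTable([f"L{i}" for i in range(n)], ThresholdSet(taus), counts)

    def test_mostly_zero_column_dropped(self):
        # a column with 98% zeros is below trainable density at cutoff 0.95
        retained, report = prune_sparse_thresholds(self._table([0.10, 0.98]), 0.95)
        assert retained.thresholds == (7.0,)
        assert report.dropped == [(7.5, pytest.approx(0.98))]

    def test_all_zero_column_always_dropped(self):
        for cutoff in (0.2, 0.5, 1.0):
            retained, _ = prune_sparse_thresholds(self._table([0.0, 1.0]), cutoff)
            assert 7.5 not in retained.thresholds

    def test_half_zero_column_retained(self):
        retained, _ = prune_sparse_thresholds(self._table([0.50]), 0.95)
        assert retained.thresholds == (7.0,)

    def test_everything_pruned_is_an_error(self):
        with pytest.raises(LabelBuildError, match="lower the thresholds"):
            prune_sparse_thresholds(self._table([0.99, 1.0]), 0.95)


class TestBinarize:
    def test_mean_rule_by_hand(self):
        counts = np.array([[0], [1], [2], [3], [4]])  # mean 2
        table = BindingCountTable([f"L{i}" for i in range(5)], ThresholdSet((7.0,)), counts)
        labels, means = binarize_by_column_mean(table)
        np.testing.assert_array_equal(labels[:, 0], [1, 1, 1, 0, 0])
        assert means[0] == pytest.approx(2.0)

    def test_tie_at_mean_is_selective(self):
        counts = np.full((6, 1), 3)
        table = BindingCountTable([f"L{i}" for i in range(6)], ThresholdSet((7.0,)), counts)
        labels, _ = binarize_by_column_mean(table)
        assert (labels == 1).all()

    def test_count_above_reference_mean_is_nonselective(self):
        # column engineered to mean 195; the 200-count ligand exceeds it
        counts = np.concatenate([[200], np.full(9, 194), [199]])[:, None]
        table = BindingCountTable(
            [f"L{i}" for i in range(11)], ThresholdSet((7.0,)), counts
        )
        labels, means = binarize_by_column_mean(table)
        assert means[0] == pytest.approx(195.0)
        assert labels[0, 0] == 0


class TestSampleWeights:
    def test_balanced_column_gives_unit_weights(self):
        labels = np.array([0, 1, 0, 1, 0, 1])[:, None]
        np.testing.assert_allclose(compute_sample_weights(labels), 1.0)

    def test_inverse_frequency_closed_form(self):
        # label-0 frequency 0.25 -> weight 2 for the 0s, 2/3 for the 1s
        labels = np.array([0, 1, 1, 1])[:, None]
        w = compute_sample_weights(labels)
        np.testing.assert_allclose(w, [2.0, 2 / 3, 2 / 3, 2 / 3])

    def test_single_class_column_warns_and_is_neutral(self):
        labels = np.column_stack([np.ones(8, dtype=int), np.arange(8) % 2])
        with pytest.warns(UserWarning, match="single-class"):
            w = compute_sample_weights(labels)
        np.testing.assert_allclose(w, 1.0)  # informative column is balanced

    def test_empty_labels_error(self):
        with pytest.raises(LabelBuildError):
            compute_sample_weights(np.empty((0, 2)))

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 1), min_size=3, max_size=3),
            min_size=4,
            max_size=60,
        )
    )
    def test_mean_is_one_and_weights_positive(self, rows):
        labels = np.array(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # single-class columns
            w = compute_sample_weights(labels)
        assert w.mean() == pytest.approx(1.0, abs=1e-9)
        assert (w > 0).all()
        assert np.isfinite(w.max() / w.min())


class TestBuildTrainingTable:
    def test_matches_stepwise_oracle_chain(self, rng):
        vals = rng.uniform(4, 11, size=(50, 20))
        smiles = ["C" * (i % 5 + 1) for i in range(50)]
        m = matrix_from(vals, smiles)
        out = build_training_table(m)
        # independent step-by-step recomputation
        t = count_bindings(m)
        retained, _ = prune_sparse_thresholds(t)
        labels, means = binarize_by_column_mean(t, retained)
        weights = compute_sample_weights(labels)
        assert out.retained_thresholds.thresholds == retained.thresholds
        np.testing.assert_array_equal(out.labels, labels)
        np.testing.assert_allclose(out.weights, weights)
        np.testing.assert_allclose(out.column_means, means)
        assert out.smiles == smiles

    def test_universal_binder_labeled_nonselective(self):
        vals = np.full((20, 10), 5.0)
        vals[0, :] = 11.0  # one ligand above every threshold everywhere
        out = build_training_table(matrix_from(vals), zero_fraction_cutoff=1.0)
        assert (out.labels[0] == 0).all()
        assert (out.labels[1:] == 1).all()

    def test_affinity_shift_drives_counts_to_saturation(self, rng):
        vals = rng.uniform(4, 6, size=(30, 8))
        m_hi = matrix_from(vals + 10)  # everything above max threshold
        t = count_bindings(m_hi)
        assert (t.counts == 8).all()

    def test_save_writes_table_and_sidecar(self, tmp_path, rng):
        vals = rng.uniform(4, 11, size=(20, 10))
        out = build_training_table(matrix_from(vals, ["CC"] * 20))
        out.save(tmp_path / "train.csv")
        df = pd.read_csv(tmp_path / "train.csv", index_col=0)
        assert "smiles" in df.columns and "weight" in df.columns
        assert (tmp_path / "train.json").exists()


class TestSplit:
    def _frame(self, n):
        return pd.DataFrame({"smiles": ["C"] * n}, index=[f"L{i}" for i in range(n)])

    def test_sizes_and_reproducibility(self):
        df = self._frame(100)
        tr1, te1 = split_train_test(df, 0.05, seed=3)
        tr2, te2 = split_train_test(df, 0.05, seed=3)
        assert len(te1) == 5 and len(tr1) == 95
        assert list(te1.index) == list(te2.index)

    def test_partition_is_disjoint_and_complete(self):
        df = self._frame(57)
        tr, te = split_train_test(df, 0.2, seed=0)
        assert set(tr.index) | set(te.index) == set(df.index)
        assert not (set(tr.index) & set(te.index))

    def test_different_seeds_differ(self):
        df = self._frame(200)
        _, te1 = split_train_test(df, 0.1, seed=1)
        _, te2 = split_train_test(df, 0.1, seed=2)
        assert len(te1) == len(te2)
        assert set(te1.index) != set(te2.index)

    def test_too_small_table_errors(self):
        with pytest.raises(LabelBuildError):
            split_train_test(self._frame(3), 0.05, seed=0)
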