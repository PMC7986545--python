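"""Descriptor extraction and cost-weighted LDA classification."""

import numpy as np
import pandas as pd
import pytest

import noisecat as nc
from noisecat import synth
from noisecat.prediction import (ALL_COLUMNS, combination_groups,
                                 combination_id, impute_table)

from conftest import flat_recording


def synthetic_descriptor_table(n_per_class=40, sep=3.0, seed=0,
                               informative_groups=None):
    """Gaussian descriptor clusters with class-dependent means.

    Only columns of ``informative_groups`` (default: all) carry class
    information; the rest are pure noise.
    """
    rng = np.random.default_rng(seed)
    if informative_groups is None:
        informative_groups = list(nc.DESCRIPTOR_GROUPS)
    info_cols = {c for g in informative_groups
                 for c in nc.DESCRIPTOR_GROUPS[g]}
    rows, labels, index = [], [], []
    means = {cat: rng.normal(scale=sep, size=12)
             for cat in nc.CATEGORIES}
    for cat in nc.CATEGORIES:
        for i in range(n_per_class):
            mu = np.array([means[cat][j] if col in info_cols else 0.0
                           for j, col in enumerate(ALL_COLUMNS)])
            rows.append(mu + rng.normal(size=12))
            labels.append(cat)
            index.append(f"{cat}_{i}")
    table = pd.DataFrame(rows, columns=list(ALL_COLUMNS), index=index)
    return table, pd.Series(labels, index=index)


class TestDescriptors:
    def test_flat_masker_response_has_unit_adaptation_ratio(self, protocol):
        rec = flat_recording(protocol, rate_hz=20.0, seed=1)
        d = nc.extract_descriptors(
            rec, "stationary", protocol,
            tfrp=nc.TFRPResult(np.zeros((100, 129)), 1000.0, 0.0, False,
                               0.0, 0.0, 0.0, 0.0))
        # FRm300/FRm200 ~ 1 for a homogeneous response; 20 trials, ~0.2-s windows
        se = np.sqrt(2 * 20.0 / (0.2 * 20)) / 20.0
        assert abs(d["masker_frm_ratio"] - 1.0) < 4 * se

    def test_adapting_masker_response_detected(self, protocol):
        arch = nc.CategoryArchetype("signal-like", (1.0,) * 3, (0.0,) * 3,
                                    masker_adaptation=0.7,
                                    response_gain_hz=60.0, trial_gain_cv=0.0)
        rec = synth.make_recording("r", "CNIC",
                                   {nt: arch for nt in protocol.noise_types},
                                   protocol, np.random.default_rng(4), False)
        d = nc.extract_descriptors(
            rec, "stationary", protocol,
            tfrp=nc.TFRPResult(np.zeros((100, 129)), 1000.0, 0.0, False,
                               0.0, 0.0, 0.0, 0.0))
        assert d["masker_frm_ratio"] < 1.0
        assert d["masker_final_50ms_spikes"] < d["masker_initial_50ms_spikes"]

    def test_silent_recording_flagged(self, protocol):
        arch = nc.CategoryArchetype("insensitive", (0.5,) * 3, (0.5,) * 3,
                                    baseline_rate_hz=0.0, response_gain_hz=0.0)
        rec = synth.make_recording("r", "CN",
                                   {nt: arch for nt in protocol.noise_types},
                                   protocol, np.random.default_rng(5), False)
        d = nc.extract_descriptors(
            rec, "chorus", protocol,
            tfrp=nc.TFRPResult(np.zeros((100, 129)), 1000.0, 0.0, False,
                               0.0, 0.0, 0.0, 0.0))
        assert d["signal_rate_hz"] == 0.0 and d["masker_rate_hz"] == 0.0
        assert np.isnan(d["masker_frm_ratio"])
        assert np.isnan(d["sig_over_frm200"])

    def test_descriptor_vector_has_twelve_entries(self, small_dataset):
        protocol = small_dataset.protocol
        rec = small_dataset.recordings[0]
        d = nc.extract_descriptors(rec, "stationary", protocol)
        assert len(d) == 12
        assert set(d) == set(ALL_COLUMNS)

    def test_impute_table_median_fill_and_exclusion(self):
        table = pd.DataFrame(np.ones((6, 12)), columns=list(ALL_COLUMNS),
                             index=[f"r{i}" for i in range(6)])
        table.iloc[0, 0] = np.nan
        table.iloc[1, :5] = np.nan  # too many holes
        fixed, excluded = impute_table(table)
        assert excluded == ["r1"]
        assert fixed.loc["r0", ALL_COLUMNS[0]] == 1.0


class TestCombinationSweep:
    def test_ids_enumerate_all_subsets_once(self):
        from itertools import combinations
        groups = list(nc.DESCRIPTOR_GROUPS)
        ids = [combination_id(c) for r in range(1, 5)
               for c in combinations(groups, r)]
        assert sorted(ids) == list(range(1, 16))

    def test_reference_id_layout(self):
        assert combination_id(nc.DESCRIPTOR_GROUPS) == 1
        assert combination_id(["tfrp"]) == 8
        assert combination_id(["signal"]) == 12
        assert combination_id(["masker"]) == 14
        assert combination_id(["signal_to_masker"]) == 15
        assert combination_id(["signal", "masker", "signal_to_masker"]) == 9
        for cid in range(1, 16):
            assert combination_id(combination_groups(cid)) == cid


class TestLDA:
    def test_separable_clusters_classified_nearly_perfectly(self):
        table, labels = synthetic_descriptor_table(sep=4.0, seed=1)
        rep = nc.train_eval_lda(table, labels, seed=0)
        assert rep.cv_accuracy_percent >= 95.0

    def test_shuffled_labels_fall_to_chance(self):
        table, labels = synthetic_descriptor_table(sep=4.0, seed=2)
        rng = np.random.default_rng(3)
        accs = [nc.train_eval_lda(
            table, pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index), seed=s).cv_accuracy_percent
            for s in range(10)]
        assert 10.0 < np.mean(accs) < 30.0

    def test_fold_determinism(self):
        table, labels = synthetic_descriptor_table(sep=2.0, seed=4)
        r1 = nc.train_eval_lda(table, labels, seed=11)
        r2 = nc.train_eval_lda(table, labels, seed=11)
        assert r1.cv_accuracy_percent == r2.cv_accuracy_percent
        pd.testing.assert_frame_equal(r1.confusion_percent, r2.confusion_percent)

    def test_cost_matrix_discourages_insensitive_predictions(self):
        """With the doubled cost, fewer samples may be called insensitive."""
        table, labels = synthetic_descriptor_table(sep=0.7, seed=5)
        flat = nc.default_cost_matrix()
        flat.loc[:, :] = 1.0
        np.fill_diagonal(flat.values, 0.0)
        base = nc.train_eval_lda(table, labels, cost_matrix=flat, seed=0)
        weighted = nc.train_eval_lda(table, labels, seed=0)

        def n_insensitive_predicted(rep):
            col = rep.confusion_percent["insensitive"]
            row_n = rep.n_test / 5
            return (col / 100 * row_n).sum()

        assert n_insensitive_predicted(weighted) <= n_insensitive_predicted(base)

    def test_uninformative_group_ablation_drops_to_chance(self):
        table, labels = synthetic_descriptor_table(
            sep=4.0, seed=6, informative_groups=["signal"])
        signal_only = nc.train_eval_lda(table, labels, ["signal"], seed=0)
        tfrp_only = nc.train_eval_lda(table, labels, ["tfrp"], seed=0)
        assert signal_only.cv_accuracy_percent >= \
            tfrp_only.cv_accuracy_percent + 20.0
        assert tfrp_only.cv_accuracy_percent < 35.0

    def test_confusion_rows_sum_to_100(self):
        table, labels = synthetic_descriptor_table(sep=1.0, seed=7)
        rep = nc.train_eval_lda(table, labels, seed=0)
        np.testing.assert_allclose(rep.confusion_percent.sum(axis=1), 100.0)

    def test_too_few_samples_per_class_rejected(self):
        table, labels = synthetic_descriptor_table(n_per_class=3, seed=8)
        with pytest.raises(ValueError):
            nc.train_eval_lda(table, labels, n_folds=5)


class TestComboSweepAndGeneralize:
    def test_sweep_returns_all_fifteen_reports(self):
        table, labels = synthetic_descriptor_table(n_per_class=25, sep=2.0,
                                                   seed=9)
        reports = nc.combo_sweep(table, labels, seed=0)
        assert sorted(reports) == list(range(1, 16))
        assert all(0.0 <= r.cv_accuracy_percent <= 100.0
                   for r in reports.values())

    def test_generalization_close_to_cv_on_iid_split(self):
        table, labels = synthetic_descriptor_table(n_per_class=60, sep=3.0,
                                                   seed=10)
        train_idx = table.index[::2]
        test_idx = table.index[1::2]
        cv = nc.train_eval_lda(table.loc[train_idx], labels.loc[train_idx],
                               seed=0)
        gen = nc.generalize(table.loc[train_idx], labels.loc[train_idx],
                            table.loc[test_idx], labels.loc[test_idx])
        assert abs(gen.cv_accuracy_percent - cv.cv_accuracy_percent) <= 10.0

    def test_overlapping_and_empty_test_sets_rejected(self):
        table, labels = synthetic_descriptor_table(n_per_class=10, seed=11)
        with pytest.raises(ValueError, match="overlap"):
            nc.generalize(table, labels, table.iloc[:5], labels.iloc[:5])
        with pytest.raises(ValueError, match="empty"):
            nc.generalize(table, labels, table.iloc[:0], labels.iloc[:0])
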