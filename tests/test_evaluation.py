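"""Metrics, stratified split, and the two experiment drivers."""

import numpy as np
import pandas as pd
import pytest

from xplatclass import (
    RunConfig,
    SimulationConfig,
    SUBTYPES,
    TransformSpec,
    accuracy,
    confusion,
    generate_paired_dataset,
    per_class_sn_sp,
    run_cross_platform,
    run_same_platform,
    stratified_split,
)
from xplatclass.exceptions import SizeError, SplitError


class TestAccuracy:
    def test_69_of_76_prints_one_decimal(self):
        y_true = np.array(["PN"] * 76)
        y_pred = np.array(["PN"] * 69 + ["N"] * 7)
        assert accuracy(y_true, y_pred) == 90.8

    def test_identical_and_disjoint_vectors(self):
        y = np.array(["PN", "N", "CL", "M"])
        assert accuracy(y, y) == 100.0
        assert accuracy(y, np.array(["N", "CL", "M", "PN"])) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(SizeError):
            accuracy(["PN"], ["PN", "N"])

    def test_equals_confusion_trace_over_total(self, rng):
        for _ in range(20):
            y = rng.choice(SUBTYPES, size=60)
            p = rng.choice(SUBTYPES, size=60)
            cm = confusion(y, p)
            assert accuracy(y, p) == round(
                100.0 * np.trace(cm.to_numpy()) / cm.to_numpy().sum(), 1
            )


class TestSnSp:
    def test_perfect_prediction_gives_ones(self):
        y = np.repeat(list(SUBTYPES), 5)
        table = per_class_sn_sp(y, y)
        assert (table["Sn"] == 1.0).all()
        assert (table["Sp"] == 1.0).all()

    def test_constant_prediction(self):
        y = np.repeat(list(SUBTYPES), 5)
        p = np.array(["PN"] * 20)
        table = per_class_sn_sp(y, p)
        assert table.loc["PN", "Sn"] == 1.0
        assert table.loc["PN", "Sp"] == 0.0

    def test_hand_computed_confusion_matrix(self):
        # true 10 per class, diagonal (8, 9, 7, 10); errors all into PN
        y = np.repeat(list(SUBTYPES), 10)
        p = y.copy()
        p[8:10] = "N"  # 2 PN -> N
        p[10 + 9 :20] = "PN"  # 1 N -> PN
        p[20 + 7 :30] = "PN"  # 3 CL -> PN
        table = per_class_sn_sp(y, p)
        assert table.loc["PN", "Sn"] == pytest.approx(8 / 10)
        assert table.loc["PN", "Sp"] == pytest.approx((30 - 4) / 30)
        assert table.loc["N", "Sn"] == pytest.approx(9 / 10)
        assert table.loc["N", "Sp"] == pytest.approx((30 - 2) / 30)
        assert table.loc["CL", "Sn"] == pytest.approx(7 / 10)
        assert table.loc["M", "Sn"] == pytest.approx(1.0)

    def test_absent_class_reported_missing_not_zero(self):
        y = np.array(["PN", "PN", "N", "N"])
        p = np.array(["PN", "N", "N", "CL"])
        table = per_class_sn_sp(y, p, classes=["PN", "N", "CL"])
        assert np.isnan(table.loc["CL", "Sn"])
        assert not np.isnan(table.loc["CL", "Sp"])

    def test_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            y = rng.choice(SUBTYPES, size=40)
            p = rng.choice(SUBTYPES, size=40)
            table = per_class_sn_sp(y, p)
            for cls in set(y):
                tp = int(((y == cls) & (p == cls)).sum())
                fn = int(((y == cls) & (p != cls)).sum())
                tn = int(((y != cls) & (p != cls)).sum())
                fp = int(((y != cls) & (p == cls)).sum())
                assert table.loc[cls, "Sn"] == pytest.approx(tp / (tp + fn))
                assert table.loc[cls, "Sp"] == pytest.approx(tn / (tn + fp))


class TestStratifiedSplit:
    def _labels(self, counts):
        ids, values = [], []
        for cls, n in zip(SUBTYPES, counts):
            ids.extend(f"{cls}{i}" for i in range(n))
            values.extend([cls] * n)
        return pd.Series(values, index=ids)

    def test_342_samples_at_three_quarters_split_257_85(self):
        labels = self._labels((90, 88, 84, 80))
        train, test = stratified_split(labels, 0.75, seed=0)
        assert (len(train), len(test)) == (257, 85)

    def test_partition_contract(self):
        labels = self._labels((11, 9, 8, 12))
        train, test = stratified_split(labels, 0.6, seed=3)
        assert set(train) | set(test) == set(labels.index)
        assert set(train) & set(test) == set()

    def test_per_class_training_counts_use_ceiling(self):
        labels = self._labels((10, 10, 10, 10))
        train, _ = stratified_split(labels, 0.66, seed=1)
        counts = pd.Series([t[:2] if t[:2] in ("PN", "CL") else t[0] for t in train])
        by_class = pd.Series(train).str.extract(r"^([A-Z]+)")[0].value_counts()
        assert (by_class == int(np.ceil(0.66 * 10))).all()

    def test_singleton_class_rejected(self):
        labels = self._labels((1, 1, 1, 1))
        with pytest.raises(SplitError):
            stratified_split(labels, 0.75, seed=0)

    def test_deterministic_per_seed(self):
        labels = self._labels((8, 8, 8, 8))
        assert stratified_split(labels, 0.75, 5) == stratified_split(labels, 0.75, 5)
        assert stratified_split(labels, 0.75, 5) != stratified_split(labels, 0.75, 6)


class TestDrivers:
    def test_zero_noise_large_effect_every_cell_perfect(self):
        cfg_sim = SimulationConfig(
            n_features=60, n_informative_per_class=4, n_tumor_per_class=10,
            n_test_per_class=4, effect_size=4.0, sigma_bio=0.0,
            sigma_platform=0.0, seed=4,
        ).validate()
        ds = generate_paired_dataset(cfg_sim)
        cfg = RunConfig(
            representations=("fc", "equal_freq"), selectors=("cv",),
            classifiers=("svm", "rf", "nb", "pam"), n_bins=4, seed=6,
            feature_grid=(16, 60), n_trees=100, snsp_top_n=None,
            prefilter_top_k=None,
        )
        report = run_cross_platform(
            ds.tumor_a, ds.normals_a, ds.tumor_b, ds.normals_b, ds.labels, cfg,
            train_ids=ds.train_ids, test_ids=ds.test_ids,
        )
        assert all(cell.accuracy == 100.0 for cell in report.cells)

    def test_degenerate_platforms_cross_equals_same(self):
        """Identity transforms and zero platform noise: the cross-platform
        report must equal the same-platform report on the matched split."""
        cfg_sim = SimulationConfig(
            n_features=80, n_informative_per_class=4, n_tumor_per_class=12,
            n_test_per_class=4, sigma_platform=0.0,
            transform_a=TransformSpec.identity(),
            transform_b=TransformSpec.identity(), seed=3,
        ).validate()
        ds = generate_paired_dataset(cfg_sim)
        cfg = RunConfig(
            representations=("fc", "equal_freq"), selectors=("cv",),
            classifiers=("svm", "nb"), n_bins=4, seed=5,
            feature_grid=(5, 20, 80), snsp_top_n=None, prefilter_top_k=None,
        )
        train_ids, test_ids = stratified_split(ds.labels, cfg.train_fraction, cfg.seed)
        same = run_same_platform(ds.tumor_a, ds.normals_a, ds.labels, cfg)
        cross = run_cross_platform(
            ds.tumor_a, ds.normals_a, ds.tumor_b, ds.normals_b, ds.labels, cfg,
            train_ids=train_ids, test_ids=test_ids,
        )
        assert same == cross

    def test_monotone_noiseless_equal_freq_transfer_matches_within_platform(self):
        """Strictly monotone platform map, zero technical noise: Equal-F bins
        of platform B equal those of A exactly, so transfer accuracy equals
        the within-platform accuracy."""
        from xplatclass import discretize_matrix, fold_change

        cfg_sim = SimulationConfig(
            n_features=80, n_informative_per_class=4, n_tumor_per_class=12,
            n_test_per_class=4, sigma_platform=0.0, seed=13,
        ).validate()
        ds = generate_paired_dataset(cfg_sim)
        fc_a = fold_change(ds.tumor_a[ds.test_ids], ds.normals_a)
        fc_b = fold_change(ds.tumor_b[ds.test_ids], ds.normals_b)
        bins_a, _ = discretize_matrix(fc_a, "equal_freq", 6)
        bins_b, _ = discretize_matrix(fc_b, "equal_freq", 6)
        assert bins_a.equals(bins_b)

    def test_report_deterministic_given_config_and_seed(self, small_scenario):
        ds = small_scenario
        cfg = RunConfig(
            representations=("equal_freq",), selectors=("cv",),
            classifiers=("svm",), n_bins=5, seed=2, feature_grid=(10, 40),
            snsp_top_n=None, prefilter_top_k=None,
        )
        r1 = run_cross_platform(
            ds.tumor_a, ds.normals_a, ds.tumor_b, ds.normals_b, ds.labels, cfg,
            train_ids=ds.train_ids, test_ids=ds.test_ids,
        )
        r2 = run_cross_platform(
            ds.tumor_a, ds.normals_a, ds.tumor_b, ds.normals_b, ds.labels, cfg,
            train_ids=ds.train_ids, test_ids=ds.test_ids,
        )
        assert r1 == r2

    def test_snsp_recorded_at_configured_feature_count(self, small_scenario):
        ds = small_scenario
        cfg = RunConfig(
            representations=("equal_freq",), selectors=("cv",),
            classifiers=("svm",), n_bins=5, seed=2, feature_grid=(10, 40),
            snsp_top_n=40, prefilter_top_k=None,
        )
        report = run_cross_platform(
            ds.tumor_a, ds.normals_a, ds.tumor_b, ds.normals_b, ds.labels, cfg,
            train_ids=ds.train_ids, test_ids=ds.test_ids,
        )
        with_snsp = [c for c in report.cells if c.snsp is not None]
        assert len(with_snsp) == 1
        assert with_snsp[0].n_features == 40
        assert set(with_snsp[0].snsp) == set(SUBTYPES)
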