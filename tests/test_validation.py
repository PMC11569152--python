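"""Confusion matrix, accuracies, multi-resolution agreement, null model."""

import numpy as np
import pandas as pd
import pytest

from deltaclue.datasets import CONFUSION_2018
from deltaclue.suitability import UndefinedMetricError
from deltaclue.validation import (
    ConfusionMatrix,
    class_accuracies,
    confusion_matrix,
    multiresolution_accuracy,
    null_model_report,
    overall_accuracy,
    round1,
)

from conftest import raster_from


class TestConfusionMatrix:
    def test_hand_counted_toy(self, spec2):
        pred = raster_from(spec2, [[0, 0], [1, 1]])
        ref = raster_from(spec2, [[0, 1], [1, 1]])
        cm = confusion_matrix(pred, ref)
        assert cm.counts.loc[0, 0] == 1
        assert cm.counts.loc[0, 1] == 1
        assert cm.counts.loc[1, 1] == 2
        assert cm.counts.loc[1, 0] == 0

    def test_identical_maps_are_diagonal(self, world):
        cm = confusion_matrix(world.landuse0, world.landuse0)
        off = cm.counts.values[~np.eye(len(cm.class_codes), dtype=bool)]
        assert (off == 0).all()
        assert cm.grand_total == int(world.landuse0.data_mask.sum())

    def test_empty_mask_gives_zero_matrix(self, toy_maps):
        pred, ref = toy_maps
        cm = confusion_matrix(pred, ref, mask=np.zeros((2, 2), bool),
                              class_codes=[0, 1])
        assert cm.grand_total == 0

    def test_unknown_class_rejected(self, toy_maps):
        pred, ref = toy_maps
        with pytest.raises(ValueError, match=r"\[1\]"):
            confusion_matrix(pred, ref, class_codes=[0])

    def test_margins_sum_to_active_cells(self, world):
        shifted = raster_from(world.spec, np.roll(world.landuse0.values, 1, axis=1))
        cm = confusion_matrix(shifted, world.landuse0)
        assert cm.counts.sum(axis=1).sum() == cm.counts.sum(axis=0).sum() == cm.grand_total


class TestOverallAccuracy:
    def test_published_validation_matrix(self):
        assert overall_accuracy(ConfusionMatrix(CONFUSION_2018)) == 87.6

    def test_identity_prediction(self, world):
        assert overall_accuracy(confusion_matrix(world.landuse0, world.landuse0)) == 100.0

    def test_toy_three_of_four(self, toy_maps):
        assert overall_accuracy(confusion_matrix(*toy_maps)) == 75.0

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(pd.DataFrame(np.zeros((2, 2), int), index=[0, 1], columns=[0, 1]))
        with pytest.raises(UndefinedMetricError):
            overall_accuracy(cm)

    def test_invariant_under_relabeling(self, world):
        shifted = raster_from(world.spec, np.roll(world.landuse0.values, 1, axis=0))
        base = overall_accuracy(confusion_matrix(shifted, world.landuse0))
        relabel = lambda r: raster_from(r.spec, np.where(r.data_mask, r.values + 7, r.values))
        swapped = overall_accuracy(
            confusion_matrix(relabel(shifted), relabel(world.landuse0))
        )
        assert base == swapped


class TestClassAccuracies:
    def test_published_clean_cells(self):
        acc = class_accuracies(ConfusionMatrix(CONFUSION_2018))
        assert acc.loc["pasture", "users_pct"] == 89.6
        assert acc.loc["pasture", "producers_pct"] == 89.6
        assert acc.loc["crops", "users_pct"] == 91.5
        assert acc.loc["crops", "producers_pct"] == 91.6
        assert acc.loc["non_forest_nature", "users_pct"] == 78.5
        assert acc.loc["non_forest_nature", "producers_pct"] == 78.4

    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(pd.DataFrame(np.diag([5, 9]), index=[0, 1], columns=[0, 1]))
        acc = class_accuracies(cm)
        assert (acc["users_pct"] == 100.0).all() and (acc["producers_pct"] == 100.0).all()

    def test_equal_margins_make_users_equal_producers(self):
        counts = pd.DataFrame([[8, 2], [2, 8]], index=[0, 1], columns=[0, 1])
        acc = class_accuracies(ConfusionMatrix(counts))
        pd.testing.assert_series_equal(
            acc["users_pct"], acc["producers_pct"], check_names=False
        )

    def test_absent_class_undefined(self):
        counts = pd.DataFrame([[4, 1], [0, 0]], index=[0, 1], columns=[0, 1])
        acc = class_accuracies(ConfusionMatrix(counts))
        assert np.isnan(acc.loc[1, "users_pct"])

    def test_rounding_half_away_from_zero(self):
        assert round1(74.75) == 74.8
        assert round1(89.55) == 89.6


class TestMultiresolution:
    def test_factor_one_equals_overall(self, world):
        shifted = raster_from(world.spec, np.roll(world.landuse0.values, 1, axis=1))
        table = multiresolution_accuracy(shifted, world.landuse0, [1])
        assert table.loc[0, "overall_accuracy_pct"] == overall_accuracy(
            confusion_matrix(shifted, world.landuse0)
        )

    def test_identical_maps_perfect_at_every_factor(self, world):
        table = multiresolution_accuracy(world.landuse0, world.landuse0, [1, 2, 5, 10])
        assert (table["overall_accuracy_pct"] == 100.0).all()

    def test_near_miss_recovered_at_coarse_resolution(self):
        # wide stripes shifted by one cell: wrong at fine scale near every
        # boundary, right once aggregated beyond the shift distance
        from deltaclue.grid import GridSpec

        spec = GridSpec(40, 40)
        stripes = np.repeat(np.arange(4).repeat(10)[None, :], 40, axis=0) % 2
        ref = raster_from(spec, stripes)
        pred = raster_from(spec, np.roll(stripes, 1, axis=1))
        table = multiresolution_accuracy(pred, ref, [1, 10])
        fine = table.loc[0, "overall_accuracy_pct"]
        coarse = table.loc[1, "overall_accuracy_pct"]
        assert coarse > fine

    def test_factor_beyond_grid_rejected(self, toy_maps):
        with pytest.raises(ValueError):
            multiresolution_accuracy(*toy_maps, factors=[5])


class TestNullModel:
    def test_baseline_equal_reference_is_perfect(self, world):
        rep = null_model_report(world.landuse0, world.landuse0)
        assert rep["label"] == "null" and rep["overall_accuracy_pct"] == 100.0

    def test_missing_class_has_zero_producers_accuracy(self, spec2):
        baseline = raster_from(spec2, [[0, 0], [0, 0]])
        ref = raster_from(spec2, [[0, 0], [0, 1]])
        rep = null_model_report(baseline, ref)
        assert rep["class_accuracies"].loc[1, "producers_pct"] == 0.0

    def test_shrinking_class_null_underperforms_model(self, world):
        """With heavy net change the frozen baseline misses the shrunk class."""
        from deltaclue.history import count_transitions
        from deltaclue.synth import gen_history

        codes = world.landuse0.class_codes()
        rates = pd.DataFrame(np.eye(5), index=codes, columns=codes)
        rates.loc[0, 0] = 0.3
        rates.loc[0, 1] = 0.7  # class 0 drains into class 1
        future = gen_history(world.landuse0, rates, 3, seed=5)[-1]
        null = null_model_report(world.landuse0, future)
        # producer's accuracy for the growing class collapses under the null
        assert null["class_accuracies"].loc[1, "producers_pct"] < 60.0
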