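"""Calibration, subtractive assignment, tuning, summaries, agreement."""

import numpy as np
import pytest
from sklearn.base import clone

from nucleomorph import (
    CascadeClassifier,
    assign_phenotype,
    calibrate,
    compare_manual_vs_auto,
    default_config,
    summarize,
    tune_multiplier,
)
from nucleomorph.cascade import (
    GROUP_OF_PHENOTYPE,
    PHENOTYPES,
    CascadeConfig,
    CascadeStep,
    PhenotypeCall,
    calibration_from_dict,
    calibration_to_dict,
)


def cell(n_objects=1.0, moment3=0.009, flatness=1.7, **extra):
    """A minimal measurement record (mapping-style) for cascade tests."""
    base = {
        "n_objects": n_objects,
        "moment1": 0.1,
        "moment2": 0.01,
        "moment3": moment3,
        "moment4": 0.0,
        "moment5": 0.0,
        "flatness": flatness,
        "elongation": 1.2,
    }
    base.update(extra)
    return base


#: A control population whose features sit in the normal bands: nothing
#: crosses any default-step threshold, so running means stay full-set means.
def quiet_control(n=10):
    return [cell() for _ in range(n)]


class TestCalibrate:
    def test_punctate_threshold_from_printed_rule(self):
        # control object counts [1]*5 + [2]*5 -> mean 1.5; 3.3 x 1.5 = 4.95
        control = [cell(n_objects=v) for v in [1] * 5 + [2] * 5]
        cal = calibrate(control, default_config())
        assert cal.thresholds[0] == pytest.approx(4.95)
        assert cal.control_sizes[0] == 10

    def test_no_crossing_means_full_set_running_means(self):
        control = quiet_control(8)
        cal = calibrate(control, default_config())
        assert cal.control_sizes == (8, 8, 8, 8)
        assert cal.control_means[0] == pytest.approx(1.0)
        assert cal.control_means[1] == pytest.approx(0.009)

    def test_hand_computed_running_means_with_removal(self):
        # step 1 (k=2.0, high, n_objects): mean over all 4 = (1+1+1+9)/4 = 3,
        # thr 6 -> removes the 9; step 2 (k=0.5, low, moment3): mean over the
        # remaining 3 = (0.01+0.01+0.004)/3 = 0.008, thr 0.004 -> removes none
        # (equality fails a low criterion); step 3 (k=0.5, low, flatness):
        # mean = (2.0+2.0+2.0)/3 = 2.0, thr 1.0; final (k=1.0, high, moment3).
        config = CascadeConfig(
            steps=(
                CascadeStep("n_objects", "high", 2.0, "punctate"),
                CascadeStep("moment3", "low", 0.5, "invagination"),
                CascadeStep("flatness", "low", 0.5, "diffuse"),
            ),
            final=CascadeStep("moment3", "high", 1.0, "ring"),
        )
        control = [
            cell(n_objects=1, moment3=0.01, flatness=2.0),
            cell(n_objects=1, moment3=0.01, flatness=2.0),
            cell(n_objects=1, moment3=0.004, flatness=2.0),
            cell(n_objects=9, moment3=0.05, flatness=2.0),
        ]
        cal = calibrate(control, config)
        assert cal.thresholds[0] == pytest.approx(3.0 * 2.0)
        assert cal.control_sizes == (4, 3, 3, 3)
        assert cal.control_means[1] == pytest.approx(0.008)
        assert cal.thresholds[1] == pytest.approx(0.004)
        assert cal.thresholds[2] == pytest.approx(1.0)

    def test_step_removing_all_control_cells_is_degenerate(self):
        control = [cell(n_objects=5.0) for _ in range(4)]  # all cross 3.3 x 5
        config = default_config({"punctate": 0.5})
        with pytest.raises(ValueError, match="degenerate"):
            calibrate(control, config)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            calibrate([], default_config())

    def test_roundtrips_through_json_dict(self):
        cal = calibrate(quiet_control(), default_config())
        back = calibration_from_dict(calibration_to_dict(cal))
        assert back.thresholds == cal.thresholds
        assert back.config.steps == cal.config.steps


class TestAssignPhenotype:
    @pytest.fixture
    def cal(self):
        return calibrate(quiet_control(), default_config())

    def test_high_object_count_is_punctate(self, cal):
        # punctate threshold = 3.3 x 1.0; a 12-object cell crosses it
        call = assign_phenotype(cell(n_objects=12), cal)
        assert call.phenotype == "punctate"
        assert call.group_flag == "abnormal"

    def test_final_split_by_moment3(self, cal):
        thr = cal.final_threshold
        assert assign_phenotype(cell(moment3=thr * 1.2), cal).phenotype == "ring"
        assert assign_phenotype(cell(moment3=thr * 0.8), cal).phenotype == "incomplete"

    def test_boundary_equality_meets_high_and_fails_low(self, cal):
        thr_p = cal.thresholds[0]
        assert assign_phenotype(cell(n_objects=thr_p), cal).phenotype == "punctate"
        thr_i = cal.thresholds[1]
        # equality on a 'low' step passes through instead of assigning
        call = assign_phenotype(cell(moment3=thr_i, flatness=0.5), cal)
        assert call.phenotype != "invagination"

    def test_missing_feature_raises(self, cal):
        with pytest.raises(KeyError):
            assign_phenotype({"n_objects": 1}, cal)

    def test_partition_every_cell_gets_exactly_one_phenotype(self, cal):
        rng = np.random.default_rng(0)
        cells = [
            cell(
                n_objects=float(rng.integers(1, 15)),
                moment3=float(rng.uniform(0.0005, 0.02)),
                flatness=float(rng.uniform(1.0, 4.0)),
            )
            for _ in range(300)
        ]
        calls = [assign_phenotype(c, cal) for c in cells]
        assert all(c.phenotype in PHENOTYPES for c in calls)
        counts = {p: sum(c.phenotype == p for c in calls) for p in PHENOTYPES}
        assert sum(counts.values()) == 300

    def test_monotone_in_object_count_and_moment3(self, cal):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = cell(
                n_objects=float(rng.integers(1, 15)),
                moment3=float(rng.uniform(0.0005, 0.02)),
                flatness=float(rng.uniform(1.0, 4.0)),
            )
            call = assign_phenotype(c, cal)
            if call.phenotype == "punctate":
                more = dict(c, n_objects=c["n_objects"] + rng.integers(1, 5))
                assert assign_phenotype(more, cal).phenotype == "punctate"
            if call.phenotype == "ring":
                higher = dict(c, moment3=c["moment3"] * 1.5)
                assert assign_phenotype(higher, cal).phenotype != "incomplete"


class TestCascadeClassifier:
    def test_sklearn_protocol(self):
        clf = CascadeClassifier()
        params = clf.get_params()
        assert "config" in params
        clone(clf)  # must be cloneable
        with pytest.raises(RuntimeError):
            clf.predict([cell()])

    def test_fit_predict_matches_functional_path(self):
        control = quiet_control(12)
        clf = CascadeClassifier().fit(control)
        cells = [cell(n_objects=9), cell(), cell(flatness=1.0)]
        preds = clf.predict(cells)
        cal = calibrate(control, default_config())
        expected = [assign_phenotype(c, cal).phenotype for c in cells]
        assert list(preds) == expected
        assert preds[0] == "punctate"


class TestTuneMultiplier:
    def test_separating_plateau_midpoint(self):
        # target cells sit at 10x the mean of the rest: any multiplier in the
        # separating plateau is optimal; the midpoint is returned
        labeled = [(cell(n_objects=1), "ring")] * 9 + [(cell(n_objects=20), "punctate")]
        step = CascadeStep("n_objects", "high", 1.0, "punctate")
        grid = np.round(np.arange(1.0, 6.01, 0.1), 10)
        k = tune_multiplier(labeled, step, grid)
        mean = (9 * 1 + 20) / 10.0  # 2.9
        # plateau: thresholds in (1, 20]/mean -> k in (0.34, 6.9] within grid
        scores = []
        for g in grid:
            met = [v >= g * mean for v in [1] * 9 + [20]]
            scores.append(met[-1] - sum(met[:-1]))
        best = grid[np.array(scores) == max(scores)]
        assert k == pytest.approx((best.min() + best.max()) / 2)

    def test_inseparable_classes_warn_and_return_grid_midpoint(self):
        labeled = [(cell(), "punctate"), (cell(), "ring")]
        step = CascadeStep("n_objects", "high", 1.0, "punctate")
        with pytest.warns(UserWarning, match="flat"):
            k = tune_multiplier(labeled, step, [1.0, 2.0, 3.0])
        assert k == pytest.approx(2.0)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        labeled = [(cell(n_objects=float(rng.integers(1, 20))),
                    rng.choice(["punctate", "ring"])) for _ in range(40)]
        labeled += [(cell(n_objects=25.0), "punctate")]
        step = CascadeStep("n_objects", "high", 1.0, "punctate")
        grid = np.arange(0.5, 5.0, 0.05)
        assert tune_multiplier(labeled, step, grid) == tune_multiplier(labeled, step, grid)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_multiplier([(cell(), "punctate"), (cell(), "ring")],
                            CascadeStep("n_objects", "high", 1.0, "punctate"), [])


class TestSummarize:
    @staticmethod
    def _calls(phenos):
        return [
            PhenotypeCall(cell_id=f"c{i}", phenotype=p, group_flag=GROUP_OF_PHENOTYPE[p])
            for i, p in enumerate(phenos)
        ]

    def test_percent_abnormal_arithmetic(self):
        phenos = ["ring"] * 21 + ["diffuse"] * 3 + ["punctate"] * 2 + \
                 ["invagination"] * 3 + ["incomplete"]
        calls = self._calls(phenos)
        group_of = {c.cell_id: "siNEG" for c in calls}
        (s,) = summarize(calls, group_of)
        assert s.n_total == 30
        assert s.percent_abnormal == pytest.approx(20.0)
        assert s.counts["ring"] == 21

    def test_all_ring_is_zero_percent(self):
        calls = self._calls(["ring"] * 12)
        (s,) = summarize(calls, {c.cell_id: "g" for c in calls})
        assert s.percent_abnormal == 0.0

    def test_missing_group_assignment_raises(self):
        calls = self._calls(["ring", "diffuse"])
        with pytest.raises(ValueError, match="group"):
            summarize(calls, {"c0": "g"})

    def test_seeded_mixture_recovered_exactly(self):
        rng = np.random.default_rng(3)
        phenos = rng.permutation(
            ["ring"] * 10 + ["diffuse"] * 5 + ["punctate"] * 3
            + ["invagination"] * 4 + ["incomplete"] * 2
        )
        calls = self._calls(list(phenos))
        (s,) = summarize(calls, {c.cell_id: "mix" for c in calls})
        assert s.counts == {"ring": 10, "diffuse": 5, "punctate": 3,
                            "invagination": 4, "incomplete": 2}
        assert s.percent_abnormal == pytest.approx(100.0 * 9 / 24)


class TestManualVsAuto:
    def test_identical_labelings_agree_fully(self):
        manual = ["normal"] * 6 + ["abnormal"] * 4
        report = compare_manual_vs_auto(manual, manual)
        assert report.percent_agreement == 100.0
        np.testing.assert_array_equal(report.table, [[6, 0], [0, 4]])

    def test_complete_disagreement(self):
        manual = ["normal"] * 5
        auto = ["abnormal"] * 5
        report = compare_manual_vs_auto(manual, auto)
        assert report.percent_agreement == 0.0

    def test_known_mixed_table(self):
        manual = ["normal"] * 7 + ["abnormal"] * 3
        auto = ["normal"] * 5 + ["abnormal"] * 5
        report = compare_manual_vs_auto(manual, auto)
        np.testing.assert_array_equal(report.table, [[5, 2], [0, 3]])
        assert report.percent_agreement == pytest.approx(80.0)
        # proportions abnormal: manual 3/10, auto 5/10 -> hand-computed z
        p_pool = (3 + 5) / 20
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / 10 + 1 / 10))
        assert report.statistic == pytest.approx((0.3 - 0.5) / se)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_manual_vs_auto(["normal"], ["normal", "abnormal"])
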