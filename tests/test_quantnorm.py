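"""Calibration and normalization: bead subpopulations and the
origin-constrained conversion slope, reporter summaries, dual-luciferase
and western-blot normalization, fold-difference error propagation, and
the distance regression."""

import math

import numpy as np
import pandas as pd
import pytest

from fretquant import quantnorm as qn
from fretquant import stats as st
from fretquant import synthdata as sd

REFS = [693.0, 2192.0, 10885.0, 34169.0, 110674.0, 325845.0]


class TestBeadSubpops:
    def test_noiseless_exact_means(self):
        beads = sd.simulate_bead_set([10, 100, 1000], 2.0, 0.0, 50, seed=0)
        np.testing.assert_allclose(
            qn.identify_bead_subpops(beads, 3), [20.0, 200.0, 2000.0]
        )

    def test_k_one_is_global_mean(self):
        beads = sd.simulate_bead_set([10, 100], 1.0, 0.1, 50, seed=0)
        out = qn.identify_bead_subpops(beads, 1)
        assert out[0] == pytest.approx(beads["MFI"].mean())

    def test_noisy_means_within_two_percent(self):
        beads = sd.simulate_bead_set(REFS, 2.0, 0.05, 500, seed=0)
        means = qn.identify_bead_subpops(beads, 6)
        np.testing.assert_allclose(means, 2.0 * np.array(REFS), rtol=0.02)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            qn.identify_bead_subpops(np.ones(20), 6)


class TestBeadSlope:
    def test_exact_proportionality(self):
        cal = qn.fit_bead_slope([20.0, 200.0, 2000.0], [10.0, 100.0, 1000.0])
        assert cal.slope == pytest.approx(2.0, rel=1e-12)
        assert cal.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_through_origin(self):
        assert qn.fit_bead_slope([6.0], [3.0]).slope == pytest.approx(2.0)

    def test_noiseless_generator_roundtrip(self):
        beads = sd.simulate_bead_set(REFS, 1.7, 0.0, 100, seed=2)
        means = qn.identify_bead_subpops(beads, 6)
        cal = qn.fit_bead_slope(means, REFS)
        assert cal.slope == pytest.approx(1.7, rel=1e-12)

    def test_conversion_subtracts_background_first(self):
        cal = qn.fit_bead_slope([20.0, 200.0], [10.0, 100.0])
        assert cal.to_calibrated(210.0, background=10.0) == pytest.approx(100.0)

    def test_zero_references_rejected(self):
        with pytest.raises(ValueError):
            qn.fit_bead_slope([1.0, 2.0], [0.0, 0.0])


class TestReporterSummary:
    @staticmethod
    def _cal(slope=1.0):
        return qn.BeadCalibration((), (), slope, 0.0)

    def test_simple_fold(self):
        arms, fold = qn.reporter_summary(
            {"ligand": [300.0], "vehicle": [100.0]}, [0.0, 0.0], self._cal()
        )
        assert arms["ligand"].mefl == pytest.approx(300.0)
        assert fold.value == pytest.approx(3.0)

    def test_vehicle_at_background_flagged(self):
        _, fold = qn.reporter_summary(
            {"ligand": [300.0], "vehicle": [100.0]}, [100.0, 100.0], self._cal()
        )
        assert not fold.defined

    def test_propagated_se(self):
        """Replicates tuned so arm SEMs are 30 and 10 on means 300 and 100."""
        lig = [300.0 + d for d in (-30 * math.sqrt(3), 0.0, 30 * math.sqrt(3))]
        veh = [100.0 + d for d in (-10 * math.sqrt(3), 0.0, 10 * math.sqrt(3))]
        _, fold = qn.reporter_summary({"ligand": lig, "vehicle": veh}, [0.0, 0.0], self._cal())
        assert fold.value == pytest.approx(3.0)
        assert fold.se == pytest.approx(3.0 * math.sqrt(0.02), rel=1e-6)


def _plate():
    rows = [
        {"condition": "vector_only", "f": (10.0, 10.0, 10.0), "r": (5.0, 5.0, 5.0)},
        {"condition": "vector_only", "f": (10.0, 10.0, 10.0), "r": (5.0, 5.0, 5.0)},
        {"condition": "vector_only", "f": (10.0, 10.0, 10.0), "r": (5.0, 5.0, 5.0)},
        {"condition": "reporter_only", "f": (910.0, 1010.0, 1110.0), "r": (95.0, 105.0, 115.0)},
        {"condition": "reporter_only", "f": (1010.0, 1010.0, 1010.0), "r": (105.0, 105.0, 105.0)},
        {"condition": "receptor", "f": (510.0, 510.0, 510.0), "r": (105.0, 105.0, 105.0)},
        {"condition": "background_like", "f": (10.0, 10.0, 10.0), "r": (5.0, 5.0, 5.0)},
    ]
    return pd.DataFrame(
        {
            "condition": [r["condition"] for r in rows],
            **{f"firefly_{i+1}": [r["f"][i] for r in rows] for i in range(3)},
            **{f"renilla_{i+1}": [r["r"][i] for r in rows] for i in range(3)},
        }
    )


class TestLuciferase:
    def test_reporter_only_anchored_to_one(self):
        out = qn.luciferase_normalize(_plate())
        anchor = out.loc[out["condition"] == "reporter_only", "normalized"]
        assert anchor.mean() == pytest.approx(1.0, rel=1e-12)

    def test_vector_like_well_is_zero(self):
        out = qn.luciferase_normalize(_plate())
        row = out.loc[out["condition"] == "background_like"].iloc[0]
        assert not row["valid"]  # renilla equals background: flagged, not a number
        assert row["firefly_net"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        """Firefly (900,1000,1100)/renilla (90,100,110), no autoluminescence,
        reporter-only mean ratio 10 -> normalized exactly 1."""
        plate = pd.DataFrame(
            {
                "condition": ["vector_only", "reporter_only"],
                "firefly_1": [0.0, 900.0], "firefly_2": [0.0, 1000.0],
                "firefly_3": [0.0, 1100.0],
                "renilla_1": [0.0, 90.0], "renilla_2": [0.0, 100.0],
                "renilla_3": [0.0, 110.0],
            }
        )
        out = qn.luciferase_normalize(plate)
        row = out.loc[out["condition"] == "reporter_only"].iloc[0]
        assert row["ratio"] == pytest.approx(10.0)
        assert row["normalized"] == pytest.approx(1.0)

    def test_idempotent_when_already_anchored(self):
        out = qn.luciferase_normalize(_plate())
        plate2 = pd.DataFrame(
            {
                "condition": out["condition"],
                "firefly_1": out["normalized"].fillna(0.0),
                "renilla_1": np.where(out["valid"], 1.0, 0.0),
            }
        )
        out2 = qn.luciferase_normalize(plate2)
        ok = out["valid"] & out2["valid"]
        np.testing.assert_allclose(out2.loc[ok, "normalized"], out.loc[ok, "normalized"])

    def test_missing_anchor_condition_rejected(self):
        plate = _plate()
        with pytest.raises(ValueError, match="reporter"):
            qn.luciferase_normalize(plate[plate["condition"] != "reporter_only"])


def _bands(gain2=1.0, flag=None):
    rows = []
    for exposure, gain in (("short", 1.0), ("long", gain2)):
        for lane, (mesa, nano) in (
            ("control", (100.0, 200.0)),
            ("test", (200.0, 200.0)),
            ("third", (100.0, 100.0)),
        ):
            rows.append(
                {
                    "exposure": exposure, "lane": lane,
                    "mesa_intensity": gain * mesa, "nanoluc_intensity": gain * nano,
                    "mesa_excluded": flag == (exposure, lane),
                    "nanoluc_excluded": False,
                }
            )
    return pd.DataFrame(rows)


class TestWestern:
    def test_identical_lanes_are_unity(self):
        bands = pd.DataFrame(
            {
                "exposure": ["e1", "e1"], "lane": ["control", "test"],
                "mesa_intensity": [50.0, 50.0], "nanoluc_intensity": [80.0, 80.0],
            }
        )
        out = qn.western_normalize(bands, "control").set_index("lane")
        np.testing.assert_allclose(out["relative_expression"], 1.0)

    def test_ratio_and_dose_factor(self):
        out = qn.western_normalize(_bands(), "control").set_index("lane")
        assert out.loc["test", "relative_expression"] == pytest.approx(2.0)
        assert out.loc["test", "suggested_dose_factor"] == pytest.approx(0.5)

    def test_gain_invariance_across_exposures(self):
        base = qn.western_normalize(_bands(gain2=1.0), "control")
        scaled = qn.western_normalize(_bands(gain2=7.3), "control")
        np.testing.assert_allclose(
            base["relative_expression"], scaled["relative_expression"], rtol=1e-12
        )

    def test_flagged_exposure_excluded_for_that_lane_only(self):
        """A saturated band drops that lane from that exposure's percents;
        the lane's result equals the value from its unflagged exposure."""
        out = qn.western_normalize(_bands(flag=("long", "test")), "control").set_index("lane")
        single = qn.western_normalize(
            _bands().query("exposure == 'short'"), "control"
        ).set_index("lane")
        assert out.loc["test", "mesa_pct"] == pytest.approx(single.loc["test", "mesa_pct"])

    def test_unusable_control_lane_rejected(self):
        with pytest.raises(ValueError):
            qn.western_normalize(_bands(), "missing_lane")


class TestDistanceRegression:
    def test_recovers_exact_line(self):
        x = np.array([8.0, 22.0, 35.0, 50.0])
        points = np.column_stack([x, -0.027 * x + 2.9])
        fit = qn.distance_regression(points)
        assert fit.slope == pytest.approx(-0.027, rel=1e-9)
        assert fit.intercept == pytest.approx(2.9, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_horizontal_points(self):
        fit = qn.distance_regression([(1.0, 2.0), (2.0, 2.0), (3.0, 2.0)])
        assert fit.slope == 0.0
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            qn.distance_regression([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
        with pytest.raises(ValueError):
            qn.distance_regression([(1.0, 2.0), (2.0, 3.0)])


class TestFoldStats:
    def test_delta_method_examples(self):
        fd = st.fold_difference(0.4, 0.04, 0.2, 0.02)
        assert fd.value == pytest.approx(2.0)
        assert fd.se == pytest.approx(2.0 * math.sqrt(0.02), rel=1e-9)
        assert not st.fold_difference(0.4, 0.04, 0.0, 0.02).defined

    def test_bootstrap_cross_check(self):
        """Delta-method SE agrees with a parametric bootstrap at CV 0.1."""
        fd = st.fold_difference(0.4, 0.04, 0.2, 0.02)
        bs = st.bootstrap_fold_se(0.4, 0.04, 0.2, 0.02, 10_000, seed=0)
        assert fd.se == pytest.approx(bs, rel=0.10)
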