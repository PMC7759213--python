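"""Flow-FRET chain: spillover estimation, compensation round trips,
gating behavior, the NFRET statistic and its calibration, and the
fold-difference summaries."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from fretquant import flowfret as ff
from fretquant import synthdata as sd


def _controls(cfg):
    return sd.simulate_control_set(cfg)


def _compensated(donor, acceptor, fret):
    events = pd.DataFrame(
        {
            "Comp Pacific Blue": np.atleast_1d(donor).astype(float),
            "Comp FITC": np.atleast_1d(acceptor).astype(float),
            "Comp AmCyan": np.atleast_1d(fret).astype(float),
        }
    )
    events.attrs["compensated"] = True
    return events


class TestEstimateSpillover:
    def test_exact_recovery_noise_free(self, clean_config):
        """Generator donor->FRET coefficient 0.4 is an exact regression slope."""
        cfg = dataclasses.replace(
            clean_config,
            n_cells=1000,
            mixing=sd.SpilloverTruth.from_bleedthrough(a=0.0, b=0.0, c=0.0, d=0.4),
        )
        controls = _controls(cfg)
        model = ff.estimate_spillover(
            {"donor": controls["donor_only"], "acceptor": controls["acceptor_only"]},
            vector_only=controls["vector_only"],
        )
        frame = model.as_frame()
        assert frame.loc["Pacific Blue", "AmCyan"] == pytest.approx(0.4, rel=1e-12)
        assert frame.loc["Pacific Blue", "FITC"] == pytest.approx(0.0, abs=1e-12)

    def test_identity_mixing_gives_identity_matrix(self, clean_config):
        cfg = dataclasses.replace(clean_config, n_cells=1000)
        controls = _controls(cfg)
        model = ff.estimate_spillover(
            {"donor": controls["donor_only"], "acceptor": controls["acceptor_only"]},
            vector_only=controls["vector_only"],
        )
        np.testing.assert_allclose(model.matrix, np.eye(4), atol=1e-12)

    def test_missing_control_named_in_error(self, clean_config):
        controls = _controls(dataclasses.replace(clean_config, n_cells=1000))
        with pytest.raises(ValueError, match="acceptor"):
            ff.estimate_spillover(
                {"donor": controls["donor_only"]}, vector_only=controls["vector_only"]
            )

    def test_all_negative_control_rejected(self, clean_config):
        controls = _controls(dataclasses.replace(clean_config, n_cells=1000))
        with pytest.raises(ValueError, match="donor"):
            ff.estimate_spillover(
                {"donor": controls["vector_only"], "acceptor": controls["acceptor_only"]},
                vector_only=controls["vector_only"],
            )


class TestCompensate:
    def test_identity_model_preserves_raw(self, base_config):
        events, _ = sd.simulate_flow_sample(base_config)
        comp = ff.compensate(events, ff.SpilloverModel.identity())
        for ch in sd.FLUOR_CHANNELS:
            np.testing.assert_allclose(comp["Comp " + ch], events[ch], rtol=1e-12)

    def test_roundtrip_recovers_sources(self, clean_config):
        """Mix with the true matrix, compensate with it: machine precision."""
        cfg = dataclasses.replace(clean_config, dimer_fraction_vehicle=0.3,
                                  mixing=sd.SpilloverTruth.from_bleedthrough())
        events, truth = sd.simulate_flow_sample(cfg)
        model = ff.SpilloverModel.from_bleedthrough(a=0.15, b=0.02, c=0.05, d=0.40)
        comp = ff.compensate(events, model)
        sens = truth["fret_efficiency"] * truth["complex_amount"]
        np.testing.assert_allclose(
            comp["Comp Pacific Blue"], truth["donor_amount"] - sens, rtol=1e-9
        )
        np.testing.assert_allclose(comp["Comp FITC"], truth["acceptor_amount"], rtol=1e-9)
        np.testing.assert_allclose(comp["Comp AmCyan"], sens, rtol=1e-9, atol=1e-9)

    def test_zero_event_stays_zero(self):
        events = pd.DataFrame({ch: [0.0] for ch in ("Pacific Blue", "FITC", "AmCyan")})
        model = ff.SpilloverModel.from_bleedthrough(0.1, 0.02, 0.05, 0.4)
        comp = ff.compensate(events, model)
        assert (comp.filter(like="Comp ") == 0).all().all()

    def test_singular_matrix_rejected(self):
        events = pd.DataFrame({"Pacific Blue": [1.0], "FITC": [1.0]})
        model = ff.SpilloverModel.__new__(ff.SpilloverModel)
        model.channels = ("Pacific Blue", "FITC")
        model.matrix = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="singular"):
            ff.compensate(events, model)


class TestGating:
    def test_doublets_removed_singlets_kept(self, base_config):
        events, truth = sd.simulate_flow_sample(base_config)
        kept = ff.gate_singlets(events)
        doublets = truth["is_doublet"].to_numpy()
        removed = ~events.index.isin(kept.index)
        assert removed[doublets].mean() >= 0.95
        assert (~removed)[~doublets].mean() >= 0.99

    def test_empty_table_warns_and_passes_through(self, base_config):
        empty, _ = sd.simulate_flow_sample(dataclasses.replace(base_config, n_cells=0))
        with pytest.warns(UserWarning):
            out = ff.gate_cells_singlets(empty)
        assert out.empty

    def test_cell_gate_keeps_requested_fraction(self, base_config):
        events, _ = sd.simulate_flow_sample(base_config)
        kept = ff.gate_cells(events, keep_fraction=0.75)
        assert 0.75 <= len(kept) / len(events) <= 0.85


class TestPositivityThreshold:
    def test_linear_interpolation_quantile(self):
        control = pd.DataFrame({"APC": np.arange(1.0, 101.0)})
        thr = ff.positivity_threshold(control, "APC", 0.01)
        assert thr == pytest.approx(99.01)
        assert (control["APC"] > thr).mean() <= 0.01

    def test_rate_half_is_median(self):
        control = pd.DataFrame({"APC": np.arange(1.0, 102.0)})
        assert ff.positivity_threshold(control, "APC", 0.5) == pytest.approx(51.0)

    def test_constant_control(self):
        control = pd.DataFrame({"APC": np.full(50, 7.0)})
        thr = ff.positivity_threshold(control, "APC", 0.01)
        assert thr == 7.0
        assert (control["APC"] > thr).mean() == 0.0

    @pytest.mark.parametrize("rate", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_rate(self, rate):
        control = pd.DataFrame({"APC": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ff.positivity_threshold(control, "APC", rate)


class TestNFRET:
    def test_closed_form(self):
        values = ff.nfret_per_cell(_compensated([4.0, 4.0, 0.0], [9.0, 9.0, 9.0],
                                                [6.0, 0.0, 6.0]))
        assert values.iloc[0] == pytest.approx(1.0)
        assert values.iloc[1] == 0.0
        assert math.isnan(values.iloc[2])  # donor = 0: undefined, excluded

    def test_uncompensated_rejected(self, base_config):
        events, _ = sd.simulate_flow_sample(base_config)
        with pytest.raises(ValueError, match="compensated"):
            ff.nfret_per_cell(events)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        d, a, f = rng.lognormal(5, 1, 1000), rng.lognormal(5, 1, 1000), rng.normal(50, 30, 1000)
        events = _compensated(d, a, f)
        vec = ff.nfret_per_cell(events).to_numpy()
        loop = np.array([fi / math.sqrt(di * ai) for di, ai, fi in zip(d, a, f)])
        np.testing.assert_allclose(vec, loop, rtol=1e-12)

    @given(s=stn.floats(1e-6, 1e6))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, s):
        base = ff.nfret_per_cell(_compensated([4.0], [9.0], [6.0])).iloc[0]
        scaled = ff.nfret_per_cell(_compensated([4.0 * s], [9.0 * s], [6.0 * s])).iloc[0]
        assert scaled == pytest.approx(base, rel=1e-12)


class TestCalibration:
    def test_endpoints_and_midpoint(self):
        assert ff.calibrate_nfret(0.2, 0.2, 0.8) == 0.0
        assert ff.calibrate_nfret(0.8, 0.2, 0.8) == 1.0
        assert ff.calibrate_nfret(0.5, 0.2, 0.8) == pytest.approx(0.5)

    def test_equal_control_means_rejected(self):
        with pytest.raises(ValueError):
            ff.calibrate_nfret(0.5, 0.3, 0.3)


class TestSummarize:
    def test_zero_error_fold(self):
        s = ff.summarize_sample([[0.4, 0.4]], [[0.2, 0.2]])
        assert s.fold_difference.value == pytest.approx(2.0)
        assert s.fold_difference.se == 0.0

    def test_identical_arms_give_unit_fold(self):
        s = ff.summarize_sample([[0.3, 0.5]], [[0.3, 0.5]])
        assert s.fold_difference.value == pytest.approx(1.0)

    def test_propagated_se(self):
        """Replicates chosen so the arm means/SEMs are 0.4+-0.04 and 0.2+-0.02."""
        lig = [[0.4 + d] for d in (-0.04 * math.sqrt(3), 0.0, 0.04 * math.sqrt(3))]
        veh = [[0.2 + d] for d in (-0.02 * math.sqrt(3), 0.0, 0.02 * math.sqrt(3))]
        s = ff.summarize_sample(lig, veh)
        assert s.ligand.mean_nfret == pytest.approx(0.4)
        assert s.ligand.sem == pytest.approx(0.04)
        assert s.fold_difference.value == pytest.approx(2.0)
        assert s.fold_difference.se == pytest.approx(2.0 * math.sqrt(0.02), rel=1e-6)

    def test_nonpositive_vehicle_flagged(self):
        s = ff.summarize_sample([[0.4]], [[-0.1]])
        assert not s.fold_difference.defined
        assert math.isnan(s.fold_difference.value)

    def test_nan_cells_excluded(self):
        s = ff.summarize_sample([[0.4, np.nan]], [[0.2]])
        assert s.ligand.mean_nfret == pytest.approx(0.4)
        assert s.ligand.n_cells == 1


class TestPipeline:
    def test_monotone_in_dimer_fraction(self, base_config):
        """Mean NFRET is nondecreasing across the dimer-fraction grid."""
        controls = _controls(base_config)
        means = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = dataclasses.replace(
                base_config, dimer_fraction_vehicle=f, dimer_fraction_max=f
            )
            events, _ = sd.simulate_flow_sample(cfg)
            means.append(np.mean(ff.flow_fret_pipeline(events, controls)))
        assert np.all(np.diff(means) >= 0)

    def test_calibrated_controls_hit_endpoints(self, base_config):
        controls = _controls(base_config)
        neg = ff.calibrated_sample_nfret(controls["negative"], controls)
        pos = ff.calibrated_sample_nfret(controls["positive"], controls)
        assert np.mean(neg) == pytest.approx(0.0, abs=1e-9)
        assert np.mean(pos) == pytest.approx(1.0, abs=1e-9)
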