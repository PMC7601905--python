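"""QC filters, calibration curves and censoring rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from saspsurv import SimulationConfig, generate_plate
from saspsurv.preprocess import (censor_at_horizon, estimate_concentration,
                                 fit_standard_curve, qc_filter,
                                 quantify_plate, replicate_cv_pct)


def _wells(rows):
    defaults = {"analyte": "CRP", "is_standard": 0, "known_conc": np.nan}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestQCFilter:
    def test_high_cv_pair_flagged(self):
        # CV of (100, 150) = sd/mean*100 = 35.36/125*100 = 28.28% > 25
        wells = _wells([
            {"well": "A1", "mfi": 100.0, "bead_count": 50, "replicate": "r1"},
            {"well": "A2", "mfi": 150.0, "bead_count": 50, "replicate": "r1"},
        ])
        report = qc_filter(wells)
        assert set(report.flagged["well"]) == {"A1", "A2"}
        assert (report.flagged["reason"] == "high_cv").all()
        assert report.flagged["cv_pct"].iloc[0] == pytest.approx(28.2843,
                                                                 abs=1e-3)

    def test_zero_variance_passes(self):
        wells = _wells([
            {"well": "A1", "mfi": 100.0, "bead_count": 50, "replicate": "r1"},
            {"well": "A2", "mfi": 100.0, "bead_count": 50, "replicate": "r1"},
        ])
        assert len(qc_filter(wells).flagged) == 0

    def test_low_beads_primary_reason(self):
        wells = _wells([
            {"well": "A1", "mfi": 100.0, "bead_count": 10, "replicate": "r1"},
            {"well": "A2", "mfi": 300.0, "bead_count": 50, "replicate": "r1"},
        ])
        report = qc_filter(wells, min_beads=35)
        reasons = dict(zip(report.flagged["well"], report.flagged["reason"]))
        assert reasons["A1"] == "low_beads"

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        wells = _wells([
            {"well": f"W{i}", "mfi": float(rng.uniform(50, 500)),
             "bead_count": int(rng.integers(10, 100)),
             "replicate": f"r{i // 2}"}
            for i in range(40)])
        first = qc_filter(wells)
        second = qc_filter(first.passed)
        assert len(second.flagged) == 0

    def test_empty_and_negative_thresholds(self):
        with pytest.raises(ValueError):
            qc_filter(_wells([]))
        with pytest.raises(ValueError):
            qc_filter(_wells([{"well": "A", "mfi": 1.0, "bead_count": 5,
                               "replicate": "r"}]), min_beads=-1)


class TestStandardCurve:
    def _standards(self, concs, b0=2.0, b1=0.9):
        return pd.DataFrame({
            "analyte": "CRP", "is_standard": 1,
            "known_conc": concs,
            "mfi": 2.0 ** (b0 + b1 * np.log2(np.asarray(concs))),
            "well": [f"S{i}" for i in range(len(concs))],
            "bead_count": 50, "replicate": "std",
        })

    def test_exact_line_recovered(self):
        curve = fit_standard_curve(self._standards([1, 4, 16, 64, 256.0]))
        assert curve.coeffs[0] == pytest.approx(0.9, abs=1e-9)
        assert curve.coeffs[1] == pytest.approx(2.0, abs=1e-9)

    def test_two_distinct_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve(self._standards([1, 1, 4, 4.0]))

    def test_non_monotone_rejected(self):
        std = self._standards([1, 4, 16, 64.0])
        std.loc[3, "mfi"] = 1.0  # force a decreasing tail
        with pytest.raises(ValueError, match="monotone"):
            fit_standard_curve(std, degree=2)

    def test_roundtrip_within_1e9(self):
        std = self._standards([1, 4, 16, 64, 256.0])
        curve = fit_standard_curve(std)
        conc, oor = estimate_concentration(std["mfi"].to_numpy(), curve)
        assert np.allclose(conc, np.log2(std["known_conc"]), atol=1e-9)
        assert not oor.any()

    def test_out_of_range_flagged(self):
        curve = fit_standard_curve(self._standards([1, 4, 16, 64.0]))
        _, oor = estimate_concentration([curve.fit_range[0] / 4.0], curve)
        assert oor.all()

    def test_nonpositive_mfi_rejected(self):
        curve = fit_standard_curve(self._standards([1, 4, 16, 64.0]))
        with pytest.raises(ValueError):
            estimate_concentration([0.0], curve)


class TestPlateRecovery:
    def test_noisy_plate_concentrations_recovered(self):
        plate = generate_plate(SimulationConfig(seed=8), analytes=["CRP"])
        tidy, _ = quantify_plate(plate)
        truth = (plate[plate["is_standard"] == 0]
                 .groupby("replicate")["known_conc"].first())
        merged = tidy.set_index("replicate").join(truth)
        rho = spearmanr(merged["log2_conc"],
                        np.log2(merged["known_conc"])).statistic
        assert rho >= 0.95
        mid = merged[(merged["known_conc"] > 2 ** 6)
                     & (merged["known_conc"] < 2 ** 10)]
        rel_err = np.abs(2 ** mid["log2_conc"] / mid["known_conc"] - 1)
        assert (rel_err < 0.25).mean() > 0.9

    def test_low_bead_well_excluded_downstream(self):
        plate = generate_plate(SimulationConfig(seed=9), analytes=["CRP"])
        plate.loc[plate.index[-1], "bead_count"] = 3
        _, report = quantify_plate(plate)
        assert plate.loc[plate.index[-1], "well"] in set(
            report.flagged["well"])


class TestCensoring:
    @pytest.mark.parametrize("time,event,expected", [
        (7.2, 1, (5.0, 0)),   # beyond horizon: administratively censored
        (4.9, 1, (4.9, 1)),   # below horizon: unchanged
        (5.0, 1, (5.0, 1)),   # boundary keeps its event status
    ])
    def test_rule(self, time, event, expected):
        assert censor_at_horizon(time, event, 5.0) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            censor_at_horizon(1.0, 1, horizon=0.0)
        with pytest.raises(ValueError):
            censor_at_horizon(0.0, 1, horizon=5.0)

    @settings(max_examples=200, deadline=None)
    @given(time=st.floats(0.01, 20.0), event=st.integers(0, 1))
    def test_never_exceeds_horizon_never_adds_events(self, time, event):
        t, e = censor_at_horizon(time, event, 5.0)
        assert t <= 5.0
        assert e <= event


def test_cv_uses_sample_sd():
    # (100, 150): sample sd = 35.355, mean 125 -> 28.28%
    assert replicate_cv_pct([100, 150]) == pytest.approx(28.28427, abs=1e-4)
    assert replicate_cv_pct([100]) == 0.0
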