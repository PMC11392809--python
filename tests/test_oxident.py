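"""ECN retention model, transition building, RT filtering and aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pufascope.io import default_reference_windows
from pufascope.lipids import Adduct, molecular_mass
from pufascope.oxident import (
    ECNCalibration,
    ReferenceWindow,
    aggregate_oxidation,
    build_ox_transitions,
    ecn,
    filter_signals_by_rt,
    fit_ecn_calibration,
)


class TestEcn:
    @pytest.mark.parametrize(
        "name, expected",
        [("PE(18:0_20:4)", 30), ("PC(16:0/20:4)", 28), ("PI(18:1/18:1)", 32),
         ("PE(14:0/14:0)", 28)],
    )
    def test_values(self, name, expected):
        assert ecn(name) == expected

    def test_oxygenation_invariance(self):
        assert ecn("PE(18:0_20:4 + 3[O])") == ecn("PE(18:0_20:4)")


class TestCalibration:
    def test_line_through_two_points(self):
        refs = [
            ReferenceWindow("PC(16:0/20:4)", 1, 2.8, 3.2),  # ECN 28, centre 3.0
            ReferenceWindow("PC(18:0/18:0)", 1, 3.8, 4.2),  # ECN 36... centre 4.0
        ]
        # ECNs 28 and 36 -> slope (4-3)/8 = 0.125; use ECN 32 species for 28->32
        cal = fit_ecn_calibration(refs)
        s = cal.strata_[("PC", 1)]
        assert s.slope == pytest.approx((4.0 - 3.0) / (36 - 28))
        for ref in refs:
            t_min, t_max = cal.predict(ref.species, 1)
            assert t_min <= ref.centre <= t_max

    def test_two_point_slope_quarter(self):
        # centres (ECN 28 -> 3.0, ECN 32 -> 4.0): slope 0.25, intercept -4.0
        refs = [
            ReferenceWindow("PC(16:0/20:4)", 1, 2.9, 3.1),   # ECN 28
            ReferenceWindow("PC(16:0/18:1)", 1, 3.9, 4.1),   # ECN 32
        ]
        cal = fit_ecn_calibration(refs)
        s = cal.strata_[("PC", 1)]
        assert s.slope == pytest.approx(0.25)
        assert s.intercept == pytest.approx(-4.0)

    def test_single_reference_stratum_reproduces_its_window(self):
        refs = [ReferenceWindow("PE(16:0/20:4)", 1, 2.79, 2.96)]
        cal = fit_ecn_calibration(refs)
        assert cal.predict("PE(16:0/20:4)", 1) == pytest.approx((2.79, 2.96), abs=0.01)

    def test_least_squares_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        pool = ["PC(14:0/14:0)", "PC(16:0/18:1)", "PC(16:0/20:4)", "PC(18:0/18:0)",
                "PC(18:1/18:1)", "PC(16:0/16:1)"]
        for _ in range(20):
            names = rng.choice(pool, size=4, replace=False)
            centres = rng.uniform(1.0, 8.0, size=4)
            refs = [
                ReferenceWindow(n, 1, c - 0.1, c + 0.1) for n, c in zip(names, centres)
            ]
            x = np.array([ecn(n) for n in names], dtype=float)
            y = np.array(centres)
            # closed-form normal equations
            sxx = np.sum((x - x.mean()) ** 2)
            slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            intercept = y.mean() - slope * x.mean()
            if slope <= 0:
                continue
            cal = fit_ecn_calibration(refs)
            s = cal.strata_[("PC", 1)]
            assert s.slope == pytest.approx(slope, abs=1e-9)
            assert s.intercept == pytest.approx(intercept, abs=1e-9)

    def test_slope_borrowed_from_unoxidized_stratum(self):
        refs = [
            ReferenceWindow("PE(14:0/14:0)", 0, 2.0, 2.2),   # ECN 28
            ReferenceWindow("PE(18:0/18:0)", 0, 3.0, 3.2),   # ECN 36 -> slope 0.125
            ReferenceWindow("PE(16:0/20:4)", 1, 2.79, 2.96),  # single ECN at 1[O]
        ]
        cal = fit_ecn_calibration(refs)
        assert cal.strata_[("PE", 1)].slope == pytest.approx(0.125)
        assert cal.predict("PE(16:0/20:4)", 1) == pytest.approx((2.79, 2.96), abs=0.01)

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            fit_ecn_calibration([])

    def test_uncovered_stratum_named_in_error(self):
        cal = fit_ecn_calibration([ReferenceWindow("PE(16:0/20:4)", 1, 2.79, 2.96)])
        with pytest.raises(KeyError, match="oxygens=3"):
            cal.predict("PE(16:0/20:4)", 3)


@pytest.fixture(scope="module")
def calibration():
    return ECNCalibration().fit(default_reference_windows())


class TestMeasuredWindows:
    """Behaviour of the calibration fitted on the shipped measured windows."""

    def test_reference_centres_reproduced_within_half_width(self, calibration):
        for ref in default_reference_windows():
            t_min, t_max = calibration.predict(ref.species, ref.oxygens)
            assert t_min - 1e-9 <= ref.centre <= t_max + 1e-9

    def test_triply_oxidized_elutes_before_singly_oxidized(self, calibration):
        w3 = calibration.predict("PC(16:0/20:4)", 3)
        w1 = calibration.predict("PC(16:0/20:4)", 1)
        assert w3[1] < w1[0]  # whole 3[O] window earlier than the 1[O] window

    def test_centre_strictly_increasing_in_ecn(self, calibration):
        series = ["PC(16:0/20:4)", "PC(16:0/18:2)", "PC(16:0/18:1)", "PC(18:0/18:1)"]
        ecns = [ecn(n) for n in series]
        assert ecns == sorted(ecns)
        for n_ox in (1, 2, 3):
            centres = [np.mean(calibration.predict(n, n_ox)) for n in series]
            assert all(a < b for a, b in zip(centres, centres[1:]))

    def test_pi_uses_pc_group_calibration(self, calibration):
        # PI and PC form one analytical group; same ECN -> same window
        assert calibration.predict("PI(16:0/20:4)", 1) == pytest.approx(
            calibration.predict("PC(16:0/20:4)", 1)
        )


class TestTransitions:
    def test_only_pufa_acyls_are_oxidation_targets(self):
        table = build_ox_transitions(["PE(16:0/20:4)"], [1])
        assert len(table) == 1
        assert table["target_acyl"].iloc[0] == "20:4"

    def test_class_adduct_applied_to_q1(self):
        table = build_ox_transitions(["PC(16:0/20:4)", "PE(16:0/20:4)"], [1])
        pc = table[table["species"] == "PC(16:0/20:4)"].iloc[0]
        pe = table[table["species"] == "PE(16:0/20:4)"].iloc[0]
        assert pc["adduct"] == "[M+OAc]-"
        assert pe["adduct"] == "[M-H]-"
        expected_pc = molecular_mass("PC(16:0/20:4 + 1[O])", Adduct.M_PLUS_OAC)
        assert pc["q1_mz"] == pytest.approx(expected_pc, abs=1e-3)

    def test_saturated_species_yield_no_transitions(self):
        assert build_ox_transitions(["PE(14:0/14:0)", "PI(18:1/18:1)"], [1, 2]).empty


class TestRtFilter:
    WINDOWS = pd.DataFrame(
        {"species": ["PC(16:0/20:4)"], "oxygens": [1], "t_min": [2.8], "t_max": [4.6]}
    )

    @staticmethod
    def _signal(rt):
        return pd.DataFrame(
            {"sample_id": ["S1"], "species": ["PC(16:0/20:4)"], "oxygens": [1],
             "intensity": [100.0], "rt_min": [rt]}
        )

    @pytest.mark.parametrize("rt, kept", [(3.0, True), (2.5, False), (2.8, True),
                                          (4.6, True), (4.61, False)])
    def test_closed_interval_decision(self, rt, kept):
        out = filter_signals_by_rt(self._signal(rt), self.WINDOWS)
        assert (len(out) == 1) is kept

    def test_missing_window_raises(self):
        with pytest.raises(KeyError):
            filter_signals_by_rt(
                self._signal(3.0).assign(species="PE(16:0/20:4)"), self.WINDOWS
            )


class TestAggregation:
    @staticmethod
    def _frames(signals):
        filtered = pd.DataFrame(signals)
        ann = pd.DataFrame({"sample_id": ["S1"], "group": ["Veh"],
                            "cell_count": [1_000_000]})
        std = pd.DataFrame(
            {"sample_id": ["S1", "S1"], "species": ["PE(14:0/14:0)", "PC(14:0/14:0)"],
             "intensity": [1000.0, 1000.0]}
        )
        return filtered, ann, std

    def test_isomer_sum_and_normalization(self):
        filtered, ann, std = self._frames(
            [{"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 3,
              "intensity": 100.0, "rt_min": 2.0},
             {"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 3,
              "intensity": 50.0, "rt_min": 2.1}]
        )
        out = aggregate_oxidation(filtered, ann, std)
        assert out["amount_per_cell"].iloc[0] == pytest.approx(1.5e-7)

    def test_additive_in_isomer_splitting(self):
        one, ann, std = self._frames(
            [{"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 1,
              "intensity": 150.0, "rt_min": 2.0}]
        )
        split, _, _ = self._frames(
            [{"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 1,
              "intensity": 90.0, "rt_min": 2.0},
             {"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 1,
              "intensity": 60.0, "rt_min": 2.05}]
        )
        a = aggregate_oxidation(one, ann, std)
        b = aggregate_oxidation(split, ann, std)
        assert a["amount_per_cell"].iloc[0] == pytest.approx(b["amount_per_cell"].iloc[0])

    def test_pi_normalized_to_dmpc_pe_to_dmpe(self):
        filtered, ann, _ = self._frames([])
        filtered = pd.DataFrame(
            [{"sample_id": "S1", "species": "PI(18:0_20:4)", "oxygens": 1,
              "intensity": 100.0, "rt_min": 2.0},
             {"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 1,
              "intensity": 100.0, "rt_min": 2.0}]
        )
        std = pd.DataFrame(
            {"sample_id": ["S1", "S1"], "species": ["PE(14:0/14:0)", "PC(14:0/14:0)"],
             "intensity": [1000.0, 500.0]}
        )
        out = aggregate_oxidation(filtered, ann, std).set_index("species")
        assert out.loc["PI(18:0_20:4)", "amount_per_cell"] == pytest.approx(2e-7)
        assert out.loc["PE(18:0_20:4)", "amount_per_cell"] == pytest.approx(1e-7)

    def test_no_surviving_signal_reports_zero(self):
        filtered, ann, std = self._frames([])
        filtered = pd.DataFrame(
            columns=["sample_id", "species", "oxygens", "intensity", "rt_min"]
        )
        expected = pd.DataFrame(
            [{"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 3}]
        )
        out = aggregate_oxidation(filtered, ann, std, expected=expected)
        assert out["amount_per_cell"].tolist() == [0.0]

    def test_most_intense_transition_selected(self):
        filtered, ann, std = self._frames(
            [{"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 1,
              "transition_id": "t1", "intensity": 100.0, "rt_min": 2.0},
             {"sample_id": "S1", "species": "PE(18:0_20:4)", "oxygens": 1,
              "transition_id": "t2", "intensity": 40.0, "rt_min": 2.0}]
        )
        out = aggregate_oxidation(filtered, ann, std)
        assert out["amount_per_cell"].iloc[0] == pytest.approx(1e-7)  # t1 only
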