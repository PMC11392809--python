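"""MRM quantification: signals, normalization, composition, contrasts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import oracle_fa_distribution, random_signal_table
from pufascope import quantify
from pufascope.quantify import (
    MissingSignalError,
    absolute_amounts,
    category_proportions,
    compute_composition,
    fa_distribution,
    fold_changes,
    percent_change_vs_vehicle,
    pufa_mufa_ratio,
    relative_intensities,
    species_signal,
)


def _signals(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "species", "fragment_id", "intensity", "rt_min"]
    )


THREE_SPECIES_PE = pd.DataFrame(
    {
        "species": ["PE(18:0_20:4)", "PE(16:0/18:1)", "PE(16:0/16:0)"],
        "rel_pct": [60.0, 30.0, 10.0],
    }
)


class TestSpeciesSignal:
    def test_mean_of_two_fragments(self):
        table = _signals([("S1", "PE(18:0_20:4)", "fa1", 120.0, 5.0),
                          ("S1", "PE(18:0_20:4)", "fa2", 80.0, 5.0)])
        assert species_signal(table, "S1", "PE(18:0_20:4)") == 100.0

    def test_single_fragment_stands_alone(self):
        table = _signals([("S1", "PE(18:0_20:4)", "fa1", 50.0, 5.0)])
        assert species_signal(table, "S1", "PE(18:0_20:4)") == 50.0

    def test_symmetric_species_identical_fragments(self):
        table = _signals([("S1", "PC(14:0/14:0)", "fa1", 42.0, 5.0),
                          ("S1", "PC(14:0/14:0)", "fa2", 42.0, 5.0)])
        assert species_signal(table, "S1", "PC(14:0/14:0)") == 42.0

    def test_missing_signal_flagged(self):
        table = _signals([("S1", "PE(18:0_20:4)", "fa1", 50.0, 5.0)])
        with pytest.raises(MissingSignalError):
            species_signal(table, "S1", "PE(16:0/16:0)")

    def test_duplicate_record_rejected(self):
        table = _signals([("S1", "PE(18:0_20:4)", "fa1", 50.0, 5.0),
                          ("S1", "PE(18:0_20:4)", "fa1", 60.0, 5.0)])
        with pytest.raises(ValueError, match="duplicate"):
            quantify.species_signals(table)


class TestAbsoluteAmounts:
    @staticmethod
    def _setup(species_signal=400.0, is_signal=200.0, protein=0.1):
        signals = _signals(
            [("S1", "PE(18:0_20:4)", "fa1", species_signal, 5.0),
             ("S1", "PE(15:0/18:1-d7)", "fa1", is_signal, 5.0)]
        )
        samples = pd.DataFrame(
            {"sample_id": ["S1"], "group": ["Veh"], "protein_mg": [protein]}
        )
        standards = pd.DataFrame(
            {"species": ["PE(15:0/18:1-d7)"], "amount_nmol": [0.2]}
        )
        return signals, samples, standards

    def test_internal_standard_normalization(self):
        amounts = absolute_amounts(*self._setup())
        assert amounts["amount_nmol_per_mg"].tolist() == [pytest.approx(4.0)]
        # the standard itself never appears in the output
        assert "PE(15:0/18:1-d7)" not in set(amounts["species"])

    def test_signal_equal_to_standard(self):
        amounts = absolute_amounts(*self._setup(200.0, 200.0, protein=1.0))
        assert amounts["amount_nmol_per_mg"].iloc[0] == pytest.approx(0.2)

    def test_invariant_to_uniform_intensity_scaling(self):
        signals, samples, standards = self._setup()
        scaled = signals.assign(intensity=signals["intensity"] * 7.3)
        a = absolute_amounts(signals, samples, standards)
        b = absolute_amounts(scaled, samples, standards)
        assert np.allclose(a["amount_nmol_per_mg"], b["amount_nmol_per_mg"])

    def test_missing_protein_or_standard_raise(self):
        signals, samples, standards = self._setup()
        with pytest.raises(ValueError, match="protein"):
            absolute_amounts(signals, samples.assign(protein_mg=np.nan), standards)
        with pytest.raises(ValueError, match="internal standard"):
            absolute_amounts(
                signals[signals["species"] != "PE(15:0/18:1-d7)"], samples, standards
            )


class TestRelativeIntensities:
    def test_single_species_class_is_100(self):
        table = _signals([("S1", "PI(18:1/18:1)", "fa1", 123.0, 5.0)])
        rel = relative_intensities(table)
        assert rel["rel_pct"].tolist() == [100.0]

    def test_proportions(self):
        table = _signals(
            [("S1", "PE(18:0_20:4)", "fa1", 60.0, 5.0),
             ("S1", "PE(16:0/18:1)", "fa1", 30.0, 5.0),
             ("S1", "PE(16:0/16:0)", "fa1", 10.0, 5.0)]
        )
        rel = relative_intensities(table).set_index("species")["rel_pct"]
        assert rel["PE(18:0_20:4)"] == pytest.approx(60.0)
        assert rel["PE(16:0/18:1)"] == pytest.approx(30.0)
        assert rel["PE(16:0/16:0)"] == pytest.approx(10.0)

    def test_deuterated_standards_excluded(self):
        table = _signals(
            [("S1", "PE(18:0_20:4)", "fa1", 60.0, 5.0),
             ("S1", "PE(15:0/18:1-d7)", "fa1", 999.0, 5.0)]
        )
        rel = relative_intensities(table)
        assert set(rel["species"]) == {"PE(18:0_20:4)"}
        assert rel["rel_pct"].iloc[0] == pytest.approx(100.0)

    def test_sums_to_100_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            rel = relative_intensities(random_signal_table(rng))
            assert rel["rel_pct"].sum() == pytest.approx(100.0, abs=1e-9)


class TestFaDistribution:
    def test_worked_three_species_panel(self):
        shares, fracs = fa_distribution(THREE_SPECIES_PE)
        assert shares["18:0"] == pytest.approx(30.0)
        assert shares["20:4"] == pytest.approx(30.0)
        assert shares["16:0"] == pytest.approx(25.0)
        assert shares["18:1"] == pytest.approx(15.0)
        assert fracs == pytest.approx({"SFA": 55.0, "MUFA": 15.0, "PUFA": 30.0})
        assert pufa_mufa_ratio(fracs) == pytest.approx(2.0)

    def test_symmetric_species(self):
        rel = pd.DataFrame({"species": ["PI(18:1/18:1)"], "rel_pct": [100.0]})
        shares, fracs = fa_distribution(rel)
        assert shares["18:1"] == pytest.approx(100.0)
        assert fracs["MUFA"] == pytest.approx(100.0)
        assert pufa_mufa_ratio(fracs) == 0.0  # all-MUFA class, no PUFA

    def test_matches_slot_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            rel = relative_intensities(random_signal_table(rng))
            shares, fracs = fa_distribution(rel)
            o_shares, o_fracs = oracle_fa_distribution(rel)
            assert set(shares.index) == set(o_shares)
            for acyl in o_shares:
                assert shares[acyl] == pytest.approx(o_shares[acyl], abs=1e-12)
            for cls in o_fracs:
                assert fracs[cls] == pytest.approx(o_fracs[cls], abs=1e-12)

    def test_pufa_monotonicity(self):
        base = THREE_SPECIES_PE.copy()
        table = _signals(
            [("S1", sp, "fa1", pct, 5.0) for sp, pct in zip(base["species"], base["rel_pct"])]
        )
        rel0 = relative_intensities(table)
        _, f0 = fa_distribution(rel0)
        boosted = table.copy()
        boosted.loc[boosted["species"] == "PE(18:0_20:4)", "intensity"] *= 2
        rel1 = relative_intensities(boosted)
        _, f1 = fa_distribution(rel1)
        assert f1["PUFA"] >= f0["PUFA"]
        assert pufa_mufa_ratio(f1) >= pufa_mufa_ratio(f0)


class TestCategories:
    def test_worked_example(self):
        cats = category_proportions(THREE_SPECIES_PE)
        assert cats["pufa_containing"] == pytest.approx(60.0)
        assert cats["sfa_mufa_only"] == pytest.approx(40.0)

    def test_pure_sfa_class(self):
        rel = pd.DataFrame({"species": ["PE(16:0/16:0)"], "rel_pct": [100.0]})
        cats = category_proportions(rel)
        assert cats == {"pufa_containing": 0.0, "sfa_mufa_only": 100.0}

    def test_oxygenation_does_not_change_category(self):
        for name in ("PE(18:0_20:4)", "PE(18:0_20:4 + 3[O])"):
            rel = pd.DataFrame({"species": [name], "rel_pct": [100.0]})
            assert category_proportions(rel)["pufa_containing"] == pytest.approx(100.0)


class TestContrasts:
    @staticmethod
    def _amounts(veh, treat):
        rows = []
        for i, v in enumerate(veh):
            rows.append({"sample_id": f"V{i}", "species": "X", "amount_nmol_per_mg": v})
        for i, t in enumerate(treat):
            rows.append({"sample_id": f"T{i}", "species": "X", "amount_nmol_per_mg": t})
        amounts = pd.DataFrame(rows).assign(species="PE(18:0_20:4)")
        ann = pd.DataFrame(
            {
                "sample_id": [f"V{i}" for i in range(len(veh))] + [f"T{i}" for i in range(len(treat))],
                "group": ["Veh"] * len(veh) + ["RSL3"] * len(treat),
            }
        )
        return amounts, ann

    def test_percent_change(self):
        amounts, ann = self._amounts([10, 10], [25, 25])
        pct = percent_change_vs_vehicle(amounts, ann, "RSL3")
        assert pct["pct_change"].iloc[0] == pytest.approx(150.0)

    def test_percent_change_identity(self):
        amounts, ann = self._amounts([5, 7], [5, 7])
        pct = percent_change_vs_vehicle(amounts, ann, "RSL3")
        assert pct["pct_change"].iloc[0] == pytest.approx(0.0)

    def test_fold_change_grid_recovered_without_noise(self):
        for fc in (0.5, 1.0, 2.0, 4.0):
            amounts, ann = self._amounts([2.0, 2.0], [2.0 * fc, 2.0 * fc])
            out = fold_changes(amounts, ann, ("RSL3", "Veh"))
            assert out["fold_change"].iloc[0] == pytest.approx(fc)
            assert out["log2fc"].iloc[0] == pytest.approx(np.log2(fc))


class TestComposition:
    def test_conservation_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        table = pd.concat(
            [random_signal_table(rng, sample_id=f"S{i}") for i in range(5)],
            ignore_index=True,
        )
        comp = compute_composition(table)
        sums = comp.relative.groupby(["sample_id", "headgroup"])["rel_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)
        frac_sums = comp.fractions[["sfa_pct", "mufa_pct", "pufa_pct"]].sum(axis=1)
        assert np.allclose(frac_sums, 100.0, atol=1e-9)
        scaled = compute_composition(table.assign(intensity=table["intensity"] * 13.7))
        pd.testing.assert_frame_equal(comp.fractions, scaled.fractions)

    def test_removing_foreign_species_leaves_other_class_untouched(self):
        table = _signals(
            [("S1", "PE(18:0_20:4)", "fa1", 60.0, 5.0),
             ("S1", "PE(16:0/16:0)", "fa1", 40.0, 5.0),
             ("S1", "PI(18:1/18:1)", "fa1", 10.0, 5.0)]
        )
        full = compute_composition(table)
        without_pi = compute_composition(table[table["species"] != "PI(18:1/18:1)"])
        pe_full = full.fractions[full.fractions["headgroup"] == "PE"].reset_index(drop=True)
        pe_wo = without_pi.fractions.reset_index(drop=True)
        pd.testing.assert_frame_equal(pe_full, pe_wo)
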