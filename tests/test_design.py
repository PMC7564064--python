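import warnings

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from ecoqsar.design import (
    DerivativeRecord,
    ScreenRules,
    SubstitutionPlan,
    enumerate_derivatives,
    evaluate_derivatives,
    screen,
)
from ecoqsar.fixtures import group_fragments, load_sites


@pytest.fixture(scope="module")
def dmp_plan():
    sites = load_sites()["DMP"]
    return SubstitutionPlan("DMP", sites["smiles"], sites["sites"],
                            group_fragments(), mode="both")


class TestEnumeration:
    def test_single_substitution_named_and_built(self):
        sites = load_sites()["DMP"]
        plan = SubstitutionPlan("DMP", sites["smiles"], sites["sites"],
                                {"NO2": "[*][N+](=O)[O-]"}, mode="single")
        recs = enumerate_derivatives(plan)
        names = [r.id for r in recs]
        assert names == ["DMP-1-NO2", "DMP-2-NO2"]
        mol = recs[0].structure.rdkit_mol
        assert mol.HasSubstructMatch(Chem.MolFromSmarts("[CH2][N+](=O)[O-]"))

    def test_double_substitution_naming(self):
        sites = load_sites()["DAP"]
        plan = SubstitutionPlan("DAP", sites["smiles"], sites["sites"],
                                {"NO2": "[*][N+](=O)[O-]", "OCH3": "[*]OC"},
                                mode="double")
        names = [r.id for r in enumerate_derivatives(plan)]
        assert "DAP-1-NO2-2-OCH3" in names
        assert len(names) == 4  # ordered pairs of 2 groups

    def test_empty_group_list_empty_result(self):
        sites = load_sites()["DMP"]
        plan = SubstitutionPlan("DMP", sites["smiles"], sites["sites"], {}, mode="single")
        assert enumerate_derivatives(plan) == []

    def test_enumeration_deterministic(self, dmp_plan):
        a = [r.id for r in enumerate_derivatives(dmp_plan)]
        b = [r.id for r in enumerate_derivatives(dmp_plan)]
        assert a == b
        # 9 packaged fragments (8 design groups + propyl): 2 sites single + 9x9 double
        assert len(a) == 2 * 9 + 81

    def test_invalid_fragment_rejected(self):
        sites = load_sites()["DMP"]
        with pytest.raises(ValueError, match="attachment"):
            SubstitutionPlan("DMP", sites["smiles"], sites["sites"],
                             {"bad": "CC"}, mode="single")

    def test_bad_site_failure_is_per_product(self):
        sites = load_sites()["DMP"]
        # site on a carbon with no free H (carbonyl carbon, index 2)
        plan = SubstitutionPlan("DMP", sites["smiles"], {"1": 2},
                                {"CH3": "[*]C"}, mode="single")
        recs = enumerate_derivatives(plan)
        assert len(recs) == 1
        assert recs[0].error is not None


class TestEvaluation:
    def test_parent_evaluated_against_itself_zero_changes(self):
        rec = DerivativeRecord(id="DMP", parent="DMP",
                               structure=object())  # predictor ignores structure
        models = {"Z": lambda mol: 0.371, "LOI": lambda mol: 22.44}
        parent = {"Z": 0.371, "LOI": 22.44}
        df = evaluate_derivatives([rec], models, parent)
        assert df.loc[0, "Z_decrease_pct"] == 0.0
        assert df.loc[0, "LOI_increase_pct"] == 0.0

    def test_sign_conventions(self):
        rec = DerivativeRecord(id="d", parent="p", structure=object())
        models = {"Z": lambda m: 0.2, "logBCF": lambda m: 0.5,
                  "LOI": lambda m: 23.0, "logLC50": lambda m: 2.0}
        parent = {"Z": 0.4, "logBCF": 1.0, "LOI": 22.0, "logLC50": 1.0}
        row = evaluate_derivatives([rec], models, parent).iloc[0]
        assert row["Z_decrease_pct"] == pytest.approx(50.0)
        assert row["logBCF_decrease_pct"] == pytest.approx(50.0)
        assert row["LOI_increase_pct"] == pytest.approx(100.0 / 22.0, abs=0.01)
        assert row["logLC50_increase_pct"] == pytest.approx(100.0)
        assert row["Z"] == 0.2  # 3-decimal reporting

    def test_missing_model_is_an_error(self):
        rec = DerivativeRecord(id="d", parent="p", structure=object())
        with pytest.raises(KeyError, match="Z"):
            evaluate_derivatives([rec], {}, {"Z": 0.4})

    def test_failed_products_skipped(self):
        bad = DerivativeRecord(id="x", parent="p", error="valence")
        df = evaluate_derivatives([bad], {"Z": lambda m: 1.0}, {"Z": 0.5})
        assert df.empty


class TestScreening:
    def test_reference_funnel_22_to_7(self, derivative_records):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # freq column absent
            out = screen(derivative_records)
        survivors = sorted(out[out["passes"]]["id"])
        assert survivors == [
            "DAP-1-NO2-2-CH2C6H5", "DAP-1-NO2-2-CH2CH3", "DAP-1-NO2-2-CH2NO2",
            "DAP-1-NO2-2-NO2", "DAP-1-NO2-2-OCH3", "DAP-2-CH2NO2",
            "DAP-2-CH=CH2-1-NO2",
        ]
        assert len(out) == 22

    def test_parent_equal_record_fails(self):
        df = pd.DataFrame([{"id": "same", "Z_decrease_pct": 0.0,
                            "LOI_increase_pct": 0.0, "logLC50_increase_pct": 0.0,
                            "logBCF_decrease_pct": 0.0, "logBCF": 1.0}])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = screen(df)
        assert not out["passes"].any()

    def test_bcf_cap_boundary(self):
        df = pd.DataFrame([{"id": "edge", "Z_decrease_pct": 10.0,
                            "LOI_increase_pct": 6.0, "logLC50_increase_pct": 10.0,
                            "logBCF_decrease_pct": 10.0, "logBCF": 3.31}])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = screen(df, ScreenRules(bcf_cap=3.30))
        assert not out.loc[0, "rule_bcf_cap"]
        assert not out.loc[0, "passes"]

    def test_screening_monotone_in_thresholds(self, derivative_records):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strict = screen(derivative_records, ScreenRules(loi_improvement_threshold_pct=5.0))
            relaxed = screen(derivative_records, ScreenRules(loi_improvement_threshold_pct=3.0))
        strict_ids = set(strict[strict["passes"]]["id"])
        relaxed_ids = set(relaxed[relaxed["passes"]]["id"])
        assert strict_ids <= relaxed_ids

    def test_koa_band_and_freq_rules_from_eco_table(self, table7):
        """With the eco-friendliness columns joined in, the semivolatility band
        trims the funnel further (one candidate falls below the band)."""
        import ecoqsar as eq

        t8 = eq.load_fixture("table8").set_index("id")
        records = table7[table7["parent"].notna()].set_index("id")
        joined = records.join(t8[["logKOA", "freq"]], how="inner").reset_index()
        out = screen(joined)
        assert len(joined) == 7
        assert int(out["passes"].sum()) == 6
        dropped = out[~out["passes"]]["id"].tolist()
        assert dropped == ["DAP-2-CH2NO2"]

    def test_warns_when_freq_absent(self, derivative_records):
        with pytest.warns(UserWarning, match="freq"):
            screen(derivative_records.head(3))

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            ScreenRules(koa_band=(10.0, 6.5))
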