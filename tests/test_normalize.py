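"""Normalization schemes, fold changes, and the labeling-activity diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import prmquant as pq


def tiny_table(analyte_area=10.0, factor_area=5.0, tic=100.0):
    rows = [
        {"protein": "TTR", "peptide": "p1", "condition": "ref", "replicate": 1,
         "area": analyte_area, "tic": tic},
        {"protein": "PC", "peptide": "q1", "condition": "ref", "replicate": 1,
         "area": factor_area, "tic": tic},
    ]
    return pd.DataFrame(rows)


ROLES = {"TTR": "analyte", "PC": "independent_factor"}


class TestNormalize:
    def test_simple_division(self):
        out = pq.normalize(tiny_table(), pq.NormalizationScheme("INDEPENDENT"),
                           "TTR", roles=ROLES)
        assert out["value"].iloc[0] == pytest.approx(2.0)

    def test_within_run_scale_invariance(self, quant_table, roles):
        scaled = quant_table.copy()
        run0 = (scaled["condition"] == "MG132+Veh") & (scaled["replicate"] == 1)
        scaled.loc[run0, ["area", "tic"]] *= 3.0
        for kind in ("TIC", "INDEPENDENT", "COMPARTMENT", "ENZYME"):
            scheme = (pq.NormalizationScheme("TIC") if kind == "TIC"
                      else pq.scheme_from_roles(kind, roles))
            a = pq.normalize(quant_table, scheme, "FLAG-TTR", roles=roles)
            b = pq.normalize(scaled, scheme, "FLAG-TTR", roles=roles)
            assert np.allclose(a["value"], b["value"])

    def test_zero_factor_is_an_error_naming_the_run(self):
        table = tiny_table(factor_area=0.0)
        with pytest.raises(pq.NormalizationError, match="ref"):
            pq.normalize(table, pq.NormalizationScheme("INDEPENDENT"), "TTR",
                         roles=ROLES)

    def test_zero_analyte_warns_and_yields_zero(self):
        table = tiny_table(analyte_area=0.0)
        with pytest.warns(UserWarning, match="zero"):
            out = pq.normalize(table, pq.NormalizationScheme("INDEPENDENT"),
                               "TTR", roles=ROLES)
        assert out["value"].iloc[0] == 0.0

    def test_median_ratio_combination(self):
        table = pd.concat([
            tiny_table(),
            pd.DataFrame([{"protein": "PC", "peptide": "q2", "condition": "ref",
                           "replicate": 1, "area": 2.0, "tic": 100.0}]),
        ], ignore_index=True)
        scheme = pq.NormalizationScheme("INDEPENDENT", ("PC",), combine="median_ratio")
        out = pq.normalize(table, scheme, "TTR", roles=ROLES)
        # median of 10/5 and 10/2
        assert out["value"].iloc[0] == pytest.approx(np.median([2.0, 5.0]))


class TestNoiseFreeIdentities:
    """Closed-form consequences of the eluate-composition model at sigma = 0."""

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("m_fold", [0.5, 1.0, 2.5])
    def test_enzyme_and_independent_fold_changes(self, alpha, m_fold, roles):
        cfg = pq.scenario_pack("comparable", noise_sigma=0.0, n_replicates=2)
        stress = [c for c in cfg.conditions if c != cfg.reference_condition][0]
        cfg.labeling_activity[stress] = alpha
        cfg.mistargeted_fraction[stress] = m_fold * cfg.mistargeted_fraction[cfg.reference_condition]
        table = pq.runs_to_frame(pq.simulate_experiment(cfg))
        fc_e = pq.fold_change(table, pq.scheme_from_roles("ENZYME", roles),
                              "FLAG-TTR", cfg.reference_condition, roles=roles)
        fc_i = pq.fold_change(table, pq.scheme_from_roles("INDEPENDENT", roles),
                              "FLAG-TTR", cfg.reference_condition, roles=roles)
        by_cond = {r.condition: r for r in fc_e}
        assert by_cond[stress].fold_change == pytest.approx(m_fold)
        by_cond = {r.condition: r for r in fc_i}
        assert by_cond[stress].fold_change == pytest.approx(alpha * m_fold)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("bg_fraction", [0.05, 0.2, 0.5])
    def test_tic_fold_change_is_intermediate(self, alpha, bg_fraction, roles):
        # tracer-scale analyte: the identity holds exactly as the analyte's
        # own TIC share vanishes (it is ~0.2% in the realistic packs)
        cfg = pq.scenario_pack("comparable", noise_sigma=0.0, n_replicates=1)
        cfg.protein_abundances["FLAG-TTR"] = 1e-3
        cfg.background_fraction = bg_fraction
        stress = [c for c in cfg.conditions if c != cfg.reference_condition][0]
        cfg.labeling_activity[stress] = alpha
        table = pq.runs_to_frame(pq.simulate_experiment(cfg))
        fcs = {}
        for kind in ("ENZYME", "INDEPENDENT", "TIC"):
            scheme = (pq.NormalizationScheme("TIC") if kind == "TIC"
                      else pq.scheme_from_roles(kind, roles))
            res = pq.fold_change(table, scheme, "FLAG-TTR",
                                 cfg.reference_condition, roles=roles)
            fcs[kind] = {r.condition: r.fold_change for r in res}[stress]
        lo, hi = sorted([fcs["ENZYME"], fcs["INDEPENDENT"]])
        tol = 1e-4 * fcs["TIC"]
        assert lo - tol <= fcs["TIC"] <= hi + tol

    def test_constant_alpha_makes_all_schemes_agree(self, roles):
        cfg = pq.scenario_pack("comparable", noise_sigma=0.0, n_replicates=2)
        cfg.protein_abundances["FLAG-TTR"] = 1e-3  # tracer limit, see above
        table = pq.runs_to_frame(pq.simulate_experiment(cfg))
        stress = [c for c in cfg.conditions if c != cfg.reference_condition][0]
        values = []
        for kind in ("TIC", "INDEPENDENT", "COMPARTMENT", "ENZYME"):
            scheme = (pq.NormalizationScheme("TIC") if kind == "TIC"
                      else pq.scheme_from_roles(kind, roles))
            res = pq.fold_change(table, scheme, "FLAG-TTR",
                                 cfg.reference_condition, roles=roles)
            values.append({r.condition: r.fold_change for r in res}[stress])
        assert np.allclose(values, values[0], rtol=1e-4)


class TestSumNormalize:
    def test_uniform_input(self):
        shares = pq.sum_normalize({c: 2.0 for c in "abcdef"})
        assert np.allclose(shares, 1 / 6)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=10))
    def test_shares_sum_to_one(self, values):
        shares = pq.sum_normalize(dict(enumerate(values)))
        assert shares.sum() == pytest.approx(1.0)

    def test_doubling_one_condition_preserves_ordering(self):
        base = {"Veh": 1.0, "ML": 6.0, "Tg": 2.5, "Tm": 1.1, "BFA": 2.0, "DTT": 0.6}
        doubled = dict(base, Tg=2 * base["Tg"])
        s1, s2 = pq.sum_normalize(base), pq.sum_normalize(doubled)
        assert list(s1.sort_values().index) == list(s2.sort_values().index)
        assert s2["Tg"] > s1["Tg"]

    def test_zero_sum_errors(self):
        with pytest.raises(pq.NormalizationError):
            pq.sum_normalize({"a": 0.0, "b": 0.0})


class TestFoldChange:
    def test_reference_is_exactly_one_per_replicate(self, quant_table, roles):
        res = pq.fold_change(quant_table, pq.NormalizationScheme("TIC"),
                             "FLAG-TTR", "MG132+Veh", roles=roles)
        ref = {r.condition: r for r in res}["MG132+Veh"]
        assert np.all(ref.values == 1.0) and ref.fold_change == 1.0

    def test_missing_pairing_lists_unpaired_replicates(self, quant_table, roles):
        broken = quant_table[~((quant_table["condition"] == "MG132+Veh")
                               & (quant_table["replicate"] == 3))]
        with pytest.raises(pq.NormalizationError, match="3"):
            pq.fold_change(broken, pq.NormalizationScheme("TIC"), "FLAG-TTR",
                           "MG132+Veh", roles=roles)

    def test_enzyme_scheme_recovers_mistargeting_ratio(self, roles):
        """ENZYME fold change estimates m_c/m_ref within 2 SEM at n=6, sigma=0.1."""
        cfg = pq.scenario_pack("decreased", noise_sigma=0.1, n_replicates=6, seed=5)
        table = pq.runs_to_frame(pq.simulate_experiment(cfg))
        res = pq.fold_change(table, pq.scheme_from_roles("ENZYME", roles),
                             "FLAG-TTR", cfg.reference_condition, roles=roles)
        r = {x.condition: x for x in res}["DTT"]
        assert abs(r.fold_change - 2.5) <= 2 * r.sem + 1e-9


class TestDiagnostic:
    def test_equal_fold_changes_are_comparable(self):
        d = pq.labeling_activity_diagnostic(2.0, 2.0)
        assert d.regime == "comparable" and d.ratio == pytest.approx(1.0)

    def test_halved_activity_detected_as_decreased(self, roles):
        cfg = pq.scenario_pack("decreased", noise_sigma=0.0)
        table = pq.runs_to_frame(pq.simulate_experiment(cfg))
        by_scheme = {
            kind: pq.fold_change(table, pq.scheme_from_roles(kind, roles),
                                 "FLAG-TTR", cfg.reference_condition, roles=roles)
            for kind in ("ENZYME", "INDEPENDENT")
        }
        d = pq.diagnose_condition(by_scheme, "DTT")
        assert d.regime == "decreased"
        assert d.ratio == pytest.approx(2.0)
        assert d.implied_activity_ratio == pytest.approx(0.5)

    def test_doubled_activity_detected_as_increased(self, roles):
        cfg = pq.scenario_pack("increased", noise_sigma=0.0)
        table = pq.runs_to_frame(pq.simulate_experiment(cfg))
        by_scheme = {
            kind: pq.fold_change(table, pq.scheme_from_roles(kind, roles),
                                 "FLAG-TTR", cfg.reference_condition, roles=roles)
            for kind in ("ENZYME", "INDEPENDENT")
        }
        assert pq.diagnose_condition(by_scheme, "ML").regime == "increased"

    def test_missing_scheme_is_unavailable(self):
        with pytest.raises(pq.NormalizationError):
            pq.diagnose_condition({"TIC": []}, "DTT")

    def test_compartment_fallback(self, roles):
        cfg = pq.scenario_pack("decreased", noise_sigma=0.0)
        table = pq.runs_to_frame(pq.simulate_experiment(cfg))
        by_scheme = {
            kind: pq.fold_change(table, pq.scheme_from_roles(kind, roles),
                                 "FLAG-TTR", cfg.reference_condition, roles=roles)
            for kind in ("COMPARTMENT", "INDEPENDENT")
        }
        assert pq.diagnose_condition(by_scheme, "DTT").regime == "decreased"
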