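"""Decision tree and Markov cohort engine."""
import copy
from dataclasses import replace

import numpy as np
import pytest

from iemscreen.cohort import (
    base_case_values,
    branch_probabilities,
    evaluate,
    normal_life_course,
    run_patient_markov,
    run_strategy,
    trace_to_frame,
)
from iemscreen.params import ModelSettings


def neutralised(dv):
    """A copy of the disease values with all early effects switched off."""
    out = copy.deepcopy(dv)
    for comp in out.comp_rr:
        out.comp_rr[comp] = np.ones_like(out.comp_rr[comp])
    out.mortality_multiplier = np.ones_like(out.mortality_multiplier)
    return out


def zero_discount(mv):
    out = copy.copy(mv)
    out.settings = replace(mv.settings, discount_rate=0.0)
    return out


class TestBranchProbabilities:
    def test_expanded_detects_every_disease(self, base_values):
        for name in base_values.diseases:
            assert branch_probabilities("expanded", name, base_values)[0] == pytest.approx(0.97)

    def test_current_detects_pku_only(self, base_values):
        assert branch_probabilities("current", "PKU", base_values)[0] == pytest.approx(0.97 * 0.985)
        assert branch_probabilities("current", "IVA", base_values)[0] == 0.0


class TestMarkovTrace:
    @pytest.mark.parametrize("disease", ["PKU", "IVA", "MMA", "PA", "MSUD", "MCD"])
    @pytest.mark.parametrize("pathway", ["early", "late"])
    def test_occupancy_conserved_and_dead_monotone(self, base_values, disease, pathway):
        res = run_patient_markov(base_values.diseases[disease], pathway, base_values,
                                 keep_trace=True)
        occ = res.trace["occupancy"][:, 0, :]
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        dead = occ[:, -1]
        assert np.all(np.diff(dead) >= -1e-12)
        assert np.all(occ >= -1e-12)

    def test_neutral_early_effect_equals_late(self, base_values):
        """With RR = 1 and no mortality effect the two pathways coincide."""
        for name, dv in base_values.diseases.items():
            ndv = neutralised(dv)
            e = run_patient_markov(ndv, "early", base_values)
            l = run_patient_markov(ndv, "late", base_values)
            assert e.qaly[0] == pytest.approx(l.qaly[0], abs=1e-12)
            assert e.cost[0] == pytest.approx(l.cost[0], abs=1e-9 * max(1, l.cost[0]))
            assert e.ly[0] == pytest.approx(l.ly[0], abs=1e-12)

    def test_qaly_never_exceeds_ly(self, base_outputs):
        for pw in base_outputs.pathways.values():
            for res in pw.values():
                assert res.qaly[0] <= res.ly[0] + 1e-12
                assert res.qaly[0] >= 0 and res.cost[0] >= 0

    def test_perfect_health_no_mortality_gives_horizon(self, base_values):
        dv = copy.deepcopy(base_values.diseases["MCD"])
        dv.q_disease = np.zeros_like(dv.q_disease)
        dv.comp_probs = {c: np.zeros_like(v) for c, v in dv.comp_probs.items()}
        dv.utilities = {s: np.ones_like(v) for s, v in dv.utilities.items()}
        mv = zero_discount(base_values)
        mv.settings = replace(mv.settings, discount_rate=0.0,
                              other_cause_qx=tuple([0.0] * 100))
        res = run_patient_markov(dv, "late", mv)
        assert res.qaly[0] == pytest.approx(100.0, abs=1e-9)
        assert res.ly[0] == pytest.approx(100.0, abs=1e-9)

    def test_discounted_never_exceeds_undiscounted(self, base_outputs):
        for pw in base_outputs.pathways.values():
            for res in pw.values():
                assert res.cost[0] <= res.cost_undiscounted[0]
                assert res.ly[0] <= res.ly_undiscounted[0]
                assert res.qaly[0] <= res.qaly_undiscounted[0]

    def test_matches_geometric_series_oracle(self, base_values):
        """Constant probabilities reduce the trace to a geometric series."""
        p_death, p_comp, r, A = 0.03, 0.1, 0.03, 100
        dv = copy.deepcopy(base_values.diseases["PKU"])
        dv.q_disease = np.full_like(dv.q_disease, 0.0)
        dv.comp_probs["neurological"] = np.full_like(dv.comp_probs["neurological"], p_comp)
        mv = copy.copy(base_values)
        mv.settings = replace(mv.settings, other_cause_qx=tuple([p_death] * A))
        res = run_patient_markov(dv, "late", mv)
        k = np.arange(A)
        alive = (1 - p_death) ** k
        expected_ly = np.sum(alive / (1 + r) ** k)
        assert res.ly[0] == pytest.approx(expected_ly, abs=1e-8)
        # closed-form split between well and complication occupancy
        well = ((1 - p_death) * (1 - p_comp)) ** k
        u_w = dv.utilities["well"][0]
        u_n = dv.utilities["neurological"][0]
        expected_qaly = np.sum((u_n * alive + (u_w - u_n) * well) / (1 + r) ** k)
        assert res.qaly[0] == pytest.approx(expected_qaly, abs=1e-8)

    def test_first_year_ipd_only_in_first_cycle(self, base_values):
        res = run_patient_markov(base_values.diseases["IVA"], "late", base_values,
                                 keep_trace=True)
        dm = res.trace["direct_medical"][:, 0]
        costs = base_values.diseases["IVA"].costs
        formula0 = base_values.diseases["IVA"].formula[0, 0]
        expected_first = (costs["ipd_first_year"][0] + costs["opd_annual"][0]
                          + formula0 + costs["pharma_annual"][0])
        assert dm[0] == pytest.approx(expected_first)

    def test_lower_complication_rr_never_reduces_qaly(self, base_values):
        dv = base_values.diseases["IVA"]
        qalys = []
        for rr in (1.0, 0.5, 0.1):
            mod = copy.deepcopy(dv)
            mod.comp_rr["neurological"] = np.array([rr])
            qalys.append(run_patient_markov(mod, "early", base_values).qaly[0])
        assert qalys[0] <= qalys[1] <= qalys[2]

    def test_higher_utility_never_reduces_qaly(self, base_values):
        dv = base_values.diseases["MSUD"]
        lo = run_patient_markov(dv, "late", base_values).qaly[0]
        mod = copy.deepcopy(dv)
        mod.utilities["well"] = mod.utilities["well"] + 0.1
        hi = run_patient_markov(mod, "late", base_values).qaly[0]
        assert hi >= lo

    def test_trace_export_shape(self, base_values):
        res = run_patient_markov(base_values.diseases["MMA"], "late", base_values,
                                 keep_trace=True)
        df = trace_to_frame(res)
        assert set(df["state"]) == {"well", "neurological", "renal",
                                    "neurological_renal", "dead"}
        assert len(df) == base_values.horizon * 5


class TestNormalLifeCourse:
    def test_discounted_le_at_3pct_in_expected_range(self, base_values):
        res = normal_life_course(base_values)
        assert 28.0 <= res.ly[0] <= 31.0
        assert res.qaly[0] == res.ly[0]

    def test_no_mortality_no_discount_gives_horizon(self, base_values):
        mv = copy.copy(base_values)
        mv.settings = replace(mv.settings, discount_rate=0.0,
                              other_cause_qx=tuple([0.0] * 100))
        assert normal_life_course(mv).ly[0] == pytest.approx(100.0)

    def test_discounting_reduces_life_years(self, base_values):
        res = normal_life_course(base_values)
        assert res.ly[0] < res.ly_undiscounted[0]


class TestStrategies:
    def test_screening_cost_components(self, base_outputs):
        assert base_outputs.current.screening_cost[0] == pytest.approx(5 * 0.97)
        assert base_outputs.expanded.screening_cost[0] == pytest.approx(294 * 0.97)

    def test_no_false_positives_under_perfect_specificity(self, base_outputs, base_values):
        total_inc = sum(dv.incidence[0] for dv in base_values.diseases.values())
        assert base_outputs.expanded.expected_confirmations[0] == pytest.approx(
            0.97 * total_inc, rel=1e-9)

    def test_guthrie_false_positives_incur_confirmation(self, base_outputs, base_values):
        # 0.05% of unaffected screened newborns retest after a Guthrie positive,
        # plus the detected PKU cases themselves
        total_inc = sum(dv.incidence[0] for dv in base_values.diseases.values())
        fp = 0.97 * 0.0005 * (1 - total_inc)
        tp = 0.97 * 0.985 * base_values.diseases["PKU"].incidence[0]
        assert base_outputs.current.expected_confirmations[0] == pytest.approx(fp + tp, rel=1e-9)

    def test_null_programme_reduces_to_normal_life_course(self, base_values):
        mv = copy.deepcopy(base_values)
        for t in mv.tests.values():
            t["unit_cost"] = np.zeros(1)
            t["sensitivity"] = np.zeros(1)
            t["specificity"] = np.ones(1)
        for dv in mv.diseases.values():
            dv.incidence = np.zeros(1)
        out = evaluate(mv)
        assert out.expanded.cost[0] == 0.0
        assert out.expanded.qaly[0] == pytest.approx(out.normal.qaly[0], rel=1e-12)

    def test_expanded_costs_more_and_gains_more(self, base_outputs):
        """At the published means the programme sits in the north-east quadrant."""
        assert base_outputs.delta_cost[0] > 0
        assert base_outputs.delta_qaly[0] > 0
        assert base_outputs.delta_ly[0] > 0

    def test_strategy_expectation_is_incidence_weighted_mixture(self, base_values, base_outputs):
        out = base_outputs
        manual = out.expanded.screening_cost[0] + out.expanded.confirmation_cost[0]
        for name, dv in base_values.diseases.items():
            pe = out.expanded.p_early[name][0]
            pw = out.pathways[name]
            manual += dv.incidence[0] * (pe * pw["early"].cost[0] + (1 - pe) * pw["late"].cost[0])
        assert out.expanded.cost[0] == pytest.approx(manual, rel=1e-12)
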