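"""Decision tree and Markov cohort engine.

A birth cohort enters a decision tree: a newborn either carries one of the
six metabolic diseases (at its incidence) or is healthy.  Screening decides
whether an affected child is treated early (pre-symptomatic, detected by the
programme) or late (after clinical presentation).  Each affected child is
then followed through a disease-specific Markov model in one-year cycles for
up to 100 years, accruing costs (THB, 2013), life years and QALYs.

Health-state topologies:

* ``A`` — Well, Neurological, Dead (PKU, IVA, MSUD, MCD)
* ``B`` — Well, Neurological, Renal, Neurological+Renal, Dead (MMA)
* ``C`` — Well, Neurological, Cardiomyopathy, both, Dead (PA)

Within a cycle, death (disease-specific and other-cause hazards combined
multiplicatively) is resolved first; survivors may acquire complications at
the age-banded annual probabilities, independently when two complications
exist.  Early detection multiplies complication probabilities by their
relative risks and scales the disease-specific death probability.  Costs and
utilities accrue at cycle start with discount factor (1+r)**(-age); no
half-cycle correction is applied.

The engine is vectorised over an arbitrary draw axis so a full probabilistic
sensitivity analysis is a single pass.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .params import (
    TOPOLOGY_COMPLICATIONS,
    AgeBandedValue,
    ModelSettings,
    ParameterSet,
    iter_param_dists,
)
from .survival import WeibullParams, annual_death_probs

__all__ = [
    "STATE_NAMES",
    "ModelValues",
    "DiseaseValues",
    "PathwayResult",
    "StrategyResult",
    "CEAOutputs",
    "base_case_values",
    "sample_values",
    "branch_probabilities",
    "run_patient_markov",
    "normal_life_course",
    "run_strategy",
    "evaluate",
    "trace_to_frame",
]

STATE_NAMES = {
    "A": ("well", "neurological", "dead"),
    "B": ("well", "neurological", "renal", "neurological_renal", "dead"),
    "C": ("well", "neurological", "cardiomyopathy", "neurological_cardiomyopathy", "dead"),
}

COST_COMPONENTS = ("ipd", "opd", "formula", "pharma", "dnm", "productivity")


@dataclass
class DiseaseValues:
    """Sampled (or base-case) numeric inputs for one disease.

    Per-age arrays have shape (horizon, n); per-draw arrays shape (n,).
    """

    name: str
    topology: str
    incidence: np.ndarray
    comp_probs: dict[str, np.ndarray]          # complication -> (A, n) baseline annual prob
    q_disease: np.ndarray                      # (A, n) annual disease death prob (late)
    comp_rr: dict[str, np.ndarray]             # complication -> (n,) early multiplier
    mortality_multiplier: np.ndarray           # (n,) early multiplier on q_disease
    utilities: dict[str, np.ndarray]           # state -> (n,)
    costs: dict[str, np.ndarray]               # scalar components -> (n,)
    formula: np.ndarray                        # (A, n) THB/year


@dataclass
class ModelValues:
    """A numeric model input set, vectorised over ``n`` parameter draws."""

    n: int
    settings: ModelSettings
    uptake: np.ndarray
    confirmation_cost: np.ndarray
    tests: dict[str, dict]                     # name -> {sens, spec, cost, covered}
    diseases: dict[str, DiseaseValues]

    @property
    def horizon(self) -> int:
        return self.settings.horizon_years

    @property
    def q_other(self) -> np.ndarray:
        qx = np.asarray(self.settings.other_cause_qx, dtype=float)
        A = self.horizon
        if len(qx) < A:
            qx = np.concatenate([qx, np.full(A - len(qx), qx[-1])])
        return qx[:A]


def _expand_banded(banded: AgeBandedValue, samples: list[np.ndarray], ages: np.ndarray) -> np.ndarray:
    idx = banded.band_index(ages)
    stacked = np.stack([np.atleast_1d(s) for s in samples])
    return stacked[idx]


def _build_values(pset: ParameterSet, samples: Mapping[tuple, np.ndarray], n: int) -> ModelValues:
    A = pset.settings.horizon_years
    ages = np.arange(A, dtype=float)

    tests = {}
    for t in pset.tests:
        tests[t.name] = {
            "sensitivity": samples[("test", t.name, "sensitivity")],
            "specificity": samples[("test", t.name, "specificity")],
            "unit_cost": samples[("test", t.name, "unit_cost_thb")],
            "covered": t.diseases_covered,
        }

    diseases = {}
    for d in pset.diseases:
        comp_probs = {}
        for comp, banded in d.complication_hazards.items():
            vals = [samples[("disease", d.name, "complication", comp, str(i))]
                    for i in range(len(banded.bands))]
            comp_probs[comp] = _expand_banded(banded, vals, ages)

        if d.mortality is None:
            q_dis = np.zeros((A, n))
        elif isinstance(d.mortality, WeibullParams):
            q_dis = annual_death_probs(
                samples[("disease", d.name, "mortality", "log_lambda")],
                samples[("disease", d.name, "mortality", "log_gamma")],
                ages,
            )
        else:  # age-banded annual probability
            vals = [samples[("disease", d.name, "mortality", "band", str(i))]
                    for i in range(len(d.mortality.bands))]
            q_dis = _expand_banded(d.mortality, vals, ages)

        comp_rr = {c: samples[("disease", d.name, "early", "rr", c)]
                   for c in d.early.complication_rr}
        mv = samples[("disease", d.name, "early", "mortality_effect")]
        mort_mult = (1.0 - mv) if d.early.mortality_kind == "reduction" else mv

        costs = {k: samples[("disease", d.name, "cost", k)]
                 for k in ("ipd_first_year", "ipd_subsequent", "opd_annual", "pharma_annual",
                           "dnm_with_complication", "dnm_without_complication",
                           "productivity_with_complication", "productivity_without_complication")}
        fvals = [samples[("disease", d.name, "cost", "formula_annual", str(i))]
                 for i in range(len(d.costs.formula_annual.bands))]
        formula = _expand_banded(d.costs.formula_annual, fvals, ages)

        utilities = {s: samples[("disease", d.name, "utility", s)] for s in d.utilities}

        diseases[d.name] = DiseaseValues(
            name=d.name, topology=d.topology,
            incidence=samples[("disease", d.name, "incidence")],
            comp_probs=comp_probs, q_disease=np.clip(q_dis, 0.0, 1.0),
            comp_rr=comp_rr, mortality_multiplier=mort_mult,
            utilities=utilities, costs=costs, formula=formula,
        )

    return ModelValues(
        n=n, settings=pset.settings,
        uptake=samples[("settings", "uptake")],
        confirmation_cost=samples[("settings", "confirmation_cost_thb")],
        tests=tests, diseases=diseases,
    )


def base_case_values(pset: ParameterSet) -> ModelValues:
    """Deterministic inputs: every parameter at its mean."""
    samples = {path: np.array([pd.mean]) for path, pd in iter_param_dists(pset)}
    return _build_values(pset, samples, 1)


def sample_values(pset: ParameterSet, rng: np.random.Generator, n: int,
                  overrides: Mapping[tuple, float] | None = None) -> ModelValues:
    """Monte-Carlo inputs: every non-fixed parameter drawn from its family.

    ``overrides`` pins chosen paths to fixed values (used by the grouped
    one-way analysis); everything else is sampled.
    """
    samples = {}
    for path, dist in iter_param_dists(pset):
        if overrides is not None and path in overrides:
            samples[path] = np.full(n, float(overrides[path]))
        else:
            samples[path] = dist.sample(rng, n)
    return _build_values(pset, samples, n)


# ---------------------------------------------------------------------------
# traces


@dataclass
class PathwayResult:
    """Lifetime expectation for one disease under one diagnosis pathway."""

    disease: str
    pathway: str                                  # "early" | "late" | "normal"
    cost: np.ndarray                              # discounted THB (n,)
    ly: np.ndarray
    qaly: np.ndarray
    cost_undiscounted: np.ndarray
    ly_undiscounted: np.ndarray
    qaly_undiscounted: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)   # discounted, by component
    clamped_cells: int = 0
    trace: dict | None = None


def _clip_count(x: np.ndarray) -> tuple[np.ndarray, int]:
    bad = int(np.sum((x < 0) | (x > 1)))
    return np.clip(x, 0.0, 1.0), bad


def run_patient_markov(dv: DiseaseValues, pathway: str, mv: ModelValues,
                       keep_trace: bool = False) -> PathwayResult:
    """Lifetime trace for an affected child diagnosed early or late."""
    A = mv.horizon
    n = mv.n
    r = mv.settings.discount_rate
    disc = (1.0 + r) ** (-np.arange(A, dtype=float))
    q_oth = mv.q_other[:, None]

    states = STATE_NAMES[dv.topology]
    comps = TOPOLOGY_COMPLICATIONS[dv.topology]
    S = len(states)

    clamped = 0
    if pathway == "early":
        q_dis, c = _clip_count(dv.q_disease * dv.mortality_multiplier[None, :]); clamped += c
        p_comp = []
        for comp in comps:
            p, c = _clip_count(dv.comp_probs[comp] * dv.comp_rr[comp][None, :]); clamped += c
            p_comp.append(p)
    else:
        q_dis = dv.q_disease
        p_comp = [dv.comp_probs[comp] for comp in comps]
    p1 = p_comp[0]
    p2 = p_comp[1] if len(p_comp) > 1 else np.zeros_like(p1)

    p_death = 1.0 - (1.0 - q_dis) * (1.0 - q_oth)

    u = np.zeros((S, n))
    for i, s in enumerate(states[:-1]):
        u[i] = dv.utilities[s]

    occ = np.zeros((n, S))
    occ[:, 0] = 1.0

    zero = np.zeros(n)
    acc = {k: zero.copy() for k in
           ("cost", "ly", "qaly", "cost_u", "ly_u", "qaly_u")}
    comp_acc = {k: zero.copy() for k in COST_COMPONENTS}
    trace = {"occupancy": [occ.copy()], "direct_medical": [], "cost_total": []} if keep_trace else None

    for a in range(A):
        alive = 1.0 - occ[:, -1]
        well = occ[:, 0]
        with_comp = alive - well

        ipd = dv.costs["ipd_first_year"] if a == 0 else dv.costs["ipd_subsequent"]
        medical = ipd + dv.costs["opd_annual"] + dv.formula[a] + dv.costs["pharma_annual"]
        dnm = well * dv.costs["dnm_without_complication"] + with_comp * dv.costs["dnm_with_complication"]
        prod = (well * dv.costs["productivity_without_complication"]
                + with_comp * dv.costs["productivity_with_complication"])
        cost_cycle = alive * medical + dnm + prod
        utility_cycle = (occ.T * u).sum(axis=0)

        acc["cost"] += disc[a] * cost_cycle
        acc["cost_u"] += cost_cycle
        acc["ly"] += disc[a] * alive
        acc["ly_u"] += alive
        acc["qaly"] += disc[a] * utility_cycle
        acc["qaly_u"] += utility_cycle
        comp_acc["ipd"] += disc[a] * alive * ipd
        comp_acc["opd"] += disc[a] * alive * dv.costs["opd_annual"]
        comp_acc["formula"] += disc[a] * alive * dv.formula[a]
        comp_acc["pharma"] += disc[a] * alive * dv.costs["pharma_annual"]
        comp_acc["dnm"] += disc[a] * dnm
        comp_acc["productivity"] += disc[a] * prod
        if keep_trace:
            trace["direct_medical"].append(alive * medical)
            trace["cost_total"].append(cost_cycle)

        # transitions
        pd_, q1, q2 = p_death[a], p1[a], p2[a]
        new = np.zeros_like(occ)
        if S == 3:
            new[:, 0] = occ[:, 0] * (1 - pd_) * (1 - q1)
            new[:, 1] = occ[:, 0] * (1 - pd_) * q1 + occ[:, 1] * (1 - pd_)
            new[:, 2] = occ[:, 2] + (occ[:, 0] + occ[:, 1]) * pd_
        else:
            sw = occ[:, 0] * (1 - pd_)
            s1 = occ[:, 1] * (1 - pd_)
            s2 = occ[:, 2] * (1 - pd_)
            s3 = occ[:, 3] * (1 - pd_)
            new[:, 0] = sw * (1 - q1) * (1 - q2)
            new[:, 1] = sw * q1 * (1 - q2) + s1 * (1 - q2)
            new[:, 2] = sw * (1 - q1) * q2 + s2 * (1 - q1)
            new[:, 3] = sw * q1 * q2 + s1 * q2 + s2 * q1 + s3
            new[:, 4] = occ[:, 4] + (occ[:, :4].sum(axis=1)) * pd_
        occ = new
        if keep_trace:
            trace["occupancy"].append(occ.copy())

    if keep_trace:
        trace["occupancy"] = np.stack(trace["occupancy"])        # (A+1, n, S)
        trace["direct_medical"] = np.stack(trace["direct_medical"])  # (A, n)
        trace["cost_total"] = np.stack(trace["cost_total"])
        trace["states"] = states

    return PathwayResult(
        disease=dv.name, pathway=pathway,
        cost=acc["cost"], ly=acc["ly"], qaly=acc["qaly"],
        cost_undiscounted=acc["cost_u"], ly_undiscounted=acc["ly_u"],
        qaly_undiscounted=acc["qaly_u"],
        components=comp_acc, clamped_cells=clamped, trace=trace,
    )


def normal_life_course(mv: ModelValues, keep_trace: bool = False) -> PathwayResult:
    """Two-state (alive/dead) trace of an unaffected newborn: utility 1, no cost."""
    A = mv.horizon
    r = mv.settings.discount_rate
    disc = (1.0 + r) ** (-np.arange(A, dtype=float))
    q = mv.q_other
    alive = np.concatenate([[1.0], np.cumprod(1.0 - q)])[:A]
    ly = float((disc * alive).sum())
    ly_u = float(alive.sum())
    z = np.zeros(mv.n)
    ones = np.ones(mv.n)
    return PathwayResult(
        disease="none", pathway="normal",
        cost=z, ly=ly * ones, qaly=ly * ones,
        cost_undiscounted=z, ly_undiscounted=ly_u * ones, qaly_undiscounted=ly_u * ones,
    )


# ---------------------------------------------------------------------------
# decision tree


@dataclass
class StrategyResult:
    strategy: str
    cost: np.ndarray            # per-newborn expected discounted THB
    ly: np.ndarray
    qaly: np.ndarray
    cost_undiscounted: np.ndarray
    ly_undiscounted: np.ndarray
    qaly_undiscounted: np.ndarray
    screening_cost: np.ndarray
    confirmation_cost: np.ndarray
    p_early: dict[str, np.ndarray]
    expected_confirmations: np.ndarray


def branch_probabilities(strategy: str, disease: str, mv: ModelValues) -> np.ndarray:
    """P(an affected newborn is detected early) under a strategy.

    Expanded: uptake x MS/MS sensitivity for every covered disease.  Current:
    uptake x Guthrie sensitivity for PKU only; other diseases present
    clinically (late) — not an error, just undetected by screening.
    """
    test = mv.tests["msms"] if strategy == "expanded" else mv.tests["guthrie"]
    if disease in test["covered"]:
        return mv.uptake * test["sensitivity"]
    return np.zeros(mv.n)


def run_strategy(strategy: str, mv: ModelValues,
                 pathways: Mapping[str, Mapping[str, PathwayResult]],
                 normal: PathwayResult) -> StrategyResult:
    """Per-newborn expectation over the decision tree."""
    test = mv.tests["msms"] if strategy == "expanded" else mv.tests["guthrie"]
    total_inc = sum(dv.incidence for dv in mv.diseases.values())

    screening = test["unit_cost"] * mv.uptake
    p_early = {}
    true_pos = np.zeros(mv.n)
    for name, dv in mv.diseases.items():
        pe = branch_probabilities(strategy, name, mv)
        p_early[name] = pe
        if name in test["covered"]:
            true_pos = true_pos + dv.incidence * mv.uptake * test["sensitivity"]
    false_pos = (1.0 - total_inc) * mv.uptake * (1.0 - test["specificity"])
    confirmations = true_pos + false_pos
    confirmation = confirmations * mv.confirmation_cost

    def mix(attr):
        out = np.zeros(mv.n)
        for name, dv in mv.diseases.items():
            pe = p_early[name]
            out = out + dv.incidence * (pe * getattr(pathways[name]["early"], attr)
                                        + (1 - pe) * getattr(pathways[name]["late"], attr))
        return out

    cost = screening + confirmation + mix("cost")
    cost_u = screening + confirmation + mix("cost_undiscounted")
    ly = mix("ly") + (1 - total_inc) * normal.ly
    qaly = mix("qaly") + (1 - total_inc) * normal.qaly
    ly_u = mix("ly_undiscounted") + (1 - total_inc) * normal.ly_undiscounted
    qaly_u = mix("qaly_undiscounted") + (1 - total_inc) * normal.qaly_undiscounted

    return StrategyResult(
        strategy=strategy, cost=cost, ly=ly, qaly=qaly,
        cost_undiscounted=cost_u, ly_undiscounted=ly_u, qaly_undiscounted=qaly_u,
        screening_cost=screening, confirmation_cost=confirmation,
        p_early=p_early, expected_confirmations=confirmations,
    )


@dataclass
class CEAOutputs:
    """Everything one model evaluation produces, vectorised over draws."""

    pathways: dict[str, dict[str, PathwayResult]]
    normal: PathwayResult
    expanded: StrategyResult
    current: StrategyResult

    @property
    def delta_cost(self) -> np.ndarray:
        return self.expanded.cost - self.current.cost

    @property
    def delta_ly(self) -> np.ndarray:
        return self.expanded.ly - self.current.ly

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.expanded.qaly - self.current.qaly

    @property
    def delta_ly_undiscounted(self) -> np.ndarray:
        return self.expanded.ly_undiscounted - self.current.ly_undiscounted

    @property
    def delta_qaly_undiscounted(self) -> np.ndarray:
        return self.expanded.qaly_undiscounted - self.current.qaly_undiscounted

    @property
    def delta_cost_undiscounted(self) -> np.ndarray:
        return self.expanded.cost_undiscounted - self.current.cost_undiscounted


def evaluate(mv: ModelValues) -> CEAOutputs:
    """Run every pathway trace once and score both screening strategies."""
    pathways = {
        name: {pw: run_patient_markov(dv, pw, mv) for pw in ("early", "late")}
        for name, dv in mv.diseases.items()
    }
    normal = normal_life_course(mv)
    return CEAOutputs(
        pathways=pathways, normal=normal,
        expanded=run_strategy("expanded", mv, pathways, normal),
        current=run_strategy("current", mv, pathways, normal),
    )


def trace_to_frame(result: PathwayResult, draw: int = 0) -> pd.DataFrame:
    """Flatten a kept trace to one row per cycle per state."""
    if result.trace is None:
        raise ValueError("run the pathway with keep_trace=True first")
    occ = result.trace["occupancy"]                 # (A+1, n, S)
    states = result.trace["states"]
    rows = []
    for a in range(occ.shape[0] - 1):
        for s, state in enumerate(states):
            rows.append({
                "cycle": a, "state": state,
                "occupancy": occ[a, draw, s],
                "cost_cycle_undiscounted": result.trace["cost_total"][a, draw] if s == 0 else np.nan,
            })
    return pd.DataFrame(rows)
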