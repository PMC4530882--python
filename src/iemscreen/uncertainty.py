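"""Probabilistic and grouped one-way sensitivity analysis.

The PSA draws every non-fixed parameter from its moment-matched distribution
(beta for probabilities and utilities, gamma for costs, lognormal for
relative risks, normal-on-log-scale for Weibull coefficients), re-runs both
screening strategies per draw and summarises the incremental cost, QALY and
ICER distributions.

The one-way analysis works on thirteen grouped factors: each group's members
are pinned simultaneously at the same 95% CI bound (mean +/- 1.96 SE clamped
to the family's support; formula and pharmaceutical costs, which carry no SE,
move +/-50% of the mean) while every other parameter is sampled
probabilistically; the spread of the mean ICER between the two bounds ranks
the factors in the tornado diagram.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CEAOutputs, evaluate, sample_values
from .params import ParameterSet, iter_param_dists

__all__ = [
    "FACTORS",
    "PSASummary",
    "TornadoEntry",
    "run_psa",
    "psa_frame",
    "one_way",
    "tornado",
    "factor_members",
]

# the thirteen grouped one-way factors: id -> predicate over parameter paths
FACTORS: dict[str, callable] = {
    "incidence": lambda p: p[0] == "disease" and p[2] == "incidence",
    "complication_probability": lambda p: p[0] == "disease" and p[2] == "complication",
    "relative_risk": lambda p: p[0] == "disease" and p[2] == "early" and p[3] == "rr",
    "utility": lambda p: p[0] == "disease" and p[2] == "utility",
    "first_year_ipd_opd": lambda p: p[0] == "disease" and p[2] == "cost"
    and p[3] in ("ipd_first_year", "opd_annual"),
    "later_direct_medical": lambda p: p[0] == "disease" and p[2] == "cost"
    and p[3] == "ipd_subsequent",
    "formula_pharma": lambda p: p[0] == "disease" and p[2] == "cost"
    and p[3] in ("formula_annual", "pharma_annual"),
    "dnm_with_complication": lambda p: p[0] == "disease" and p[2] == "cost"
    and p[3] == "dnm_with_complication",
    "dnm_without_complication": lambda p: p[0] == "disease" and p[2] == "cost"
    and p[3] == "dnm_without_complication",
    "productivity_with_complication": lambda p: p[0] == "disease" and p[2] == "cost"
    and p[3] == "productivity_with_complication",
    "productivity_without_complication": lambda p: p[0] == "disease" and p[2] == "cost"
    and p[3] == "productivity_without_complication",
    "uptake": lambda p: p == ("settings", "uptake"),
    "msms_screening_cost": lambda p: p == ("test", "msms", "unit_cost_thb"),
}

#: factors whose inputs carry no SE and are varied +/-50% of the mean instead
_HALF_RANGE_FACTORS = {"formula_pharma"}


def factor_members(pset: ParameterSet, factor: str) -> list[tuple]:
    if factor not in FACTORS:
        raise KeyError(f"unknown one-way factor {factor!r}; known: {sorted(FACTORS)}")
    pred = FACTORS[factor]
    return [path for path, _ in iter_param_dists(pset) if pred(path)]


@dataclass(frozen=True)
class PSASummary:
    n_draws: int
    mean_delta_cost: float
    mean_delta_qaly: float
    mean_delta_ly: float
    ci_delta_cost: tuple[float, float]
    ci_delta_qaly: tuple[float, float]
    ci_icer: tuple[float, float]
    icer_ratio_of_means: float
    icer_mean_of_ratios: float
    quadrant_fractions: dict[str, float]   # NE / NW / SE / SW of the CE plane

    @property
    def fraction_north_east(self) -> float:
        return self.quadrant_fractions["NE"]


def _summarise(dc: np.ndarray, dq: np.ndarray, dly: np.ndarray) -> PSASummary:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(dq != 0, dc / dq, np.nan)
    quads = {
        "NE": float(np.mean((dc > 0) & (dq > 0))),
        "NW": float(np.mean((dc > 0) & (dq <= 0))),
        "SE": float(np.mean((dc <= 0) & (dq > 0))),
        "SW": float(np.mean((dc <= 0) & (dq <= 0))),
    }
    lo, hi = np.percentile(ratios[np.isfinite(ratios)], [2.5, 97.5])
    return PSASummary(
        n_draws=len(dc),
        mean_delta_cost=float(dc.mean()),
        mean_delta_qaly=float(dq.mean()),
        mean_delta_ly=float(dly.mean()),
        ci_delta_cost=tuple(np.percentile(dc, [2.5, 97.5])),
        ci_delta_qaly=tuple(np.percentile(dq, [2.5, 97.5])),
        ci_icer=(float(lo), float(hi)),
        icer_ratio_of_means=float(dc.mean() / dq.mean()),
        icer_mean_of_ratios=float(np.nanmean(ratios)),
        quadrant_fractions=quads,
    )


def run_psa(pset: ParameterSet, n: int = 1000, seed: int | np.random.SeedSequence = 0,
            ) -> tuple[CEAOutputs, PSASummary]:
    """Monte-Carlo propagation of all parameter uncertainty.

    Returns the vectorised model outputs (one slot per draw) and their
    summary.  Identical seeds give identical draws.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    mv = sample_values(pset, rng, n)
    out = evaluate(mv)
    return out, _summarise(out.delta_cost, out.delta_qaly, out.delta_ly)


def psa_frame(out: CEAOutputs) -> pd.DataFrame:
    """Draw-level results, one row per simulation round."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(out.delta_qaly != 0, out.delta_cost / out.delta_qaly, np.nan)
    return pd.DataFrame({
        "draw": np.arange(len(out.delta_cost)),
        "delta_cost_thb": out.delta_cost,
        "delta_ly": out.delta_ly,
        "delta_qaly": out.delta_qaly,
        "icer_thb_per_qaly": ratio,
    })


def _bound_value(dist, factor: str, which: str) -> float:
    if factor in _HALF_RANGE_FACTORS:
        return dist.mean * (1.5 if which == "upper" else 0.5)
    return dist.ci_bound(which)


def one_way(pset: ParameterSet, factor: str, bound: str, n: int = 500,
            seed: int | np.random.SeedSequence = 0) -> float:
    """Mean ICER with one grouped factor pinned at its lower or upper bound.

    All member parameters move to the same bound simultaneously; every other
    parameter is sampled from its distribution.  The ICER is summarised as
    the ratio of mean incremental cost to mean incremental QALYs, which is
    stable when single-draw QALY differences approach zero.
    """
    if bound not in ("lower", "upper"):
        raise ValueError("bound must be 'lower' or 'upper'")
    dists = dict(iter_param_dists(pset))
    overrides = {path: _bound_value(dists[path], factor, bound)
                 for path in factor_members(pset, factor)}
    rng = np.random.default_rng(seed)
    mv = sample_values(pset, rng, n, overrides=overrides)
    out = evaluate(mv)
    return float(out.delta_cost.mean() / out.delta_qaly.mean())


@dataclass(frozen=True)
class TornadoEntry:
    factor: str
    icer_lower: float
    icer_upper: float

    @property
    def spread(self) -> float:
        return abs(self.icer_upper - self.icer_lower)


def tornado(pset: ParameterSet, n: int = 500,
            seed: int | np.random.SeedSequence = 0) -> list[TornadoEntry]:
    """Grouped one-way results for all thirteen factors, widest spread first.

    The same seed (hence the same background draws) is reused for every
    factor and bound so spreads reflect the factor, not Monte-Carlo noise.
    """
    entries = []
    for factor in FACTORS:
        lo = one_way(pset, factor, "lower", n=n, seed=seed)
        hi = one_way(pset, factor, "upper", n=n, seed=seed)
        entries.append(TornadoEntry(factor=factor, icer_lower=lo, icer_upper=hi))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "factor": e.factor,
        "icer_lower_bound": e.icer_lower,
        "icer_upper_bound": e.icer_upper,
        "spread": e.spread,
    } for e in entries])
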