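"""Cost-effectiveness arithmetic: ICERs, currency conversion, NMB, CEAC.

The incremental cost-effectiveness ratio compares the expanded screening
programme against current practice: ICER = (C1 - C0) / (E1 - E0), in THB per
life year or per QALY gained.  Results convert to international dollars at
the 2013 purchasing-power parity of 17.79 THB per I$, and are judged against
the Thai willingness-to-pay threshold of 120,000 THB per QALY.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PPP_THB_PER_INTL_DOLLAR",
    "Dominance",
    "CEAResult",
    "CEACCurve",
    "icer",
    "to_international_dollars",
    "net_monetary_benefit",
    "cea_result",
    "ceac",
    "ceac_crossover",
]

PPP_THB_PER_INTL_DOLLAR = 17.79


class Dominance(str, enum.Enum):
    dominant = "dominant"      # cheaper and more effective
    dominated = "dominated"    # costlier and less effective
    tradeoff = "tradeoff"      # an ICER is meaningful


class UndefinedICERError(ZeroDivisionError):
    pass


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio; raises if the effect delta is 0."""
    if delta_effect == 0:
        raise UndefinedICERError("effect difference is zero; ICER undefined")
    return delta_cost / delta_effect


def dominance(delta_cost: float, delta_effect: float) -> Dominance:
    if delta_cost < 0 and delta_effect > 0:
        return Dominance.dominant
    if delta_cost > 0 and delta_effect < 0:
        return Dominance.dominated
    return Dominance.tradeoff


def to_international_dollars(thb, ppp: float = PPP_THB_PER_INTL_DOLLAR):
    """Convert 2013 THB to international dollars at purchasing-power parity."""
    return np.asarray(thb, dtype=float) / ppp if np.ndim(thb) else thb / ppp


def net_monetary_benefit(delta_cost, delta_qaly, threshold: float):
    """NMB = threshold * dQALY - dCost; positive favours the new strategy."""
    if threshold < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return threshold * np.asarray(delta_qaly, dtype=float) - np.asarray(delta_cost, dtype=float)


@dataclass(frozen=True)
class CEAResult:
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    dominance_flag: Dominance

    @property
    def icer_per_ly(self) -> float:
        return icer(self.delta_cost, self.delta_ly)

    @property
    def icer_per_qaly(self) -> float:
        return icer(self.delta_cost, self.delta_qaly)


def cea_result(delta_cost: float, delta_ly: float, delta_qaly: float) -> CEAResult:
    return CEAResult(float(delta_cost), float(delta_ly), float(delta_qaly),
                     dominance(float(delta_cost), float(delta_qaly)))


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is cost-effective across thresholds."""

    thresholds: np.ndarray
    p_expanded: np.ndarray

    @property
    def p_current(self) -> np.ndarray:
        return 1.0 - self.p_expanded


DEFAULT_THRESHOLDS = np.arange(0.0, 3_000_001.0, 10_000.0)


def ceac(delta_cost, delta_qaly, thresholds=None) -> CEACCurve:
    """Fraction of simulation draws with positive net monetary benefit.

    Draws exactly at NMB = 0 count toward the comparator, so with two
    strategies the probabilities are complementary at every threshold.
    """
    dc = np.asarray(delta_cost, dtype=float)
    dq = np.asarray(delta_qaly, dtype=float)
    if dc.size == 0:
        raise ValueError("at least one simulation draw required")
    thr = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, dtype=float)
    nmb = thr[:, None] * dq[None, :] - dc[None, :]
    return CEACCurve(thresholds=thr, p_expanded=(nmb > 0).mean(axis=1))


def ceac_crossover(curve: CEACCurve) -> float:
    """First threshold at which the expanded strategy is favoured (p > 0.5).

    Returns NaN if the curve never crosses within the grid.
    """
    above = curve.p_expanded > 0.5
    if not above.any():
        return float("nan")
    return float(curve.thresholds[int(np.argmax(above))])
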