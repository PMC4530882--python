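"""Model inputs: distribution-tagged parameters, moment matching and sampling.

Every quantity the cost-utility model consumes — screening test accuracy,
disease incidences, annual complication probabilities, Weibull mortality
coefficients, treatment costs and health-state utilities — is represented as
a :class:`ParamDist`: a sampling family (beta / gamma / lognormal / fixed)
plus a natural-scale mean and standard error.  Probabilistic sensitivity
analysis draws every non-fixed parameter from its moment-matched
distribution; the base case uses the means.

The bundled parameter file (``data/parameters.yaml``) transcribes the Thai
newborn-screening evaluation inputs in 2013 THB, and
``data/thai_life_table_2013.csv`` carries an approximate Thai 2013 period
life table for death from other causes.
"""
from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Family",
    "ParamDist",
    "AgeBand",
    "AgeBandedValue",
    "ScreeningTest",
    "EarlyEffect",
    "CostSchedule",
    "DiseaseSpec",
    "ModelSettings",
    "ParameterSet",
    "SchemaError",
    "moment_match_beta",
    "moment_match_gamma",
    "lognormal_from_mean_se",
    "load_parameters",
    "load_default_parameters",
    "load_life_table",
    "iter_param_dists",
]

DISEASES = ("PKU", "IVA", "MMA", "PA", "MSUD", "MCD")

#: complication sets per Markov topology
TOPOLOGY_COMPLICATIONS = {
    "A": ("neurological",),
    "B": ("neurological", "renal"),
    "C": ("neurological", "cardiomyopathy"),
}


class Family(str, enum.Enum):
    beta = "beta"
    gamma = "gamma"
    lognormal = "lognormal"
    fixed = "fixed"


class SchemaError(ValueError):
    """Aggregated parameter-file validation failure."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("parameter file invalid:\n" + "\n".join(f"  - {e}" for e in self.errors))


class InfeasibleVarianceError(ValueError):
    pass


def moment_match_beta(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the requested mean and variance se**2.

    Requires 0 < mean < 1 and se**2 < mean*(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0,1), got {mean}")
    var = se * se
    if var <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if var >= mean * (1.0 - mean):
        raise InfeasibleVarianceError(
            f"variance {var} >= mean(1-mean) = {mean * (1 - mean)}; no beta distribution exists"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def moment_match_gamma(mean: float, se: float) -> tuple[float, float]:
    """Gamma(shape, scale) with the requested mean and variance se**2."""
    if mean <= 0 or se <= 0:
        raise ValueError(f"gamma moment matching needs mean > 0 and se > 0, got ({mean}, {se})")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def lognormal_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the requested natural-scale moments."""
    if mean <= 0:
        raise ValueError(f"lognormal mean must be positive, got {mean}")
    sigma2 = math.log1p((se / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class ParamDist:
    """A model input tagged with its sampling family.

    ``mean`` and ``se`` are on the natural scale except when
    ``log_scale=True`` (used for Weibull survival coefficients): then they are
    the mean and normal dispersion of the *log* parameter, i.e. the (mu,
    sigma) of a lognormal on the natural scale.
    """

    family: Family
    mean: float
    se: float | None = None
    log_scale: bool = False

    def __post_init__(self):
        if self.family is Family.beta and not self.log_scale and not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"beta-family mean must lie in [0,1], got {self.mean}")
        if self.family is Family.gamma and self.mean < 0:
            raise ValueError(f"gamma-family mean must be >= 0, got {self.mean}")
        if self.se is not None and self.se < 0:
            raise ValueError(f"se must be >= 0, got {self.se}")

    @property
    def is_fixed(self) -> bool:
        """Fixed families, absent SEs, and degenerate beta means are not sampled."""
        if self.family is Family.fixed or self.se is None or self.se == 0:
            return True
        if self.family is Family.beta and not self.log_scale and self.mean in (0.0, 1.0):
            return True
        if self.family is Family.lognormal and not self.log_scale and self.mean == 0.0:
            return True
        if self.family is Family.gamma and self.mean == 0.0:
            return True
        return False

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` values; fixed parameters return the mean verbatim."""
        if self.log_scale:
            # natural-scale parameter exp(x), x ~ Normal(mean, se)
            if self.se is None or self.se == 0:
                return np.full(n, self.mean)
            return rng.normal(self.mean, self.se, size=n)
        if self.is_fixed:
            return np.full(n, self.mean)
        if self.family is Family.beta:
            a, b = moment_match_beta(self.mean, self.se)
            return rng.beta(a, b, size=n)
        if self.family is Family.gamma:
            shape, scale = moment_match_gamma(self.mean, self.se)
            return rng.gamma(shape, scale, size=n)
        if self.family is Family.lognormal:
            mu, sigma = lognormal_from_mean_se(self.mean, self.se)
            return rng.lognormal(mu, sigma, size=n)
        raise AssertionError(f"unhandled family {self.family}")

    def ci_bound(self, which: str) -> float:
        """95% CI bound (mean +/- 1.96 SE) clamped to the family's support."""
        if self.is_fixed and not self.log_scale:
            return self.mean
        z = 1.96 if which == "upper" else -1.96
        x = self.mean + z * (self.se or 0.0)
        if self.log_scale:
            return x
        if self.family is Family.beta:
            return min(max(x, 0.0), 1.0)
        if self.family in (Family.gamma, Family.lognormal):
            return max(x, 0.0)
        return x


def fixed(value: float) -> ParamDist:
    return ParamDist(Family.fixed, value)


@dataclass(frozen=True)
class AgeBand:
    start: float
    end: float | None  # None = open-ended
    value: ParamDist


@dataclass(frozen=True)
class AgeBandedValue:
    """Contiguous, non-overlapping age bands from birth; last band open-ended."""

    bands: tuple[AgeBand, ...]

    def __post_init__(self):
        if not self.bands:
            raise ValueError("at least one age band required")
        if self.bands[0].start != 0:
            raise ValueError("first age band must start at 0")
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if prev.end is None or prev.end != nxt.start:
                raise ValueError("age bands must be contiguous and non-overlapping")
        if self.bands[-1].end is not None:
            raise ValueError("final age band must be open-ended")

    def band_index(self, ages: np.ndarray) -> np.ndarray:
        edges = [b.start for b in self.bands[1:]]
        return np.searchsorted(edges, ages, side="right")

    def at_ages(self, ages: np.ndarray, values: Sequence[np.ndarray] | None = None) -> np.ndarray:
        """Per-age array (len(ages), ...) using band means or supplied samples."""
        idx = self.band_index(np.asarray(ages, dtype=float))
        if values is None:
            vals = np.array([b.value.mean for b in self.bands])
            return vals[idx]
        stacked = np.stack([np.atleast_1d(v) for v in values])  # (n_bands, n)
        return stacked[idx]


@dataclass(frozen=True)
class ScreeningTest:
    name: str
    sensitivity: ParamDist
    specificity: ParamDist
    unit_cost_thb: ParamDist
    diseases_covered: frozenset[str]


@dataclass(frozen=True)
class EarlyEffect:
    """Effect of pre-symptomatic (screen-detected) treatment vs clinical diagnosis.

    ``complication_rr`` multiplies the annual complication probabilities;
    ``mortality_kind`` is ``"rr"`` (hazard multiplier = value) or
    ``"reduction"`` (multiplier = 1 - value), applied to the disease-specific
    death probability only — death from other causes is untouched.
    """

    complication_rr: Mapping[str, ParamDist]
    mortality_kind: str
    mortality_value: ParamDist

    def __post_init__(self):
        if self.mortality_kind not in ("rr", "reduction"):
            raise ValueError(f"mortality effect kind must be rr|reduction, got {self.mortality_kind}")


@dataclass(frozen=True)
class CostSchedule:
    """Annual treatment cost components, 2013 THB per patient-year."""

    ipd_first_year: ParamDist
    ipd_subsequent: ParamDist
    opd_annual: ParamDist
    pharma_annual: ParamDist
    formula_annual: AgeBandedValue
    dnm_with_complication: ParamDist
    dnm_without_complication: ParamDist
    productivity_with_complication: ParamDist
    productivity_without_complication: ParamDist


@dataclass(frozen=True)
class DiseaseSpec:
    name: str
    incidence: ParamDist
    topology: str  # A | B | C
    complication_hazards: Mapping[str, AgeBandedValue]
    mortality: object  # WeibullParams | AgeBandedValue | None
    early: EarlyEffect
    costs: CostSchedule
    utilities: Mapping[str, ParamDist]  # health-state -> utility weight

    def __post_init__(self):
        expected = set(TOPOLOGY_COMPLICATIONS[self.topology])
        got = set(self.complication_hazards)
        if got != expected:
            raise ValueError(
                f"{self.name}: topology {self.topology} requires complications {sorted(expected)}, got {sorted(got)}"
            )


@dataclass(frozen=True)
class ModelSettings:
    discount_rate: float = 0.03
    cycle_length_years: float = 1.0
    horizon_years: int = 100
    uptake: ParamDist = field(default_factory=lambda: fixed(0.97))
    confirmation_cost_thb: ParamDist = field(default_factory=lambda: fixed(2349.0))
    threshold_thb_per_qaly: float = 120_000.0
    ppp_thb_per_intl_dollar: float = 17.79
    other_cause_qx: tuple[float, ...] = ()  # annual death probability, age 0..len-1

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.horizon_years < 1:
            raise ValueError("horizon must be >= 1 year")


@dataclass(frozen=True)
class ParameterSet:
    settings: ModelSettings
    diseases: tuple[DiseaseSpec, ...]
    tests: tuple[ScreeningTest, ...]

    def disease(self, name: str) -> DiseaseSpec:
        for d in self.diseases:
            if d.name == name:
                return d
        raise KeyError(name)

    def test(self, name: str) -> ScreeningTest:
        for t in self.tests:
            if t.name == name:
                return t
        raise KeyError(name)


# ---------------------------------------------------------------------------
# parameter-file loading


def _dist(node, key: str, errors: list[str], log_scale: bool = False) -> ParamDist:
    try:
        fam = Family(node.get("family", "fixed"))
        return ParamDist(fam, float(node["mean"]),
                         None if node.get("se") is None else float(node["se"]),
                         log_scale=log_scale)
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"{key}: {exc}")
        return fixed(0.0)


def _banded(node, key: str, errors: list[str]) -> AgeBandedValue:
    bands = []
    for i, b in enumerate(node):
        bands.append(AgeBand(float(b["start"]),
                             None if b.get("end") is None else float(b["end"]),
                             _dist(b["value"], f"{key}[{i}].value", errors)))
    try:
        return AgeBandedValue(tuple(bands))
    except ValueError as exc:
        errors.append(f"{key}: {exc}")
        return AgeBandedValue((AgeBand(0.0, None, fixed(0.0)),))


def _formula_banded(node, key: str, errors: list[str]) -> AgeBandedValue:
    """Formula costs printed as per-band ranges become per-year bands with
    linearly interpolated fixed values across each range."""
    bands: list[AgeBand] = []
    for i, b in enumerate(node):
        start = float(b["start"])
        end = None if b.get("end") is None else float(b["end"])
        if "low" in b:  # a range over the band, interpolated per single year
            if end is None:
                errors.append(f"{key}[{i}]: open-ended band cannot carry a range")
                continue
            ages = np.arange(start, end)
            vals = np.linspace(float(b["low"]), float(b["high"]), len(ages))
            for a, v in zip(ages, vals):
                bands.append(AgeBand(float(a), float(a + 1), fixed(float(v))))
        else:
            bands.append(AgeBand(start, end, _dist(b["value"], f"{key}[{i}].value", errors)))
    try:
        return AgeBandedValue(tuple(bands))
    except ValueError as exc:
        errors.append(f"{key}: {exc}")
        return AgeBandedValue((AgeBand(0.0, None, fixed(0.0)),))


def _utilities(node, key: str, errors: list[str]) -> dict[str, ParamDist]:
    out = {}
    for state, d in node.items():
        pd = _dist(d, f"{key}.{state}", errors)
        if not 0.0 <= pd.mean <= 1.0:
            errors.append(f"{key}.{state}: utility {pd.mean} outside [0,1]")
        out[state] = pd
    return out


def load_life_table(path: str | Path | None = None) -> tuple[float, ...]:
    """Annual probability of death from other causes, indexed by age."""
    if path is None:
        ref = resources.files("iemscreen.data") / "thai_life_table_2013.csv"
        with resources.as_file(ref) as p:
            return load_life_table(p)
    qx: list[float] = []
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            qx.append(float(row["qx"]))
    if not qx:
        raise SchemaError(["life table is empty"])
    return tuple(qx)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a structured-text parameter file.

    Validation problems are aggregated and raised together as a
    :class:`SchemaError` naming every offending key.
    """
    path = Path(path)
    with open(path) as f:
        doc = yaml.safe_load(f)
    errors: list[str] = []

    s = doc.get("settings", {})
    life_path = s.get("life_table")
    if life_path is not None:
        life_path = (path.parent / life_path) if not Path(life_path).is_absolute() else life_path
        qx = load_life_table(life_path)
    else:
        qx = load_life_table()
    try:
        settings = ModelSettings(
            discount_rate=float(s.get("discount_rate", 0.03)),
            cycle_length_years=float(s.get("cycle_length_years", 1.0)),
            horizon_years=int(s.get("horizon_years", 100)),
            uptake=_dist(s["uptake"], "settings.uptake", errors),
            confirmation_cost_thb=_dist(s["confirmation_cost_thb"], "settings.confirmation_cost_thb", errors),
            threshold_thb_per_qaly=float(s.get("threshold_thb_per_qaly", 120_000)),
            ppp_thb_per_intl_dollar=float(s.get("ppp_thb_per_intl_dollar", 17.79)),
            other_cause_qx=qx,
        )
    except (KeyError, ValueError) as exc:
        errors.append(f"settings: {exc}")
        settings = ModelSettings(other_cause_qx=qx)

    tests = []
    for t in doc.get("screening_tests", []):
        name = t.get("name", "?")
        tests.append(ScreeningTest(
            name=name,
            sensitivity=_dist(t["sensitivity"], f"screening_tests.{name}.sensitivity", errors),
            specificity=_dist(t["specificity"], f"screening_tests.{name}.specificity", errors),
            unit_cost_thb=_dist(t["unit_cost_thb"], f"screening_tests.{name}.unit_cost_thb", errors),
            diseases_covered=frozenset(t.get("diseases_covered", [])),
        ))

    diseases = []
    for d in doc.get("diseases", []):
        name = d.get("name", "?")
        key = f"diseases.{name}"
        topology = d.get("topology", "A")
        comps: dict[str, AgeBandedValue] = {}
        for comp, bands in d.get("complications", {}).items():
            comps[comp] = _banded(bands, f"{key}.complications.{comp}", errors)
        for comp in TOPOLOGY_COMPLICATIONS.get(topology, ()):
            if comp not in comps:
                errors.append(f"{key}.complications.{comp}: missing for topology {topology}")

        mort_node = d.get("mortality")
        mortality: object
        if mort_node is None or mort_node.get("kind") == "none":
            mortality = None
        elif mort_node["kind"] == "weibull":
            from .survival import WeibullParams  # local import; no cycle at module load
            mortality = WeibullParams(
                log_lambda=_dist(mort_node["log_lambda"], f"{key}.mortality.log_lambda", errors, log_scale=True),
                log_gamma=_dist(mort_node["log_gamma"], f"{key}.mortality.log_gamma", errors, log_scale=True),
            )
        elif mort_node["kind"] == "age_banded":
            mortality = _banded(mort_node["bands"], f"{key}.mortality", errors)
        else:
            errors.append(f"{key}.mortality.kind: unknown kind {mort_node.get('kind')!r}")
            mortality = None

        e = d.get("early", {})
        early = EarlyEffect(
            complication_rr={c: _dist(v, f"{key}.early.complication_rr.{c}", errors)
                             for c, v in e.get("complication_rr", {}).items()},
            mortality_kind=e.get("mortality_effect", {}).get("kind", "rr"),
            mortality_value=_dist(e.get("mortality_effect", {}).get("value", {"mean": 1.0}),
                                  f"{key}.early.mortality_effect", errors),
        )

        c = d.get("costs", {})

        def cost(k: str) -> ParamDist:
            if k not in c:
                errors.append(f"{key}.costs.{k}: missing")
                return fixed(0.0)
            pd = _dist(c[k], f"{key}.costs.{k}", errors)
            if pd.mean < 0:
                errors.append(f"{key}.costs.{k}: negative cost {pd.mean}")
            return pd

        costs = CostSchedule(
            ipd_first_year=cost("ipd_first_year"),
            ipd_subsequent=cost("ipd_subsequent"),
            opd_annual=cost("opd_annual"),
            pharma_annual=cost("pharma_annual"),
            formula_annual=_formula_banded(c.get("formula_annual", [{"start": 0, "value": {"mean": 0}}]),
                                           f"{key}.costs.formula_annual", errors),
            dnm_with_complication=cost("dnm_with_complication"),
            dnm_without_complication=cost("dnm_without_complication"),
            productivity_with_complication=cost("productivity_with_complication"),
            productivity_without_complication=cost("productivity_without_complication"),
        )

        utilities = _utilities(d.get("utilities", {}), f"{key}.utilities", errors)
        try:
            diseases.append(DiseaseSpec(
                name=name,
                incidence=_dist(d["incidence"], f"{key}.incidence", errors),
                topology=topology,
                complication_hazards=comps,
                mortality=mortality,
                early=early,
                costs=costs,
                utilities=utilities,
            ))
        except (KeyError, ValueError) as exc:
            errors.append(f"{key}: {exc}")

    if errors:
        raise SchemaError(errors)
    return ParameterSet(settings=settings, diseases=tuple(diseases), tests=tuple(tests))


def load_default_parameters() -> ParameterSet:
    """The bundled 2013 Thai parameter set."""
    ref = resources.files("iemscreen.data") / "parameters.yaml"
    with resources.as_file(ref) as p:
        return load_parameters(p)


# ---------------------------------------------------------------------------
# parameter registry (used by the PSA and the grouped one-way analysis)


def iter_param_dists(pset: ParameterSet) -> Iterator[tuple[tuple[str, ...], ParamDist]]:
    """Yield (path, ParamDist) for every sampleable input in the set.

    Paths are stable identifiers like ``("disease", "PKU", "incidence")`` or
    ``("settings", "uptake")``; the uncertainty module groups them into the
    one-way factors.
    """
    from .survival import WeibullParams

    yield ("settings", "uptake"), pset.settings.uptake
    yield ("settings", "confirmation_cost_thb"), pset.settings.confirmation_cost_thb
    for t in pset.tests:
        yield ("test", t.name, "sensitivity"), t.sensitivity
        yield ("test", t.name, "specificity"), t.specificity
        yield ("test", t.name, "unit_cost_thb"), t.unit_cost_thb
    for d in pset.diseases:
        yield ("disease", d.name, "incidence"), d.incidence
        for comp, banded in d.complication_hazards.items():
            for i, band in enumerate(banded.bands):
                yield ("disease", d.name, "complication", comp, str(i)), band.value
        if isinstance(d.mortality, AgeBandedValue):
            for i, band in enumerate(d.mortality.bands):
                yield ("disease", d.name, "mortality", "band", str(i)), band.value
        elif isinstance(d.mortality, WeibullParams):
            yield ("disease", d.name, "mortality", "log_lambda"), d.mortality.log_lambda
            yield ("disease", d.name, "mortality", "log_gamma"), d.mortality.log_gamma
        for comp, rr in d.early.complication_rr.items():
            yield ("disease", d.name, "early", "rr", comp), rr
        yield ("disease", d.name, "early", "mortality_effect"), d.early.mortality_value
        cs = d.costs
        for k in ("ipd_first_year", "ipd_subsequent", "opd_annual", "pharma_annual",
                  "dnm_with_complication", "dnm_without_complication",
                  "productivity_with_complication", "productivity_without_complication"):
            yield ("disease", d.name, "cost", k), getattr(cs, k)
        for i, band in enumerate(cs.formula_annual.bands):
            yield ("disease", d.name, "cost", "formula_annual", str(i)), band.value
        for state, u in d.utilities.items():
            yield ("disease", d.name, "utility", state), u
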