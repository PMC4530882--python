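"""Synthetic registry generation and survival-model recovery.

Simulates a hospital record review shaped like the original 119-patient
registry, then re-estimates the Weibull death hazard from the censored
records and compares Weibull vs exponential by AIC.
"""
import numpy as np

from iemscreen.params import load_default_parameters
from iemscreen.registry import HISTORICAL_REGISTRY_SIZES, RegistrySpec, generate_registry
from iemscreen.survival import WeibullParams, fit_exponential, fit_weibull, select_by_aic

pset = load_default_parameters()
spec = RegistrySpec(
    n_per_disease={d: 50 * n for d, n in HISTORICAL_REGISTRY_SIZES.items()},  # scaled-up review
    mortality={d.name: d.mortality if isinstance(d.mortality, WeibullParams) else None
               for d in pset.diseases},
    complication_probs={d.name: dict(d.complication_hazards) for d in pset.diseases},
    seed=42,
)
records = generate_registry(spec)
print(f"generated {len(records)} patient records "
      f"({sum(r.event == 'died' for r in records)} deaths)")

for disease in ("IVA", "MMA"):
    recs = [r for r in records if r.disease == disease]
    times = np.array([r.time_years for r in recs])
    events = np.array([r.event == "died" for r in recs])
    best = select_by_aic([fit_weibull(times, events), fit_exponential(times, events)])
    truth = pset.disease(disease).mortality
    print(f"{disease}: selected {best.family:11} "
          f"log-lambda {best.params.log_lambda.mean:+.3f} (true {truth.log_lambda.mean:+.3f})  "
          f"log-gamma {best.params.log_gamma.mean:+.3f} (true {truth.log_gamma.mean:+.3f})")

print()
print("With enough patients the censored MLE recovers the generating")
print("coefficients and AIC keeps the Weibull whenever the hazard is not flat.")
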