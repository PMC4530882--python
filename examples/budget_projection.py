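"""Ten-year budget impact of introducing the MS/MS programme.

Projects undiscounted calendar-year budgets (million THB) for the expanded
programme vs the status quo: screening of 750,000 births/year with uptake
ramping 80% -> 100%, 0.5% annual cost inflation, and the accumulating
direct-medical treatment cost of screen-detected patients.
"""
from iemscreen.budget import BIASettings, project_budget
from iemscreen.params import load_default_parameters

pset = load_default_parameters()
table = project_budget(pset, BIASettings())

cols = ["year", "expanded_screening_mthb", "expanded_treatment_mthb",
        "expanded_total_mthb", "status_quo_total_mthb", "difference_mthb"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:9.1f}"))
print()
print("Screening spend is roughly flat once uptake saturates; treatment spend")
print("grows every year because each new birth cohort adds surviving patients")
print("who need lifelong care. The final row totals the ten-year budgets.")
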