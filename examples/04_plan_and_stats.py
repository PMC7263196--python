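"""Plan the genome-wide combinatorial experiment and compute its statistics.

16 targets x 3 alternative-base oligos x 4 sgRNAs = 192 electroporations;
exactly one alternative per base is a transition, so oligo rows split 64/128
transition/transversion.  Colony counts then give editing efficiency
(white/(white+red), Wilson 95% CI) and survival (CFU/ug).
"""

import pandas as pd

from pinpoint import build_plan, efficiency, survival_rate, tally_edit_classes
from pinpoint.experiment_stats import TargetPlanSpec, success_table

specs = [TargetPlanSpec(f"t{i + 1:02d}", "ACGT"[i % 4]) for i in range(16)]
plan = build_plan(specs)
n_ts, n_tv = tally_edit_classes(plan)
print(f"plan: {len(plan)} electroporations, {plan['oligo'].nunique()} oligos, "
      f"{n_ts} transition rows / {n_tv} transversion rows")

est = efficiency(white=95, red=5)
print(f"\nefficiency for 95 white / 5 red colonies: "
      f"{est.point:.2f} (95% CI {est.ci_low:.2f}-{est.ci_high:.2f}, n={est.n})")
print(f"survival for 34 colonies, 0.2 ug DNA, 2e5 dilution: "
      f"{survival_rate(34, 0.2, 2e5):.2e} CFU/ug")

records = pd.DataFrame(
    [{"edit_class": "transversion", "pairing": "Py:Py", "n_sequenced": 3, "n_edited": e}
     for e in (2, 1, 0, 3)]
    + [{"edit_class": "transition", "pairing": "Pu:Py", "n_sequenced": 3, "n_edited": 0}] * 3
)
print("\nsuccess table (success = >=1 of 3 sequenced colonies edited):")
print(success_table(records).to_string(index=False))

# pct_of_electroporations counts successful electroporations; pct_of_colonies
# counts edited colonies — both denominators are reported.
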