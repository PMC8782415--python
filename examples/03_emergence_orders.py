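"""Enumerate and filter gene-class emergence scenarios.

All 13 weak orders of {AGL6, E, A} after the fixed B -> CD prefix are
screened by two formability rules (no flower without E once A exists; no
sound development with E but without AGL6), leaving the two admissible
evolutionary paths.
"""

import floralquant as fq

model = fq.default_model()
scenarios = fq.enumerate_weak_orders(["AGL6", "E", "A"], fixed_prefix=("B", "CD"))
admissible, audit = fq.admissible_orders(model, scenarios, fq.default_rules())

print(f"{len(scenarios)} candidate scenarios (ordered Bell number for 3 classes)")
for a in audit:
    status = "ADMISSIBLE" if a.admissible else f"rejected by {a.eliminated_by}"
    print(f"  {a.scenario.describe():38s} {status}")

print(f"\n{len(admissible)} admissible orders; stage-by-stage organ formation:")
for s in admissible:
    print(f"  {s.describe()}")
    for st in fq.scenario_timeline(model, s):
        print(f"    stage {st.stage}: present={sorted(st.present)} -> "
              f"formable organs {sorted(st.formable) or '(none)'}")
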