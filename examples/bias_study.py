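"""Quantify readmission-rate bias from linkage error under two scenarios.

Runs a reduced version of the simulation study: populations of 20,000
individuals with an 8.8% readmission prevalence are linked in two stages
(deterministic on the unique identifier, then probabilistic at a 1%
false-match rate) under each weight variant, for a 30% completely-random
unique-id error (scenario A) and the same 30% concentrated in pairs that
also err on another identifier (scenario C).
"""

import linkvar as lv

gen = lv.GeneratorConfig(n_individuals=20_000, n_hospitals=50)
for scenario in ("A", "C"):
    res = lv.run_study(gen, lv.ScenarioConfig(scenario), n_reps=20, seed=5)
    print(f"\nscenario {scenario} (true readmission rate "
          f"{100 * res.true_rate:.2f}%, {res.n_reps} replicates)")
    print(res.to_frame().round(3).to_string(index=False))

print(
    "\nNegative % bias means readmissions are under-counted because missed\n"
    "matches split one readmitted patient into two apparent single-admission\n"
    "patients. Attribute- and organisation-specific weights recover part of\n"
    "that loss; the dependence scenario (C) hurts every method most."
)
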