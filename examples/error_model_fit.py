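"""Model identifier-error risk by individual attributes and hospital.

Builds per-(pair x identifier) error records from synthetic matched pairs,
fits a multilevel logistic regression (hospital random intercept, adaptive
Gauss-Hermite quadrature) and prints odds ratios, the between-hospital
variance, and how many hospitals fall outside 99.8% funnel control limits.
"""

import linkvar as lv

cfg = lv.GeneratorConfig(n_individuals=40_000, readmission_prob=0.5,
                         n_hospitals=40, seed=2)
pairs, _ = lv.generate_population(cfg)
records = lv.build_error_records(pairs)

fit = lv.fit_error_model(records, include_random_effect=True)
print(f"fitted on {fit.n_obs} error records ({fit.method}); converged={fit.converged}")
print(f"between-hospital variance (log-odds scale): {fit.hospital_variance:.3f}\n")
print(f"{'term':<24} {'OR':>6}   95% CI")
for term in fit.fixed_effects:
    if term == "intercept":
        continue
    or_, lo, hi = fit.odds_ratio(term)
    print(f"{term:<24} {or_:>6.3f}   ({lo:.3f}, {hi:.3f})")

dep = lv.test_pairwise_dependence(pairs, "date_of_birth", "postcode")
print(
    f"\ndob-vs-postcode error dependence: OR {dep.odds_ratio:.2f}, "
    f"p = {dep.p_value:.3f}"
)

funnel = lv.funnel_table(records)
n_out = int(funnel["outlier_0.998"].sum())
print(f"hospitals outside 99.8% funnel limits: {n_out} of {len(funnel)}")
print(
    "\nOdds ratios below 1 mark groups whose identifiers are recorded more\n"
    "reliably; the hospital variance and funnel count quantify how much\n"
    "recording quality clusters by organisation."
)
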