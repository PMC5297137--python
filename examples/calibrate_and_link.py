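"""Calibrate a classification threshold at a 1% false-match rate and link.

Scores candidate pairs under traditional and attribute-specific weights,
picks the lowest weight cut-off whose acceptance region keeps the
false-match rate at or below 1%, and compares the sensitivity achieved by
the two weighting schemes at the same error guarantee.
"""

import linkvar as lv

schema = lv.IdentifierSchema()
cfg = lv.GeneratorConfig(n_individuals=80_000, n_hospitals=30, seed=3)
train, _ = lv.generate_population(cfg)
train = lv.prefilter_pairs(train, schema)

test, _ = lv.generate_population(
    lv.GeneratorConfig(n_individuals=20_000, n_hospitals=30, seed=4)
)
test = lv.prefilter_pairs(test, schema)

for variant in ("traditional", "attribute"):
    model = lv.fit_weight_model(train, schema, variant, min_stratum_matches=100)
    scored = lv.score_pairs(test, model)
    thr = lv.calibrate_threshold(scored, target_fmr=0.01)
    decisions = lv.classify(scored, thr.cutoff)
    metrics = lv.linkage_metrics(decisions, scored["is_match"].astype(bool))
    print(
        f"{variant:<12} cutoff {thr.cutoff:>6.2f}  accepted {thr.n_accepted:>5}"
        f"  sensitivity {metrics.sensitivity:.3f}"
        f"  false-match rate {metrics.false_match_rate:.4f}"
    )

print(
    "\nBoth schemes respect the same 1% false-match guarantee, but the\n"
    "attribute-specific weights re-rank pairs within strata whose postcode\n"
    "is often missing, recovering true matches the single global weight\n"
    "table has to reject."
)
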