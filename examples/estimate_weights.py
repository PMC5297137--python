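"""Estimate m/u probabilities and match weights from a labelled pair set.

Generates a small synthetic extract of matched and non-matched record pairs,
drops the pattern classes assumed to be non-matches (no agreement, or
sex-only agreement), then prints per-identifier m/u probabilities and the
match weight of every agreement pattern under the traditional (independence)
and joint (pattern-level) schemes.
"""

import linkvar as lv

schema = lv.IdentifierSchema()
cfg = lv.GeneratorConfig(
    n_individuals=60_000, n_hospitals=25, n_nonmatch_pairs=1_500_000, seed=1
)
pairs, _ = lv.generate_population(cfg)
pairs = lv.prefilter_pairs(pairs, schema)

mu = lv.estimate_mu_independent(pairs, schema)
joint = lv.estimate_mu_joint(pairs, schema)

print(f"{mu.n_matches} matches, {mu.n_nonmatches} retained non-matches")
print("\nidentifier        m (agree|match)   u (agree|non-match)")
for name in schema.names:
    print(f"{name:<16} {mu.m(name):>12.4f} {mu.u(name):>16.4f}")

print("\npattern {dob,sex,postcode}   traditional W   joint W")
for pat in lv.enumerate_patterns(schema):
    wt = lv.weight_traditional(pat, mu)
    wj = lv.weight_joint(pat, joint)
    print(f"  {pat.as_string():<24} {wt:>10.1f} {wj:>9.1f}")

print(
    "\nWeights are log2 likelihood ratios: a pair with weight W is 2^W times\n"
    "more likely under the match than the non-match hypothesis. Full\n"
    "agreement scores highest, and because ~half of matched pairs lack a\n"
    "usable postcode, the *penalty* term for disagreeing on postcode is\n"
    "under one bit - far milder than for date of birth or sex."
)
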