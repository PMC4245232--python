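"""Pool study-level standardised effects with the random-effects model.

Shows the empirical-Bayes between-study variance, Cochran's Q
heterogeneity test, and the inverse-variance pooled effect with a normal
95% interval.
"""

import medimeta as mm

# six study-level estimates (posterior mean y, posterior variance v)
estimates = [
    mm.EffectEstimate(sid, "indirect", y, v, y - 2 * v**0.5, y + 2 * v**0.5)
    for sid, y, v in [
        ("s1", 0.12, 0.04), ("s2", -0.05, 0.09), ("s3", 0.30, 0.05),
        ("s4", 0.22, 0.11), ("s5", 0.01, 0.03), ("s6", 0.45, 0.15),
    ]
]

m = mm.random_effects_meta(estimates)
print(f"pooled effect: {m.pooled:+.3f}  [{m.ci_low:+.3f}, {m.ci_high:+.3f}]  p = {m.p:.3f}")
print(f"tau^2 = {m.tau2:.3f} (SE {m.tau2_se:.3f})  -- between-study variance")
print(f"Q({m.df}) = {m.Q:.2f}, p = {m.p_Q:.3f}      -- heterogeneity test")
# tau^2 = 0 with a non-significant Q means the studies are statistically
# consistent: one common effect explains them all.
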