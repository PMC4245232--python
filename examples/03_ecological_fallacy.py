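"""Why the pooled mediator-outcome correlation is the wrong test.

Builds two groups offset on both the mediator and the outcome but with
no association between them *within* either group.  The naive regression
through all animals finds a strong "effect"; the ANCOVA within-group
slope, which is the individual-level test, does not.
"""

import numpy as np

import medimeta as mm

rng = np.random.default_rng(7)
n = 30
T = np.array([0.0] * n + [1.0] * n)
M = rng.normal(size=2 * n) + 4 * T  # treated animals: more new neurons
Y = rng.normal(size=2 * n) + 4 * T  # ... and better behaviour, but not BECAUSE of M

study = mm.StandardizedStudy(
    T=T, M=mm.standardize(M), Y=mm.standardize(Y),
    meta=mm.StudyMeta(study_id="two-clusters", control_group="ctrl"),
)
res = mm.within_group_association(study)
report = mm.ecological_gap(res)

print(f"pooled slope (ignoring groups): {res.pooled_slope:+.3f}  p = {res.pooled_p:.2g}")
print(f"within-group slope (ANCOVA):    {res.within_slope:+.3f}  p = {res.within_p:.2g}")
print(f"ecological-fallacy flag: {report.flag}")
print(report.message)
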