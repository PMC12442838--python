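"""Competing indirect effects: why raw RTs can hide real changes.

Working while answering lowers both the drift rate (slower access to
affect information -> slower RTs) and the boundary separation (less
caution -> faster RTs).  The two indirect paths pull the observed RT in
opposite directions, so the total effect can be near zero even though the
process changes are real.  This example builds scored data with exactly
that structure and recovers it with a 1-1-1 mediation model.
"""
import numpy as np
import pandas as pd

from emadiff import multilevel

rng = np.random.default_rng(7)
J, n = 400, 12
g = np.repeat(np.arange(J), n)
work = (rng.random((J, n)) < 0.3).astype(float)
# work lowers drift (a1 < 0) and lowers boundary (a2 < 0); drift speeds RTs
# up (b1 < 0) and boundary slows them down (b2 > 0)
drift = -0.25 * work + rng.normal(0, 1, (J, n)) + rng.normal(0, 0.5, J)[:, None]
bound = -0.13 * work + rng.normal(0, 1, (J, n)) + rng.normal(0, 0.5, J)[:, None]
log_rt = (-0.2 * drift + 0.19 * bound + rng.normal(0, 0.6, (J, n))
          + rng.normal(0, 0.4, J)[:, None])
df = pd.DataFrame({"work": work.ravel(), "drift": drift.ravel(),
                   "boundary": bound.ravel(), "log_rt": log_rt.ravel(), "g": g})

med = multilevel.fit_mediation(df, "work", ("drift", "boundary"), "log_rt", "g",
                               predictor_level="within", seed=1)
print("path               estimate")
for m in med.mediators:
    print(f"a ({med.predictor} -> {m}):   {med.a_paths[m]:+.3f}")
    print(f"b ({m} -> RT):    {med.b_paths[m]:+.3f}")
print(f"direct effect c':        {med.direct:+.3f}")
print(f"total effect c:          {med.total:+.3f}")
for m in med.mediators:
    lo, hi = med.indirect_ci[m]
    print(f"indirect via {m:9s} {med.indirect_std[m]:+.4f}  95% CI [{lo:+.4f}, {hi:+.4f}]")
# Expect a positive indirect effect through drift and a negative one through
# boundary (opposite signs, both intervals excluding 0) while the total
# effect stays small -- the cancellation pattern that raw RTs cannot reveal.
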