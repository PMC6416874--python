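"""Where does the mean-substitution power approximation break down?

Evaluates exact and approximate power over a grid of predictor means and
variances for a fixed coefficient shift.  The approximation error grows
with the predictor variance (whose noncentrality contribution it drops)
and shrinks as the predictor mean moves the intercept-level term away
from zero.
"""

import itertools

from regpower import EffectSpec, PredictorSpec, power_approx, power_exact

effect = EffectSpec.simple(0.3, 1.3, 0.0, 1.0, error_variance=1.0)
n = 60

print(f"{'mu_X':>5} {'var_X':>6} {'exact':>8} {'approx':>8} {'shortfall':>10}")
for mu, var in itertools.product((0.0, 0.5, 1.0), (0.5, 1.0, 2.0)):
    predictor = PredictorSpec.simple(mu, var)
    pe = power_exact(effect, predictor, n).power
    pa = power_approx(effect, predictor, n).power
    print(f"{mu:5.1f} {var:6.1f} {pe:8.4f} {pa:8.4f} {pa - pe:10.4f}")

# Every shortfall is negative: replacing random predictors by their mean
# can only lose power.  At mu_X = 0 the approximate noncentrality collapses
# to N * beta_ID^2 / sigma^2 and the shortfall is dramatic.
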