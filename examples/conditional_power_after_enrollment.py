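"""Conditional power once the predictor values are in hand.

Before a study, power must be averaged over the predictor distribution
(unconditional).  After enrollment, the observed predictor mean and
scatter are known and power conditions on them — a single noncentral F
tail probability.  This script draws one realized design and compares
the two notions.
"""

from regpower import (
    DesignSummary,
    EffectSpec,
    PredictorSpec,
    generate_predictors,
    power_conditional,
    power_exact,
)

effect = EffectSpec.simple(0.3, 1.3, 0.0, 1.0, error_variance=1.0)
predictor = PredictorSpec.simple(mean=0.5, variance=1.0)
n = 48

unconditional = power_exact(effect, predictor, n).power
print(f"planning (unconditional) power: {unconditional:.4f}")

for seed in (1, 2, 3):
    x = generate_predictors(predictor, n, seed=seed)
    design = DesignSummary.from_predictors(x)
    res = power_conditional(effect, design, 0.05)
    print(f"realized design {seed}: xbar = {design.xbar[0]:+.3f}, "
          f"SSX = {design.scatter[0, 0]:6.1f} -> "
          f"conditional power {res.power:.4f}")

# Individual designs scatter around the planning value: a lucky draw with
# large predictor spread gives more power, an unlucky one less.  The
# unconditional formula is exactly the average of these over designs.
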