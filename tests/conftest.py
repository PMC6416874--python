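import itertools

import numpy as np
import pytest

from regpower import EffectSpec, PredictorSpec, StudyCell


@pytest.fixture(scope="session")
def fetal_effect():
    """Fetal-weight validation benchmark: log-birthweight regression on the
    summed ultrasound measurements, tested against the published formula."""
    return EffectSpec.simple(4.1, 0.15, 4.198, 0.143, error_variance=0.095)


@pytest.fixture(scope="session")
def fetal_predictor():
    return PredictorSpec.simple(mean=24.2, variance=6.0)


def shift_cell(d, mu, sigma2_x, family="normal", sigma2=1.0):
    """Benchmark cell: both coefficients shifted by d off the null (0, 1)."""
    return StudyCell(
        effect=EffectSpec.simple(d, 1.0 + d, 0.0, 1.0, sigma2),
        predictor=PredictorSpec.simple(mu, sigma2_x, family),
    )


def stress_grid():
    """Configurations spanning small-to-moderate effects, predictor means,
    variances and sample sizes, used by the dominance/monotonicity/quadrature
    property tests."""
    return [
        (d, mu, sx2, n)
        for d, mu, sx2, n in itertools.product(
            (0.1, 0.3, 0.5), (0.0, 0.5, 1.0), (0.5, 1.0, 2.0), (20, 50, 100, 200)
        )
    ]


def batched_joint_f(x, y, theta, crit):
    """Vectorised joint F test, re-derived independently of the package's
    batched path: per-replicate normal equations assembled from sufficient
    statistics.  x: (R, n, p); y: (R, n)."""
    r, n, p = x.shape
    xf = np.concatenate([np.ones((r, n, 1)), x], axis=2)
    gram = np.einsum("rni,rnj->rij", xf, xf)
    beta = np.linalg.solve(gram, np.einsum("rni,rn->ri", xf, y)[..., None])[..., 0]
    resid = y - np.einsum("rni,ri->rn", xf, beta)
    sigma2 = np.einsum("rn,rn->r", resid, resid) / (n - p - 1)
    diff = beta - theta
    f = np.einsum("ri,rij,rj->r", diff, gram, diff) / (p + 1) / sigma2
    return f > crit
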