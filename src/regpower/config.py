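"""Plain-text (YAML) study configuration.

A study file mirrors the in-memory types block by block::

    effect:
      true: [4.1, 0.15]
      null: [4.198, 0.143]
      sigma2: 0.095          # or sigma: 0.3082... (squared on ingestion)
    predictor:
      mu: 24.2               # scalar for p = 1, list for p > 1
      sigma2_x: 6.0          # scalar variance, or covariance: [[...], ...]
      family: normal
    test:
      alpha: 0.05
      target_power: 0.80     # exactly one of target_power / n
      method: exact
    simulation:
      replicates: 10000
      seed: 1
    output:
      precision: 4

Command-line flags compose with a config file; flags win.  Reports emitted
by the CLI are themselves valid YAML whose ``config`` block round-trips
through this parser.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .errors import InputError
from .specs import EffectSpec, PredictorSpec

__all__ = ["StudyConfig", "load_config", "parse_config"]


@dataclass(frozen=True)
class StudyConfig:
    """Fully resolved study request."""

    effect: EffectSpec
    predictor: PredictorSpec
    alpha: float = 0.05
    n: Optional[int] = None
    target_power: Optional[float] = None
    method: str = "exact"
    replicates: int = 10_000
    seed: int = 0
    precision: int = 4

    def __post_init__(self):
        if (self.n is None) == (self.target_power is None):
            raise InputError(
                "exactly one of 'n' and 'target_power' must be given"
            )

    def to_dict(self) -> dict:
        """Round-trippable plain representation (valid config content)."""
        cov = self.predictor.covariance
        pred: dict = {"family": self.predictor.family}
        if self.predictor.p == 1:
            pred["mu"] = float(self.predictor.mean[0])
            pred["sigma2_x"] = float(cov[0, 0])
        else:
            pred["mu"] = self.predictor.mean.tolist()
            pred["covariance"] = cov.tolist()
        test: dict = {"alpha": self.alpha, "method": self.method}
        if self.n is not None:
            test["n"] = self.n
        else:
            test["target_power"] = self.target_power
        return {
            "effect": {
                "true": self.effect.true_coefficients.tolist(),
                "null": self.effect.null_coefficients.tolist(),
                "sigma2": self.effect.error_variance,
            },
            "predictor": pred,
            "test": test,
            "simulation": {"replicates": self.replicates, "seed": self.seed},
            "output": {"precision": self.precision},
        }


def _need(block: dict, key: str, where: str):
    if key not in block:
        raise InputError(f"config: missing '{key}' in the {where} block")
    return block[key]


def parse_config(data: dict) -> StudyConfig:
    """Build a :class:`StudyConfig` from parsed YAML content."""
    if not isinstance(data, dict):
        raise InputError("config: top level must be a mapping")
    eff = _need(data, "effect", "top-level")
    # YAML reads bare `true:` / `null:` keys as the boolean True and None;
    # accept those spellings alongside quoted strings
    eff = {
        {True: "true", None: "null"}.get(k, k): v for k, v in eff.items()
    }
    true = np.atleast_1d(_need(eff, "true", "effect"))
    null = np.atleast_1d(_need(eff, "null", "effect"))
    if "sigma2" in eff:
        sigma2 = float(eff["sigma2"])
    elif "sigma" in eff:
        sigma2 = float(eff["sigma"]) ** 2
    else:
        raise InputError("config: effect block needs 'sigma2' (or 'sigma')")
    effect = EffectSpec(true, null, sigma2)

    pred = _need(data, "predictor", "top-level")
    mu = np.atleast_1d(_need(pred, "mu", "predictor"))
    if "covariance" in pred:
        cov = np.atleast_2d(pred["covariance"])
    elif "sigma2_x" in pred:
        cov = np.diag(np.broadcast_to(np.atleast_1d(pred["sigma2_x"]), mu.shape))
    else:
        raise InputError(
            "config: predictor block needs 'sigma2_x' or 'covariance'"
        )
    predictor = PredictorSpec(mu, cov, pred.get("family", "normal"))

    test = data.get("test", {})
    sim = data.get("simulation", {})
    out = data.get("output", {})
    n = test.get("n")
    target = test.get("target_power")
    return StudyConfig(
        effect=effect,
        predictor=predictor,
        alpha=float(test.get("alpha", 0.05)),
        n=None if n is None else int(n),
        target_power=None if target is None else float(target),
        method=str(test.get("method", "exact")),
        replicates=int(sim.get("replicates", 10_000)),
        seed=int(sim.get("seed", 0)),
        precision=int(out.get("precision", 4)),
    )


def load_config(path) -> StudyConfig:
    """Read and parse a YAML study-configuration file."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise InputError(f"config: not valid YAML ({exc})") from None
    return parse_config(data)
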