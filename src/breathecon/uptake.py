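"""Uptake (acceptance) probabilities of service configurations.

A configured service is modelled as a take-it-or-leave-it offer against the
opt-out (utility 0), so p(uptake) = expit(U) where U is the configuration's
fitted utility.  Confidence intervals propagate coefficient uncertainty by
the delta method on U (then mapped through the inverse logit, which keeps the
interval inside (0,1)), or by respondent-cluster bootstrap when the raw
choice data are available.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .choice_model import Z975, BootstrapCI, CoefficientSet, cluster_bootstrap
from .design import (
    Attribute,
    ChoiceDataset,
    ServiceConfiguration,
    UnknownLevelError,
    validate_configuration,
)


@dataclass
class UptakeEstimate:
    configuration: ServiceConfiguration
    utility: float
    probability: float
    ci95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "configuration": "opt_out" if self.configuration.is_opt_out
            else dict(self.configuration.levels),
            "utility": self.utility,
            "probability": self.probability,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
        }


def configuration_utility(
    coeffs: CoefficientSet,
    config: ServiceConfiguration,
    design: Sequence[Attribute] | None = None,
) -> float:
    """U = ASC + sum of the configuration's level coefficients.

    Level keys missing from ``betas`` contribute zero (reference levels under
    dummy coding).  Published vectors carrying a weight for every level are
    handled identically — the sum just includes them all.  Linear-coded
    attributes need ``design`` to map the level to its numeric value.
    """
    if config.is_opt_out:
        return 0.0
    if design is not None:
        validate_configuration(config, design)
        linear = {a.name: a for a in design if a.coding == "linear"}
    else:
        linear = {}
    u = coeffs.asc
    for attr_name, level in config.levels.items():
        if attr_name in linear:
            beta = coeffs.betas.get(attr_name)
            if beta is not None:
                u += beta * linear[attr_name].level_value(level)
            continue
        key = f"{attr_name}:{level}"
        if key in coeffs.betas:
            u += coeffs.betas[key]
        elif design is None and not any(
            k.partition(":")[0] == attr_name for k in coeffs.betas
        ):
            raise UnknownLevelError(
                f"no coefficient matches attribute {attr_name!r} (level {level!r}) "
                "and no design was supplied to resolve it"
            )
        # otherwise: reference level, contributes 0
    return float(u)


def _utility_gradient(
    coeffs: CoefficientSet,
    config: ServiceConfiguration,
    design: Sequence[Attribute] | None,
) -> np.ndarray:
    """dU/dtheta in the coefficient ordering ["asc", *betas]."""
    linear = {a.name: a for a in design if a.coding == "linear"} if design else {}
    g = np.zeros(1 + len(coeffs.betas))
    if config.is_opt_out:
        return g
    g[0] = 1.0
    for i, key in enumerate(coeffs.betas, start=1):
        attr_name, _, level = key.partition(":")
        if key in config_keys(config):
            g[i] = 1.0
        elif attr_name in linear and attr_name in config.levels and not level:
            g[i] = linear[attr_name].level_value(config.levels[attr_name])
    return g


def config_keys(config: ServiceConfiguration) -> set[str]:
    return {f"{a}:{l}" for a, l in config.levels.items()}


def uptake_probability(
    coeffs: CoefficientSet,
    config: ServiceConfiguration,
    design: Sequence[Attribute] | None = None,
) -> UptakeEstimate:
    """Point uptake probability with a delta-method CI when a covariance exists."""
    u = configuration_utility(coeffs, config, design)
    p = float(expit(u))
    ci: tuple[float, float] | None = None
    if coeffs.vcov is not None and not config.is_opt_out:
        g = _utility_gradient(coeffs, config, design)
        var_u = float(g @ coeffs.vcov @ g)
        if not np.isfinite(var_u) or var_u < 0:
            raise ValueError(f"utility variance is not finite/non-negative: {var_u}")
        half = Z975 * np.sqrt(var_u)
        ci = (float(expit(u - half)), float(expit(u + half)))
    return UptakeEstimate(config, u, p, ci)


def uptake_probability_bootstrap(
    dataset: ChoiceDataset,
    config: ServiceConfiguration,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Cluster-bootstrap CI for p(uptake): resample respondents, refit, expit(U)."""
    return cluster_bootstrap(
        dataset,
        n_boot=n_boot,
        seed=seed,
        statistic=lambda cs: float(
            expit(configuration_utility(cs, config, dataset.design))
        ),
    )


def rank_configurations(
    coeffs: CoefficientSet,
    configs: Sequence[ServiceConfiguration],
    design: Sequence[Attribute] | None = None,
) -> list[UptakeEstimate]:
    """Uptake estimates sorted descending; ties broken by configuration key."""
    if not configs:
        raise ValueError("need at least one configuration to rank")
    estimates = [uptake_probability(coeffs, c, design) for c in configs]
    estimates.sort(key=lambda e: (-e.probability, e.configuration.key()))
    return estimates


def utility_increment(p_from: float, p_to: float) -> float:
    """Logit-scale increment that moves an uptake probability from p_from to p_to."""
    return float(logit(p_to) - logit(p_from))


def configuration_ladder() -> list[ServiceConfiguration]:
    """Seven service configurations from least to most preferred.

    Starting from the least-valued package (GP surgery, non-medicinal review
    only, no support, 8-week wait), each step adds one improvement: a
    medicinal treatment review, therapist-and-social-worker support, shorter
    waits (4 then 2 weeks), then home visits, then outpatient clinics.
    """
    steps = [
        {"place": "GP surgery", "review": "non-medicinal only",
         "support": "none", "waiting": "8 weeks"},
        {"place": "GP surgery", "review": "medicinal and non-medicinal",
         "support": "none", "waiting": "8 weeks"},
        {"place": "GP surgery", "review": "medicinal and non-medicinal",
         "support": "therapists and social worker", "waiting": "8 weeks"},
        {"place": "GP surgery", "review": "medicinal and non-medicinal",
         "support": "therapists and social worker", "waiting": "4 weeks"},
        {"place": "GP surgery", "review": "medicinal and non-medicinal",
         "support": "therapists and social worker", "waiting": "2 weeks"},
        {"place": "home visit", "review": "medicinal and non-medicinal",
         "support": "therapists and social worker", "waiting": "2 weeks"},
        {"place": "outpatient clinic", "review": "medicinal and non-medicinal",
         "support": "therapists and social worker", "waiting": "2 weeks"},
    ]
    return [ServiceConfiguration(s) for s in steps]
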