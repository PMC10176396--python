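"""Synthetic inputs for every pipeline stage, with known ground truth.

The study geometry this emulates: roughly 256 respondents answering 6 choice
tasks of 3 alternatives each, a two-arm 12-week trial supplying per-cycle
cost and EQ-5D payoffs, and a national life table.  Everything is seedable
and ships with a sidecar-able truth record so estimators can be tested for
recovery.

The default preference truth combines the published point estimates for the
place/review/support levels and the any-service constant with *synthetic*
placeholder waiting-time coefficients (waiting-time weights were never
printed in text form and are not invented as real): 2 weeks +0.15, 4 weeks
+0.05, 8 weeks -0.20.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .choice_model import CoefficientSet
from .design import (
    Attribute,
    ChoiceDataset,
    default_design,
    generate_choice_tasks,
)
from .markov import (
    CohortSpec,
    MortalitySchedule,
    Scenario,
    StatePayoff,
    make_strategy,
)
from .psa import ParamDistribution
from .uptake import configuration_utility

#: Published preference weights (utility units) for the varying attributes.
PRINTED_PREFERENCE_BETAS = {
    "place:GP surgery": -0.30,
    "place:outpatient clinic": 0.16,
    "place:home visit": 0.15,
    "review:medicinal and non-medicinal": 0.15,
    "support:none": -0.23,
    "support:social worker alone": -0.15,
    "support:therapists and social worker": 0.19,
}

#: Synthetic placeholders — waiting-time weights are not published in text
#: form.  Shorter waits carry higher utility.
SYNTHETIC_WAITING_BETAS = {
    "waiting:2 weeks": 0.15,
    "waiting:4 weeks": 0.05,
    "waiting:8 weeks": -0.20,
}

DEFAULT_ASC = 1.52  # the any-service constant


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset (write alongside it as a sidecar).

    Trial payoff defaults are anchored to the published incremental results:
    a per-cycle health/social-care cost of ~£2000 under usual care, a saving
    of ~£780/cycle while the service effect lasts, an EQ-5D gain of 0.06, and
    per-patient noise that reproduces the printed CI widths at ~100 patients
    per arm.
    """

    true_coefficients: CoefficientSet
    control_cycle_cost: float = 2000.0
    cycle_cost_saving: float = 780.0
    control_utility: float = 0.70
    utility_gain: float = 0.06
    cost_sd: float = 1750.0
    utility_sd: float = 0.155
    utility_bounds: tuple[float, float] = (-0.6, 1.0)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["true_coefficients"] = self.true_coefficients.to_dict()
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        data["true_coefficients"] = CoefficientSet.from_dict(data["true_coefficients"])
        data["utility_bounds"] = tuple(data["utility_bounds"])
        return cls(**data)


def default_truth(seed: int = 0) -> SyntheticTruth:
    """The default ground truth: printed preference weights + trial-anchored payoffs."""
    coeffs = CoefficientSet(
        asc=DEFAULT_ASC,
        betas={**PRINTED_PREFERENCE_BETAS, **SYNTHETIC_WAITING_BETAS},
        vcov=None,
    )
    return SyntheticTruth(true_coefficients=coeffs, seed=seed)


# ---------------------------------------------------------------------------
# choice data
# ---------------------------------------------------------------------------

def simulate_choice_data(
    design: Sequence[Attribute],
    truth: SyntheticTruth | CoefficientSet,
    n_respondents: int,
    n_tasks: int,
    seed: int,
) -> ChoiceDataset:
    """Draw choices from the softmax over true utilities (opt-out utility 0).

    Equivalent to adding independent Gumbel errors to each alternative's
    utility and picking the maximum.
    """
    coeffs = truth.true_coefficients if isinstance(truth, SyntheticTruth) else truth
    rng = np.random.default_rng(seed)
    dataset = generate_choice_tasks(design, n_respondents, n_tasks, rng=rng)
    cache: dict[str, float] = {}
    for task in dataset.tasks:
        utilities = np.empty(3)
        for j, alt in enumerate(task.alternatives):
            key = alt.key()
            if key not in cache:
                cache[key] = configuration_utility(coeffs, alt, design)
            utilities[j] = cache[key]
        e = np.exp(utilities - utilities.max())
        task.chosen_index = int(rng.choice(3, p=e / e.sum()))
    return dataset


# ---------------------------------------------------------------------------
# trial payoffs
# ---------------------------------------------------------------------------

@dataclass
class ArmSummary:
    cost_mean: float
    cost_se: float
    utility_mean: float
    utility_se: float


@dataclass
class TrialPayoffs:
    """Arm-level payoff summaries from a simulated two-arm trial."""

    control: ArmSummary
    intervention: ArmSummary
    n_per_arm: int
    n_resampled: int = 0

    def state_payoffs(self) -> tuple[StatePayoff, StatePayoff]:
        """(usual-care payoff, effect payoff) with variances of the means."""
        usual = StatePayoff(
            cycle_cost=self.control.cost_mean,
            cycle_utility=self.control.utility_mean,
            cost_var=self.control.cost_se**2,
            utility_var=self.control.utility_se**2,
        )
        effect = StatePayoff(
            cycle_cost=self.intervention.cost_mean,
            cycle_utility=self.intervention.utility_mean,
            cost_var=self.intervention.cost_se**2,
            utility_var=self.intervention.utility_se**2,
        )
        return usual, effect


def synth_trial_payoffs(
    truth: SyntheticTruth,
    n_patients_per_arm: int = 100,
    seed: int = 0,
) -> TrialPayoffs:
    """Per-patient gamma costs and bounded-normal EQ-5D utilities, summarised per arm.

    Utility draws outside ``truth.utility_bounds`` are resampled (counted).
    """
    if not np.isfinite([truth.cycle_cost_saving, truth.utility_gain]).all():
        raise ValueError("effect sizes must be finite")
    lo, hi = truth.utility_bounds
    for name, m in (
        ("control", truth.control_utility),
        ("intervention", truth.control_utility + truth.utility_gain),
    ):
        if not lo <= m <= hi:
            raise ValueError(f"{name} mean utility {m} outside bounds {truth.utility_bounds}")
    rng = np.random.default_rng(seed)
    n_resampled = 0

    def draw_costs(mean: float) -> np.ndarray:
        if truth.cost_sd == 0:
            return np.full(n_patients_per_arm, mean)
        shape = (mean / truth.cost_sd) ** 2
        scale = truth.cost_sd**2 / mean
        return rng.gamma(shape, scale, size=n_patients_per_arm)

    def draw_utils(mean: float) -> np.ndarray:
        nonlocal n_resampled
        out = rng.normal(mean, truth.utility_sd, size=n_patients_per_arm)
        bad = (out < lo) | (out > hi)
        while bad.any():
            n_resampled += int(bad.sum())
            out[bad] = rng.normal(mean, truth.utility_sd, size=int(bad.sum()))
            bad = (out < lo) | (out > hi)
        return out

    def summarise(costs: np.ndarray, utils: np.ndarray) -> ArmSummary:
        n = len(costs)
        return ArmSummary(
            cost_mean=float(costs.mean()),
            cost_se=float(costs.std(ddof=1) / np.sqrt(n)),
            utility_mean=float(utils.mean()),
            utility_se=float(utils.std(ddof=1) / np.sqrt(n)),
        )

    control = summarise(draw_costs(truth.control_cycle_cost),
                        draw_utils(truth.control_utility))
    interv = summarise(
        draw_costs(truth.control_cycle_cost - truth.cycle_cost_saving),
        draw_utils(truth.control_utility + truth.utility_gain),
    )
    return TrialPayoffs(control, interv, n_patients_per_arm, n_resampled)


def build_scenario(
    trial: TrialPayoffs,
    cohort: CohortSpec,
    mortality: MortalitySchedule,
    effect_cycles: int = 1,
    **scenario_kwargs,
) -> Scenario:
    """Wire trial payoff summaries into a control/intervention scenario.

    The usual-care payoff object is shared between arms, so the delta-method
    variance and PSA draws treat it as one (correlated) parameter.
    """
    usual, effect = trial.state_payoffs()
    control = make_strategy("usual_care", usual)
    name = {1: "bs", 2: "bs_extended"}[effect_cycles]
    intervention = make_strategy(name, usual, effect, effect_cycles=effect_cycles)
    return Scenario(
        cohort=cohort,
        control=control,
        intervention=intervention,
        mortality=mortality,
        **scenario_kwargs,
    )


def psa_distributions(
    trial: TrialPayoffs,
    effect_cycles: int = 1,
    utility_bounds: tuple[float, float] = (-0.6, 1.0),
) -> list[ParamDistribution]:
    """Standard PSA families for the trial payoffs: gamma costs, beta utilities.

    Targets address the shared usual-care payoff once (aliasing propagates it
    to both arms) and the intervention's effect-state payoff separately.
    """
    effect_state = {1: "bs_effect", 2: "bs_extended_effect"}[effect_cycles]
    usual_path = "control.payoffs.usual_care"
    effect_path = f"intervention.payoffs.{effect_state}"
    lo, hi = utility_bounds
    return [
        ParamDistribution.gamma_mm(
            f"{usual_path}.cycle_cost", trial.control.cost_mean, trial.control.cost_se
        ),
        ParamDistribution.beta_mm(
            f"{usual_path}.cycle_utility",
            trial.control.utility_mean, trial.control.utility_se, lo=lo, hi=hi,
        ),
        ParamDistribution.gamma_mm(
            f"{effect_path}.cycle_cost",
            trial.intervention.cost_mean, trial.intervention.cost_se,
        ),
        ParamDistribution.beta_mm(
            f"{effect_path}.cycle_utility",
            trial.intervention.utility_mean, trial.intervention.utility_se, lo=lo, hi=hi,
        ),
    ]


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

def synth_life_table(
    age_range: tuple[int, int] = (65, 96),
    sex_levels: Sequence[str] = ("male", "female"),
    base_annual_mortality: float = 0.04,
    respiratory_fraction: float = 0.35,
    gompertz_slope: float = float(np.log(1.1)),
    sex_multipliers: dict[str, float] | None = None,
) -> MortalitySchedule:
    """Synthetic life table with log-linear (Gompertz-like) mortality growth.

    ``base_annual_mortality`` applies at ``age_range[0]``; annual all-cause
    mortality then grows by a factor ``exp(gompertz_slope)`` per year of age.
    Respiratory mortality is a constant fraction of all-cause.  Probabilities
    are clamped to [0, 1] with a warning naming the first affected age.
    """
    import pandas as pd

    if not 0.0 <= base_annual_mortality <= 1.0:
        raise ValueError("base_annual_mortality must be in [0,1]")
    if not 0.0 <= respiratory_fraction <= 1.0:
        raise ValueError("respiratory_fraction must be in [0,1]")
    lo, hi = age_range
    ages = np.arange(lo, hi + 1)
    rows = []
    warned = False
    for sex in sex_levels:
        mult = (sex_multipliers or {}).get(sex, 1.0)
        p = mult * base_annual_mortality * np.exp(gompertz_slope * (ages - lo))
        if (p > 1.0).any() and not warned:
            first_age = int(ages[np.argmax(p > 1.0)])
            warnings.warn(
                f"all-cause mortality exceeds 1 from age {first_age}; clamping",
                UserWarning,
            )
            warned = True
        p = np.clip(p, 0.0, 1.0)
        for age, pa in zip(ages, p):
            rows.append(
                {
                    "age": int(age),
                    "sex": sex,
                    "annual_all_cause": float(pa),
                    "annual_respiratory": float(respiratory_fraction * pa),
                }
            )
    return MortalitySchedule(pd.DataFrame(rows))
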