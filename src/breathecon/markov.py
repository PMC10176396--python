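"""Markov cohort model of breathlessness-service cost-effectiveness.

Five mutually exclusive states — ``usual_care``, ``bs_effect``,
``bs_extended_effect``, ``no_change`` and absorbing ``dead`` — tracked over
20 cycles of 12 weeks (0.25 years) each, i.e. a 5-year horizon.  At entry an
intervention strategy splits the cohort by the uptake probability: the
accepting fraction starts in the effect state, the remainder receives usual
care within the same strategy.  Service effects last ``effect_cycles`` cycles
(1 for the base service, 2 for the lasting-effects scenario), after which
occupants move to ``no_change`` (usual-care payoffs by default).

Mortality is age- and sex-specific: all-cause in the first cycle,
respiratory in later cycles, with age advanced every four cycles.  Annual
probabilities convert to per-cycle ones via 1-(1-p)^0.25.  Costs and QALYs
accrue on cycle-start occupancy and are discounted at 3.5%/year compounded
per cycle; no half-cycle correction by default (a flag enables it).
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .choice_model import Z975

STATES = ("usual_care", "bs_effect", "bs_extended_effect", "no_change", "dead")
_IDX = {s: i for i, s in enumerate(STATES)}
_LIVE = np.array([True, True, True, True, False])


def per_cycle_discount(
    cycle_index: int, annual_rate: float, cycle_length_years: float = 0.25
) -> float:
    """Compound discount factor (1+r)^(-cycle_length * cycle_index)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle_length_years * cycle_index))


def annual_to_cycle_probability(
    p_annual: float, cycle_length_years: float = 0.25
) -> float:
    """Convert an annual event probability to a per-cycle one (constant hazard)."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability out of [0,1]: {p_annual}")
    return float(1.0 - (1.0 - p_annual) ** cycle_length_years)


@dataclass
class CohortSpec:
    """Starting cohort: e.g. 75-year-old men with COPD, uptake from the DCE."""

    age_start: float
    sex: str
    diagnosis: str = "COPD"
    uptake: float = 1.0

    def __post_init__(self) -> None:
        if self.age_start <= 0:
            raise ValueError("age_start must be positive")
        if not 0.0 <= self.uptake <= 1.0:
            raise ValueError(f"uptake out of [0,1]: {self.uptake}")


class MortalitySchedule:
    """Age/sex-indexed annual all-cause and respiratory mortality."""

    COLUMNS = ("age", "sex", "annual_all_cause", "annual_respiratory")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"life table missing column(s): {sorted(missing)}")
        for col in ("annual_all_cause", "annual_respiratory"):
            vals = table[col].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} contains probabilities outside [0,1]")
        self.table = table.reset_index(drop=True)
        self._lookup = {
            (str(r.sex), int(r.age)): (float(r.annual_all_cause), float(r.annual_respiratory))
            for r in self.table.itertuples()
        }

    def annual(self, age: float, sex: str, cause: str) -> float:
        key = (str(sex), int(age))
        if key not in self._lookup:
            raise KeyError(f"life table has no row for sex={sex!r}, age={int(age)}")
        all_cause, respiratory = self._lookup[key]
        if cause == "all_cause":
            return all_cause
        if cause == "respiratory":
            return respiratory
        raise ValueError(f"unknown cause {cause!r}")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalitySchedule":
        return cls(pd.read_csv(path))

    def __deepcopy__(self, memo) -> "MortalitySchedule":
        return self  # read-only within the model; shared across PSA clones


@dataclass
class StatePayoff:
    """Per-cycle cost (GBP per 12-week cycle) and EQ-5D utility weight.

    ``cost_var``/``utility_var`` are variances *of the mean* payoff, fed into
    delta-method intervals; they default to 0 (known payoff).
    """

    cycle_cost: float
    cycle_utility: float
    cost_var: float = 0.0
    utility_var: float = 0.0

    def __post_init__(self) -> None:
        if self.cycle_cost < 0:
            raise ValueError("cycle_cost must be >= 0")
        if self.cycle_utility > 1.0:
            raise ValueError("cycle_utility (EQ-5D weight) must be <= 1")
        if self.cost_var < 0 or self.utility_var < 0:
            raise ValueError("payoff variances must be >= 0")


_DEAD_PAYOFF = StatePayoff(0.0, 0.0)


@dataclass
class StrategySpec:
    """One modelled alternative: usual care, service, or service with lasting effects."""

    name: str
    payoffs: dict[str, StatePayoff]
    effect_cycles: int = 0
    uptake_applied: bool = True

    def __post_init__(self) -> None:
        if self.effect_cycles not in (0, 1, 2):
            raise ValueError("effect_cycles must be 0, 1 or 2")
        unknown = set(self.payoffs) - set(STATES)
        if unknown:
            raise ValueError(f"payoffs reference unknown state(s): {sorted(unknown)}")
        if "usual_care" not in self.payoffs:
            raise ValueError("payoffs must cover the usual_care state")
        if self.effect_cycles and self.effect_state not in self.payoffs:
            raise ValueError(f"payoffs must cover the {self.effect_state} state")

    @property
    def effect_state(self) -> str | None:
        return {0: None, 1: "bs_effect", 2: "bs_extended_effect"}[self.effect_cycles]


def make_strategy(
    name: str,
    usual: StatePayoff,
    effect: StatePayoff | None = None,
    effect_cycles: int = 0,
) -> StrategySpec:
    """Assemble a strategy; no_change shares the usual-care payoff object."""
    payoffs: dict[str, StatePayoff] = {"usual_care": usual, "no_change": usual}
    if effect_cycles:
        if effect is None:
            raise ValueError("an effect payoff is required when effect_cycles > 0")
        payoffs[{1: "bs_effect", 2: "bs_extended_effect"}[effect_cycles]] = effect
    return StrategySpec(name=name, payoffs=payoffs, effect_cycles=effect_cycles)


@dataclass
class CohortTrace:
    """Per-cycle occupancy plus discounted accumulators and delta-method inputs.

    ``occupancy`` has ``n_cycles + 1`` rows (cycle starts and the terminal
    distribution); each row sums to one.  ``payoff_weights`` records, for
    every distinct payoff object, the discounted occupancy weight multiplying
    its cost (and the same x 0.25 years for utility) — the exact gradients of
    the linear accumulators used for variance propagation.
    """

    occupancy: np.ndarray
    states: tuple[str, ...]
    discounted_cost: float
    discounted_qaly: float
    cost_variance: float
    qaly_variance: float
    payoff_weights: list[tuple[StatePayoff, float, float]]
    cycle_length_years: float = 0.25
    n_cycles: int = 20
    discount_rate_annual: float = 0.035

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


def run_cohort(
    cohort: CohortSpec,
    strategy: StrategySpec,
    mortality: MortalitySchedule,
    n_cycles: int = 20,
    cycle_length_years: float = 0.25,
    discount_rate_annual: float = 0.035,
    half_cycle_correction: bool = False,
) -> CohortTrace:
    """Propagate the cohort through the state-transition model.

    Cycle 1 applies all-cause mortality, later cycles respiratory mortality;
    age advances every four cycles.  Occupancy conservation is enforced to
    1e-9 (drift beyond that aborts).
    """
    payoffs = dict(strategy.payoffs)
    payoffs.setdefault("no_change", payoffs["usual_care"])
    payoffs.setdefault("dead", _DEAD_PAYOFF)
    effect_state = strategy.effect_state

    occ = np.zeros((n_cycles + 1, len(STATES)))
    p_take = cohort.uptake if strategy.uptake_applied else 1.0
    if effect_state is not None:
        occ[0, _IDX[effect_state]] = p_take
        occ[0, _IDX["usual_care"]] = 1.0 - p_take
    else:
        occ[0, _IDX["usual_care"]] = 1.0

    occupied = {s for s, i in _IDX.items() if occ[0, i] > 0}
    missing = occupied - set(payoffs)
    if missing:
        raise ValueError(f"no payoff defined for occupied state(s): {sorted(missing)}")

    costs_vec = np.array([payoffs.get(s, _DEAD_PAYOFF).cycle_cost for s in STATES])
    utils_vec = np.array([payoffs.get(s, _DEAD_PAYOFF).cycle_utility for s in STATES])

    state_cost_w = np.zeros(len(STATES))
    for t in range(n_cycles):
        d = per_cycle_discount(t, discount_rate_annual, cycle_length_years)
        age = int(cohort.age_start) + t // 4
        cause = "all_cause" if t == 0 else "respiratory"
        q = annual_to_cycle_probability(
            mortality.annual(age, cohort.sex, cause), cycle_length_years
        )
        nxt = occ[t].copy()
        deaths = nxt[_LIVE] * q
        nxt[_LIVE] -= deaths
        nxt[_IDX["dead"]] += deaths.sum()
        if effect_state is not None and t + 1 >= strategy.effect_cycles:
            nxt[_IDX["no_change"]] += nxt[_IDX[effect_state]]
            nxt[_IDX[effect_state]] = 0.0
        if abs(nxt.sum() - 1.0) > 1e-9:
            raise RuntimeError(
                f"occupancy drift {abs(nxt.sum() - 1.0):.2e} at cycle {t + 1}"
            )
        occ[t + 1] = nxt
        accrual = 0.5 * (occ[t] + occ[t + 1]) if half_cycle_correction else occ[t]
        state_cost_w += accrual * d

    state_qaly_w = state_cost_w * cycle_length_years
    cost = float(state_cost_w @ costs_vec)
    qaly = float(state_qaly_w @ utils_vec)

    # group weights by payoff object identity: states sharing a payoff share
    # its sampled value, so their weights add before squaring
    by_obj: dict[int, tuple[StatePayoff, float, float]] = {}
    for s, i in _IDX.items():
        po = payoffs.get(s, _DEAD_PAYOFF)
        prev = by_obj.get(id(po))
        if prev is None:
            by_obj[id(po)] = (po, state_cost_w[i], state_qaly_w[i])
        else:
            by_obj[id(po)] = (po, prev[1] + state_cost_w[i], prev[2] + state_qaly_w[i])
    weights = list(by_obj.values())
    cost_var = sum(w_c**2 * po.cost_var for po, w_c, _ in weights)
    qaly_var = sum(w_q**2 * po.utility_var for po, _, w_q in weights)

    return CohortTrace(
        occupancy=occ,
        states=STATES,
        discounted_cost=cost,
        discounted_qaly=qaly,
        cost_variance=float(cost_var),
        qaly_variance=float(qaly_var),
        payoff_weights=weights,
        cycle_length_years=cycle_length_years,
        n_cycles=n_cycles,
        discount_rate_annual=discount_rate_annual,
    )


@dataclass
class CEResult:
    """Incremental cost, incremental QALY, and the resulting ICER."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    status: str  # dominant | dominated | tradeoff | equivalent | undefined
    delta_cost_ci: tuple[float, float] | None = None
    delta_qaly_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "status": self.status,
            "delta_cost_ci": list(self.delta_cost_ci) if self.delta_cost_ci else None,
            "delta_qaly_ci": list(self.delta_qaly_ci) if self.delta_qaly_ci else None,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def delta_ci(
    delta_estimate: float,
    input_variances: Sequence[float],
    gradient: Sequence[float] | None = None,
) -> tuple[float, float]:
    """First-order delta-method 95% interval: var = sum_i g_i^2 var_i."""
    v = np.asarray(input_variances, dtype=float)
    if (~np.isfinite(v)).any() or (v < 0).any():
        raise ValueError("input variances must be finite and >= 0")
    g = np.ones_like(v) if gradient is None else np.asarray(gradient, dtype=float)
    if g.shape != v.shape:
        raise ValueError("gradient and variance vectors must have equal length")
    half = Z975 * float(np.sqrt((g**2 * v).sum()))
    return (delta_estimate - half, delta_estimate + half)


def _delta_variances(
    control: CohortTrace, intervention: CohortTrace
) -> tuple[float, float]:
    """Variance of (intervention - control) totals, sharing-aware.

    Payoff objects appearing in both arms contribute through their *net*
    weight (a shared usual-care payoff largely cancels); arm-specific payoffs
    contribute independently.
    """
    net: dict[int, tuple[StatePayoff, float, float]] = {}
    for po, w_c, w_q in intervention.payoff_weights:
        net[id(po)] = (po, w_c, w_q)
    for po, w_c, w_q in control.payoff_weights:
        if id(po) in net:
            prev = net[id(po)]
            net[id(po)] = (po, prev[1] - w_c, prev[2] - w_q)
        else:
            net[id(po)] = (po, -w_c, -w_q)
    cost_var = sum(w_c**2 * po.cost_var for po, w_c, _ in net.values())
    qaly_var = sum(w_q**2 * po.utility_var for po, _, w_q in net.values())
    return float(cost_var), float(qaly_var)


def incremental_results(
    control: CohortTrace,
    intervention: CohortTrace,
    vcov_inputs: Mapping[str, float] | None = None,
    tol: float = 1e-12,
) -> CEResult:
    """Incremental cost/QALY and ICER of intervention vs control.

    ``vcov_inputs`` may override the propagated variances with keys
    ``delta_cost_var`` and ``delta_qaly_var``.  A zero QALY difference with a
    non-zero cost difference leaves the ICER undefined (never +/-inf).
    """
    if control.occupancy.shape != intervention.occupancy.shape or (
        control.n_cycles != intervention.n_cycles
    ):
        raise ValueError("traces do not share a cycle structure")
    dc = intervention.discounted_cost - control.discounted_cost
    dq = intervention.discounted_qaly - control.discounted_qaly
    if vcov_inputs is not None:
        cost_var = float(vcov_inputs["delta_cost_var"])
        qaly_var = float(vcov_inputs["delta_qaly_var"])
    else:
        cost_var, qaly_var = _delta_variances(control, intervention)
    dc_ci = delta_ci(dc, [cost_var]) if cost_var > 0 else None
    dq_ci = delta_ci(dq, [qaly_var]) if qaly_var > 0 else None

    if abs(dc) <= tol and abs(dq) <= tol:
        return CEResult(dc, dq, None, "equivalent", dc_ci, dq_ci)
    if abs(dq) <= tol:
        return CEResult(dc, dq, None, "undefined", dc_ci, dq_ci)
    icer = dc / dq
    if dc < 0 and dq > 0:
        status = "dominant"
    elif dc > 0 and dq < 0:
        status = "dominated"
    else:
        status = "tradeoff"
    return CEResult(dc, dq, float(icer), status, dc_ci, dq_ci)


@dataclass
class Scenario:
    """A control/intervention pair sharing a cohort and mortality schedule."""

    cohort: CohortSpec
    control: StrategySpec
    intervention: StrategySpec
    mortality: MortalitySchedule
    n_cycles: int = 20
    cycle_length_years: float = 0.25
    discount_rate_annual: float = 0.035
    half_cycle_correction: bool = False

    def run_arm(self, which: str) -> CohortTrace:
        strategy = {"control": self.control, "intervention": self.intervention}[which]
        return run_cohort(
            self.cohort,
            strategy,
            self.mortality,
            n_cycles=self.n_cycles,
            cycle_length_years=self.cycle_length_years,
            discount_rate_annual=self.discount_rate_annual,
            half_cycle_correction=self.half_cycle_correction,
        )

    def run(self) -> CEResult:
        return incremental_results(self.run_arm("control"), self.run_arm("intervention"))

    def clone(self) -> "Scenario":
        """Deep copy preserving payoff aliasing; the life table is shared."""
        return copy.deepcopy(self)


def load_scenario(
    config_path: str | Path,
    life_table_path: str | Path,
    intervention: str = "bs",
) -> Scenario:
    """Build a scenario from a model-config YAML/JSON plus a life-table CSV.

    Config schema::

        cohort: {age_start: 75, sex: male, diagnosis: COPD, uptake: 0.85}
        n_cycles: 20
        discount_rate_annual: 0.035
        payoffs:
          usual_care: {cycle_cost: 2000, cycle_utility: 0.70,
                       cost_var: 0, utility_var: 0}
          bs_effect: {...}
          bs_extended_effect: {...}

    ``intervention`` selects ``bs`` (one effect cycle) or ``bs_extended``
    (two).  The usual-care payoff object is shared between arms so PSA draws
    perturb both consistently.
    """
    config_path = Path(config_path)
    raw = config_path.read_text()
    cfg = json.loads(raw) if config_path.suffix == ".json" else yaml.safe_load(raw)
    cohort = CohortSpec(**cfg["cohort"])
    payoffs = {name: StatePayoff(**vals) for name, vals in cfg["payoffs"].items()}
    usual = payoffs["usual_care"]
    control = make_strategy("usual_care", usual)
    if intervention == "bs":
        inter = make_strategy("bs", usual, payoffs["bs_effect"], effect_cycles=1)
    elif intervention == "bs_extended":
        inter = make_strategy(
            "bs_extended", usual, payoffs["bs_extended_effect"], effect_cycles=2
        )
    else:
        raise ValueError(f"unknown intervention {intervention!r}")
    return Scenario(
        cohort=cohort,
        control=control,
        intervention=inter,
        mortality=MortalitySchedule.from_csv(life_table_path),
        n_cycles=int(cfg.get("n_cycles", 20)),
        discount_rate_annual=float(cfg.get("discount_rate_annual", 0.035)),
        cycle_length_years=float(cfg.get("cycle_length_years", 0.25)),
    )
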