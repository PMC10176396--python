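"""Probabilistic sensitivity analysis and cost-effectiveness acceptability curves.

Each PSA iteration redraws uncertain model inputs from their assigned
distributions (gamma for costs, beta or logit-normal for utilities, normal
for unbounded coefficients), reruns both model arms, and records the
incremental cost and QALY pair.  The CEAC reports, for each willingness to
pay lambda, the fraction of draws with positive net monetary benefit
lambda * dQALY - dCost.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .markov import Scenario

DEFAULT_WTP_GRID = np.arange(0.0, 50_001.0, 1000.0)
_FAMILIES = ("normal", "gamma", "beta", "logit-normal")


@dataclass
class ParamDistribution:
    """A sampling distribution attached to one model parameter.

    ``target`` is a dot-path into a :class:`~breathecon.markov.Scenario`
    (attributes and dict keys), e.g.
    ``"intervention.payoffs.bs_effect.cycle_cost"``.  ``params`` holds
    ``mean``/``sd`` (normal, and method-of-moments gamma/beta) or
    ``mu``/``sigma`` on the logit scale (logit-normal).  ``support`` rescales
    beta/logit-normal draws onto ``(lo, hi)`` and enforces bounds on the
    others by resampling (counted).
    """

    target: str
    family: str
    params: dict[str, float]
    support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; use one of {_FAMILIES}")

    # -- constructors ----------------------------------------------------
    @classmethod
    def normal(cls, target: str, mean: float, sd: float,
               support: tuple[float, float] | None = None) -> "ParamDistribution":
        return cls(target, "normal", {"mean": mean, "sd": sd}, support)

    @classmethod
    def gamma_mm(cls, target: str, mean: float, sd: float) -> "ParamDistribution":
        """Gamma matched to a mean and sd (the standard choice for costs)."""
        if mean <= 0:
            raise ValueError("gamma mean must be positive")
        return cls(target, "gamma", {"mean": mean, "sd": sd})

    @classmethod
    def beta_mm(cls, target: str, mean: float, sd: float,
                lo: float = 0.0, hi: float = 1.0) -> "ParamDistribution":
        """Beta matched to a mean and sd, rescaled onto (lo, hi) — utilities."""
        return cls(target, "beta", {"mean": mean, "sd": sd}, (lo, hi))

    # -- sampling --------------------------------------------------------
    def _draw_raw(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "normal":
            return float(rng.normal(p["mean"], p["sd"]))
        if self.family == "gamma":
            mean, sd = p["mean"], p["sd"]
            if sd == 0:
                return float(mean)
            shape = (mean / sd) ** 2
            scale = sd**2 / mean
            return float(rng.gamma(shape, scale))
        if self.family == "beta":
            lo, hi = self.support if self.support else (0.0, 1.0)
            span = hi - lo
            m = (p["mean"] - lo) / span
            s = p["sd"] / span
            if s == 0:
                return float(p["mean"])
            if not 0 < m < 1:
                raise ValueError(f"beta mean {p['mean']} outside support ({lo}, {hi})")
            nu = m * (1 - m) / s**2 - 1
            if nu <= 0:
                raise ValueError("beta sd too large for the given mean and support")
            return float(lo + span * rng.beta(m * nu, (1 - m) * nu))
        # logit-normal
        lo, hi = self.support if self.support else (0.0, 1.0)
        if p["sigma"] == 0:
            return float(lo + (hi - lo) * expit(p["mu"]))
        return float(lo + (hi - lo) * expit(rng.normal(p["mu"], p["sigma"])))

    def draw(self, rng: np.random.Generator, max_tries: int = 1000) -> tuple[float, int]:
        """One draw respecting the support; returns (value, n_resampled)."""
        if self.support is None or self.family in ("beta", "logit-normal"):
            return self._draw_raw(rng), 0
        lo, hi = self.support
        for tries in range(max_tries):
            v = self._draw_raw(rng)
            if lo <= v <= hi:
                return v, tries
        raise RuntimeError(
            f"could not draw {self.target} inside {self.support} in {max_tries} tries"
        )


def _assign(scenario: Scenario, path: str, value: float) -> None:
    obj: object = scenario
    parts = path.split(".")
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise KeyError(f"no parameter {last!r} at path {path!r}")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise AttributeError(f"no parameter {last!r} at path {path!r}")
        setattr(obj, last, value)


@dataclass
class PSASample:
    """Monte Carlo draws of (delta_cost, delta_qaly)."""

    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    seed: int
    n: int
    n_resampled: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_cost": self.delta_costs, "delta_qaly": self.delta_qalys}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "PSASample":
        df = pd.read_csv(path)
        return cls(
            df["delta_cost"].to_numpy(),
            df["delta_qaly"].to_numpy(),
            seed=seed,
            n=len(df),
        )


def draw_psa(
    scenario: Scenario,
    distributions: Sequence[ParamDistribution],
    n: int,
    seed: int,
) -> PSASample:
    """Run the probabilistic sensitivity analysis.

    For every iteration the scenario is cloned (payoff aliasing preserved, so
    a shared usual-care payoff moves identically in both arms), all targeted
    parameters are redrawn, and both arms are rerun through the cohort model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    # validate targets up front on a throwaway clone
    probe = scenario.clone()
    for dist in distributions:
        _assign(probe, dist.target, getattr_path(probe, dist.target))
    rng = np.random.default_rng(seed)
    dcs = np.empty(n)
    dqs = np.empty(n)
    n_resampled = 0
    for i in range(n):
        sc = scenario.clone()
        for dist in distributions:
            value, resampled = dist.draw(rng)
            n_resampled += resampled
            _assign(sc, dist.target, value)
        res = sc.run()
        dcs[i] = res.delta_cost
        dqs[i] = res.delta_qaly
    return PSASample(dcs, dqs, seed=seed, n=n, n_resampled=n_resampled)


def getattr_path(scenario: Scenario, path: str) -> float:
    obj: object = scenario
    for part in path.split("."):
        if isinstance(obj, dict):
            if part not in obj:
                raise KeyError(f"no parameter {part!r} along path {path!r}")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise AttributeError(f"no parameter {part!r} along path {path!r}")
            obj = getattr(obj, part)
    return obj  # type: ignore[return-value]


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB = wtp * delta_qaly - delta_cost (positive favours the intervention)."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("willingness to pay must be >= 0")
    return wtp * delta_qaly - delta_cost


@dataclass
class CEACCurve:
    wtp_grid: np.ndarray
    acceptability: np.ndarray

    def __post_init__(self) -> None:
        self.wtp_grid = np.asarray(self.wtp_grid, dtype=float)
        self.acceptability = np.asarray(self.acceptability, dtype=float)
        if self.wtp_grid.shape != self.acceptability.shape:
            raise ValueError("wtp_grid and acceptability must share a length")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "acceptability": self.acceptability})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def ceac(sample: PSASample, wtp_grid: Sequence[float] | None = None) -> CEACCurve:
    """Acceptability(lambda) = fraction of draws with positive net monetary benefit.

    Ties (NMB exactly zero) count as non-acceptance.
    """
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if sample.n == 0:
        raise ValueError("PSA sample is empty")
    nmb = sample.delta_qalys[:, None] * grid[None, :] - sample.delta_costs[:, None]
    return CEACCurve(grid, (nmb > 0).mean(axis=0))


def plot_ceac(curve: CEACCurve, ax=None):
    """Acceptability against willingness to pay (matplotlib axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.wtp_grid, curve.acceptability)
    ax.set_xlabel("Willingness to pay (£/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_ce_plane(sample: PSASample, wtp: float | None = None, ax=None):
    """Incremental cost-effectiveness plane of the PSA draws."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(sample.delta_qalys, sample.delta_costs, s=6, alpha=0.4)
    ax.axhline(0.0, lw=0.8, color="grey")
    ax.axvline(0.0, lw=0.8, color="grey")
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, ls="--", lw=0.8, color="black")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (£)")
    return ax
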