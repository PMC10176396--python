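"""Conditional logit estimation of service preferences.

The probability that a respondent picks alternative *j* in a task is the
softmax of the alternatives' linear utilities,

    P(j) = exp(x_j' beta) / sum_k exp(x_k' beta),

with the opt-out alternative's utility normalised to zero (an all-zero design
row) and the alternative-specific constant (ASC) measuring "any service vs
neither".  The log-likelihood is globally concave, so a damped Newton
iteration from the zero vector converges reliably; the covariance is the
inverse observed information, optionally sandwiched with respondent-level
score sums (cluster-robust, because each respondent answers several tasks).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import ASC_COLUMN, ChoiceDataset, build_design_matrix

Z975 = float(stats.norm.ppf(0.975))
# |beta| beyond these bounds signals a separated (numerically unbounded)
# likelihood: 15 utility units already means ~3e6:1 odds
_SEPARATION_HARD = 30.0
_SEPARATION_SOFT = 15.0


class SeparationWarning(UserWarning):
    """The likelihood appears unbounded (perfect separation)."""


@dataclass
class CoefficientSet:
    """Fitted (or assumed) utility weights: ASC plus level coefficients.

    ``vcov`` is ordered as ``["asc", *betas]``; it is ``None`` for coefficient
    vectors supplied without uncertainty (e.g. published point estimates).
    """

    asc: float
    betas: dict[str, float]
    vcov: np.ndarray | None = None
    log_likelihood: float | None = None
    n_tasks: int = 0

    def __post_init__(self) -> None:
        if self.vcov is not None:
            self.vcov = np.asarray(self.vcov, dtype=float)
            k = 1 + len(self.betas)
            if self.vcov.shape != (k, k):
                raise ValueError(
                    f"vcov shape {self.vcov.shape} does not match {k} parameters"
                )

    @property
    def columns(self) -> list[str]:
        return [ASC_COLUMN, *self.betas]

    @property
    def values(self) -> np.ndarray:
        return np.array([self.asc, *self.betas.values()])

    def se(self) -> dict[str, float] | None:
        if self.vcov is None:
            return None
        sds = np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
        return dict(zip(self.columns, sds))

    def ci95(self) -> dict[str, tuple[float, float]] | None:
        se = self.se()
        if se is None:
            return None
        return {
            c: (v - Z975 * se[c], v + Z975 * se[c])
            for c, v in zip(self.columns, self.values)
        }

    def to_dict(self) -> dict:
        out: dict[str, object] = {
            "asc": self.asc,
            "betas": dict(self.betas),
            "log_likelihood": self.log_likelihood,
            "n_tasks": self.n_tasks,
        }
        se = self.se()
        if se is not None:
            out["se"] = se
            out["ci95"] = {k: list(v) for k, v in self.ci95().items()}
            out["vcov"] = self.vcov.tolist()
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, data: dict) -> "CoefficientSet":
        return cls(
            asc=float(data["asc"]),
            betas={k: float(v) for k, v in data["betas"].items()},
            vcov=np.asarray(data["vcov"]) if data.get("vcov") is not None else None,
            log_likelihood=data.get("log_likelihood"),
            n_tasks=int(data.get("n_tasks", 0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CoefficientSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FitResult:
    coefficients: CoefficientSet
    converged: bool
    n_iterations: int
    gradient_norm: float


@dataclass
class BootstrapCI:
    low: float
    high: float
    samples: np.ndarray
    n_failed: int = 0


# ---------------------------------------------------------------------------
# array preparation
# ---------------------------------------------------------------------------

def _arrays(
    dataset: ChoiceDataset, drop_unanswered: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(tasks, 3, K) design tensor, chosen indices and respondent codes."""
    X, cols = build_design_matrix(dataset)
    T = dataset.n_tasks
    X3 = X.reshape(T, 3, len(cols))
    chosen = np.array(
        [-1 if t.chosen_index is None else t.chosen_index for t in dataset.tasks]
    )
    resp = np.array([t.respondent_id for t in dataset.tasks])
    if drop_unanswered:
        mask = chosen >= 0
        X3, chosen, resp = X3[mask], chosen[mask], resp[mask]
    return X3, chosen, resp, cols


def _ll_arrays(beta: np.ndarray, X3: np.ndarray, chosen: np.ndarray) -> float:
    U = X3 @ beta
    m = U.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(U - m).sum(axis=1))
    return float((np.take_along_axis(U, chosen[:, None], axis=1)[:, 0] - lse).sum())


def loglikelihood(beta_vector: Sequence[float], dataset: ChoiceDataset) -> float:
    """Conditional logit log-likelihood over answered tasks (log-sum-exp stabilised)."""
    X3, chosen, _, cols = _arrays(dataset)
    beta = np.asarray(beta_vector, dtype=float)
    if beta.shape != (len(cols),):
        raise ValueError(
            f"beta_vector has length {beta.size}, design matrix has {len(cols)} columns"
        )
    return _ll_arrays(beta, X3, chosen)


def _check_separability(X3: np.ndarray, cols: list[str]) -> None:
    within_task_range = X3.max(axis=1) - X3.min(axis=1)
    varying = (within_task_range > 0).any(axis=0)
    if not varying.all():
        bad = [c for c, v in zip(cols, varying) if not v]
        raise ValueError(
            f"design column(s) {bad} are constant across alternatives within every task; "
            "the corresponding coefficients are not identified"
        )


def _fit_arrays(
    X3: np.ndarray,
    chosen: np.ndarray,
    cols: list[str],
    resp: np.ndarray | None = None,
    start: Sequence[float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    cluster_se: bool = True,
) -> FitResult:
    T, A, K = X3.shape
    if T == 0:
        raise ValueError("no answered tasks to fit on")
    beta = np.zeros(K) if start is None else np.asarray(start, dtype=float).copy()
    if beta.shape != (K,):
        raise ValueError(f"start vector has length {beta.size}, expected {K}")

    Xc = np.take_along_axis(X3, chosen[:, None, None], axis=1)[:, 0, :]
    ll = _ll_arrays(beta, X3, chosen)
    converged = False
    gnorm = np.inf
    it = 0
    separated = False
    for it in range(1, max_iter + 1):
        U = X3 @ beta
        U -= U.max(axis=1, keepdims=True)
        E = np.exp(U)
        P = E / E.sum(axis=1, keepdims=True)
        xbar = np.einsum("ta,tak->tk", P, X3)
        score_t = Xc - xbar
        g = score_t.sum(axis=0)
        gnorm = float(np.abs(g).max())
        if gnorm < tol:
            converged = True
            break
        S = np.einsum("ta,tak,tal->kl", P, X3, X3)
        info = S - xbar.T @ xbar  # observed information (= -Hessian), PSD
        try:
            step = linalg.solve(info, g, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(info, g)[0]
        # concave objective: step-halve if a full Newton step overshoots
        for _ in range(40):
            new_beta = beta + step
            new_ll = _ll_arrays(new_beta, X3, chosen)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll = new_beta, new_ll
        if np.abs(beta).max() > _SEPARATION_HARD:
            separated = True
            break

    if not separated and np.abs(beta).max() > _SEPARATION_SOFT:
        separated = True
    if separated:
        warnings.warn(
            "coefficient(s) diverging; the likelihood appears unbounded "
            "(perfect separation)",
            SeparationWarning,
        )

    # information and covariance at the optimum
    U = X3 @ beta
    U -= U.max(axis=1, keepdims=True)
    E = np.exp(U)
    P = E / E.sum(axis=1, keepdims=True)
    xbar = np.einsum("ta,tak->tk", P, X3)
    score_t = Xc - xbar
    info = np.einsum("ta,tak,tal->kl", P, X3, X3) - xbar.T @ xbar
    try:
        bread = linalg.inv(info)
    except linalg.LinAlgError:
        bread = linalg.pinvh(info)
    if cluster_se and resp is not None:
        codes, uniques = pd.factorize(resp)
        G = len(uniques)
        grouped = np.zeros((G, len(cols)))
        np.add.at(grouped, codes, score_t)
        meat = grouped.T @ grouped
        if G > 1:
            meat *= G / (G - 1)
        vcov = bread @ meat @ bread
    else:
        vcov = bread

    coeffs = CoefficientSet(
        asc=float(beta[0]),
        betas={c: float(b) for c, b in zip(cols[1:], beta[1:])},
        vcov=vcov,
        log_likelihood=ll,
        n_tasks=T,
    )
    return FitResult(
        coefficients=coeffs,
        converged=converged and not separated,
        n_iterations=it,
        gradient_norm=gnorm,
    )


def fit_conditional_logit(
    dataset: ChoiceDataset,
    start: Sequence[float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    cluster_se: bool = True,
) -> FitResult:
    """Maximum-likelihood conditional logit fit.

    Tasks without a recorded choice are dropped task-wise.  The returned
    covariance is cluster-robust by respondent unless ``cluster_se=False``
    (then it is the inverse observed information).
    """
    X3, chosen, resp, cols = _arrays(dataset)
    _check_separability(X3, cols)
    return _fit_arrays(
        X3, chosen, cols, resp=resp, start=start, tol=tol, max_iter=max_iter,
        cluster_se=cluster_se,
    )


def lr_test(full: FitResult, nested: FitResult, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of a nested against a fuller preference model."""
    if not (full.converged and nested.converged):
        raise ValueError("both fits must have converged for a likelihood-ratio test")
    ll_full = full.coefficients.log_likelihood
    ll_nested = nested.coefficients.log_likelihood
    stat = 2.0 * (ll_full - ll_nested)
    if stat < -1e-6:
        raise ValueError(
            f"full-model log-likelihood ({ll_full:.6f}) is below the nested model's "
            f"({ll_nested:.6f}); optimisation failed"
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def lr_test_split(
    dataset: ChoiceDataset,
    group_of: Callable[[str], object],
    **fit_kwargs,
) -> tuple[float, float, int]:
    """Subgroup heterogeneity test: group-specific coefficients vs pooled.

    ``group_of`` maps a respondent id to a group label (e.g. patient vs
    carer).  The full model fits each group separately; the nested model
    pools.  Returns (statistic, p, df).
    """
    groups: dict[object, list] = {}
    for t in dataset.tasks:
        groups.setdefault(group_of(t.respondent_id), []).append(t)
    if len(groups) < 2:
        raise ValueError("group_of produced a single group; nothing to compare")
    pooled = fit_conditional_logit(dataset, **fit_kwargs)
    ll_full = 0.0
    k = len(pooled.coefficients.values)
    for label, tasks in groups.items():
        sub = ChoiceDataset(tasks, dataset.design)
        fit = fit_conditional_logit(sub, **fit_kwargs)
        if not fit.converged:
            raise ValueError(f"subgroup fit for {label!r} did not converge")
        ll_full += fit.coefficients.log_likelihood
    df = (len(groups) - 1) * k
    stat = 2.0 * (ll_full - pooled.coefficients.log_likelihood)
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df)), df


def cluster_bootstrap(
    dataset: ChoiceDataset,
    n_boot: int,
    seed: int,
    statistic: Callable[[CoefficientSet], float],
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile CI of a coefficient functional by respondent-cluster resampling.

    Respondents are resampled with replacement; the model is refitted on each
    resample.  Refits that fail to converge are discarded and counted; more
    than 10% discards triggers a warning.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for percentile intervals")
    X3, chosen, resp, cols = _arrays(dataset)
    _check_separability(X3, cols)
    codes, uniques = pd.factorize(resp)
    G = len(uniques)
    group_rows = [np.flatnonzero(codes == g) for g in range(G)]
    rng = np.random.default_rng(seed)
    values = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        for _ in range(n_boot):
            pick = rng.integers(0, G, size=G)
            idx = np.concatenate([group_rows[p] for p in pick])
            try:
                fit = _fit_arrays(X3[idx], chosen[idx], cols, cluster_se=False)
            except (ValueError, linalg.LinAlgError):
                n_failed += 1
                continue
            if not fit.converged:
                n_failed += 1
                continue
            values.append(statistic(fit.coefficients))
    if n_failed > 0.1 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap refits discarded (non-convergence)",
            UserWarning,
        )
    samples = np.asarray(values)
    low, high = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(float(low), float(high), samples, n_failed)


def reexpress(
    coeffs: CoefficientSet,
    design: Sequence["object"],
    new_references: dict[str, str] | None = None,
) -> CoefficientSet:
    """Re-express per-level coefficients against (new) reference levels.

    Treats any ``"attribute:level"`` key absent from ``betas`` as zero, then
    rewrites each dummy-coded attribute's coefficients relative to the chosen
    reference, absorbing the reference levels' values into the ASC.  Published
    vectors that print a weight for *every* level become identifiable dummy
    parameterisations this way.  The covariance is dropped (set to None).
    """
    refs = {a.name: a.reference_level for a in design}
    if new_references:
        for name, lvl in new_references.items():
            if name not in refs:
                raise KeyError(f"unknown attribute {name!r}")
            refs[name] = lvl
    asc = coeffs.asc
    betas: dict[str, float] = {}
    for attr in design:
        if attr.coding == "linear":
            key = attr.name
            if key in coeffs.betas:
                betas[key] = coeffs.betas[key]
            continue
        ref_value = coeffs.betas.get(f"{attr.name}:{refs[attr.name]}", 0.0)
        asc += ref_value
        for lvl in attr.levels:
            if lvl == refs[attr.name]:
                continue
            betas[f"{attr.name}:{lvl}"] = (
                coeffs.betas.get(f"{attr.name}:{lvl}", 0.0) - ref_value
            )
    return CoefficientSet(asc=asc, betas=betas, vcov=None,
                          log_likelihood=coeffs.log_likelihood, n_tasks=coeffs.n_tasks)
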