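"""Attribute/level space of a breathlessness support service and choice-task plumbing.

A discrete choice experiment (DCE) presents respondents with repeated choice
tasks.  Each task here pairs two hypothetical service configurations with a
"neither" (opt-out) alternative whose utility is normalised to zero.  A
service configuration fixes one level per attribute (place of consultation,
nature of treatment review, additional support, waiting time).  This module
defines those objects, encodes them into the numeric design matrix that the
conditional logit estimator consumes, and generates seedable synthetic task
sets with approximately balanced level frequencies.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ASC_COLUMN = "asc"
N_ALTERNATIVES = 3  # two services + opt-out


class UnknownLevelError(KeyError):
    """A configuration references an attribute level absent from the design."""


@dataclass(frozen=True)
class Attribute:
    """One service attribute with its ordered levels.

    ``coding="dummy"`` contributes one design column per non-reference level;
    ``coding="linear"`` contributes a single numeric column whose value is
    taken from ``level_values`` (or parsed from the leading number of the
    level name, e.g. ``"8 weeks"`` -> 8.0).
    """

    name: str
    levels: tuple[str, ...]
    reference_level: str
    coding: str = "dummy"
    level_values: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        if len(self.levels) < 2:
            raise ValueError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r} has duplicate levels")
        if self.reference_level not in self.levels:
            raise ValueError(
                f"reference level {self.reference_level!r} not among levels of {self.name!r}"
            )
        if self.coding not in ("dummy", "linear"):
            raise ValueError(f"coding must be 'dummy' or 'linear', got {self.coding!r}")

    @property
    def non_reference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference_level)

    def level_value(self, level: str) -> float:
        """Numeric value of a level (used under linear coding)."""
        if self.level_values is not None:
            return float(self.level_values[level])
        try:
            return float(str(level).split()[0])
        except ValueError as exc:
            raise ValueError(
                f"cannot derive a numeric value for level {level!r} of {self.name!r}; "
                "supply level_values"
            ) from exc


@dataclass(frozen=True)
class ServiceConfiguration:
    """One level per attribute, or the opt-out ('neither') alternative."""

    levels: Mapping[str, str] = field(default_factory=dict)
    is_opt_out: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", dict(self.levels))
        if self.is_opt_out and self.levels:
            raise ValueError("opt-out configuration must not carry attribute levels")

    @classmethod
    def opt_out(cls) -> "ServiceConfiguration":
        return cls(levels={}, is_opt_out=True)

    def key(self) -> str:
        """Deterministic serialisation, used for tie-breaking in rankings."""
        if self.is_opt_out:
            return "opt_out"
        return "|".join(f"{a}={l}" for a, l in sorted(self.levels.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ServiceConfiguration):
            return NotImplemented
        return self.is_opt_out == other.is_opt_out and self.levels == other.levels


def validate_configuration(config: ServiceConfiguration, design: Sequence[Attribute]) -> None:
    """Check that a service configuration fixes exactly one known level per attribute."""
    if config.is_opt_out:
        return
    names = [a.name for a in design]
    extra = set(config.levels) - set(names)
    if extra:
        raise UnknownLevelError(f"configuration sets unknown attribute(s): {sorted(extra)}")
    for attr in design:
        if attr.name not in config.levels:
            raise ValueError(f"configuration missing a level for attribute {attr.name!r}")
        level = config.levels[attr.name]
        if level not in attr.levels:
            raise UnknownLevelError(
                f"unknown level {level!r} for attribute {attr.name!r}"
            )


@dataclass
class ChoiceTask:
    """One choice question: two services plus the opt-out, with the observed choice.

    ``chosen_index`` is 0-based into ``alternatives`` and ``None`` for a
    non-response (the task is then excluded from the likelihood but kept in
    the dataset).
    """

    respondent_id: str
    task_id: int
    alternatives: tuple[ServiceConfiguration, ...]
    chosen_index: int | None = None

    def __post_init__(self) -> None:
        self.alternatives = tuple(self.alternatives)
        if len(self.alternatives) != N_ALTERNATIVES:
            raise ValueError("a choice task must offer exactly 3 alternatives")
        n_opt = sum(a.is_opt_out for a in self.alternatives)
        if n_opt != 1:
            raise ValueError("a choice task must contain exactly one opt-out alternative")
        services = [a for a in self.alternatives if not a.is_opt_out]
        if services[0].levels == services[1].levels:
            raise ValueError("the two service alternatives must differ in >=1 attribute")
        if self.chosen_index is not None and not 0 <= self.chosen_index < N_ALTERNATIVES:
            raise ValueError(f"chosen_index out of range: {self.chosen_index}")


@dataclass
class ChoiceDataset:
    """Long-format DCE evidence: tasks plus the attribute design they draw on."""

    tasks: list[ChoiceTask]
    design: list[Attribute]

    def __post_init__(self) -> None:
        self.tasks = list(self.tasks)
        self.design = list(self.design)

    def validate(self) -> None:
        for task in self.tasks:
            for alt in task.alternatives:
                validate_configuration(alt, self.design)

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_answered_tasks(self) -> int:
        return sum(t.chosen_index is not None for t in self.tasks)

    @property
    def n_observations(self) -> int:
        """One observation per alternative row (3 per task)."""
        return N_ALTERNATIVES * self.n_tasks

    @property
    def n_answered_observations(self) -> int:
        return N_ALTERNATIVES * self.n_answered_tasks

    @property
    def respondents(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tasks:
            seen.setdefault(t.respondent_id)
        return list(seen)

    # ---- long-format CSV interface -------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        attr_names = [a.name for a in self.design]
        rows = []
        for task in self.tasks:
            for j, alt in enumerate(task.alternatives):
                row: dict[str, object] = {
                    "respondent_id": task.respondent_id,
                    "task_id": task.task_id,
                    "alt_id": j + 1,
                    "chosen": int(task.chosen_index == j) if task.chosen_index is not None else 0,
                    "is_opt_out": int(alt.is_opt_out),
                }
                for name in attr_names:
                    row[name] = "" if alt.is_opt_out else alt.levels[name]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design: Sequence[Attribute]) -> "ChoiceDataset":
        attr_names = [a.name for a in design]
        tasks: list[ChoiceTask] = []
        for (resp, task_id), grp in df.groupby(["respondent_id", "task_id"], sort=True):
            grp = grp.sort_values("alt_id")
            alts = []
            for _, r in grp.iterrows():
                if int(r["is_opt_out"]):
                    alts.append(ServiceConfiguration.opt_out())
                else:
                    alts.append(
                        ServiceConfiguration({n: str(r[n]) for n in attr_names})
                    )
            chosen_flags = grp["chosen"].astype(int).to_numpy()
            if chosen_flags.sum() > 1:
                raise ValueError(
                    f"respondent {resp!r} task {task_id}: more than one alternative marked chosen"
                )
            chosen = int(np.argmax(chosen_flags)) if chosen_flags.sum() == 1 else None
            tasks.append(ChoiceTask(str(resp), int(task_id), tuple(alts), chosen))
        ds = cls(tasks, list(design))
        ds.validate()
        return ds

    @classmethod
    def from_csv(cls, path: str | Path, design: Sequence[Attribute]) -> "ChoiceDataset":
        return cls.from_dataframe(pd.read_csv(path, keep_default_na=False), design)


# ---------------------------------------------------------------------------
# design-matrix encoding
# ---------------------------------------------------------------------------

def design_columns(design: Sequence[Attribute]) -> list[str]:
    """Column labels: ASC first, then per-attribute dummy or linear columns."""
    cols = [ASC_COLUMN]
    for attr in design:
        if attr.coding == "dummy":
            cols.extend(f"{attr.name}:{lvl}" for lvl in attr.non_reference_levels)
        else:
            cols.append(attr.name)
    return cols


def encode_configuration(
    config: ServiceConfiguration, design: Sequence[Attribute]
) -> np.ndarray:
    """Design-matrix row of one alternative; opt-out encodes to all zeros."""
    cols = design_columns(design)
    row = np.zeros(len(cols))
    if config.is_opt_out:
        return row
    validate_configuration(config, design)
    row[0] = 1.0  # any-service constant
    pos = 1
    for attr in design:
        level = config.levels[attr.name]
        if attr.coding == "dummy":
            for lvl in attr.non_reference_levels:
                if level == lvl:
                    row[pos] = 1.0
                pos += 1
        else:
            row[pos] = attr.level_value(level)
            pos += 1
    return row


def decode_design_row(
    row: np.ndarray, design: Sequence[Attribute]
) -> ServiceConfiguration:
    """Inverse of :func:`encode_configuration` (exact round-trip)."""
    row = np.asarray(row, dtype=float)
    if not row.any():
        return ServiceConfiguration.opt_out()
    levels: dict[str, str] = {}
    pos = 1
    for attr in design:
        if attr.coding == "dummy":
            block = row[pos : pos + len(attr.non_reference_levels)]
            hits = np.flatnonzero(block == 1.0)
            if len(hits) > 1:
                raise ValueError(f"row sets multiple levels of {attr.name!r}")
            levels[attr.name] = (
                attr.non_reference_levels[hits[0]] if len(hits) else attr.reference_level
            )
            pos += len(attr.non_reference_levels)
        else:
            value = row[pos]
            matches = [l for l in attr.levels if attr.level_value(l) == value]
            if not matches:
                raise ValueError(f"no level of {attr.name!r} has value {value}")
            levels[attr.name] = matches[0]
            pos += 1
    return ServiceConfiguration(levels)


def build_design_matrix(
    dataset: ChoiceDataset, drop_unanswered: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Stack alternative rows into a numeric matrix.

    Rows appear in task order, three per task, alternative order preserved.
    With ``drop_unanswered=True`` only answered tasks contribute rows (the
    likelihood's view of the data).
    """
    cols = design_columns(dataset.design)
    tasks = (
        [t for t in dataset.tasks if t.chosen_index is not None]
        if drop_unanswered
        else dataset.tasks
    )
    X = np.empty((N_ALTERNATIVES * len(tasks), len(cols)))
    for i, task in enumerate(tasks):
        for j, alt in enumerate(task.alternatives):
            X[N_ALTERNATIVES * i + j] = encode_configuration(alt, dataset.design)
    return X, cols


# ---------------------------------------------------------------------------
# task generation
# ---------------------------------------------------------------------------

def n_possible_configurations(design: Sequence[Attribute]) -> int:
    n = 1
    for a in design:
        n *= len(a.levels)
    return n


def _random_configuration(design: Sequence[Attribute], rng: np.random.Generator) -> ServiceConfiguration:
    return ServiceConfiguration(
        {a.name: a.levels[rng.integers(len(a.levels))] for a in design}
    )


def generate_choice_tasks(
    design: Sequence[Attribute],
    n_respondents: int,
    n_tasks: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ChoiceDataset:
    """Random paired task generation: two distinct configurations plus opt-out.

    Uniform level sampling keeps level frequencies approximately balanced.
    Bit-identical output under a fixed seed.
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    if not design:
        raise ValueError("design must be non-empty")
    if n_possible_configurations(design) < 2:
        raise ValueError("design admits a single configuration; cannot form distinct pairs")
    if rng is None:
        rng = np.random.default_rng(seed)
    tasks = []
    for r in range(n_respondents):
        rid = f"r{r + 1:04d}"
        for t in range(1, n_tasks + 1):
            first = _random_configuration(design, rng)
            for _ in range(1000):
                second = _random_configuration(design, rng)
                if second.levels != first.levels:
                    break
            else:  # pragma: no cover - unreachable with >=2 configurations
                raise RuntimeError("failed to draw a distinct paired configuration")
            tasks.append(
                ChoiceTask(rid, t, (first, second, ServiceConfiguration.opt_out()), None)
            )
    return ChoiceDataset(tasks, list(design))


# ---------------------------------------------------------------------------
# default catalogue and config I/O
# ---------------------------------------------------------------------------

#: Two attributes held fixed across all presented services (they shift every
#: service alternative identically, so their weight is absorbed by the ASC and
#: they are not part of the varying design).
FIXED_EXPECTATIONS = {
    "expectation_breathlessness": "being more mobile at home & outside and enjoying social activities",
    "expectation_health_service": "having fewer hospital admissions",
}


def default_design(waiting_coding: str = "dummy") -> list[Attribute]:
    """Default attribute catalogue for a breathlessness support service.

    Place of consultation, nature of treatment review, additional support and
    waiting time to first appointment.  Waiting time defaults to dummy coding
    with 8 weeks as the reference; ``waiting_coding="linear"`` switches to a
    single numeric weeks column for willingness-to-wait analyses.
    """
    return [
        Attribute(
            "place",
            ("GP surgery", "home visit", "outpatient clinic"),
            reference_level="GP surgery",
        ),
        Attribute(
            "review",
            ("non-medicinal only", "medicinal and non-medicinal"),
            reference_level="non-medicinal only",
        ),
        Attribute(
            "support",
            ("none", "social worker alone", "therapists and social worker"),
            reference_level="none",
        ),
        Attribute(
            "waiting",
            ("2 weeks", "4 weeks", "8 weeks"),
            reference_level="8 weeks",
            coding=waiting_coding,
            level_values={"2 weeks": 2.0, "4 weeks": 4.0, "8 weeks": 8.0},
        ),
    ]


def load_design(path: str | Path) -> list[Attribute]:
    """Read an attribute design from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    attrs = []
    for entry in data["attributes"]:
        attrs.append(
            Attribute(
                name=entry["name"],
                levels=tuple(entry["levels"]),
                reference_level=entry["reference_level"],
                coding=entry.get("coding", "dummy"),
                level_values=entry.get("level_values"),
            )
        )
    return attrs


def save_design(design: Sequence[Attribute], path: str | Path) -> None:
    data = {
        "attributes": [
            {
                "name": a.name,
                "levels": list(a.levels),
                "reference_level": a.reference_level,
                "coding": a.coding,
                **({"level_values": dict(a.level_values)} if a.level_values else {}),
            }
            for a in design
        ]
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
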