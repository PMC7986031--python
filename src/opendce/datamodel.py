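"""Core data types for discrete choice experiments.

A study is described by a :class:`StudySpec` (attributes, their levels, the
number of choice tasks per respondent and alternatives per task, declared
attribute interactions, and respondent covariates).  A :class:`ChoiceDesign`
assigns attribute levels to the alternatives of every task in one or more
design versions, and a :class:`ChoiceDataset` joins a design with observed
(or simulated) choices and respondent covariates.

Level indices are 1-based in files (the conjoint-software convention) and
0-based everywhere in memory; the I/O layer performs the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "StudySpec",
    "ChoiceDesign",
    "RespondentRecord",
    "ChoiceDataset",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a spec, design or dataset violates a structural invariant."""


@dataclass(frozen=True)
class AttributeSpec:
    """One product attribute with its ordered levels.

    Parameters
    ----------
    name : str
        Attribute name, unique within a study.
    levels : tuple of str
        Ordered level labels; at least two, unique within the attribute.
    in_design : bool
        Whether the attribute appears in the choice design.  Supports study
        variants that drop an attribute (for instance a five-attribute survey
        version that removes the effect-on-menstruation attribute).
    """

    name: str
    levels: tuple[str, ...]
    in_design: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ValidationError(
                f"attribute {self.name!r}: needs >= 2 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(f"attribute {self.name!r}: duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class StudySpec:
    """Full specification of a choice experiment.

    ``n_tasks`` (t) is the number of non-fixed choice tasks per respondent and
    ``n_alternatives`` (a) the number of product alternatives per task.
    ``interactions`` lists pairs of in-design attribute names whose first-order
    interaction enters the utility model.  ``covariates`` names respondent
    covariates carried by the response file and used in the upper model of the
    hierarchical estimator.
    """

    attributes: tuple[AttributeSpec, ...]
    n_tasks: int = 10
    n_alternatives: int = 2
    interactions: tuple[tuple[str, str], ...] = ()
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(
            self, "interactions", tuple(tuple(p) for p in self.interactions)
        )
        object.__setattr__(self, "covariates", tuple(self.covariates))
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate attribute name(s): {dupes}")
        if self.n_tasks < 1:
            raise ValidationError(f"n_tasks must be >= 1, got {self.n_tasks}")
        if self.n_alternatives < 2:
            raise ValidationError(
                f"n_alternatives must be >= 2, got {self.n_alternatives}"
            )
        in_design = {a.name for a in self.design_attributes}
        for pair in self.interactions:
            if len(pair) != 2:
                raise ValidationError(f"interaction must be a pair, got {pair!r}")
            for name in pair:
                if name not in in_design:
                    raise ValidationError(
                        f"interaction references unknown or out-of-design "
                        f"attribute {name!r}"
                    )

    @property
    def design_attributes(self) -> tuple[AttributeSpec, ...]:
        """Attributes that actually appear in the choice design."""
        return tuple(a for a in self.attributes if a.in_design)

    @property
    def max_levels(self) -> int:
        """Largest number of levels over in-design attributes (the c of the
        Johnson–Orme sample-size rule)."""
        return max(a.n_levels for a in self.design_attributes)

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(f"no attribute named {name!r}")


@dataclass
class ChoiceDesign:
    """Assignment of attribute levels to alternatives within tasks.

    ``table`` is a long-format DataFrame with one row per alternative and
    columns ``version``, ``task``, ``alt`` plus one 0-based level-index column
    per in-design attribute, and a boolean ``is_fixed`` flag marking the
    comprehension task shown to every respondent but excluded from analysis.
    """

    spec: StudySpec
    table: pd.DataFrame
    fixed_task: int | None = None

    _META = ("version", "task", "alt", "is_fixed")

    def __post_init__(self) -> None:
        self.validate()

    @property
    def attribute_columns(self) -> list[str]:
        return [a.name for a in self.spec.design_attributes]

    @property
    def versions(self) -> list:
        return sorted(self.table["version"].unique().tolist())

    @property
    def n_tasks_total(self) -> int:
        """Number of non-fixed (version, task) pairs in the design."""
        t = self.table[~self.table["is_fixed"]]
        return len(t.groupby(["version", "task"], sort=False))

    def validate(self) -> None:
        a = self.spec.n_alternatives
        cols = set(self._META) | set(self.attribute_columns)
        missing = cols - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        sizes = self.table.groupby(["version", "task"]).size()
        bad = sizes[sizes != a]
        if len(bad):
            raise ValidationError(
                f"every (version, task) needs exactly {a} alternatives; "
                f"violations at {bad.index.tolist()[:5]}"
            )
        for attr in self.spec.design_attributes:
            col = self.table[attr.name]
            if col.min() < 0 or col.max() >= attr.n_levels:
                raise ValidationError(
                    f"attribute {attr.name!r}: level index out of range "
                    f"[0, {attr.n_levels - 1}]"
                )
        # no two identical alternatives within a task
        dup = (
            self.table.groupby(["version", "task"])[self.attribute_columns]
            .apply(lambda g: g.duplicated().any())
        )
        if dup.any():
            where = dup[dup].index.tolist()[:5]
            raise ValidationError(f"identical alternatives within task(s) {where}")

    def task_array(self, version) -> np.ndarray:
        """Level indices for one version as an (n_tasks, a, n_attrs) array,
        fixed task excluded, tasks in sorted order."""
        t = self.table[(self.table["version"] == version) & (~self.table["is_fixed"])]
        t = t.sort_values(["task", "alt"])
        n_attr = len(self.attribute_columns)
        arr = t[self.attribute_columns].to_numpy()
        return arr.reshape(-1, self.spec.n_alternatives, n_attr)


@dataclass
class RespondentRecord:
    """One respondent: design version, covariates, and chosen alternative
    (0-based) for each non-fixed task in task order."""

    respondent_id: str | int
    version: str | int
    covariates: dict[str, float]
    choices: np.ndarray

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)


@dataclass
class ChoiceDataset:
    """A design joined with respondent choices and covariates."""

    spec: StudySpec
    design: ChoiceDesign
    respondents: list[RespondentRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.respondents:
            raise ValidationError("no respondents in dataset")
        versions = set(self.design.versions)
        a = self.spec.n_alternatives
        t = self.spec.n_tasks
        for r in self.respondents:
            if r.version not in versions:
                raise ValidationError(
                    f"respondent {r.respondent_id}: unknown design version "
                    f"{r.version!r}"
                )
            if len(r.choices) != t:
                raise ValidationError(
                    f"respondent {r.respondent_id}: expected {t} choices, "
                    f"got {len(r.choices)}"
                )
            if (r.choices < 0).any() or (r.choices >= a).any():
                raise ValidationError(
                    f"respondent {r.respondent_id}: choice index out of range"
                )
            for cov in self.spec.covariates:
                if cov not in r.covariates or r.covariates[cov] is None or (
                    isinstance(r.covariates[cov], float)
                    and np.isnan(r.covariates[cov])
                ):
                    raise ValidationError(
                        f"respondent {r.respondent_id}: missing covariate {cov!r}"
                    )

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    def covariate_matrix(self) -> np.ndarray:
        """Respondent covariates as an (n_respondents, n_covariates) array in
        spec order."""
        return np.array(
            [[float(r.covariates[c]) for c in self.spec.covariates]
             for r in self.respondents]
        )
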