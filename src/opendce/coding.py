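"""Effects coding of attribute levels and construction of design matrices.

Each attribute with L levels contributes L-1 effects-coded columns: level k
(k < L) maps to the unit vector with a 1 in position k, and the last
(reference) level maps to a vector of -1s, so the implied per-level utilities
sum to zero within every attribute.  Declared first-order interactions add
element-wise products of the two attributes' main-effect columns,
(Li-1)(Lj-1) columns per pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ChoiceDataset, StudySpec, ValidationError

__all__ = ["effects_code", "CodedMatrix", "build_design_matrix", "expand_utilities"]


def effects_code(level: int, n_levels: int) -> np.ndarray:
    """Effects-code a single 1-based level index into a length ``n_levels - 1``
    vector.

    Levels ``1 .. n_levels - 1`` map to unit vectors; the reference level
    ``n_levels`` maps to all -1.
    """
    if not 1 <= level <= n_levels:
        raise ValueError(f"level {level} out of range 1..{n_levels}")
    if level == n_levels:
        return -np.ones(n_levels - 1)
    v = np.zeros(n_levels - 1)
    v[level - 1] = 1.0
    return v


def _coding_table(n_levels: int) -> np.ndarray:
    """(n_levels, n_levels - 1) table whose row l is the coded vector for
    0-based level l."""
    t = np.eye(n_levels)[:, : n_levels - 1]
    t[-1, :] = -1.0
    return t


@dataclass
class CodedMatrix:
    """Effects-coded representation of a study's utility parameterization.

    ``labels`` names every coded column as ``attr=level`` for main effects and
    ``attr1=level1 x attr2=level2`` for interaction products; ``main_slices``
    and ``interaction_slices`` locate each attribute's (or pair's) columns.
    When built from a dataset, ``matrix`` holds the coded rows for every
    non-fixed design alternative, sorted by (version, task, alt).
    """

    spec: StudySpec
    labels: list[str]
    main_slices: dict[str, slice]
    interaction_slices: dict[tuple[str, str], slice]
    matrix: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.labels)

    @classmethod
    def from_spec(cls, spec: StudySpec) -> "CodedMatrix":
        labels: list[str] = []
        main_slices: dict[str, slice] = {}
        inter_slices: dict[tuple[str, str], slice] = {}
        for attr in spec.design_attributes:
            start = len(labels)
            labels.extend(f"{attr.name}={lv}" for lv in attr.levels[:-1])
            main_slices[attr.name] = slice(start, len(labels))
        for a1, a2 in spec.interactions:
            s1 = spec.attribute(a1)
            s2 = spec.attribute(a2)
            start = len(labels)
            labels.extend(
                f"{a1}={l1} x {a2}={l2}"
                for l1 in s1.levels[:-1]
                for l2 in s2.levels[:-1]
            )
            inter_slices[(a1, a2)] = slice(start, len(labels))
        return cls(spec, labels, main_slices, inter_slices)

    def code_levels(self, levels: np.ndarray) -> np.ndarray:
        """Code an array of 0-based level indices.

        ``levels`` has shape (..., n_design_attributes), in spec attribute
        order; the result has shape (..., n_params).
        """
        levels = np.asarray(levels)
        attrs = self.spec.design_attributes
        if levels.shape[-1] != len(attrs):
            raise ValidationError(
                f"expected {len(attrs)} level columns, got {levels.shape[-1]}"
            )
        parts = {}
        for k, attr in enumerate(attrs):
            table = _coding_table(attr.n_levels)
            parts[attr.name] = table[levels[..., k]]
        out = [parts[a.name] for a in attrs]
        for a1, a2 in self.spec.interactions:
            x1 = parts[a1]
            x2 = parts[a2]
            prod = x1[..., :, None] * x2[..., None, :]
            out.append(prod.reshape(*prod.shape[:-2], -1))
        return np.concatenate(out, axis=-1)

    def respondent_tensors(self, dataset: ChoiceDataset) -> tuple[np.ndarray, np.ndarray]:
        """Coded design and choices aligned per respondent.

        Returns ``(X, chosen)`` with ``X`` of shape (n_respondents, n_tasks,
        n_alternatives, n_params) and ``chosen`` of shape (n_respondents,
        n_tasks), 0-based chosen alternative indices.
        """
        coded_by_version = {
            v: self.code_levels(dataset.design.task_array(v))
            for v in dataset.design.versions
        }
        X = np.stack([coded_by_version[r.version] for r in dataset.respondents])
        chosen = np.stack([r.choices for r in dataset.respondents])
        return X, chosen


def build_design_matrix(dataset: ChoiceDataset) -> CodedMatrix:
    """Effects-code every non-fixed design row of a dataset's design.

    Main-effect columns come first in spec attribute order, then one block of
    product columns per declared interaction; the column count is
    sum(L_k - 1) + sum over pairs (L_i - 1)(L_j - 1).
    """
    cm = CodedMatrix.from_spec(dataset.spec)
    design = dataset.design
    t = design.table[~design.table["is_fixed"]].sort_values(["version", "task", "alt"])
    cm.matrix = cm.code_levels(t[design.attribute_columns].to_numpy())
    return cm


def expand_utilities(beta: np.ndarray, cm: CodedMatrix) -> pd.DataFrame:
    """Expand coded coefficient vectors to full per-level utilities.

    ``beta`` is (..., n_params); the result is a tidy DataFrame with columns
    ``attribute``, ``level``, and one ``utility`` column per leading row of
    beta (a single ``utility`` column for a 1-D input).  Reference-level
    utilities equal minus the sum of the attribute's coded coefficients, so
    utilities sum to zero within each attribute.  Interaction blocks are
    expanded to their full level-by-level grid the same way.
    """
    beta = np.atleast_2d(np.asarray(beta))
    rows: list[tuple[str, str]] = []
    cols: list[np.ndarray] = []
    for attr in cm.spec.design_attributes:
        sl = cm.main_slices[attr.name]
        table = _coding_table(attr.n_levels)
        u = beta[:, sl] @ table.T  # (n, L)
        for l, lv in enumerate(attr.levels):
            rows.append((attr.name, lv))
            cols.append(u[:, l])
    for (a1, a2), sl in cm.interaction_slices.items():
        s1, s2 = cm.spec.attribute(a1), cm.spec.attribute(a2)
        t1, t2 = _coding_table(s1.n_levels), _coding_table(s2.n_levels)
        g = beta[:, sl].reshape(-1, s1.n_levels - 1, s2.n_levels - 1)
        grid = np.einsum("ik,nkl,jl->nij", t1, g, t2)
        for i, l1 in enumerate(s1.levels):
            for j, l2 in enumerate(s2.levels):
                rows.append((f"{a1} x {a2}", f"{l1} x {l2}"))
                cols.append(grid[:, i, j])
    values = np.column_stack(cols).T  # (n_rows, n_beta)
    out = pd.DataFrame(rows, columns=["attribute", "level"])
    if values.shape[1] == 1:
        names = ["utility"]
    else:
        names = [f"utility_{k}" for k in range(values.shape[1])]
    return pd.concat(
        [out, pd.DataFrame(values, columns=names, index=out.index)], axis=1)
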