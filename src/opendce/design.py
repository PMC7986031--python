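"""Choice-design generation, efficiency scoring and design testing.

Designs are generated with a balanced-overlap strategy: attribute levels are
drawn by quota (sampling without replacement from a level-balanced pool per
attribute), which keeps level frequencies near-perfectly balanced across the
design while still allowing both alternatives of a task to share a level.
Identical full profiles within a task are repaired by swapping one
attribute's draw, so no task ever shows the same product twice.

Efficiency is summarized by D-efficiency at the zero coefficient vector (the
utility-neutral evaluation point used when no priors are available), and a
design is stress-tested by simulating uniformly random responders and fitting
the aggregate logit: main effects should be near zero with small standard
errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import CodedMatrix
from .datamodel import ChoiceDesign, StudySpec
from .mnl import MultinomialLogit, RankDeficientError

__all__ = ["min_sample_size", "generate_design", "d_efficiency", "test_design",
           "DesignDiagnostics"]


def min_sample_size(c: int, t: int, a: int, multiplier: float = 1.0) -> int:
    """Johnson–Orme rule-of-thumb minimum sample size, N > 500c/(t*a).

    ``c`` is the largest number of levels over attributes, ``t`` the number of
    choice tasks per respondent, ``a`` the alternatives per task.  The bound
    value itself is treated as the attainable minimum; ``multiplier`` (>= 1)
    scales it, e.g. 2 for the commonly recommended doubling.
    """
    if c < 2 or t < 1 or a < 2:
        raise ValueError(f"need c >= 2, t >= 1, a >= 2; got c={c}, t={t}, a={a}")
    if multiplier < 1:
        raise ValueError(f"multiplier must be >= 1, got {multiplier}")
    return math.ceil(multiplier * 500.0 * c / (t * a))


@dataclass
class DesignDiagnostics:
    """Balance, overlap and efficiency measures for a design, plus the
    simulated-respondent test results when :func:`test_design` produced it."""

    level_balance: dict[str, dict[str, int]]
    overlap_rate: dict[str, float]
    d_efficiency: float
    estimates: dict[str, float] = field(default_factory=dict)
    simulated_se: dict[str, float] = field(default_factory=dict)
    adequate: bool | None = None
    se_threshold: float = 0.05


# ---------------------------------------------------------------------------
# generation

def _balanced_pool(n_levels: int, n_rows: int, rng: np.random.Generator) -> list[int]:
    reps = np.tile(np.arange(n_levels), n_rows // n_levels + 1)[:n_rows]
    rng.shuffle(reps)
    return reps.tolist()


def generate_design(spec: StudySpec, n_versions: int, seed: int | None = None,
                    include_fixed: bool = False) -> ChoiceDesign:
    """Generate a randomized balanced-overlap design.

    Produces ``n_versions`` versions of ``spec.n_tasks`` tasks with
    ``spec.n_alternatives`` alternatives each.  Level frequencies per
    attribute are exact to within rounding across the whole design; duplicate
    profiles within a task are repaired by redrawing one attribute.  With
    ``include_fixed`` a comprehension task (task 0, flagged ``is_fixed``)
    pairing each attribute's first level against its last is prepended to
    every version.
    """
    if n_versions < 1:
        raise ValueError("n_versions must be >= 1")
    rng = np.random.default_rng(seed)
    attrs = spec.design_attributes
    t, a = spec.n_tasks, spec.n_alternatives
    n_rows = n_versions * t * a
    pools = {attr.name: _balanced_pool(attr.n_levels, n_rows, rng) for attr in attrs}

    rows = []
    for v in range(1, n_versions + 1):
        if include_fixed:
            for alt in range(a):
                prof = {attr.name: (0 if alt == 0 else attr.n_levels - 1)
                        for attr in attrs}
                rows.append({"version": v, "task": 0, "alt": alt + 1,
                             "is_fixed": True, **prof})
        for task in range(1, t + 1):
            task_profiles: list[tuple] = []
            for alt in range(a):
                profile = {attr.name: pools[attr.name].pop() for attr in attrs}
                tries = 0
                while tuple(profile.values()) in task_profiles and tries < 50:
                    # redraw one attribute from its remaining pool to break
                    # the duplicate without disturbing balance
                    order = rng.permutation(len(attrs))
                    fixed = False
                    for ai in order:
                        attr = attrs[ai]
                        pool = pools[attr.name]
                        cand = [ix for ix, lv in enumerate(pool)
                                if lv != profile[attr.name]]
                        if cand:
                            ix = int(rng.choice(cand))
                            pool.append(profile[attr.name])
                            profile[attr.name] = pool.pop(ix)
                            fixed = True
                            break
                    if not fixed:  # pools exhausted of alternatives (rare)
                        attr = attrs[int(rng.integers(len(attrs)))]
                        profile[attr.name] = int(
                            (profile[attr.name] + 1) % attr.n_levels)
                    tries += 1
                task_profiles.append(tuple(profile.values()))
                rows.append({"version": v, "task": task, "alt": alt + 1,
                             "is_fixed": False, **profile})
    table = pd.DataFrame(rows)
    return ChoiceDesign(spec=spec, table=table,
                        fixed_task=0 if include_fixed else None)


# ---------------------------------------------------------------------------
# diagnostics

def _coded_tasks(design: ChoiceDesign, spec: StudySpec,
                 cm: CodedMatrix | None = None) -> np.ndarray:
    """All non-fixed tasks of all versions as one (T, a, p) tensor."""
    cm = cm or CodedMatrix.from_spec(spec)
    arrays = [cm.code_levels(design.task_array(v)) for v in design.versions]
    return np.concatenate(arrays, axis=0)


def d_efficiency(design: ChoiceDesign, spec: StudySpec) -> float:
    """Per-task D-efficiency at the zero coefficient vector.

    With V the inverse of the aggregate-logit information matrix at beta = 0
    and p the number of coded parameters, the D-error is det(V)^(1/p); the
    score returned is 1 / (n_tasks * D-error), normalized so replicating every
    task leaves the per-task score unchanged.  Raises
    :class:`~opendce.mnl.RankDeficientError` for unidentified designs.
    """
    cm = CodedMatrix.from_spec(spec)
    X = _coded_tasks(design, spec, cm)
    T, a, p = X.shape
    # information at beta=0: sum_t X_t' (diag(pi) - pi pi') X_t, pi = 1/a
    xbar = X.mean(axis=1)
    M = np.einsum("tap,taq->pq", X, X) / a - xbar.T @ xbar
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        w, v = np.linalg.eigh(M)
        bad = w < 1e-10 * max(w.max(), 1.0)
        cols = np.abs(v[:, bad]).max(axis=1) > 1e-6
        raise RankDeficientError([cm.labels[i] for i in np.nonzero(cols)[0]])
    # 1/(T * det(M^-1)^(1/p)) = det(M)^(1/p) / T
    return float(np.exp(logdet / p) / T)


def _level_balance(design: ChoiceDesign, spec: StudySpec) -> dict[str, dict[str, int]]:
    t = design.table[~design.table["is_fixed"]]
    out: dict[str, dict[str, int]] = {}
    for attr in spec.design_attributes:
        counts = t[attr.name].value_counts()
        out[attr.name] = {lv: int(counts.get(i, 0))
                          for i, lv in enumerate(attr.levels)}
    return out


def _overlap_rate(design: ChoiceDesign, spec: StudySpec) -> dict[str, float]:
    t = design.table[~design.table["is_fixed"]]
    out = {}
    for attr in spec.design_attributes:
        shared = t.groupby(["version", "task"])[attr.name].apply(
            lambda g: g.duplicated().any())
        out[attr.name] = float(shared.mean())
    return out


def design_diagnostics(design: ChoiceDesign, spec: StudySpec) -> DesignDiagnostics:
    """Balance, overlap and D-efficiency without the simulation test."""
    return DesignDiagnostics(
        level_balance=_level_balance(design, spec),
        overlap_rate=_overlap_rate(design, spec),
        d_efficiency=d_efficiency(design, spec),
    )


def test_design(design: ChoiceDesign, spec: StudySpec, n_sim_respondents: int = 300,
                seed: int | None = None, se_threshold: float = 0.05) -> DesignDiagnostics:
    """Stress-test a design with simulated random responders.

    ``n_sim_respondents`` synthetic respondents (assigned to versions
    round-robin) choose uniformly at random; the aggregate multinomial logit
    is then fitted and each main effect's estimate and standard error
    reported.  The design is flagged ``adequate`` when every main-effect SE is
    below ``se_threshold`` (0.05 by default, the usual conjoint-practice
    bar for "reasonable precision").  Rank deficiency (e.g. an attribute that
    never varies) propagates as :class:`~opendce.mnl.RankDeficientError`.
    """
    rng = np.random.default_rng(seed)
    cm = CodedMatrix.from_spec(spec)
    versions = design.versions
    coded = {v: cm.code_levels(design.task_array(v)) for v in versions}
    X_list, y_list = [], []
    for i in range(n_sim_respondents):
        v = versions[i % len(versions)]
        X_list.append(coded[v])
        y_list.append(rng.integers(spec.n_alternatives, size=spec.n_tasks))
    X = np.concatenate(X_list, axis=0)
    y = np.concatenate(y_list)
    est = MultinomialLogit().fit(X, y, labels=cm.labels)
    if not est.converged_:
        raise RuntimeError("aggregate logit did not converge on the design test")
    n_main = sum(attr.n_levels - 1 for attr in spec.design_attributes)
    estimates = dict(zip(cm.labels[:n_main], est.coef_[:n_main]))
    ses = dict(zip(cm.labels[:n_main], est.se_[:n_main]))
    diag = design_diagnostics(design, spec)
    diag.estimates = estimates
    diag.simulated_se = ses
    diag.se_threshold = se_threshold
    diag.adequate = bool(max(ses.values()) < se_threshold)
    return diag
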