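"""Share-of-preference market simulation from individual utilities.

A hypothetical product assigns one level to every in-design attribute; its
utility for a respondent is the sum of that respondent's part-worth utilities
over the profile's levels, plus any declared interaction utilities for
co-occurring level pairs.  Under the default first-choice rule each
respondent votes for their highest-utility product (ties split equally, for
determinism); the logit rule averages respondent-level softmax shares and is
provided for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import CodedMatrix
from .datamodel import StudySpec

__all__ = ["ProductProfile", "SimulationResult", "product_utility",
           "share_of_preference", "preference_gain"]


@dataclass(frozen=True)
class ProductProfile:
    """One hypothetical product: a level label for every in-design attribute."""

    name: str
    levels: dict[str, str]

    def validate(self, spec: StudySpec) -> None:
        for attr in spec.design_attributes:
            if attr.name not in self.levels:
                raise ValueError(
                    f"profile {self.name!r}: missing level for attribute "
                    f"{attr.name!r}"
                )
            if self.levels[attr.name] not in attr.levels:
                raise ValueError(
                    f"profile {self.name!r}: unknown level "
                    f"{self.levels[attr.name]!r} for attribute {attr.name!r}"
                )
        extra = set(self.levels) - {a.name for a in spec.design_attributes}
        if extra:
            raise ValueError(f"profile {self.name!r}: unknown attributes {sorted(extra)}")

    def level_indices(self, spec: StudySpec) -> np.ndarray:
        self.validate(spec)
        return np.array([
            attr.levels.index(self.levels[attr.name])
            for attr in spec.design_attributes
        ])


@dataclass
class SimulationResult:
    """Predicted shares of preference for a set of product profiles."""

    profiles: list[str]
    shares: np.ndarray  # (n_profiles,), sums to 1
    rule: str
    votes: np.ndarray = field(default=None, repr=False)  # (n_resp, n_profiles)

    def share(self, profile: str) -> float:
        return float(self.shares[self.profiles.index(profile)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"profile": self.profiles, "share": self.shares})


def product_utility(beta: np.ndarray, profile: ProductProfile,
                    cm: CodedMatrix) -> float | np.ndarray:
    """Total utility of a product for one respondent (1-D ``beta``) or a
    population (2-D ``beta``, one row per respondent).

    Includes declared interaction terms for the profile's co-occurring level
    pairs, since the coded profile vector carries the interaction columns.
    """
    x = cm.code_levels(profile.level_indices(cm.spec))
    out = np.asarray(beta) @ x
    return float(out) if np.ndim(out) == 0 else out


def share_of_preference(beta: np.ndarray, profiles: list[ProductProfile],
                        cm: CodedMatrix, rule: str = "first-choice") -> SimulationResult:
    """Simulate a market of the given profiles over a population.

    ``beta`` is (n_respondents, n_params) individual coded utilities.  Under
    ``rule="first-choice"`` each respondent contributes one vote split equally
    among their argmax-utility profiles; under ``rule="logit"`` each
    respondent contributes softmax shares.  Shares always sum to 1.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 product profiles to simulate a market")
    if rule not in ("first-choice", "logit"):
        raise ValueError(f"unknown rule {rule!r}; use 'first-choice' or 'logit'")
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    U = np.column_stack([product_utility(beta, pr, cm) for pr in profiles])
    if rule == "first-choice":
        best = U.max(axis=1, keepdims=True)
        is_best = np.isclose(U, best, rtol=0.0, atol=1e-12)
        votes = is_best / is_best.sum(axis=1, keepdims=True)
    else:
        u = U - U.max(axis=1, keepdims=True)
        e = np.exp(u)
        votes = e / e.sum(axis=1, keepdims=True)
    shares = votes.mean(axis=0)
    return SimulationResult(profiles=[p.name for p in profiles], shares=shares,
                            rule=rule, votes=votes)


def preference_gain(result: SimulationResult, target: str, reference: str) -> float:
    """Relative share gain of ``target`` over ``reference``, in percent:
    100 * (share_target - share_reference) / share_reference."""
    s_t = result.share(target)
    s_r = result.share(reference)
    if s_r == 0.0:
        raise ZeroDivisionError(
            f"reference profile {reference!r} has zero share; gain undefined"
        )
    return 100.0 * (s_t - s_r) / s_r
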