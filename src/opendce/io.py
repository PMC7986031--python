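"""Readers and writers for study specs, designs, responses and results.

File conventions follow common conjoint-software practice: level indices and
alternative indices are 1-based in every CSV and converted to 0-based in
memory.  The design CSV carries an ``is_fixed`` flag for the comprehension
task, which is stored but always excluded from estimation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (AttributeSpec, ChoiceDataset, ChoiceDesign,
                        RespondentRecord, StudySpec, ValidationError)
from .hb import HBConfig
from .importance import ImportanceTable
from .market import ProductProfile

__all__ = [
    "read_study_spec", "write_study_spec", "read_design", "write_design",
    "read_choice_data", "write_responses", "read_utilities", "write_utilities",
    "read_importance", "write_importance", "read_profiles", "write_simulation",
    "read_hb_config",
]


# ---------------------------------------------------------------------------
# study spec

def read_study_spec(path: str | Path) -> StudySpec:
    """Read a JSON study spec; every violated invariant raises
    :class:`~opendce.datamodel.ValidationError` naming the field."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        attributes = tuple(
            AttributeSpec(a["name"], tuple(a["levels"]), a.get("in_design", True))
            for a in doc["attributes"]
        )
        return StudySpec(
            attributes=attributes,
            n_tasks=int(doc.get("n_tasks", 10)),
            n_alternatives=int(doc.get("n_alternatives", 2)),
            interactions=tuple(tuple(p) for p in doc.get("interactions", [])),
            covariates=tuple(doc.get("covariates", [])),
        )
    except KeyError as e:
        raise ValidationError(f"study spec missing required field {e}") from e


def write_study_spec(spec: StudySpec, path: str | Path) -> None:
    doc = {
        "attributes": [
            {"name": a.name, "levels": list(a.levels), "in_design": a.in_design}
            for a in spec.attributes
        ],
        "n_tasks": spec.n_tasks,
        "n_alternatives": spec.n_alternatives,
        "interactions": [list(p) for p in spec.interactions],
        "covariates": list(spec.covariates),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# design

def read_design(path: str | Path, spec: StudySpec) -> ChoiceDesign:
    """Read a design CSV (columns: version, task, alt, one 1-based level
    column per in-design attribute, is_fixed)."""
    t = pd.read_csv(path)
    needed = {"version", "task", "alt"} | {a.name for a in spec.design_attributes}
    missing = needed - set(t.columns)
    if missing:
        raise ValidationError(f"design file missing columns: {sorted(missing)}")
    if "is_fixed" not in t.columns:
        t["is_fixed"] = False
    t["is_fixed"] = t["is_fixed"].astype(bool)
    for a in spec.design_attributes:
        t[a.name] = t[a.name].astype(int) - 1  # 1-based in files
    fixed = t.loc[t["is_fixed"], "task"]
    fixed_task = int(fixed.iloc[0]) if len(fixed) else None
    return ChoiceDesign(spec=spec, table=t, fixed_task=fixed_task)


def write_design(design: ChoiceDesign, path: str | Path) -> None:
    t = design.table.copy()
    for a in design.spec.design_attributes:
        t[a.name] = t[a.name].astype(int) + 1
    cols = ["version", "task", "alt"] + design.attribute_columns + ["is_fixed"]
    t[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# responses

def read_choice_data(design_path: str | Path, responses_path: str | Path,
                     spec: StudySpec) -> ChoiceDataset:
    """Join a design file with a long-format response file.

    The response CSV has one row per (respondent, task) with columns
    ``respondent_id, version, task, choice`` (1-based chosen alternative)
    plus one column per spec covariate.  Rows for the fixed comprehension
    task are dropped before analysis.
    """
    design = read_design(design_path, spec)
    r = pd.read_csv(responses_path)
    if len(r) == 0:
        raise ValidationError("no respondents: responses file is empty")
    needed = {"respondent_id", "version", "task", "choice"} | set(spec.covariates)
    missing = needed - set(r.columns)
    if missing:
        raise ValidationError(f"responses file missing columns: {sorted(missing)}")
    if design.fixed_task is not None:
        r = r[r["task"] != design.fixed_task]
    versions = set(design.versions)
    non_fixed_tasks = sorted(
        design.table.loc[~design.table["is_fixed"], "task"].unique())
    respondents = []
    for rid, g in r.groupby("respondent_id", sort=False):
        v = g["version"].iloc[0]
        if v not in versions:
            raise ValidationError(
                f"respondent {rid}: unknown design version {v!r}")
        g = g.set_index("task")
        missing_tasks = [tk for tk in non_fixed_tasks if tk not in g.index]
        if missing_tasks:
            raise ValidationError(
                f"respondent {rid}: missing choice for task(s) {missing_tasks}")
        choices = g.loc[non_fixed_tasks, "choice"].to_numpy(dtype=int) - 1
        covs = {c: g[c].iloc[0] for c in spec.covariates}
        respondents.append(RespondentRecord(
            respondent_id=rid, version=v, covariates=covs, choices=choices))
    return ChoiceDataset(spec=spec, design=design, respondents=respondents)


def write_responses(dataset: ChoiceDataset, path: str | Path) -> None:
    non_fixed = sorted(
        dataset.design.table.loc[~dataset.design.table["is_fixed"], "task"].unique())
    rows = []
    for r in dataset.respondents:
        for task, choice in zip(non_fixed, r.choices):
            rows.append({
                "respondent_id": r.respondent_id, "version": r.version,
                "task": task, "choice": int(choice) + 1,
                **{c: r.covariates[c] for c in dataset.spec.covariates},
            })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results

def write_utilities(point_utils: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy per-respondent utility frame
    (respondent_id, attribute, level, utility) to CSV at full precision."""
    point_utils.to_csv(path, index=False, float_format="%.17g")


def read_utilities(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_importance(table: ImportanceTable, path: str | Path) -> None:
    table.table.to_csv(path, index=False, float_format="%.17g")


def read_importance(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_profiles(path: str | Path) -> list[ProductProfile]:
    """Read product profiles from JSON: a list of {id, <attribute>: <level>}
    maps (or {id, levels: {...}})."""
    with open(path) as fh:
        doc = json.load(fh)
    profiles = []
    for item in doc:
        item = dict(item)
        name = str(item.pop("id"))
        levels = item.pop("levels", None) or item
        profiles.append(ProductProfile(name=name, levels=dict(levels)))
    return profiles


def write_simulation(result, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_hb_config(path: str | Path) -> HBConfig:
    """Read MCMC settings from a YAML or JSON document; unknown keys are
    rejected so typos do not silently fall back to defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = set(HBConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(f"unknown HB config keys: {sorted(unknown)}")
    return HBConfig(**doc)
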