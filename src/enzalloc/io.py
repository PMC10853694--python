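"""Pathway and result documents: schema-versioned YAML plus TSV tables.

One structured-text schema (versioned) describes a pathway together with
the rate law and requested task; results (optimal states, control
profiles, growth laws) are written back as YAML and as tab-separated
tables with one row per reaction and one per metabolite.  Documents
round-trip losslessly and unknown fields are rejected by name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .allocate import OptimalState
from .cellmodel import CellModelSpec, GrowthLaw
from .errors import SchemaError
from .mca import ControlProfile
from .ratelaws import PathwaySpec, RateLawKind, ReactionKinetics

__all__ = [
    "SCHEMA_VERSION",
    "PathwayDocument",
    "read_pathway",
    "write_pathway",
    "read_cell_model",
    "write_results",
    "results_table",
]

SCHEMA_VERSION = "1"

_TASKS = ("allocate", "mca", "steady_state", "growth", "sweep")
_REACTION_FIELDS = ("kcat_fwd", "kcat_rev", "K_S", "K_P", "K_eq")
_PATHWAY_FIELDS = (
    "reactions", "s0", "sn", "eps_tot", "s_tot",
    "enzyme_weights", "metabolite_weights",
)
_CELL_FIELDS = (
    "kcat_t", "kcat_m", "kcat_r", "K_Mt", "K_Mm", "K_Mr",
    "eps_tot", "s_tot", "s_sugar",
)


@dataclass(frozen=True)
class PathwayDocument:
    """A pathway plus the rate law and (optional) task it is meant for."""

    pathway: PathwaySpec
    rate_law: RateLawKind
    task: Optional[str] = None
    schema_version: str = SCHEMA_VERSION


def _reject_unknown(mapping: dict, allowed, context: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise SchemaError(
            f"unknown field(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(allowed)}"
        )


def _parse_pathway(raw: dict) -> PathwaySpec:
    if not isinstance(raw, dict):
        raise SchemaError("'pathway' must be a mapping")
    _reject_unknown(raw, _PATHWAY_FIELDS, "pathway")
    reactions = raw.get("reactions")
    if not isinstance(reactions, list) or not reactions:
        raise SchemaError("pathway.reactions must be a non-empty list")
    kins = []
    for i, r in enumerate(reactions):
        if not isinstance(r, dict):
            raise SchemaError(f"reaction {i + 1} must be a mapping")
        _reject_unknown(r, _REACTION_FIELDS, f"reaction {i + 1}")
        if "kcat_fwd" not in r:
            raise SchemaError(f"reaction {i + 1}: kcat_fwd is required")
        kins.append(ReactionKinetics(**{k: float(v) for k, v in r.items()}))
    def opt(name):
        v = raw.get(name)
        return None if v is None else float(v)
    weights = raw.get("enzyme_weights")
    met_weights = raw.get("metabolite_weights")
    return PathwaySpec(
        reactions=tuple(kins),
        s0=opt("s0"),
        sn=opt("sn"),
        eps_tot=float(raw.get("eps_tot", 1.0)),
        s_tot=opt("s_tot"),
        enzyme_weights=tuple(weights) if weights else None,
        metabolite_weights=tuple(met_weights) if met_weights else None,
    )


def read_pathway(path: Union[str, Path]) -> PathwayDocument:
    """Read and validate a pathway document; errors name field and constraint."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError("document root must be a mapping")
    _reject_unknown(raw, ("schema_version", "rate_law", "pathway", "task"), "document")
    version = str(raw.get("schema_version", ""))
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"schema_version {version!r} not supported (expected {SCHEMA_VERSION!r})"
        )
    try:
        law = RateLawKind(raw.get("rate_law"))
    except ValueError as exc:
        raise SchemaError(f"unknown rate_law {raw.get('rate_law')!r}") from exc
    task = raw.get("task")
    if task is not None and task not in _TASKS:
        raise SchemaError(f"unknown task {task!r}; allowed: {_TASKS}")
    pw = _parse_pathway(raw.get("pathway"))
    for i, kin in enumerate(pw.reactions):
        try:
            kin.require(law)
        except Exception as exc:
            raise SchemaError(f"reaction {i + 1}: {exc}") from exc
    return PathwayDocument(pathway=pw, rate_law=law, task=task)


def _pathway_to_dict(pw: PathwaySpec) -> dict:
    reactions = []
    for kin in pw.reactions:
        d = {f: getattr(kin, f) for f in _REACTION_FIELDS if getattr(kin, f) is not None}
        reactions.append(d)
    out: dict = {"reactions": reactions, "eps_tot": pw.eps_tot}
    for f in ("s0", "sn", "s_tot"):
        if getattr(pw, f) is not None:
            out[f] = getattr(pw, f)
    if pw.enzyme_weights is not None:
        out["enzyme_weights"] = list(pw.enzyme_weights)
    if pw.metabolite_weights is not None:
        out["metabolite_weights"] = list(pw.metabolite_weights)
    return out


def write_pathway(doc: PathwayDocument, path: Union[str, Path]) -> None:
    data = {
        "schema_version": SCHEMA_VERSION,
        "rate_law": doc.rate_law.value,
        "pathway": _pathway_to_dict(doc.pathway),
    }
    if doc.task is not None:
        data["task"] = doc.task
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_cell_model(path: Union[str, Path]) -> CellModelSpec:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError("document root must be a mapping")
    _reject_unknown(raw, ("schema_version", "cell_model"), "document")
    if str(raw.get("schema_version", "")) != SCHEMA_VERSION:
        raise SchemaError(f"schema_version must be {SCHEMA_VERSION!r}")
    cell = raw.get("cell_model")
    if not isinstance(cell, dict):
        raise SchemaError("'cell_model' must be a mapping")
    _reject_unknown(cell, _CELL_FIELDS, "cell_model")
    return CellModelSpec(**{k: float(v) for k, v in cell.items()})


def _clean(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def _state_to_dict(state: OptimalState) -> dict:
    return {
        "rate_law": state.rate_law.value,
        "J_star": float(state.J_star),
        "eps_star": [float(x) for x in state.eps_star],
        "s_star": [_clean(float(x)) for x in state.s_star],
        "free_metabolites": [bool(x) for x in state.free_metabolites],
        "theta_star": [_clean(float(x)) for x in state.theta_star],
        "diagnostics": {
            k: v for k, v in state.diagnostics.items()
            if isinstance(v, (int, float, str, bool))
        },
    }


def results_table(result: Union[OptimalState, ControlProfile]) -> pd.DataFrame:
    """Tabular export: one row per reaction then one per metabolite."""
    if isinstance(result, OptimalState):
        n = result.n
        rows = [
            {"kind": "reaction", "index": i + 1,
             "eps_star": result.eps_star[i],
             "theta_star": result.theta_star[i]}
            for i in range(n)
        ]
        rows += [
            {"kind": "metabolite", "index": i,
             "s_star": result.s_star[i],
             "free": bool(result.free_metabolites[i])}
            for i in range(n + 1)
        ]
        return pd.DataFrame(rows)
    if isinstance(result, ControlProfile):
        n = len(result.flux_control)
        rows = [
            {"kind": "reaction", "index": l + 1,
             "C_J": result.flux_control[l]}
            for l in range(n)
        ]
        rows += [
            {"kind": "metabolite", "index": i, "s": result.s[i]}
            for i in range(n + 1)
        ]
        return pd.DataFrame(rows)
    raise SchemaError(f"no table representation for {type(result).__name__}")


def write_results(
    result: Union[OptimalState, ControlProfile, GrowthLaw],
    path: Union[str, Path],
) -> None:
    """Write a result as YAML (.yaml/.yml) or TSV (.tsv) by extension."""
    path = Path(path)
    if path.suffix == ".tsv":
        results_table(result).to_csv(path, sep="\t", index=False, float_format="%.12g")
        return
    if isinstance(result, OptimalState):
        data = _state_to_dict(result)
    elif isinstance(result, ControlProfile):
        data = {
            "flux_control": [float(x) for x in result.flux_control],
            "conc_control": [[float(x) for x in row] for row in result.conc_control],
            "elasticities": [[float(x) for x in row] for row in result.elasticities],
            "summation_residual": float(result.summation_residual),
            "connectivity_residuals": [float(x) for x in result.connectivity_residuals],
            "J": float(result.J),
            "s": [_clean(float(x)) for x in result.s],
        }
    elif isinstance(result, GrowthLaw):
        data = {
            "law_kind": result.law_kind,
            "mu_max": float(result.mu_max),
            "K_Monod": _clean(result.K_Monod) if result.K_Monod is None else float(result.K_Monod),
            "A": None if result.A is None else float(result.A),
            "B": None if result.B is None else float(result.B),
        }
    else:
        raise SchemaError(f"cannot serialize {type(result).__name__}")
    path.write_text(yaml.safe_dump(data, sort_keys=False))
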