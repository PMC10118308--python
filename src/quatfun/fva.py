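"""Flux variability analysis with gene knockouts on small metabolic models.

Models are a minimal JSON dialect::

    {"metabolites": [{"id": "A", "boundary": false}, ...],
     "reactions": [{"id": "R1",
                    "stoichiometry": {"A": -1, "B": 1},
                    "lower_bound": 0, "upper_bound": 10,
                    "gpr": "g1 or g2"}, ...]}

Boundary metabolites are excluded from the steady-state constraint.
A knockout closes every reaction whose GPR evaluates false with the gene
removed; a reaction is *affected* if its maximum absolute feasible flux
drops by more than the threshold fraction (default 50%), and *blocked* if
the whole feasible range lies below 1e-6 in absolute value.
"""

from __future__ import annotations

import ast
import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

BLOCKED_THRESHOLD = 1e-6
AFFECTED_FRACTION = 0.5


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: str = ""


@dataclass
class MetabolicModel:
    metabolites: list[str]
    boundary: set[str]
    reactions: list[Reaction]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            if rxn.gpr:
                out |= _gpr_genes(rxn.gpr)
        return out

    def stoichiometric_matrix(self) -> np.ndarray:
        internal = [m for m in self.metabolites if m not in self.boundary]
        index = {m: i for i, m in enumerate(internal)}
        s = np.zeros((len(internal), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                if met in index:
                    s[index[met], j] = coeff
        return s


@dataclass
class FluxRange:
    reaction_ids: list[str]
    minimum: np.ndarray
    maximum: np.ndarray

    def max_abs(self) -> np.ndarray:
        return np.maximum(np.abs(self.minimum), np.abs(self.maximum))

    def span(self) -> np.ndarray:
        return self.maximum - self.minimum

    def blocked(self, threshold: float = BLOCKED_THRESHOLD) -> np.ndarray:
        return (np.abs(self.minimum) < threshold) & (
            np.abs(self.maximum) < threshold
        )


@dataclass
class KnockoutEffect:
    gene: str
    affected: list[str] = field(default_factory=list)
    blocked: list[str] = field(default_factory=list)

    @property
    def any_affected(self) -> bool:
        return bool(self.affected)


def _validate(model: MetabolicModel) -> MetabolicModel:
    met_set = set(model.metabolites)
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ValueError(
                f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        unknown = set(rxn.stoichiometry) - met_set
        if unknown:
            raise ValueError(
                f"reaction {rxn.id}: unknown metabolites {sorted(unknown)}"
            )
        if rxn.gpr:
            _parse_gpr(rxn.gpr)
    return model


def read_model(source: str | Path | dict) -> MetabolicModel:
    """Read and validate the JSON model dialect."""
    if isinstance(source, dict):
        doc = source
    else:
        doc = json.loads(Path(source).read_text())
    metabolites = [m["id"] for m in doc["metabolites"]]
    boundary = {m["id"] for m in doc["metabolites"] if m.get("boundary")}
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=r.get("gpr", ""),
        )
        for r in doc["reactions"]
    ]
    return _validate(
        MetabolicModel(metabolites=metabolites, boundary=boundary,
                       reactions=reactions)
    )


def _parse_gpr(expr: str) -> ast.expr:
    tree = ast.parse(expr, mode="eval").body
    def check(node: ast.expr) -> None:
        if isinstance(node, ast.BoolOp):
            for v in node.values:
                check(v)
        elif isinstance(node, ast.Name):
            pass
        else:
            raise ValueError(f"unsupported GPR syntax in {expr!r}")
    check(tree)
    return tree


def _gpr_genes(expr: str) -> set[str]:
    tree = _parse_gpr(expr)
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


def evaluate_gpr(expr: str, knocked: set[str]) -> bool:
    """Evaluate a GPR boolean rule with the knocked genes set to False."""
    if not expr:
        return True
    tree = _parse_gpr(expr)
    def ev(node: ast.expr) -> bool:
        if isinstance(node, ast.Name):
            return node.id not in knocked
        assert isinstance(node, ast.BoolOp)
        vals = [ev(v) for v in node.values]
        return all(vals) if isinstance(node.op, ast.And) else any(vals)
    return ev(tree)


def run_fva(model: MetabolicModel, tol: float = 1e-9) -> FluxRange:
    """Per-reaction LP min/max of flux subject to S v = 0 and bounds."""
    s = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    n = len(model.reactions)
    vmin = np.zeros(n)
    vmax = np.zeros(n)
    b_eq = np.zeros(s.shape[0])
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        lo = linprog(c, A_eq=s, b_eq=b_eq, bounds=bounds, method="highs")
        hi = linprog(-c, A_eq=s, b_eq=b_eq, bounds=bounds, method="highs")
        if not (lo.success and hi.success):
            raise ValueError(
                f"infeasible model while optimizing {model.reactions[j].id}"
            )
        vmin[j] = lo.fun
        vmax[j] = -hi.fun
    vmin[np.abs(vmin) < tol] = 0.0
    vmax[np.abs(vmax) < tol] = 0.0
    return FluxRange(
        reaction_ids=[r.id for r in model.reactions],
        minimum=vmin, maximum=vmax,
    )


def knockout(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Close every reaction whose GPR evaluates false without ``gene``."""
    if gene not in model.genes():
        raise ValueError(f"gene {gene!r} appears in no GPR")
    ko = copy.deepcopy(model)
    for rxn in ko.reactions:
        if rxn.gpr and not evaluate_gpr(rxn.gpr, {gene}):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return ko


def closed_reactions(model: MetabolicModel, gene: str) -> set[str]:
    """Reactions whose GPR evaluates false once ``gene`` is removed."""
    return {
        rxn.id for rxn in model.reactions
        if rxn.gpr and not evaluate_gpr(rxn.gpr, {gene})
    }


def knockout_effect(
    wild: FluxRange,
    ko: FluxRange,
    gene: str = "",
    affected_fraction: float = AFFECTED_FRACTION,
    blocked_threshold: float = BLOCKED_THRESHOLD,
    mode: str = "max_abs",
    exclude: set[str] = frozenset(),
) -> KnockoutEffect:
    """Affected = flux reduced by more than ``affected_fraction``; blocked =
    feasible range below ``blocked_threshold`` in absolute value.

    ``mode`` selects the FVA quantity compared: 'max_abs' (default),
    'min_abs' or 'span'.  Reactions already blocked in the wild type are
    never counted as affected; ``exclude`` removes reactions (typically the
    ones closed directly by the knocked gene) so the effect measures network
    propagation rather than the knockout itself.
    """
    if wild.reaction_ids != ko.reaction_ids:
        raise ValueError("wild-type and knockout reaction sets differ")
    if mode == "max_abs":
        w, k = wild.max_abs(), ko.max_abs()
    elif mode == "min_abs":
        w = np.minimum(np.abs(wild.minimum), np.abs(wild.maximum))
        k = np.minimum(np.abs(ko.minimum), np.abs(ko.maximum))
    elif mode == "span":
        w, k = wild.span(), ko.span()
    else:
        raise ValueError(f"unknown comparison mode {mode!r}")
    wild_blocked = wild.blocked(blocked_threshold)
    excluded = np.array(
        [rid in exclude for rid in wild.reaction_ids], dtype=bool
    )
    affected_mask = (
        (~wild_blocked) & (~excluded) & (k < (1.0 - affected_fraction) * w)
    )
    blocked_mask = ko.blocked(blocked_threshold) & ~wild_blocked & ~excluded
    ids = np.array(wild.reaction_ids)
    return KnockoutEffect(
        gene=gene,
        affected=ids[affected_mask].tolist(),
        blocked=ids[blocked_mask].tolist(),
    )


def gene_knockout_effect(
    model: MetabolicModel,
    gene: str,
    wild: FluxRange | None = None,
    affected_fraction: float = AFFECTED_FRACTION,
    blocked_threshold: float = BLOCKED_THRESHOLD,
    mode: str = "max_abs",
) -> KnockoutEffect:
    """Wild-type FVA vs knockout FVA for one gene, with the directly closed
    reactions excluded from the effect tally."""
    if wild is None:
        wild = run_fva(model)
    ko_model = knockout(model, gene)
    ko = run_fva(ko_model)
    return knockout_effect(
        wild, ko, gene=gene,
        affected_fraction=affected_fraction,
        blocked_threshold=blocked_threshold,
        mode=mode,
        exclude=closed_reactions(model, gene),
    )
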