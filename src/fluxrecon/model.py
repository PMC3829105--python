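"""Stoichiometric model representation and linear-programming analyses.

The model is the usual constraint-based object: a stoichiometric matrix S,
per-reaction flux bounds, a biomass (objective) reaction and an ATP
maintenance drain.  Flux balance analysis (FBA) optimizes a single reaction
flux subject to S v = 0 and the bounds; flux variability analysis (FVA)
fixes the objective at a given value and reports, reaction by reaction, the
interval the flux can span while every other flux varies freely within its
constraints.

Fluxes are mmol/gDCW/h throughout; the biomass reaction flux numerically
equals the specific growth rate mu (1/h).  All LPs are solved with HiGHS
via scipy.optimize.linprog.

Alternate optima are expected in underdetermined networks: objective values
and FVA intervals are stable contracts, individual FBA flux vectors are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .gpr import evaluate_gpr, gpr_genes, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxDistribution",
    "FVAResult",
    "ModelValidationError",
    "load_model",
    "save_model",
    "fba",
    "fva",
    "essential_genes",
    "delete_genes",
    "set_maintenance",
]

#: Solver feasibility/optimality tolerance passed to HiGHS.
SOLVER_TOL = 1e-9
#: Tolerance used when asserting mass balance / bounds on solutions.
BALANCE_TOL = 1e-6


class ModelValidationError(ValueError):
    """Model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    formula: Optional[Dict[str, float]] = None


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry (mmol per unit flux), bounds, GPR.

    Reversibility is encoded solely through the bounds; a negative lower
    bound means the reaction may run backwards.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        parse_gpr(self.gpr)  # raises GprError on malformed rules


@dataclass
class MetabolicModel:
    reactions: List[Reaction]
    metabolites: List[Metabolite]
    objective_reaction: str
    atp_maintenance_reaction: Optional[str] = None
    id: str = "model"

    def __post_init__(self):
        self.validate()

    # -- structure -----------------------------------------------------
    def validate(self) -> None:
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            dup = sorted({i for i in mids if mids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        declared = set(mids)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - declared
            if unknown:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites {sorted(unknown)}"
                )
        if self.objective_reaction not in set(rids):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        if (
            self.atp_maintenance_reaction is not None
            and self.atp_maintenance_reaction not in set(rids)
        ):
            raise ModelValidationError(
                f"maintenance reaction {self.atp_maintenance_reaction!r} not in model"
            )

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for rxn in self.reactions:
            out |= gpr_genes(rxn.gpr)
        return out

    def reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)

    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        midx = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[midx[met], j] = coef
        return S

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            metabolites=list(self.metabolites),
            objective_reaction=self.objective_reaction,
            atp_maintenance_reaction=self.atp_maintenance_reaction,
            id=self.id,
        )

    def with_bounds(self, bounds: Mapping[str, Tuple[float, float]]) -> "MetabolicModel":
        """Copy with selected reaction bounds replaced."""
        new = []
        for rxn in self.reactions:
            if rxn.id in bounds:
                lo, hi = bounds[rxn.id]
                new.append(replace(rxn, lower_bound=lo, upper_bound=hi))
            else:
                new.append(rxn)
        return MetabolicModel(
            new, list(self.metabolites), self.objective_reaction,
            self.atp_maintenance_reaction, self.id,
        )


@dataclass
class FluxDistribution:
    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FVAResult:
    intervals: Dict[str, Tuple[float, float]]
    objective_reaction: str
    objective_value: float

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.intervals[rid]


# ---------------------------------------------------------------------------
# JSON serialization (schema: metabolites / reactions / objective /
# atp_maintenance).
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, **({"formula": m.formula} if m.formula else {})}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
            }
            for r in model.reactions
        ],
        "objective": model.objective_reaction,
        "atp_maintenance": model.atp_maintenance_reaction,
    }


def model_from_dict(data: Mapping) -> MetabolicModel:
    metabolites = [
        Metabolite(m["id"], m.get("formula")) for m in data["metabolites"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=r.get("gpr", "") or "",
        )
        for r in data["reactions"]
    ]
    return MetabolicModel(
        reactions=reactions,
        metabolites=metabolites,
        objective_reaction=data["objective"],
        atp_maintenance_reaction=data.get("atp_maintenance"),
        id=data.get("id", "model"),
    )


def load_model(path, fmt: str = "json") -> MetabolicModel:
    """Load a model from JSON (native schema) or SBML L3/FBC."""
    if fmt == "json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    if fmt == "sbml":
        from .sbml import read_sbml_model

        return read_sbml_model(path)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path, fmt: str = "json") -> None:
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if fmt == "sbml":
        from .sbml import write_sbml_model

        write_sbml_model(model, path)
        return
    raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(model: MetabolicModel, c: np.ndarray,
           fixed: Optional[Mapping[str, float]] = None):
    S = model.stoichiometric_matrix()
    bounds = []
    ridx = model.reaction_index()
    fixed = dict(fixed or {})
    for rid, val in fixed.items():
        if rid not in ridx:
            raise KeyError(f"unknown reaction {rid!r} in fixed fluxes")
        rxn = model.reaction(rid)
        if not (rxn.lower_bound - BALANCE_TOL <= val <= rxn.upper_bound + BALANCE_TOL):
            raise ValueError(
                f"fixed flux {val} for {rid!r} outside bounds "
                f"[{rxn.lower_bound}, {rxn.upper_bound}]"
            )
    for rxn in model.reactions:
        if rxn.id in fixed:
            bounds.append((fixed[rxn.id], fixed[rxn.id]))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"presolve": True, "primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    return res


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
    fixed_fluxes: Optional[Mapping[str, float]] = None,
) -> FluxDistribution:
    """Optimize one reaction flux; infeasibility is reported via status."""
    objective = objective or model.objective_reaction
    ridx = model.reaction_index()
    if objective not in ridx:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    c = np.zeros(len(model.reactions))
    c[ridx[objective]] = -1.0 if sense == "max" else 1.0
    res = _solve(model, c, fixed_fluxes)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxDistribution({}, None, status)
    fluxes = {r.id: float(res.x[i]) for i, r in enumerate(model.reactions)}
    obj = fluxes[objective]
    return FluxDistribution(fluxes, obj, "optimal")


def fva(
    model: MetabolicModel,
    objective: Optional[str] = None,
    objective_value: Optional[float] = None,
    reactions: Optional[Sequence[str]] = None,
) -> FVAResult:
    """Per-reaction flux intervals with the objective flux held fixed.

    If ``objective_value`` is None the objective is first maximized by FBA
    and fixed at that optimum.
    """
    objective = objective or model.objective_reaction
    if objective_value is None:
        sol = fba(model, objective, "max")
        if sol.status != "optimal":
            raise RuntimeError(f"FBA at objective {objective!r} is {sol.status}")
        objective_value = sol.objective_value
    ridx = model.reaction_index()
    todo = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    fixed = {objective: objective_value}
    intervals: Dict[str, Tuple[float, float]] = {}
    n = len(model.reactions)
    for rid in todo:
        if rid not in ridx:
            raise KeyError(f"unknown reaction {rid!r}")
        if rid == objective:
            intervals[rid] = (objective_value, objective_value)
            continue
        c = np.zeros(n)
        c[ridx[rid]] = 1.0
        lo_res = _solve(model, c, fixed)
        hi_res = _solve(model, -c, fixed)
        if lo_res.status == 2 or hi_res.status == 2:
            raise RuntimeError(
                f"FVA infeasible with {objective}={objective_value}"
            )
        lo = -np.inf if lo_res.status == 3 else float(lo_res.x[ridx[rid]])
        hi = np.inf if hi_res.status == 3 else float(hi_res.x[ridx[rid]])
        if lo > hi:  # solver noise on a fixed flux
            lo = hi = 0.5 * (lo + hi)
        intervals[rid] = (lo, hi)
    return FVAResult(intervals, objective, objective_value)


# ---------------------------------------------------------------------------
# Gene deletions and maintenance injection
# ---------------------------------------------------------------------------

def delete_genes(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Zero the bounds of every reaction whose GPR goes inactive.

    Spontaneous (empty-GPR) reactions are never affected.
    """
    gset = set(genes)
    bounds = {}
    for rxn in model.reactions:
        if rxn.gpr.strip() and not evaluate_gpr(rxn.gpr, gset):
            bounds[rxn.id] = (0.0, 0.0)
    return model.with_bounds(bounds)


def essential_genes(model: MetabolicModel, growth_threshold: float = 0.01) -> Set[str]:
    """Genes whose single deletion drops max growth below a wild-type fraction."""
    wt = fba(model, model.objective_reaction, "max")
    if wt.status != "optimal" or wt.objective_value <= BALANCE_TOL:
        raise RuntimeError("wild-type model does not grow; essentiality undefined")
    cutoff = growth_threshold * wt.objective_value
    essential: Set[str] = set()
    for gene in sorted(model.genes):
        ko = fba(delete_genes(model, {gene}), model.objective_reaction, "max")
        if ko.status != "optimal" or ko.objective_value < cutoff:
            essential.add(gene)
    return essential


def set_maintenance(model: MetabolicModel, gam: float, ngam: float) -> MetabolicModel:
    """Write GAM/NGAM into a copy of the model.

    GAM (mmol ATP per gDCW) becomes the ATP-hydrolysis quartet of the
    biomass reaction: gam x (atp + h2o -> adp + pi) per unit biomass flux.
    NGAM (mmol ATP per gDCW per h) becomes the lower bound of the ATP
    maintenance drain, forcing that hydrolysis flux in every feasible state.
    """
    if gam < 0 or ngam < 0:
        raise ValueError("gam and ngam must be non-negative")
    if model.atp_maintenance_reaction is None:
        raise ModelValidationError("model has no ATP maintenance reaction")
    new = model.copy()
    biomass = new.reaction(new.objective_reaction)
    maint = new.reaction(new.atp_maintenance_reaction)
    # the maintenance drain defines which species play ATP/ADP/Pi/H2O here
    consumed = {m for m, c in maint.stoichiometry.items() if c < 0}
    produced = {m for m, c in maint.stoichiometry.items() if c > 0}
    stoich = dict(biomass.stoichiometry)
    for met in consumed:
        stoich[met] = -gam
    for met in produced:
        stoich[met] = gam
    if gam == 0:
        for met in consumed | produced:
            stoich.pop(met, None)
    idx = new.reaction_index()
    new.reactions[idx[biomass.id]] = replace(biomass, stoichiometry=stoich)
    new.reactions[idx[maint.id]] = replace(
        maint, lower_bound=ngam, upper_bound=max(maint.upper_bound, ngam)
    )
    new.validate()
    return new
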