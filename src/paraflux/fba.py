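"""Flux balance analysis: linear programming over S·v = 0.

The LP variables are the reaction fluxes, one equality row per metabolite,
and the objective is a single reaction flux optimized in either sense.
The backend is HiGHS through :func:`scipy.optimize.linprog`, run at a
feasibility/optimality tolerance of 1e-9 so that optimal objective values
are stable well below the precision at which yields are reported.

Because FBA optima are generically degenerate, nothing in this module (or
above it) should read an individual flux off a single solve to decide
whether a reaction is active: :func:`flux_range` answers that question as a
minimum/maximum over the optimal face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .errors import ModelStructureError, InfeasibleError
from .model import DEFAULT_BOUND, MetabolicModel, Reaction

#: solver feasibility / optimality tolerance
SOLVER_TOL = 1e-9
#: fluxes smaller than this (absolute) are solver noise, not activity
NONZERO_FLUX_TOL = 1e-6
#: tolerance for verifying the steady-state residual of a reported optimum
STEADY_STATE_TOL = 1e-6

_LINPROG_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": SOLVER_TOL,
    "dual_feasibility_tolerance": SOLVER_TOL,
}


@dataclass(frozen=True)
class Constraint:
    """An extra bound applied on top of a model for one solve.

    kind 'fix' pins the flux, 'lower'/'upper' tighten one side.
    """

    reaction_id: str
    kind: Literal["fix", "lower", "upper"]
    value: float


@dataclass
class FluxState:
    status: Literal["optimal", "infeasible", "unbounded"]
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _bounds_with_constraints(
    model: MetabolicModel, constraints: Iterable[Constraint]
) -> dict[str, tuple[float, float]]:
    bounds = {rid: (r.lower_bound, r.upper_bound) for rid, r in model.reactions.items()}
    for c in constraints:
        if c.reaction_id not in bounds:
            raise ModelStructureError(f"constraint references unknown reaction {c.reaction_id}")
        lb, ub = bounds[c.reaction_id]
        if c.kind == "fix":
            lb = ub = c.value
        elif c.kind == "lower":
            lb = c.value
        elif c.kind == "upper":
            ub = c.value
        else:
            raise ValueError(f"unknown constraint kind {c.kind!r}")
        bounds[c.reaction_id] = (lb, ub)
    return bounds


def solve(
    model: MetabolicModel,
    objective: str,
    sense: Literal["maximize", "minimize"] = "maximize",
    constraints: Iterable[Constraint] = (),
) -> FluxState:
    """Optimize one reaction flux subject to S·v = 0 and bounds.

    Constraints are applied on top of the model for this solve only. The
    objective value of an optimal state is unique even when the flux vector
    is not; the returned fluxes are one optimal vertex.
    """
    if objective not in model.reactions:
        raise ModelStructureError(f"unknown objective reaction {objective}")
    constraints = list(constraints)
    bounds = _bounds_with_constraints(model, constraints)
    for rid, (lb, ub) in bounds.items():
        if lb > ub:
            return FluxState(status="infeasible")

    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met_id, coef in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(coef)
    A_eq = sp.csr_matrix((data, (rows, cols)), shape=(len(met_index), len(rxn_ids)))

    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective)] = -1.0 if sense == "maximize" else 1.0

    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(len(met_index)),
        bounds=[bounds[rid] for rid in rxn_ids],
        method="highs",
        options=_LINPROG_OPTIONS,
    )
    if res.status == 2:
        return FluxState(status="infeasible")
    if res.status == 3:
        return FluxState(status="unbounded")
    if res.status != 0:  # pragma: no cover - numerical failure
        raise RuntimeError(f"LP solver failure: {res.message}")
    sign = -1.0 if sense == "maximize" else 1.0
    return FluxState(
        status="optimal",
        objective_value=float(sign * res.fun),
        fluxes={rid: float(v) for rid, v in zip(rxn_ids, res.x)},
    )


def flux_range(
    model: MetabolicModel,
    target: str,
    constraints: Iterable[Constraint] = (),
    fix_objective_at: float | None = None,
    objective: str | None = None,
) -> tuple[float, float]:
    """Minimal and maximal feasible flux of ``target`` under the constraints
    (flux-variability query).

    With ``fix_objective_at`` the model objective (or ``objective``) is
    pinned first, so the range is taken over the optimal face.  Raises
    :class:`InfeasibleError` if the constraint set admits no flux vector —
    deliberately distinct from a (0, 0) range.
    """
    constraints = list(constraints)
    if fix_objective_at is not None:
        obj = objective or model.objective_id
        if obj is None:
            raise ModelStructureError("no objective to fix")
        constraints.append(Constraint(obj, "fix", fix_objective_at))
    lo = solve(model, target, "minimize", constraints)
    if not lo.ok:
        raise InfeasibleError(f"flux range of {target}: problem is {lo.status}")
    hi = solve(model, target, "maximize", constraints)
    if not hi.ok:  # pragma: no cover - cannot differ from lo in a bounded model
        raise InfeasibleError(f"flux range of {target}: problem is {hi.status}")
    return lo.objective_value, hi.objective_value


MIXTURE_SUPPLY_ID = "SUPPLY_MIXTURE"


def with_mixture_supply(
    model: MetabolicModel,
    components: Mapping[str, float],
    reaction_id: str = MIXTURE_SUPPLY_ID,
) -> MetabolicModel:
    """Return a copy of the model with one irreversible pseudo-reaction
    producing the given metabolites in fixed proportions.

    This encodes feeding a substrate mixture at a fixed molar ratio: one
    unit of supply flux delivers ``coefficient`` mmol of each component.
    Components with coefficient 0 are dropped; at least one must be > 0.
    """
    kept: dict[str, float] = {}
    for met_id, coef in components.items():
        if coef < 0:
            raise ValueError(f"mixture coefficient for {met_id} must be non-negative")
        if met_id not in model.metabolites:
            raise ModelStructureError(f"mixture references unknown metabolite {met_id}")
        if coef > 0:
            kept[met_id] = float(coef)
    if not kept:
        raise ValueError("mixture must contain at least one positive component")
    supply = Reaction(
        id=reaction_id,
        name="fixed-ratio substrate supply",
        stoichiometry=kept,
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
    )
    return model.with_reaction(supply)


def closed_model(model: MetabolicModel, keep_open: Iterable[str]) -> MetabolicModel:
    """Close uptake through every exchange not listed in ``keep_open``;
    secretion bounds are untouched."""
    keep = set(keep_open)
    exchange_ids = {r.id for r in model.exchanges}
    bad = keep - exchange_ids
    if bad:
        raise ValueError(f"keep_open contains non-exchange reactions: {sorted(bad)}")
    out = model
    for rid in exchange_ids - keep:
        if len(model.reactions[rid].stoichiometry) != 1:
            continue  # EX_-prefixed multi-metabolite oddity: leave as-is
        out = out.close_uptake(rid)
    return out


def steady_state_residual(model: MetabolicModel, fluxes: Mapping[str, float]) -> float:
    """max_i |sum_j S_ij v_j| — how far a flux vector is from steady state."""
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    v = np.array([fluxes[rid] for rid in rxn_ids])
    return float(np.max(np.abs(S @ v))) if len(met_ids) else 0.0
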