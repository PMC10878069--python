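"""Simulation protocols for yield prediction and maintenance estimation.

Each function is a short, auditable recipe over the LP core:

* ``max_theoretical_yield`` — Y^max of Pirt's equation: substrate uptake
  fixed to 1 mmol g-DW^-1 h^-1, non-growth ATP hydrolysis fixed to 0,
  biomass maximized.
* ``batch_yield`` — growth rate fixed to its measured value, maintenance
  ATP fixed, carbon uptake minimized; Y = 1000 mu / q_min.
* ``anoxic_yield`` — same with O2 uptake closed and nitrate open
  (denitrifying growth, N2 free to leave).
* ``atp_yield`` — mol ATP per mol substrate: growth fixed to 0, uptake
  fixed to 1, flux through the ATP hydrolysis reaction maximized.
* ``scenario_compare`` — re-run a yield protocol with alternative reaction
  sets disabled (e.g. the two formate-dehydrogenase hypotheses).
* ``ratio_scan`` / ``activation_threshold`` — feed a two-substrate mixture
  at a fixed molar ratio through a single supply pseudo-reaction, minimize
  the supply at fixed mu and maintenance, and record the forced flux range
  of a target reaction (CO2 fixation) per mol of base substrate; the
  threshold is the smallest ratio at which the minimal flux is nonzero.
* ``estimate_maintenance`` — combine per-substrate maintenance uptakes with
  ATP-per-substrate coefficients: m_ATP = sum_i yield_i * m_s,i.
* ``leak_check`` — no growth may be possible with every organic uptake
  closed.

Because FBA optima are degenerate, protocols never report an individual
flux from a single solve: activity of the target reaction is always a
flux-range statement over the optimal face.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import MMOL_PER_MOL
from .errors import ConfigurationError, InfeasibleError
from .fba import (
    Constraint,
    FluxState,
    MIXTURE_SUPPLY_ID,
    NONZERO_FLUX_TOL,
    closed_model,
    flux_range,
    solve,
    with_mixture_supply,
)
from .model import DEFAULT_BOUND, MetabolicModel

# --------------------------------------------------------------------------
# medium specification
# --------------------------------------------------------------------------

#: metabolite id stems / names treated as inorganic medium components
INORGANIC_STEMS = {
    "o2", "oxygen", "h2o", "water", "h", "proton", "pi", "phosphate",
    "nh3", "nh4", "ammonium", "ammonia", "so4", "sulfate", "sulphate",
    "co2", "n2", "no3", "nitrate", "fe2", "fe3", "mg2", "k", "na1", "ca2",
    "cl", "zn2", "mn2", "cu2", "cobalt2", "mobd",
}


def _stem(met_id: str, name: str = "") -> str:
    stem = met_id.lower()
    for suffix in ("_c", "_e", "_p", "_c0", "_e0", "_p0", "[c]", "[e]", "[p]"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return stem if stem in INORGANIC_STEMS else name.strip().lower()


@dataclass(frozen=True)
class MediumSpec:
    """Which exchange reactions may take anything up, and how much.

    ``uptakes`` maps exchange id -> maximal uptake (positive magnitude,
    mmol g-DW^-1 h^-1), with None meaning effectively unbounded.  Applying
    the medium closes uptake through every other exchange; secretion bounds
    are never touched.  The carbon source under protocol control is handled
    by per-solve constraints, so it need not be listed.
    """

    uptakes: Mapping[str, float | None] = field(default_factory=dict)
    o2_exchange: str | None = None
    nitrate_exchange: str | None = None
    name: str = "medium"

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        out = model
        for rxn in model.exchanges:
            if len(rxn.stoichiometry) != 1:
                continue
            if rxn.id in self.uptakes:
                cap = self.uptakes[rxn.id]
                out = out.with_uptake_capacity(
                    rxn.id, DEFAULT_BOUND if cap is None else cap
                )
            else:
                out = out.close_uptake(rxn.id)
        return out

    def anoxic(self) -> "MediumSpec":
        """Denitrifying variant: O2 uptake closed, nitrate uptake open."""
        uptakes = {k: v for k, v in self.uptakes.items() if k != self.o2_exchange}
        if self.nitrate_exchange is not None:
            uptakes[self.nitrate_exchange] = None
        return replace(self, uptakes=uptakes, name=f"{self.name}-anoxic")

    @classmethod
    def inorganic(cls, model: MetabolicModel, anoxic: bool = False) -> "MediumSpec":
        """Open every inorganic exchange of the model (heuristic by
        metabolite id stem / name); nitrate stays closed unless anoxic."""
        uptakes: dict[str, float | None] = {}
        o2 = nitrate = None
        for rxn in model.exchanges:
            if len(rxn.stoichiometry) != 1:
                continue
            met = model.metabolites[model.exchange_metabolite(rxn.id)]
            stem = _stem(met.id, met.name)
            if stem not in INORGANIC_STEMS:
                continue
            if stem in ("o2", "oxygen"):
                o2 = rxn.id
            if stem in ("no3", "nitrate"):
                nitrate = rxn.id
                continue  # closed by default in the aerobic medium
            if stem in ("co2", "n2"):
                continue  # free for secretion only, never taken up
            uptakes[rxn.id] = None
        medium = cls(uptakes=uptakes, o2_exchange=o2, nitrate_exchange=nitrate,
                     name="inorganic")
        return medium.anoxic() if anoxic else medium


# --------------------------------------------------------------------------
# maintenance reaction lookup
# --------------------------------------------------------------------------

_ATP_STEMS = {"atp"}
_ADP_STEMS = {"adp"}
_H2O_STEMS = {"h2o", "water", "oh2"}
_PI_STEMS = {"pi", "phosphate", "hpo4", "po4"}
_H_STEMS = {"h", "h+", "proton"}


def find_maintenance_reaction(model: MetabolicModel) -> str | None:
    """Locate the non-growth ATP hydrolysis (maintenance) reaction.

    Resolution order: explicit ``maintenance_reaction`` annotation; an id
    of ``ATPM`` (any compartment suffix) or a name containing
    'maintenance'; finally a stoichiometric pattern search for
    ATP + H2O -> ADP + Pi (+ H) with no other participants.
    """
    annotated = model.annotations.get("maintenance_reaction")
    if annotated and annotated in model.reactions:
        return annotated
    for rxn in model.reactions.values():
        if rxn.id.upper().split("_")[0] == "ATPM" or "maintenance" in rxn.name.lower():
            return rxn.id
    for rxn in model.reactions.values():
        if rxn.is_exchange or not 3 <= len(rxn.stoichiometry) <= 5:
            continue
        stems = {}
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            stems[_stem(met.id, met.name) or met.id.lower()] = coef
        def has(group, sign):
            return any(s in group and np.sign(c) == sign for s, c in stems.items())
        if (has(_ATP_STEMS, -1) and has(_H2O_STEMS, -1)
                and has(_ADP_STEMS, +1) and has(_PI_STEMS, +1)):
            return rxn.id
    return None


def _maintenance_constraint(
    model: MetabolicModel, value: float, maintenance_id: str | None
) -> list[Constraint]:
    rid = maintenance_id or find_maintenance_reaction(model)
    if rid is None:
        if value == 0.0:
            return []  # nothing to pin: the model has no maintenance sink
        raise ConfigurationError(
            "no ATP maintenance (non-growth ATP hydrolysis) reaction found; "
            "expected an ATPM-like reaction ATP + H2O -> ADP + Pi + H or a "
            "'maintenance_reaction' annotation"
        )
    return [Constraint(rid, "fix", value)]


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class YieldPrediction:
    """A (mu, q_s, Y) triple for one substrate under one scenario.

    Y = 1000 * mu / q_s in g-DW per mol substrate; with maintenance fixed
    to zero and uptake to one this is Y^max of Pirt's equation.
    """

    substrate_id: str
    growth_rate: float
    uptake: float
    yield_g_per_mol: float
    scenario: str = ""
    maintenance: float = 0.0
    diagnostic: str | None = None

    @property
    def grew(self) -> bool:
        return self.yield_g_per_mol > 0


@dataclass
class RatioScanResult:
    """Forced flux ranges of a target reaction along a supply-ratio scan.

    Fluxes are normalized per mol of the base (denominator) substrate
    consumed.  ``threshold`` is the smallest ratio at which the *minimal*
    target flux exceeds the nonzero tolerance, refined by bisection; None
    if the target is never forced on.
    """

    ratios: list[float]
    supply: list[float]
    min_flux: list[float]
    max_flux: list[float]
    feasible: list[bool]
    target_id: str
    threshold: float | None = None
    evaluate: Callable[[float], float | None] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio": self.ratios,
                "supply": self.supply,
                "min_flux": self.min_flux,
                "max_flux": self.max_flux,
                "feasible": self.feasible,
            }
        )


@dataclass(frozen=True)
class MaintenanceEstimate:
    per_condition: tuple[float, ...]
    mean: float
    sd: float
    coefficients: Mapping[str, float]


@dataclass(frozen=True)
class LeakCheckResult:
    passed: bool
    max_carbonless_growth: float


# --------------------------------------------------------------------------
# protocols
# --------------------------------------------------------------------------


def _require_objective(model: MetabolicModel) -> str:
    if model.objective_id is None:
        raise ConfigurationError("model declares no biomass objective")
    return model.objective_id


def max_theoretical_yield(
    model: MetabolicModel,
    substrate: str,
    medium: MediumSpec,
    maintenance_id: str | None = None,
    scenario: str = "",
) -> YieldPrediction:
    """Maximal yield Y^max: uptake fixed to 1, maintenance to 0, biomass
    maximized.  A model that cannot grow yields an explicit zero-yield
    result with a diagnostic rather than an exception."""
    biomass = _require_objective(model)
    mdl = medium.apply(model)
    constraints = _maintenance_constraint(mdl, 0.0, maintenance_id)
    constraints.append(Constraint(substrate, "fix", mdl.uptake_flux(substrate, 1.0)))
    state = solve(mdl, biomass, "maximize", constraints)
    if not state.ok or state.objective_value <= NONZERO_FLUX_TOL:
        return YieldPrediction(
            substrate_id=substrate, growth_rate=0.0, uptake=1.0,
            yield_g_per_mol=0.0, scenario=scenario, maintenance=0.0,
            diagnostic=f"no growth on {substrate} ({state.status})",
        )
    mu = state.objective_value
    return YieldPrediction(
        substrate_id=substrate, growth_rate=mu, uptake=1.0,
        yield_g_per_mol=MMOL_PER_MOL * mu / 1.0, scenario=scenario,
    )


def _minimize_uptake(
    model: MetabolicModel, substrate: str, constraints: list[Constraint]
) -> tuple[float, FluxState]:
    direction = model.uptake_direction(substrate)
    open_uptake = (
        Constraint(substrate, "lower", -DEFAULT_BOUND)
        if direction < 0
        else Constraint(substrate, "upper", DEFAULT_BOUND)
    )
    sense = "maximize" if direction < 0 else "minimize"
    state = solve(model, substrate, sense, constraints + [open_uptake])
    if not state.ok:
        raise InfeasibleError(f"uptake minimization for {substrate}: {state.status}")
    return model.uptake_magnitude(substrate, state.objective_value), state


def batch_yield(
    model: MetabolicModel,
    substrate: str,
    mu: float,
    m_atp: float,
    medium: MediumSpec,
    maintenance_id: str | None = None,
    scenario: str = "",
) -> YieldPrediction:
    """Batch-growth yield: biomass fixed to the measured mu, maintenance to
    m_atp, carbon uptake minimized."""
    if mu <= 0:
        raise ValueError("growth rate mu must be positive")
    if m_atp < 0:
        raise ValueError("maintenance ATP rate must be non-negative")
    biomass = _require_objective(model)
    mdl = medium.apply(model)
    constraints = _maintenance_constraint(mdl, m_atp, maintenance_id)
    constraints.append(Constraint(biomass, "fix", mu))
    try:
        q, _ = _minimize_uptake(mdl, substrate, constraints)
    except InfeasibleError as exc:
        raise InfeasibleError(
            f"growth rate mu={mu} h^-1 on {substrate} with maintenance "
            f"{m_atp} is infeasible"
        ) from exc
    if q <= 0:
        raise InfeasibleError(
            f"growth at mu={mu} requires no {substrate} uptake; yield undefined"
        )
    return YieldPrediction(
        substrate_id=substrate, growth_rate=mu, uptake=q,
        yield_g_per_mol=MMOL_PER_MOL * mu / q, scenario=scenario, maintenance=m_atp,
    )


def anoxic_yield(
    model: MetabolicModel,
    substrate: str,
    mu: float,
    m_atp: float,
    medium: MediumSpec,
    maintenance_id: str | None = None,
    scenario: str = "anoxic",
) -> YieldPrediction:
    """Denitrifying batch yield: O2 uptake closed, nitrate open, N2 free to
    leave; otherwise identical to :func:`batch_yield`."""
    return batch_yield(
        model, substrate, mu, m_atp, medium.anoxic(),
        maintenance_id=maintenance_id, scenario=scenario,
    )


def atp_yield(
    model: MetabolicModel,
    substrate: str,
    medium: MediumSpec,
    maintenance_id: str | None = None,
) -> float:
    """Mol ATP producible per mol substrate: growth fixed to 0, uptake to
    1, flux through the ATP hydrolysis reaction maximized."""
    biomass = _require_objective(model)
    mdl = medium.apply(model)
    rid = maintenance_id or find_maintenance_reaction(mdl)
    if rid is None:
        raise ConfigurationError(
            "ATP yield needs the non-growth ATP hydrolysis reaction "
            "(ATP + H2O -> ADP + Pi + H); none found"
        )
    constraints = [
        Constraint(biomass, "fix", 0.0),
        Constraint(substrate, "fix", mdl.uptake_flux(substrate, 1.0)),
        Constraint(rid, "upper", DEFAULT_BOUND),
    ]
    state = solve(mdl, rid, "maximize", constraints)
    if not state.ok:
        raise InfeasibleError(f"ATP yield on {substrate}: problem is {state.status}")
    return state.objective_value


def scenario_compare(
    model: MetabolicModel,
    substrate: str,
    scenarios: Mapping[str, Iterable[str]],
    medium: MediumSpec,
    mu: float | None = None,
    m_atp: float = 0.0,
    maintenance_id: str | None = None,
) -> dict[str, YieldPrediction]:
    """Yield under alternative hypotheses: for each scenario the listed
    reactions are disabled (bounds 0, 0) before running the protocol —
    maximal theoretical yield by default, batch yield when ``mu`` is given.
    The input model is never modified."""
    results: dict[str, YieldPrediction] = {}
    for label, disabled in scenarios.items():
        mdl = model
        for rid in disabled:
            if rid == model.objective_id:
                raise ValueError(f"scenario {label!r} disables the biomass reaction")
            mdl = mdl.with_bounds(rid, lower=0.0, upper=0.0)
        if mu is None:
            results[label] = replace(
                max_theoretical_yield(mdl, substrate, medium,
                                      maintenance_id=maintenance_id),
                scenario=label,
            )
        else:
            results[label] = batch_yield(
                mdl, substrate, mu, m_atp, medium,
                maintenance_id=maintenance_id, scenario=label,
            )
    return results


def _scan_point(
    base: MetabolicModel,
    numerator_met: str,
    denominator_met: str,
    ratio: float,
    constraints: list[Constraint],
    target: str,
) -> tuple[bool, float, float, float]:
    """One mixture-ratio point: minimize supply, then the forced range of
    the target at that supply, normalized per mol denominator substrate."""
    mdl = with_mixture_supply(base, {numerator_met: ratio, denominator_met: 1.0})
    state = solve(mdl, MIXTURE_SUPPLY_ID, "minimize", constraints)
    if not state.ok:
        return False, float("nan"), float("nan"), float("nan")
    s = state.objective_value
    pin = [Constraint(MIXTURE_SUPPLY_ID, "upper", s * (1 + 1e-9) + 1e-12)]
    lo, hi = flux_range(mdl, target, constraints + pin)
    if s > NONZERO_FLUX_TOL:
        lo, hi = lo / s, hi / s  # per mol of denominator substrate (coef 1)
    return True, s, lo, hi


def ratio_scan(
    model: MetabolicModel,
    numerator_met: str,
    denominator_met: str,
    ratios: Sequence[float],
    mu: float,
    m_atp: float,
    target: str,
    medium: MediumSpec,
    maintenance_id: str | None = None,
    nonzero_tol: float = NONZERO_FLUX_TOL,
) -> RatioScanResult:
    """Scan mixture supply ratios (numerator : 1 denominator), minimizing
    the supply flux at fixed mu and maintenance, and record the forced
    flux range of ``target`` at each supply optimum.

    Direct uptake exchanges for the two component metabolites are closed so
    the mixture pseudo-reaction is the only way in.  Infeasible ratios are
    flagged and the scan continues.
    """
    ratios = list(ratios)
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("ratios must be strictly increasing")
    if target not in model.reactions:
        raise ValueError(f"unknown target reaction {target}")
    biomass = _require_objective(model)
    base = medium.apply(model)
    for rxn in base.exchanges:
        if len(rxn.stoichiometry) == 1 and base.exchange_metabolite(rxn.id) in (
            numerator_met, denominator_met,
        ):
            base = base.close_uptake(rxn.id)
    constraints = _maintenance_constraint(base, m_atp, maintenance_id)
    constraints.append(Constraint(biomass, "fix", mu))

    result = RatioScanResult([], [], [], [], [], target_id=target)
    for r in ratios:
        ok, s, lo, hi = _scan_point(base, numerator_met, denominator_met, r,
                                    constraints, target)
        result.ratios.append(r)
        result.feasible.append(ok)
        result.supply.append(s)
        result.min_flux.append(lo)
        result.max_flux.append(hi)

    def evaluate(r: float) -> float | None:
        ok, _, lo, _ = _scan_point(base, numerator_met, denominator_met, r,
                                   constraints, target)
        return lo if ok else None

    result.evaluate = evaluate
    result.threshold = activation_threshold(result, nonzero_tol)
    return result


def activation_threshold(
    scan: RatioScanResult,
    nonzero_tol: float = NONZERO_FLUX_TOL,
    resolution: float = 0.01,
) -> float | None:
    """Smallest scanned ratio whose minimal target flux exceeds
    ``nonzero_tol``, refined by bisection between the bracketing grid
    points down to ``resolution``; None if the flux is never forced."""
    if len(scan.ratios) < 2:
        raise ValueError("scan must contain at least two ratios")
    active = [
        i
        for i, (ok, lo) in enumerate(zip(scan.feasible, scan.min_flux))
        if ok and lo > nonzero_tol
    ]
    if not active:
        return None
    i = active[0]
    if i == 0 or scan.evaluate is None:
        return scan.ratios[i]
    lo_r, hi_r = scan.ratios[i - 1], scan.ratios[i]
    while hi_r - lo_r > resolution:
        mid = 0.5 * (lo_r + hi_r)
        val = scan.evaluate(mid)
        if val is not None and val > nonzero_tol:
            hi_r = mid
        else:
            lo_r = mid
    return hi_r


def estimate_maintenance(
    atp_yields: Mapping[str, float],
    maintenance_uptakes: Sequence[Mapping[str, float]],
) -> MaintenanceEstimate:
    """Combine per-condition maintenance substrate uptakes m_s with ATP
    yield coefficients: m_ATP = sum_i yield_i * m_s,i per condition, then
    mean and standard deviation over conditions."""
    if not maintenance_uptakes:
        raise ValueError("at least one condition is required")
    values = []
    for cond in maintenance_uptakes:
        total = 0.0
        for substrate, m_s in cond.items():
            if substrate not in atp_yields:
                raise ValueError(f"no ATP yield coefficient for substrate {substrate!r}")
            total += atp_yields[substrate] * m_s
        values.append(total)
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return MaintenanceEstimate(
        per_condition=tuple(values),
        mean=float(arr.mean()),
        sd=sd,
        coefficients=dict(atp_yields),
    )


def leak_check(
    model: MetabolicModel,
    inorganic_exchanges: Iterable[str],
    maintenance_id: str | None = None,
) -> LeakCheckResult:
    """A sound model must not grow with every organic uptake closed.

    Guards against mass-creating curation artifacts such as a model that
    can only grow by importing AMP.  Maintenance is pinned to zero so even
    marginal carbonless growth is exposed.
    """
    biomass = _require_objective(model)
    mdl = closed_model(model, inorganic_exchanges)
    constraints = _maintenance_constraint(mdl, 0.0, maintenance_id)
    state = solve(mdl, biomass, "maximize", constraints)
    growth = state.objective_value if state.ok else 0.0
    return LeakCheckResult(passed=growth <= NONZERO_FLUX_TOL,
                           max_carbonless_growth=growth)
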