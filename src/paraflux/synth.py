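"""Synthetic stoichiometric networks and chemostat datasets.

These generators are first-class study material, not throwaway fixtures:
each family emulates one structural feature the analysis protocols must
handle, with analytically known behavior.

* ``toy_linear`` — a chain with a single optimum and an exactly known
  maximal yield (general sanity / unit-convention anchor).
* ``toy_dual_pathway`` — two stoichiometrically equivalent branches, the
  degenerate-optima case (like the two alternative propionyl-CoA routes,
  methylmalonyl-CoA pathway vs methylcitrate cycle).
* ``toy_respiratory`` — oxidation routes with different ATP-per-substrate
  stoichiometries (P/O-like variants; electron-acceptor or dehydrogenase
  scenario contrasts), with a proper ATP/ADP cycle and an ATPM sink.
* ``toy_dual_substrate`` — an energy-only C1 substrate plus a carbon
  substrate and an ATP-consuming CO2-fixation reaction, reproducing the
  forced activation of fixation above a supply-ratio threshold.  The
  generator returns the exact threshold from its own brute-force LP
  oracle, which shares no code with the protocol layer.
* ``toy_leaky`` — a deliberately broken model that grows with every
  organic uptake closed (a mass-creating curation artifact), for testing
  the leak check.
* ``chemostat_dataset`` — noisy Pirt-law (mu, q_s) data.

All randomness is drawn from an explicitly seeded ``numpy`` generator; no
global random state is used. Identical inputs give identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .constants import MMOL_PER_MOL
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from .pirt import ChemostatPoint

_F = {  # formulas reused across generators
    "glc": {"C": 6, "H": 12, "O": 6},
    "triose": {"C": 3, "H": 6, "O": 3},
    "h2o": {"H": 2, "O": 1},
}


# --------------------------------------------------------------------------
# linear chain
# --------------------------------------------------------------------------


def toy_linear(yield_g_per_mol: float = 200.0) -> MetabolicModel:
    """Substrate -> 2 precursor -> biomass chain whose maximal yield at
    unit uptake is exactly ``yield_g_per_mol`` (g-DW mol^-1)."""
    if yield_g_per_mol <= 0:
        raise ValueError("yield must be positive")
    n = 2.0 * MMOL_PER_MOL / yield_g_per_mol  # precursor demand per unit growth
    mets = [
        Metabolite("s", "substrate", formula=_F["glc"], compartment="e"),
        Metabolite("x", "precursor", formula=_F["triose"]),
        Metabolite("bio", "biomass"),
    ]
    rxns = [
        Reaction("EX_S", {"s": -1.0}, "substrate exchange",
                 lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND),
        Reaction("CONV", {"s": -1.0, "x": 2.0}, "substrate cleavage"),
        Reaction("BIOMASS", {"x": -n, "bio": 1.0}, "biomass"),
        Reaction("EX_BIO", {"bio": -1.0}, "biomass drain"),
    ]
    return MetabolicModel.from_lists(
        mets, rxns, objective_id="BIOMASS",
        annotations={"family": "linear", "model_id": "toy_linear"},
    )


# --------------------------------------------------------------------------
# degenerate dual pathway
# --------------------------------------------------------------------------


def toy_dual_pathway() -> MetabolicModel:
    """Two equivalent substrate -> precursor branches; closing either one
    must leave every yield unchanged."""
    mets = [
        Metabolite("s", "substrate", compartment="e"),
        Metabolite("i1", "intermediate 1"),
        Metabolite("i2", "intermediate 2"),
        Metabolite("p", "precursor"),
        Metabolite("bio", "biomass"),
    ]
    rxns = [
        Reaction("EX_S", {"s": -1.0}, lower_bound=-DEFAULT_BOUND),
        Reaction("B1A", {"s": -1.0, "i1": 1.0}, "branch 1 entry"),
        Reaction("B1B", {"i1": -1.0, "p": 1.0}, "branch 1 exit"),
        Reaction("B2A", {"s": -1.0, "i2": 1.0}, "branch 2 entry"),
        Reaction("B2B", {"i2": -1.0, "p": 1.0}, "branch 2 exit"),
        Reaction("BIOMASS", {"p": -10.0, "bio": 1.0}),
        Reaction("EX_BIO", {"bio": -1.0}),
    ]
    return MetabolicModel.from_lists(
        mets, rxns, objective_id="BIOMASS",
        annotations={"family": "dual_pathway", "model_id": "toy_dual_pathway"},
    )


# --------------------------------------------------------------------------
# respiratory variants
# --------------------------------------------------------------------------


def toy_respiratory(
    atp_per_substrate_variants: Mapping[str, float] | None = None,
    biomass_atp_cost: float = 20.0,
    o2_per_substrate: float = 1.0,
) -> MetabolicModel:
    """One aerobic oxidation route per variant, each regenerating its
    stated ATP per substrate, with an explicit ATP/ADP cycle.

    ``atp_yield`` with a single variant enabled returns its stoichiometry
    exactly; with all enabled, the best route wins.  Growth needs O2, so
    the anoxic protocol is infeasible on this family by construction.
    """
    if atp_per_substrate_variants is None:
        atp_per_substrate_variants = {"high_po": 10.0, "low_po": 6.0}
    variants = dict(atp_per_substrate_variants)
    if not variants:
        raise ValueError("at least one variant is required")
    if any(k <= 0 for k in variants.values()):
        raise ValueError("ATP stoichiometries must be positive")
    mets = [
        Metabolite("s", "substrate", compartment="e"),
        Metabolite("o2", "O2", formula={"O": 2}, compartment="e"),
        Metabolite("co2", "CO2", formula={"C": 1, "O": 2}, compartment="e"),
        Metabolite("h2o", "H2O", formula=_F["h2o"], compartment="e"),
        Metabolite("atp", "ATP"),
        Metabolite("adp", "ADP"),
        Metabolite("pi", "phosphate"),
        Metabolite("bio", "biomass"),
    ]
    c = biomass_atp_cost
    rxns = [
        Reaction("EX_S", {"s": -1.0}, lower_bound=-DEFAULT_BOUND),
        Reaction("EX_O2", {"o2": -1.0}, lower_bound=-DEFAULT_BOUND),
        Reaction("EX_CO2", {"co2": -1.0}),
        Reaction("EX_H2O", {"h2o": -1.0}, lower_bound=-DEFAULT_BOUND),
    ]
    for label, k in variants.items():
        rxns.append(
            Reaction(
                f"OXID_{label}",
                {"s": -1.0, "o2": -o2_per_substrate, "adp": -k, "pi": -k,
                 "atp": k, "co2": 1.0},
                f"oxidation route {label} ({k:g} ATP per substrate)",
            )
        )
    rxns += [
        Reaction("ATPM", {"atp": -1.0, "h2o": -1.0, "adp": 1.0, "pi": 1.0},
                 "non-growth ATP maintenance"),
        Reaction("BIOMASS", {"atp": -c, "adp": c, "pi": c, "bio": 1.0}),
        Reaction("EX_BIO", {"bio": -1.0}),
    ]
    return MetabolicModel.from_lists(
        mets, rxns, objective_id="BIOMASS",
        annotations={
            "family": "respiratory",
            "model_id": "toy_respiratory",
            "maintenance_reaction": "ATPM",
        },
    )


# --------------------------------------------------------------------------
# dual-substrate activation threshold
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DualSubstrateParams:
    """Stoichiometry of the two-substrate network.

    The C1 substrate (methanol analogue) is energy-only: its oxidation
    yields ``atp_per_c1`` ATP and one fixable CO2.  The carbon substrate
    (mannitol analogue) either becomes precursor directly or is burned
    for ``atp_per_carbon`` ATP (releasing ``co2_per_carbon`` fixable CO2).
    Fixation turns one CO2 plus ``fixation_atp_cost`` ATP into precursor.
    Growth at rate mu demands ``biomass_precursor_demand`` precursor and
    ``biomass_atp_demand`` ATP per unit flux; ``maintenance`` is the fixed
    non-growth ATP drain.

    A finite activation threshold exists only when fixation is an energy
    *sink of last resort*: ``fixation_atp_cost`` must exceed
    ``atp_per_carbon``, otherwise fixing CO2 is cheaper (in supply) than
    direct assimilation at every ratio and the fixation flux is forced on
    from ratio zero.  With the defaults the threshold sits at
    (b_A mu + m) / (k_C1 b_P mu) = 2.5.
    """

    atp_per_c1: float = 1.8
    atp_per_carbon: float = 10.0
    co2_per_carbon: float = 0.0
    fixation_atp_cost: float = 30.0
    biomass_precursor_demand: float = 10.0
    biomass_atp_demand: float = 20.0
    mu: float = 0.3
    maintenance: float = 7.5


def _dual_substrate_forced_fix(p: DualSubstrateParams, r: float) -> float | None:
    """Independent oracle for one ratio point: minimal supply flux, then
    the minimal fixation flux per mol of carbon substrate at that optimum.

    Built directly from the balance equations with its own tiny LP — it
    shares no code with the model builder or the protocol layer.
    Variables: supply s, direct assimilation x1, carbon-substrate burning
    x2, fixation vR, CO2 venting.
    """
    pd_, ad = p.biomass_precursor_demand * p.mu, p.biomass_atp_demand * p.mu + p.maintenance
    # rows: supply split, precursor, ATP, CO2
    A_eq = np.array(
        [
            [-1.0, 1.0, 1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 1.0, 0.0],
            [p.atp_per_c1 * r, 0.0, p.atp_per_carbon, -p.fixation_atp_cost, 0.0],
            [r, 0.0, p.co2_per_carbon, -1.0, -1.0],
        ]
    )
    b_eq = np.array([0.0, pd_, ad, 0.0])
    bounds = [(0, None)] * 5
    first = linprog(np.array([1.0, 0, 0, 0, 0]), A_eq=A_eq, b_eq=b_eq,
                    bounds=bounds, method="highs")
    if first.status != 0:
        return None
    s_min = first.fun
    A_ub = np.array([[1.0, 0, 0, 0, 0]])
    second = linprog(np.array([0.0, 0, 0, 1.0, 0]), A_eq=A_eq, b_eq=b_eq,
                     A_ub=A_ub, b_ub=[s_min * (1 + 1e-9) + 1e-12],
                     bounds=bounds, method="highs")
    if second.status != 0:
        return None
    v_fix = second.fun
    return v_fix / s_min if s_min > 1e-9 else v_fix


def dual_substrate_oracle_threshold(
    p: DualSubstrateParams,
    r_max: float = 5.0,
    grid_step: float = 0.05,
    nonzero_tol: float = 1e-6,
    resolution: float = 1e-3,
) -> float | None:
    """Exact activation threshold by dense grid plus bisection over the
    oracle LP; None when fixation is never forced up to ``r_max``."""
    grid = np.arange(0.0, r_max + grid_step / 2, grid_step)
    active = None
    for i, r in enumerate(grid):
        v = _dual_substrate_forced_fix(p, float(r))
        if v is not None and v > nonzero_tol:
            active = i
            break
    if active is None:
        return None
    if active == 0:
        return float(grid[0])
    lo, hi = float(grid[active - 1]), float(grid[active])
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        v = _dual_substrate_forced_fix(p, mid)
        if v is not None and v > nonzero_tol:
            hi = mid
        else:
            lo = mid
    return hi


def toy_dual_substrate(
    params: DualSubstrateParams | None = None,
) -> tuple[MetabolicModel, float | None]:
    """Two-substrate network with a CO2-fixation reaction that is forced
    on only above a supply-ratio threshold.

    Returns the model and the exact threshold computed by the internal
    brute-force oracle (None if fixation is never forced).  Feed it with
    ``protocols.ratio_scan(model, "meoh", "mann", ...)`` at the mu and
    maintenance stored in the params.
    """
    p = params or DualSubstrateParams()
    mets = [
        Metabolite("meoh", "methanol-like C1 substrate", compartment="e"),
        Metabolite("mann", "mannitol-like carbon substrate", compartment="e"),
        Metabolite("co2", "CO2", formula={"C": 1, "O": 2}, compartment="e"),
        Metabolite("h2o", "H2O", formula=_F["h2o"], compartment="e"),
        Metabolite("prec", "biomass precursor"),
        Metabolite("atp", "ATP"),
        Metabolite("adp", "ADP"),
        Metabolite("pi", "phosphate"),
        Metabolite("bio", "biomass"),
    ]
    k1, kc, f = p.atp_per_c1, p.atp_per_carbon, p.fixation_atp_cost
    oxid_c = {"mann": -1.0, "adp": -kc, "pi": -kc, "atp": kc}
    if p.co2_per_carbon > 0:
        oxid_c["co2"] = p.co2_per_carbon
    rxns = [
        Reaction("EX_MEOH", {"meoh": -1.0}, lower_bound=-DEFAULT_BOUND),
        Reaction("EX_MANN", {"mann": -1.0}, lower_bound=-DEFAULT_BOUND),
        Reaction("EX_CO2", {"co2": -1.0}),
        Reaction("EX_H2O", {"h2o": -1.0}, lower_bound=-DEFAULT_BOUND),
        Reaction("OXID_C1", {"meoh": -1.0, "adp": -k1, "pi": -k1, "atp": k1,
                             "co2": 1.0}, "energy-only C1 oxidation"),
        Reaction("OXID_C", oxid_c, "carbon-substrate oxidation"),
        Reaction("ASSIM", {"mann": -1.0, "prec": 1.0}, "direct assimilation"),
        Reaction("FIX", {"co2": -1.0, "atp": -f, "adp": f, "pi": f, "prec": 1.0},
                 "CO2 fixation (RuBisCO analogue)"),
        Reaction("ATPM", {"atp": -1.0, "h2o": -1.0, "adp": 1.0, "pi": 1.0},
                 "non-growth ATP maintenance"),
        Reaction("BIOMASS", {"prec": -p.biomass_precursor_demand,
                             "atp": -p.biomass_atp_demand,
                             "adp": p.biomass_atp_demand,
                             "pi": p.biomass_atp_demand, "bio": 1.0}),
        Reaction("EX_BIO", {"bio": -1.0}),
    ]
    model = MetabolicModel.from_lists(
        mets, rxns, objective_id="BIOMASS",
        annotations={
            "family": "dual_substrate",
            "model_id": "toy_dual_substrate",
            "maintenance_reaction": "ATPM",
        },
    )
    return model, dual_substrate_oracle_threshold(p)


# --------------------------------------------------------------------------
# deliberately leaky model
# --------------------------------------------------------------------------


def toy_leaky(yield_g_per_mol: float = 200.0) -> MetabolicModel:
    """A linear toy plus a mass-creating defect: an internal reaction that
    turns water into an AMP-like organic, so the model grows with every
    organic uptake closed.  ``leak_check`` must fail on it."""
    base = toy_linear(yield_g_per_mol)
    mets = list(base.metabolites.values()) + [
        Metabolite("h2o", "H2O", formula=_F["h2o"], compartment="e"),
        Metabolite("amp", "AMP-like organic",
                   formula={"C": 10, "H": 14, "N": 5, "O": 7, "P": 1}),
    ]
    rxns = list(base.reactions.values()) + [
        Reaction("EX_H2O", {"h2o": -1.0}, lower_bound=-DEFAULT_BOUND),
        Reaction("AMP_SPAWN", {"h2o": -1.0, "amp": 1.0},
                 "spurious AMP source (curation artifact)"),
        Reaction("AMP_TO_X", {"amp": -1.0, "x": 1.0}),
    ]
    return MetabolicModel.from_lists(
        mets, rxns, objective_id="BIOMASS",
        annotations={"family": "leaky", "model_id": "toy_leaky"},
    )


# --------------------------------------------------------------------------
# chemostat data
# --------------------------------------------------------------------------


def chemostat_dataset(
    m_s: float,
    y_max: float,
    mu_grid,
    noise_sd: float,
    seed: int,
    substrate: str = "",
) -> list[ChemostatPoint]:
    """Pirt-law data q_s = m_s + 1000 mu / y_max + N(0, noise_sd),
    reproducible per seed."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    mu = np.asarray(list(mu_grid), dtype=float)
    if mu.size == 0 or np.any(mu <= 0):
        raise ValueError("mu_grid must be non-empty and positive")
    rng = np.random.default_rng(seed)
    q = m_s + MMOL_PER_MOL * mu / y_max + rng.normal(0.0, noise_sd, mu.size)
    if np.any(q <= 0):
        raise ValueError(
            "noise drove q_s non-positive; lower noise_sd or raise m_s"
        )
    return [ChemostatPoint(float(m), float(v), substrate) for m, v in zip(mu, q)]


# --------------------------------------------------------------------------
# declarative spec
# --------------------------------------------------------------------------

_FAMILIES = {
    "linear": lambda p: toy_linear(**p),
    "dual_pathway": lambda p: toy_dual_pathway(**p),
    "respiratory": lambda p: toy_respiratory(**p),
    "dual_substrate": lambda p: toy_dual_substrate(
        DualSubstrateParams(**p) if p else None
    )[0],
    "leaky": lambda p: toy_leaky(**p),
}


@dataclass(frozen=True)
class ToySpec:
    """Declarative handle on a generator: same (family, parameters, seed)
    always builds the identical model."""

    family: str
    parameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def build(self) -> MetabolicModel:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown toy family {self.family!r}")
        return _FAMILIES[self.family](dict(self.parameters))
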