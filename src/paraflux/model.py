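"""Core in-memory representation of a constraint-based metabolic model.

A :class:`MetabolicModel` is the stoichiometric matrix S together with flux
bounds and a biomass objective: metabolites are the rows, reactions the
columns, and a signed coefficient S[i, j] < 0 means reaction j consumes
metabolite i.  Fluxes are in mmol g-DW^-1 h^-1; the biomass pseudo-reaction
carries the specific growth rate mu in h^-1 and produces 1 g dry weight per
unit flux.

Exchange pseudo-reactions move a single metabolite across the system
boundary.  The sign convention is the standard constraint-based one: a
negative exchange flux is uptake, a positive one secretion.  Helpers on
:class:`MetabolicModel` translate between that convention and the positive
uptake magnitudes used by the protocol layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, ModelStructureError

#: conventional "effectively unbounded" flux magnitude, mmol g-DW^-1 h^-1
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental composition string like ``C6H12O6`` into
    ``{"C": 6, "H": 12, "O": 6}``.

    Repeated elements accumulate. Raises :class:`FormatError` on anything
    that is not a plain element/count sequence.
    """
    if not text:
        raise FormatError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormatError(f"cannot parse formula {text!r} at position {pos}")
        el, n = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
        pos = m.end()
    if pos != len(text):
        raise FormatError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Serialize an element->count map in Hill-ish deterministic order."""
    keys = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in keys)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, int] | None = None
    charge: int | None = None
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelStructureError("metabolite id must be non-empty")
        if self.formula is not None:
            for el, n in self.formula.items():
                if not isinstance(n, int) or n < 0:
                    raise ModelStructureError(
                        f"metabolite {self.id}: formula count {el}={n} must be a "
                        "non-negative integer"
                    )


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite id -> signed coefficient
    (negative = consumed). Coefficients of exactly zero are rejected.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_association: str | None = None
    subsystem: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ModelStructureError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id}: empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ModelStructureError(f"reaction {self.id}: zero coefficient")
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Exchange pseudo-reaction: touches a single metabolite, or is
        explicitly tagged by the conventional ``EX_`` id prefix."""
        return len(self.stoichiometry) == 1 or self.id.startswith("EX_")

    def bounded(self, lower: float | None = None, upper: float | None = None) -> "Reaction":
        return replace(
            self,
            lower_bound=self.lower_bound if lower is None else lower,
            upper_bound=self.upper_bound if upper is None else upper,
        )

    def genes(self) -> set[str]:
        """Distinct gene labels appearing in the boolean association text."""
        if not self.gene_association:
            return set()
        tokens = re.split(r"[()\s]+", self.gene_association)
        return {t for t in tokens if t and t.lower() not in ("and", "or")}


@dataclass
class MetabolicModel:
    """An ordered collection of metabolites and reactions plus the biomass
    objective.  ``validate()`` enforces the referential invariants; parsers
    and generators call it before handing a model out."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_id: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    # -- construction -------------------------------------------------
    @classmethod
    def from_lists(
        cls,
        metabolites,
        reactions,
        objective_id=None,
        annotations=None,
        validate: bool = True,
    ) -> "MetabolicModel":
        model = cls(
            metabolites={m.id: m for m in metabolites},
            reactions={r.id: r for r in reactions},
            objective_id=objective_id,
            annotations=dict(annotations or {}),
        )
        if len(model.metabolites) != len(list(metabolites)):
            raise ModelStructureError("duplicate metabolite id")
        if len(model.reactions) != len(list(reactions)):
            raise ModelStructureError("duplicate reaction id")
        if validate:
            model.validate()
        return model

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelStructureError(
                        f"reaction {rxn.id} references undeclared metabolite {met_id}"
                    )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ModelStructureError(
                f"objective reaction {self.objective_id} not in model"
            )

    def copy(self) -> "MetabolicModel":
        # Metabolite/Reaction are frozen; shallow-copying the dicts suffices.
        return MetabolicModel(
            metabolites=dict(self.metabolites),
            reactions=dict(self.reactions),
            objective_id=self.objective_id,
            annotations=dict(self.annotations),
        )

    # -- queries ------------------------------------------------------
    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S with its row (metabolite) and column (reaction) ids."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[met_id], j] = coef
        return S, met_ids, rxn_ids

    # -- exchange sign helpers ----------------------------------------
    def exchange_metabolite(self, exchange_id: str) -> str:
        rxn = self.reactions[exchange_id]
        if not rxn.is_exchange or len(rxn.stoichiometry) != 1:
            raise ModelStructureError(f"{exchange_id} is not a single-metabolite exchange")
        return next(iter(rxn.stoichiometry))

    def uptake_direction(self, exchange_id: str) -> int:
        """+1 if positive flux imports the metabolite, -1 if negative flux
        does (the usual ``A <-> (boundary)`` writing)."""
        rxn = self.reactions[exchange_id]
        coef = rxn.stoichiometry[self.exchange_metabolite(exchange_id)]
        return 1 if coef > 0 else -1

    def uptake_flux(self, exchange_id: str, magnitude: float) -> float:
        """Signed exchange flux corresponding to an uptake of ``magnitude``
        (positive mmol g-DW^-1 h^-1)."""
        return self.uptake_direction(exchange_id) * magnitude

    def uptake_magnitude(self, exchange_id: str, flux: float) -> float:
        """Positive uptake implied by a signed exchange flux (0 if secreting)."""
        return max(0.0, self.uptake_direction(exchange_id) * flux)

    # -- mutation-by-copy ---------------------------------------------
    def with_reaction(self, rxn: Reaction) -> "MetabolicModel":
        out = self.copy()
        out.reactions[rxn.id] = rxn
        return out

    def with_bounds(self, reaction_id: str, lower=None, upper=None) -> "MetabolicModel":
        if reaction_id not in self.reactions:
            raise ModelStructureError(f"unknown reaction {reaction_id}")
        return self.with_reaction(self.reactions[reaction_id].bounded(lower, upper))

    def with_uptake_capacity(self, exchange_id: str, magnitude: float) -> "MetabolicModel":
        """Set the maximal import through an exchange to ``magnitude``
        (positive, mmol g-DW^-1 h^-1); secretion bounds unchanged."""
        if magnitude < 0:
            raise ValueError("uptake capacity must be non-negative")
        if self.uptake_direction(exchange_id) > 0:
            return self.with_bounds(exchange_id, upper=magnitude)
        return self.with_bounds(exchange_id, lower=-magnitude)

    def close_uptake(self, exchange_id: str) -> "MetabolicModel":
        """Forbid import through an exchange; secretion bounds unchanged."""
        return self.with_uptake_capacity(exchange_id, 0.0)
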