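"""Model I/O: SBML and a two-file tab-separated table format.

SBML reading accepts the two dialects a SEED-derived, later-curated model
plausibly ships in:

* Level 3 with the ``fbc`` package — flux bounds as parameters referenced
  from each reaction, objective declared via an fbc objective;
* Level 2 with bounds embedded as kinetic-law parameters named
  ``LOWER_BOUND`` / ``UPPER_BOUND`` and gene associations / formulas in
  notes (``GENE_ASSOCIATION: ...``, ``FORMULA: ...``).

When bounds are missing entirely, community defaults apply: [-1000, 1000]
for reversible reactions, [0, 1000] otherwise.

The tab format is the package's own documented schema (the deposit's files
are named but not described):

* reactions table columns: ``id  name  equation  lower_bound  upper_bound
  gene_association  subsystem``; an optional leading comment line
  ``# objective: <reaction id>`` records the biomass objective.
* metabolites table columns: ``id  name  formula  charge  compartment``.

Equation grammar: ``2 A + B --> C + 3 D`` with ``<=>`` marking a
reversible arrow (informative only — bounds are authoritative); an empty
side writes an exchange, e.g. ``A -->`` (consumes A) or ``--> A``.
Column-name variants (lb/lower/lower_bound, ...) are tolerated;
unrecognized columns are preserved in ``model.annotations``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import NamedTuple

import libsbml
import pandas as pd

from .errors import FormatError, ModelStructureError, SBMLParseError
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    format_formula,
    parse_formula,
)

# --------------------------------------------------------------------------
# summaries and balance checking
# --------------------------------------------------------------------------


class ModelSummary(NamedTuple):
    genes: int
    reactions: int
    metabolites: int


def model_summary(model: MetabolicModel) -> ModelSummary:
    """Counts of distinct gene labels, reactions and metabolites."""
    genes: set[str] = set()
    for rxn in model.reactions.values():
        genes |= rxn.genes()
    return ModelSummary(len(genes), len(model.reactions), len(model.metabolites))


@dataclass
class MassBalanceReport:
    balanced: list[str] = field(default_factory=list)
    imbalanced: dict[str, dict[str, float]] = field(default_factory=dict)
    unverifiable: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.imbalanced


def check_mass_balance(model: MetabolicModel, tol: float = 1e-9) -> MassBalanceReport:
    """Elemental balance of every non-exchange reaction.

    A reaction is balanced iff each element's coefficient-weighted net count
    is zero; reactions touching any metabolite without a formula are
    unverifiable (never reported imbalanced); exchanges are excluded.
    """
    report = MassBalanceReport()
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue
        if any(model.metabolites[m].formula is None for m in rxn.stoichiometry):
            report.unverifiable.append(rxn.id)
            continue
        delta: dict[str, float] = {}
        for met_id, coef in rxn.stoichiometry.items():
            for el, n in model.metabolites[met_id].formula.items():
                delta[el] = delta.get(el, 0.0) + coef * n
        delta = {el: d for el, d in delta.items() if abs(d) > tol}
        if delta:
            report.imbalanced[rxn.id] = delta
        else:
            report.balanced.append(rxn.id)
    return report


# --------------------------------------------------------------------------
# SBML
# --------------------------------------------------------------------------

_NOTES_FIELD = re.compile(r"([A-Z_]+):\s*([^<\n]*)")


def _notes_fields(sbase) -> dict[str, str]:
    notes = sbase.getNotesString() if sbase.isSetNotes() else ""
    return {k: v.strip() for k, v in _NOTES_FIELD.findall(notes)}


def _species_formula_charge(species) -> tuple[dict[str, int] | None, int | None]:
    fbc = species.getPlugin("fbc")
    formula_text = None
    charge = None
    if fbc is not None:
        if fbc.isSetChemicalFormula():
            formula_text = fbc.getChemicalFormula()
        if fbc.isSetCharge():
            charge = fbc.getCharge()
    fields = _notes_fields(species)
    if formula_text is None:
        formula_text = fields.get("FORMULA") or None
    if charge is None and "CHARGE" in fields:
        try:
            charge = int(fields["CHARGE"])
        except ValueError:
            charge = None
    formula = None
    if formula_text:
        try:
            formula = parse_formula(formula_text)
        except FormatError:
            formula = None  # non-elemental formulas (R-groups etc.)
    return formula, charge


def _reaction_bounds(sbml_model, reaction) -> tuple[float, float]:
    fbc = reaction.getPlugin("fbc")
    if fbc is not None and fbc.isSetLowerFluxBound() and fbc.isSetUpperFluxBound():
        lo = sbml_model.getParameter(fbc.getLowerFluxBound())
        hi = sbml_model.getParameter(fbc.getUpperFluxBound())
        if lo is not None and hi is not None:
            return lo.getValue(), hi.getValue()
    law = reaction.getKineticLaw()
    if law is not None:
        lo = law.getParameter("LOWER_BOUND")
        hi = law.getParameter("UPPER_BOUND")
        if lo is not None and hi is not None:
            return lo.getValue(), hi.getValue()
    if reaction.getReversible():
        return -DEFAULT_BOUND, DEFAULT_BOUND
    return 0.0, DEFAULT_BOUND


def _reaction_gpr(reaction, fbc_model) -> str | None:
    fbc = reaction.getPlugin("fbc")
    if fbc is not None and fbc.isSetGeneProductAssociation():
        assoc = fbc.getGeneProductAssociation().getAssociation()
        if assoc is not None:
            text = assoc.toInfix()
            if fbc_model is not None:
                # map gene-product SIds back to their labels where set
                for i in range(fbc_model.getNumGeneProducts()):
                    gp = fbc_model.getGeneProduct(i)
                    if gp.isSetLabel():
                        text = re.sub(rf"\b{re.escape(gp.getId())}\b", gp.getLabel(), text)
            return text
    return _notes_fields(reaction).get("GENE_ASSOCIATION") or None


def parse_sbml(document: str) -> MetabolicModel:
    """Parse an SBML document (text) into a :class:`MetabolicModel`."""
    doc = libsbml.readSBMLFromString(document)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLParseError(err.getMessage().strip(), line=err.getLine())
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError("document contains no model")

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are the implicit exterior
        formula, charge = _species_formula_charge(sp)
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment() or "c",
            )
        )
    met_ids = {m.id for m in metabolites}
    boundary_ids = {
        sbml_model.getSpecies(i).getId()
        for i in range(sbml_model.getNumSpecies())
        if sbml_model.getSpecies(i).getBoundaryCondition()
    }

    fbc_model = sbml_model.getPlugin("fbc")
    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for refs, sign in ((rx.getListOfReactants(), -1.0), (rx.getListOfProducts(), +1.0)):
            for ref in refs:
                sid = ref.getSpecies()
                if sid in boundary_ids:
                    continue
                if sid not in met_ids:
                    raise ModelStructureError(
                        f"reaction {rx.getId()} references undeclared species {sid}"
                    )
                coef = ref.getStoichiometry()
                if coef != coef:  # NaN -> SBML default
                    coef = 1.0
                stoich[sid] = stoich.get(sid, 0.0) + sign * coef
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich:
            continue  # pure boundary <-> boundary pseudo-reaction
        lb, ub = _reaction_bounds(sbml_model, rx)
        reactions.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_association=_reaction_gpr(rx, fbc_model),
                subsystem=_notes_fields(rx).get("SUBSYSTEM") or None,
            )
        )

    objective_id = None
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        active = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()
    if objective_id is None:
        for rxn in reactions:
            if "biomass" in rxn.id.lower() or "biomass" in rxn.name.lower():
                objective_id = rxn.id
                break

    return MetabolicModel.from_lists(
        metabolites, reactions, objective_id=objective_id,
        annotations={"source": "sbml", "sbml_level": str(sbml_model.getLevel())},
    )


def write_sbml(model: MetabolicModel) -> str:
    """Serialize a model as SBML Level 3 + fbc v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.annotations.get("model_id", "model"))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(format_formula(met.formula))
        splug.setCharge(met.charge if met.charge is not None else 0)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        rx = sm.createReaction()
        rx.setId(rxn.id)
        rx.setName(rxn.name)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        notes = []
        if rxn.gene_association:
            notes.append(f"GENE_ASSOCIATION: {rxn.gene_association}")
        if rxn.subsystem:
            notes.append(f"SUBSYSTEM: {rxn.subsystem}")
        if notes:
            body = "".join(f"<p>{t}</p>" for t in notes)
            rx.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    return libsbml.writeSBMLToString(doc)


# --------------------------------------------------------------------------
# tab-separated tables
# --------------------------------------------------------------------------

_RXN_COLS = {
    "id": {"id", "reaction", "reaction_id", "rxn", "abbreviation"},
    "name": {"name", "reaction_name", "description"},
    "equation": {"equation", "reaction_equation", "rxn_equation", "stoichiometry"},
    "lower_bound": {"lower_bound", "lb", "lower", "lowerbound", "min_flux"},
    "upper_bound": {"upper_bound", "ub", "upper", "upperbound", "max_flux"},
    "gene_association": {"gene_association", "gpr", "genes", "gene_reaction_rule"},
    "subsystem": {"subsystem", "pathway"},
}
_MET_COLS = {
    "id": {"id", "metabolite", "metabolite_id", "abbreviation"},
    "name": {"name", "metabolite_name", "description"},
    "formula": {"formula", "chemical_formula", "composition"},
    "charge": {"charge"},
    "compartment": {"compartment", "comp", "location"},
}

_OBJECTIVE_COMMENT = re.compile(r"#\s*objective\s*[:=]\s*(\S+)")
_ARROW = re.compile(r"\s*(<=>|<-->|<->|-->|->|=>)\s*")


def _canonical_columns(df: pd.DataFrame, colmap: dict[str, set[str]]) -> tuple[pd.DataFrame, list[str]]:
    renames, unknown = {}, []
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "_")
        for canon, variants in colmap.items():
            if key in variants:
                renames[col] = canon
                break
        else:
            unknown.append(str(col))
    return df.rename(columns=renames), unknown


def parse_equation(text: str) -> dict[str, float]:
    """Parse ``2 A + B --> C`` (or ``<=>``) into a signed coefficient map."""
    m = _ARROW.search(text)
    if m is None:
        raise FormatError(f"equation {text!r} has no reaction arrow")
    left, right = text[: m.start()], text[m.end():]
    stoich: dict[str, float] = {}
    for side, sign in ((left, -1.0), (right, +1.0)):
        side = side.strip()
        if not side:
            continue
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                raise FormatError(f"empty term in equation {text!r}")
            parts = term.split()
            if len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise FormatError(f"bad coefficient in term {term!r}") from exc
                met = parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise FormatError(f"cannot parse term {term!r} in {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    return {k: v for k, v in stoich.items() if v != 0.0}


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def side(items):
        # repr keeps full float precision so parse(format(s)) == s exactly
        return " + ".join(
            (f"{abs(c)!r} {m}" if abs(c) != 1.0 else m) for m, c in items
        )

    left = [(m, c) for m, c in stoich.items() if c < 0]
    right = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "-->"
    return f"{side(left)} {arrow} {side(right)}".strip()


def _read_table(text: str) -> tuple[pd.DataFrame, str | None]:
    objective = None
    lines = []
    for line in io.StringIO(text):
        if line.lstrip().startswith("#"):
            m = _OBJECTIVE_COMMENT.search(line)
            if m:
                objective = m.group(1)
            continue
        lines.append(line)
    if not lines:
        raise FormatError("table has no header row")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", dtype=str,
                     keep_default_na=False)
    return df, objective


def parse_tab(reactions_table: str, metabolites_table: str) -> MetabolicModel:
    """Parse the two-file tab format into a model.

    ``reactions_table`` and ``metabolites_table`` are the file *contents*.
    """
    met_df, _ = _read_table(metabolites_table)
    met_df, unknown_met = _canonical_columns(met_df, _MET_COLS)
    if "id" not in met_df.columns:
        raise FormatError("metabolites table lacks an id column")
    metabolites = []
    for idx, row in met_df.iterrows():
        formula = None
        if row.get("formula", ""):
            formula = parse_formula(str(row["formula"]))
        charge = None
        raw_charge = str(row.get("charge", "")).strip()
        if raw_charge:
            try:
                charge = int(float(raw_charge))
            except ValueError as exc:
                raise FormatError(
                    f"metabolites table row {idx + 2}: non-numeric charge {raw_charge!r}"
                ) from exc
        metabolites.append(
            Metabolite(
                id=str(row["id"]),
                name=str(row.get("name", "")),
                formula=formula,
                charge=charge,
                compartment=str(row.get("compartment", "") or "c"),
            )
        )

    rxn_df, objective = _read_table(reactions_table)
    rxn_df, unknown_rxn = _canonical_columns(rxn_df, _RXN_COLS)
    for required in ("id", "equation"):
        if required not in rxn_df.columns:
            raise FormatError(f"reactions table lacks an {required} column")
    reactions = []
    for idx, row in rxn_df.iterrows():
        bounds = {}
        for col, default in (("lower_bound", None), ("upper_bound", None)):
            raw = str(row.get(col, "")).strip()
            if raw:
                try:
                    bounds[col] = float(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"reactions table row {idx + 2}: non-numeric {col} {raw!r}"
                    ) from exc
        stoich = parse_equation(str(row["equation"]))
        reversible = "<" in str(row["equation"])
        lb = bounds.get("lower_bound", -DEFAULT_BOUND if reversible else 0.0)
        ub = bounds.get("upper_bound", DEFAULT_BOUND)
        reactions.append(
            Reaction(
                id=str(row["id"]),
                name=str(row.get("name", "")),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_association=str(row.get("gene_association", "")) or None,
                subsystem=str(row.get("subsystem", "")) or None,
            )
        )

    annotations = {"source": "tab"}
    if unknown_rxn or unknown_met:
        annotations["unrecognized_columns"] = ";".join(unknown_rxn + unknown_met)
    try:
        return MetabolicModel.from_lists(
            metabolites, reactions, objective_id=objective, annotations=annotations
        )
    except ModelStructureError as exc:
        raise ModelStructureError(f"tab tables are inconsistent: {exc}") from exc


def write_tab(model: MetabolicModel) -> tuple[str, str]:
    """Serialize a model as (reactions_table, metabolites_table) text.

    Full float precision (repr) is used for bounds so the round-trip through
    :func:`parse_tab` is exact.
    """
    rxn_lines = []
    if model.objective_id is not None:
        rxn_lines.append(f"# objective: {model.objective_id}")
    rxn_lines.append(
        "id\tname\tequation\tlower_bound\tupper_bound\tgene_association\tsubsystem"
    )
    for rxn in model.reactions.values():
        rxn_lines.append(
            "\t".join(
                [
                    rxn.id,
                    rxn.name,
                    format_equation(rxn.stoichiometry, rxn.reversible),
                    repr(rxn.lower_bound),
                    repr(rxn.upper_bound),
                    rxn.gene_association or "",
                    rxn.subsystem or "",
                ]
            )
        )
    met_lines = ["id\tname\tformula\tcharge\tcompartment"]
    for met in model.metabolites.values():
        met_lines.append(
            "\t".join(
                [
                    met.id,
                    met.name,
                    format_formula(met.formula) if met.formula is not None else "",
                    str(met.charge) if met.charge is not None else "",
                    met.compartment,
                ]
            )
        )
    return "\n".join(rxn_lines) + "\n", "\n".join(met_lines) + "\n"
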