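"""Stoichiometric model representation, SBML I/O and declarative model edits.

The in-memory containers (:class:`Metabolite`, :class:`Reaction`,
:class:`MetabolicModel`) are deliberately small: a model is a list of
metabolites and a list of reactions whose stoichiometries reference
metabolite ids.  The stoichiometric matrix ``S`` is assembled on demand with
one balance row per *non-boundary* metabolite; boundary species (SBML
``boundaryCondition=true`` or an id suffix configured per file, since
published models differ in convention) are excluded from mass balance.

SBML reading accepts both fbc-style flux bounds and the legacy
kinetic-law ``LOWER_BOUND``/``UPPER_BOUND`` parameter encoding.  When a
reaction carries no explicit bounds, the conventional defaults apply:
``[-1000, 1000]`` flux units if reversible, ``[0, 1000]`` otherwise.

Model edits (bound changes, flux fixing, direction flips, added exchange
reactions) are pure functions returning an edited copy, and can be driven
from a declarative patch file (YAML/JSON list of edit records) so that
published-model corrections live in data, not code.  Every edit is logged
with before/after bounds.
"""

from __future__ import annotations

import copy
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

import libsbml

logger = logging.getLogger(__name__)

#: Default magnitude bound (flux units) for otherwise unconstrained reactions.
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class SBMLParseError(ValueError):
    """Malformed SBML input; message carries the libsbml error line."""


class ModelValidationError(ValueError):
    """Structurally inconsistent model (duplicate ids, dangling references...)."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a chemical formula string like ``C6H12O6`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class Metabolite:
    """A chemical species located in one compartment.

    ``formula`` is an optional element -> count map used only by the
    elemental-balance audit; toy fixtures typically omit it.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    boundary_condition: bool = False

    def __post_init__(self) -> None:
        if self.formula is not None:
            for el, n in self.formula.items():
                if not (isinstance(n, (int, np.integer)) and n >= 0):
                    raise ModelValidationError(
                        f"metabolite {self.id}: formula count {el}={n!r} "
                        "must be a non-negative integer"
                    )


@dataclass
class Reaction:
    """A (possibly reversible) reaction: one column of S plus flux bounds.

    ``stoichiometry`` maps metabolite id -> signed coefficient
    (negative = consumed).  Bounds are in flux units (mmol gDW^-1 h^-1 scale).
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites, reactions, optional objective."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str | None = None
    id: str = "model"

    def __post_init__(self) -> None:
        self._check()

    # -- bookkeeping ---------------------------------------------------
    def _check(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id} references unknown metabolites {sorted(missing)}"
                )
        if self.objective_id is not None and self.objective_id not in set(rxn_ids):
            raise ModelValidationError(f"objective reaction {self.objective_id} not in model")

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise KeyError(f"no metabolite {metabolite_id!r}")

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"no reaction {reaction_id!r}")

    def has_metabolite(self, metabolite_id: str) -> bool:
        return any(m.id == metabolite_id for m in self.metabolites)

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- numeric view --------------------------------------------------
    def to_arrays(self) -> tuple[np.ndarray, list[str], list[str], np.ndarray, np.ndarray]:
        """Assemble ``(S, metabolite_ids, reaction_ids, lb, ub)``.

        S has one row per non-boundary metabolite and one column per
        reaction; boundary species do not get a balance row.
        """
        rows = [m.id for m in self.metabolites if not m.boundary_condition]
        row_index = {mid: i for i, mid in enumerate(rows)}
        cols = self.reaction_ids
        S = np.zeros((len(rows), len(cols)))
        lb = np.empty(len(cols))
        ub = np.empty(len(cols))
        for j, r in enumerate(self.reactions):
            lb[j], ub[j] = r.lower_bound, r.upper_bound
            for mid, coeff in r.stoichiometry.items():
                i = row_index.get(mid)
                if i is not None:
                    S[i, j] = coeff
        return S, rows, cols, lb, ub

    def structurally_equal(self, other: "MetabolicModel", tol: float = 1e-9) -> bool:
        """Same metabolites, reactions, stoichiometries and bounds (order-free)."""
        if set(self.metabolite_ids) != set(other.metabolite_ids):
            return False
        if set(self.reaction_ids) != set(other.reaction_ids):
            return False
        for m in self.metabolites:
            o = other.metabolite(m.id)
            if m.boundary_condition != o.boundary_condition:
                return False
        for r in self.reactions:
            o = other.reaction(r.id)
            if abs(r.lower_bound - o.lower_bound) > tol:
                return False
            if abs(r.upper_bound - o.upper_bound) > tol:
                return False
            if set(r.stoichiometry) != set(o.stoichiometry):
                return False
            for mid, c in r.stoichiometry.items():
                if abs(c - o.stoichiometry[mid]) > tol:
                    return False
        return True


# ---------------------------------------------------------------------------
# SBML reading / writing
# ---------------------------------------------------------------------------

def _bounds_from_sbml(reaction: libsbml.Reaction, sbml_model: libsbml.Model) -> tuple[float, float] | None:
    """Extract bounds from fbc attributes or legacy kinetic-law parameters."""
    fbc = reaction.getPlugin("fbc")
    if fbc is not None:
        lo_id = fbc.getLowerFluxBound()
        hi_id = fbc.getUpperFluxBound()
        if lo_id and hi_id:
            lo_p = sbml_model.getParameter(lo_id)
            hi_p = sbml_model.getParameter(hi_id)
            if lo_p is not None and hi_p is not None:
                return lo_p.getValue(), hi_p.getValue()
    kl = reaction.getKineticLaw()
    if kl is not None:
        lo = kl.getParameter("LOWER_BOUND")
        hi = kl.getParameter("UPPER_BOUND")
        if lo is not None and hi is not None:
            return lo.getValue(), hi.getValue()
    return None


def _clip_bound(value: float) -> float:
    # Infinities are encoded as the conventional magnitude cap so that every
    # LP stays bounded.
    if not np.isfinite(value):
        return DEFAULT_BOUND if value > 0 else -DEFAULT_BOUND
    return float(np.clip(value, -DEFAULT_BOUND, DEFAULT_BOUND))


def parse_sbml(
    path: str | Path,
    boundary_suffixes: Sequence[str] = (),
) -> MetabolicModel:
    """Read an SBML (L2/L3) file into a :class:`MetabolicModel`.

    Parameters
    ----------
    path:
        SBML file with fbc-style or kinetic-law flux-bound encoding.
    boundary_suffixes:
        Extra metabolite-id suffixes (e.g. ``"_b"``) treated as boundary
        species, for files that mark the system boundary by naming
        convention rather than ``boundaryCondition``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"{path.name}: line {err.getLine()}: {err.getMessage().strip()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise SBMLParseError(f"{path.name}: no model element")

    metabolites = []
    for sp in sm.getListOfSpecies():
        boundary = bool(sp.getBoundaryCondition()) or any(
            sp.getId().endswith(suf) for suf in boundary_suffixes
        )
        formula = None
        fbc_sp = sp.getPlugin("fbc")
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = parse_formula(fbc_sp.getChemicalFormula())
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=formula,
                boundary_condition=boundary,
            )
        )
    met_ids = {m.id for m in metabolites}
    boundary_ids = {m.id for m in metabolites if m.boundary_condition}

    encoding = "defaults"
    reactions = []
    for rx in sm.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            sid = ref.getSpecies()
            if sid not in met_ids:
                raise ModelValidationError(
                    f"reaction {rx.getId()} references unknown species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) - (ref.getStoichiometry() or 1.0)
        for ref in rx.getListOfProducts():
            sid = ref.getSpecies()
            if sid not in met_ids:
                raise ModelValidationError(
                    f"reaction {rx.getId()} references unknown species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) + (ref.getStoichiometry() or 1.0)
        bounds = _bounds_from_sbml(rx, sm)
        if bounds is None:
            reversible = rx.getReversible()
            bounds = (-DEFAULT_BOUND if reversible else 0.0, DEFAULT_BOUND)
        else:
            encoding = "explicit"
        lb, ub = (_clip_bound(bounds[0]), _clip_bound(bounds[1]))
        internal = [mid for mid in stoich if mid not in boundary_ids]
        is_exchange = len(internal) == 1 and (
            len(stoich) == 1 or all(mid in boundary_ids for mid in stoich if mid != internal[0])
        )
        reactions.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=is_exchange,
            )
        )

    objective_id = None
    fbc_m = sm.getPlugin("fbc")
    if fbc_m is not None and fbc_m.getNumObjectives() > 0:
        obj = fbc_m.getActiveObjective() or fbc_m.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()

    logger.info("parsed %s: %d metabolites, %d reactions, bounds=%s",
                path.name, len(metabolites), len(reactions), encoding)
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        id=sm.getId() or path.stem,
    )


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML L3V1 with fbc v2 flux bounds."""
    doc = libsbml.SBMLDocument(3, 1)
    doc.enablePackage(libsbml.FbcExtension.getXmlnsL3V1V2(), "fbc", True)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    fbc_m = sm.getPlugin("fbc")
    fbc_m.setStrict(False)

    compartments = {m.compartment for m in model.metabolites}
    for cid in sorted(compartments):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setBoundaryCondition(m.boundary_condition)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        if m.formula:
            fbc_sp = sp.getPlugin("fbc")
            fbc_sp.setChemicalFormula(
                "".join(f"{el}{n if n != 1 else ''}" for el, n in sorted(m.formula.items()))
            )

    bound_params: dict[float, str] = {}

    def _param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for mid, coeff in r.stoichiometry.items():
            if coeff < 0:
                ref = rx.createReactant()
                ref.setSpecies(mid)
                ref.setStoichiometry(-coeff)
            else:
                ref = rx.createProduct()
                ref.setSpecies(mid)
                ref.setStoichiometry(coeff)
            ref.setConstant(True)
        fbc_r = rx.getPlugin("fbc")
        fbc_r.setLowerFluxBound(_param_for(r.lower_bound))
        fbc_r.setUpperFluxBound(_param_for(r.upper_bound))

    if model.objective_id is not None:
        obj = fbc_m.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        fbc_m.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(Path(path)))


# ---------------------------------------------------------------------------
# Model edits
# ---------------------------------------------------------------------------

def add_exchange(
    model: MetabolicModel,
    metabolite_id: str,
    direction: str = "both",
    reaction_id: str | None = None,
    replace: bool = False,
) -> MetabolicModel:
    """Return a copy of the model with an exchange reaction for a metabolite.

    ``direction`` is ``"import"`` (nothing -> metabolite, bounds [0, 1000]),
    ``"export"`` (metabolite -> nothing, bounds [0, 1000]) or ``"both"``
    (reversible, bounds [-1000, 1000], export-positive sign convention).
    """
    if direction not in ("import", "export", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    model.metabolite(metabolite_id)  # raises KeyError if absent
    new = model.copy()
    existing = [
        r for r in new.reactions if r.is_exchange and metabolite_id in r.stoichiometry
    ]
    if existing and not replace:
        raise ValueError(
            f"metabolite {metabolite_id} already has exchange(s) "
            f"{[r.id for r in existing]}; pass replace=True to replace"
        )
    for r in existing:
        new.reactions.remove(r)
    rid = reaction_id or f"EX_{metabolite_id}"
    if new.has_reaction(rid):
        raise ValueError(f"reaction id {rid} already in model")
    if direction == "import":
        stoich, lb, ub = {metabolite_id: 1.0}, 0.0, DEFAULT_BOUND
    elif direction == "export":
        stoich, lb, ub = {metabolite_id: -1.0}, 0.0, DEFAULT_BOUND
    else:
        stoich, lb, ub = {metabolite_id: -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND
    new.reactions.append(
        Reaction(id=rid, name=f"{direction} exchange for {metabolite_id}",
                 stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                 is_exchange=True)
    )
    logger.info("add_exchange %s: %s (%s) bounds [%g, %g]", rid, metabolite_id, direction, lb, ub)
    return new


def set_bounds(model: MetabolicModel, reaction_id: str, lb: float, ub: float) -> MetabolicModel:
    """Return a copy with the reaction's bounds replaced."""
    if lb > ub:
        raise ValueError(f"lower bound {lb} > upper bound {ub}")
    model.reaction(reaction_id)
    new = model.copy()
    r = new.reaction(reaction_id)
    logger.info("set_bounds %s: [%g, %g] -> [%g, %g]",
                reaction_id, r.lower_bound, r.upper_bound, lb, ub)
    r.lower_bound, r.upper_bound = float(lb), float(ub)
    return new


def fix_flux(model: MetabolicModel, reaction_id: str, value: float) -> MetabolicModel:
    """Return a copy with the reaction's flux fixed (lb = ub = value)."""
    return set_bounds(model, reaction_id, value, value)


def flip_direction(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Return a copy with the reaction's stoichiometry negated and bounds mirrored.

    Used to apply published direction corrections declaratively.
    """
    model.reaction(reaction_id)
    new = model.copy()
    r = new.reaction(reaction_id)
    logger.info("flip_direction %s", reaction_id)
    r.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
    r.lower_bound, r.upper_bound = -r.upper_bound, -r.lower_bound
    return new


def apply_patch(model: MetabolicModel, patch: str | Path | Iterable[Mapping]) -> MetabolicModel:
    """Apply a declarative patch (YAML/JSON file or list of edit records).

    Each record is a mapping with a ``reaction_id`` or ``metabolite_id`` and
    one of: ``{new_lb, new_ub}``, ``{fix: value}``, ``{flip_direction: true}``,
    ``{add_exchange: import|export|both}`` (optional ``id``/``replace`` keys).
    """
    if isinstance(patch, (str, Path)):
        text = Path(patch).read_text()
        patch = yaml.safe_load(text) if str(patch).endswith((".yaml", ".yml")) else json.loads(text)
    for record in patch:
        if record.get("flip_direction"):
            model = flip_direction(model, record["reaction_id"])
        elif "add_exchange" in record:
            model = add_exchange(
                model,
                record["metabolite_id"],
                direction=record["add_exchange"],
                reaction_id=record.get("id"),
                replace=bool(record.get("replace", False)),
            )
        elif "fix" in record:
            model = fix_flux(model, record["reaction_id"], float(record["fix"]))
        elif "new_lb" in record or "new_ub" in record:
            r = model.reaction(record["reaction_id"])
            lb = float(record.get("new_lb", r.lower_bound))
            ub = float(record.get("new_ub", r.upper_bound))
            model = set_bounds(model, record["reaction_id"], lb, ub)
        else:
            raise ValueError(f"unrecognized patch record: {record!r}")
    return model


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of :func:`validate_model`: structural issues, never mutations."""

    orphan_metabolites: list[str] = field(default_factory=list)
    blocked_reactions: list[str] = field(default_factory=list)
    unbalanced_reactions: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.orphan_metabolites or self.blocked_reactions or self.unbalanced_reactions)


def validate_model(model: MetabolicModel, check_blocked: bool = True, tol: float = 1e-6) -> ValidationReport:
    """Audit a model for orphan metabolites, blocked reactions and element leaks.

    Elemental balance is only checked for internal reactions in which every
    participating (non-boundary) metabolite carries a formula; models without
    formulas therefore report zero unbalanced reactions.
    """
    report = ValidationReport()

    used = {mid for r in model.reactions for mid in r.stoichiometry}
    report.orphan_metabolites = sorted(m.id for m in model.metabolites if m.id not in used)

    boundary = {m.id for m in model.metabolites if m.boundary_condition}
    for r in model.reactions:
        if r.is_exchange:
            continue
        internal = {mid: c for mid, c in r.stoichiometry.items() if mid not in boundary}
        formulas = {mid: model.metabolite(mid).formula for mid in internal}
        if any(f is None for f in formulas.values()):
            continue
        balance: dict[str, float] = {}
        for mid, c in internal.items():
            for el, n in formulas[mid].items():
                balance[el] = balance.get(el, 0.0) + c * n
        if any(abs(v) > tol for v in balance.values()):
            report.unbalanced_reactions.append(r.id)

    if check_blocked and model.reactions:
        from . import lp_core  # local import: lp_core depends on these types

        open_model = model.copy()
        for r in open_model.reactions:
            if r.is_exchange:
                r.lower_bound = -DEFAULT_BOUND
                r.upper_bound = DEFAULT_BOUND
        ranges = lp_core.flux_ranges(open_model)
        report.blocked_reactions = [
            fr.reaction_id for fr in ranges
            if abs(fr.min_flux) <= tol and abs(fr.max_flux) <= tol
        ]
    return report
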