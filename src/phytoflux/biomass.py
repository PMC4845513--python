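"""Biomass compositions: normalization, producibility, reaction assembly.

A biomass objective function (BOF) is a pseudo-reaction consuming precursor
metabolites X_i in fixed proportions c_i (mmol per gram dry weight) plus a
growth-associated maintenance (GAM) ATP-hydrolysis term, and producing one
unit of a biomass pseudo-metabolite.  Maximizing its flux under steady-state
mass balance is the growth-rate prediction.

Weight normalization rescales all coefficients by a single factor so that
one unit of biomass flux corresponds to exactly 1 g of biomass
(sum c_i * MW_i / 1000 = 1); this is the step that puts compositions
published in different units on a common footing before they are swapped
between models.  GAM is a separate scalar, deliberately not a component, so
composition swaps never alter the maintenance cost.

Perturbed or partial compositions are *not* re-normalized: varying one
coefficient while "the rest stays unchanged" means a biomass flux unit no
longer equals exactly 1 g, which :func:`effective_mass_per_flux` reports.
"""

from __future__ import annotations

import copy
import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model_io import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
)

logger = logging.getLogger(__name__)

MACRO_CLASSES = (
    "cell wall",
    "protein",
    "lipid",
    "carbohydrate",
    "nucleic acid",
    "soluble",
    "other",
)

#: default tolerance on producibility (max export flux must exceed this)
PRODUCIBILITY_TOL = 1e-6


@dataclass
class BiomassComponent:
    """One biomass precursor: coefficient, macromolecule class, MW, C count."""

    metabolite_id: str
    coefficient: float  # mmol / gDW
    macro_class: str = "other"
    molecular_weight: float | None = None  # g / mol
    carbon_atoms: int | None = None

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError(
                f"component {self.metabolite_id}: coefficient must be > 0, "
                f"got {self.coefficient}"
            )
        if self.macro_class not in MACRO_CLASSES:
            raise ValueError(
                f"component {self.metabolite_id}: unknown macro class "
                f"{self.macro_class!r} (expected one of {MACRO_CLASSES})"
            )


@dataclass
class BiomassComposition:
    """A named set of biomass components plus the GAM scalar (ATP eq / unit)."""

    id: str
    components: list[BiomassComponent] = field(default_factory=list)
    gam: float = 0.0

    def __post_init__(self) -> None:
        ids = [c.metabolite_id for c in self.components]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate component ids: {dup}")

    def copy(self) -> "BiomassComposition":
        return copy.deepcopy(self)

    def component(self, metabolite_id: str) -> BiomassComponent:
        for c in self.components:
            if c.metabolite_id == metabolite_id:
                return c
        raise KeyError(f"no component {metabolite_id!r}")

    @property
    def component_ids(self) -> list[str]:
        return [c.metabolite_id for c in self.components]

    @property
    def coefficients(self) -> dict[str, float]:
        return {c.metabolite_id: c.coefficient for c in self.components}

    def total_mass(self) -> float:
        """Grams of biomass per unit flux: sum c_i * MW_i / 1000."""
        missing = [c.metabolite_id for c in self.components if c.molecular_weight is None]
        if missing:
            raise ValueError(f"components missing molecular weight: {missing}")
        return sum(c.coefficient * c.molecular_weight / 1000.0 for c in self.components)


#: alias used in reports for perturbed compositions
effective_mass_per_flux = BiomassComposition.total_mass


def normalize_by_weight(
    composition: BiomassComposition,
    mw_table: Mapping[str, float] | None = None,
    rescale_gam: bool = False,
) -> BiomassComposition:
    """Rescale all coefficients by one factor so 1 flux unit = 1 g biomass.

    ``mw_table`` fills in molecular weights for components lacking one.
    The GAM scalar is rescaled by the same factor only when ``rescale_gam``
    is set (default off: maintenance is a property of the model, not of the
    composition's unit system).  Idempotent and scale-invariant.
    """
    comp = composition.copy()
    if mw_table:
        for c in comp.components:
            if c.molecular_weight is None and c.metabolite_id in mw_table:
                c.molecular_weight = float(mw_table[c.metabolite_id])
    missing = [c.metabolite_id for c in comp.components if not c.molecular_weight]
    if missing:
        raise ValueError(
            f"cannot weight-normalize: missing or zero molecular weight for {missing}"
        )
    mass = comp.total_mass()
    if mass <= 0:
        raise ValueError("total composition mass is zero")
    k = 1.0 / mass
    for c in comp.components:
        c.coefficient *= k
    if rescale_gam:
        comp.gam *= k
    logger.info("normalize_by_weight %s: factor %.6g (was %.6g g per flux unit)",
                comp.id, k, mass)
    return comp


def producible(
    model: MetabolicModel,
    metabolite_id: str,
    constraints=None,
    tol: float = PRODUCIBILITY_TOL,
) -> bool:
    """True iff the metabolite's maximal export flux exceeds ``tol``.

    The model is augmented with a temporary export drain for the metabolite,
    that drain is maximized under the scenario's nutrient constraints, and
    the metabolite counts as producible when the optimum is positive.
    """
    from . import lp_core

    model.metabolite(metabolite_id)  # KeyError if absent
    if constraints is not None:
        from .scenarios import apply_constraints

        model = apply_constraints(model, constraints)
    probe = model.copy()
    drain_id = "__producibility_probe__"
    probe.reactions.append(
        Reaction(id=drain_id, stoichiometry={metabolite_id: -1.0},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, is_exchange=True)
    )
    probe.objective_id = drain_id
    res = lp_core.solve_fba(probe)
    return res.optimal and res.objective_value > tol


def intersect_components(
    compositions: Sequence[BiomassComposition],
    models: Sequence[MetabolicModel],
    constraints=None,
    tol: float = PRODUCIBILITY_TOL,
) -> tuple[set[str], dict[str, list[str]]]:
    """Component ids producible in *every* model, plus per-model exclusions.

    The candidate set is the union of all compositions' component ids.  A
    component absent from a model's metabolite list, or present but unable
    to carry positive export flux under the constraints, is excluded and
    listed under that model's id.  Order of inputs does not matter.
    """
    if not compositions or not models:
        raise ValueError("need at least one composition and one model")
    candidates = sorted({cid for comp in compositions for cid in comp.component_ids})
    exclusions: dict[str, list[str]] = {m.id: [] for m in models}
    common = set(candidates)
    for model in models:
        for cid in candidates:
            ok = model.has_metabolite(cid) and producible(model, cid, constraints, tol=tol)
            if not ok:
                exclusions[model.id].append(cid)
                common.discard(cid)
    return common, exclusions


def restrict(composition: BiomassComposition, component_ids: Iterable[str]) -> BiomassComposition:
    """Composition restricted to the given component ids (GAM untouched)."""
    keep = set(component_ids)
    comp = composition.copy()
    comp.components = [c for c in comp.components if c.metabolite_id in keep]
    return comp


@dataclass
class GAMRecipe:
    """Species ids for the ATP-hydrolysis stoichiometry of maintenance.

    ATP + H2O -> ADP + Pi (+ H); entries set to None are skipped, so toy
    networks with a bare energy-currency metabolite can use
    ``GAMRecipe(atp="E")``.  Default compartment is the cytosol; pass the
    matching ids for models that keep maintenance elsewhere.
    """

    atp: str
    adp: str | None = None
    pi: str | None = None
    h2o: str | None = None
    h: str | None = None

    def stoichiometry(self, gam: float) -> dict[str, float]:
        st = {self.atp: -gam}
        if self.h2o:
            st[self.h2o] = st.get(self.h2o, 0.0) - gam
        if self.adp:
            st[self.adp] = st.get(self.adp, 0.0) + gam
        if self.pi:
            st[self.pi] = st.get(self.pi, 0.0) + gam
        if self.h:
            st[self.h] = st.get(self.h, 0.0) + gam
        return st


BIOMASS_REACTION_ID = "Biomass"
BIOMASS_METABOLITE_ID = "biomass"
BIOMASS_SINK_ID = "Biomass_sink"


def remove_biomass_reaction(model: MetabolicModel) -> MetabolicModel:
    """Inverse of :func:`build_biomass_reaction`; restores the original model."""
    new = model.copy()
    new.reactions = [r for r in new.reactions
                     if r.id not in (BIOMASS_REACTION_ID, BIOMASS_SINK_ID)]
    new.metabolites = [m for m in new.metabolites if m.id != BIOMASS_METABOLITE_ID]
    if new.objective_id == BIOMASS_REACTION_ID:
        new.objective_id = None
    return new


def build_biomass_reaction(
    model: MetabolicModel,
    composition: BiomassComposition,
    energy: GAMRecipe | None = None,
) -> MetabolicModel:
    """Assemble the biomass reaction from a composition and set it as objective.

    Adds (or replaces) a single reaction consuming ``c_i`` of every
    component, hydrolyzing ``gam`` ATP equivalents via ``energy``, and
    producing 1 unit of a biomass pseudo-metabolite that is drained by a
    sink so the pseudo-metabolite itself stays balanceable at steady state.
    """
    missing = [cid for cid in composition.component_ids if not model.has_metabolite(cid)]
    if missing:
        raise KeyError(f"biomass components not in model: {missing}")
    if composition.gam > 0:
        if energy is None:
            raise ValueError("composition has gam > 0 but no ATP-hydrolysis recipe given")
        if not model.has_metabolite(energy.atp):
            raise KeyError(f"ATP species {energy.atp!r} not in model")

    new = remove_biomass_reaction(model)
    stoich: dict[str, float] = {cid: -c for cid, c in composition.coefficients.items()}
    if composition.gam > 0:
        for mid, coeff in energy.stoichiometry(composition.gam).items():
            if not new.has_metabolite(mid):
                raise KeyError(f"maintenance species {mid!r} not in model")
            stoich[mid] = stoich.get(mid, 0.0) + coeff
    stoich[BIOMASS_METABOLITE_ID] = 1.0

    new.metabolites.append(Metabolite(id=BIOMASS_METABOLITE_ID, name="biomass", compartment="c"))
    new.reactions.append(
        Reaction(id=BIOMASS_REACTION_ID, name=f"biomass ({composition.id})",
                 stoichiometry=stoich, lower_bound=0.0, upper_bound=DEFAULT_BOUND)
    )
    new.reactions.append(
        Reaction(id=BIOMASS_SINK_ID, name="biomass sink",
                 stoichiometry={BIOMASS_METABOLITE_ID: -1.0},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, is_exchange=True)
    )
    new.objective_id = BIOMASS_REACTION_ID
    return new


def class_weight_percent(composition: BiomassComposition) -> dict[str, float]:
    """Percent of total biomass mass contributed by each macromolecule class."""
    if not composition.components:
        raise ValueError("empty composition")
    total = composition.total_mass()
    out: dict[str, float] = {}
    for c in composition.components:
        mass = c.coefficient * c.molecular_weight / 1000.0
        out[c.macro_class] = out.get(c.macro_class, 0.0) + mass
    return {cls: 100.0 * m / total for cls, m in out.items()}


def weight_fraction(composition: BiomassComposition) -> dict[str, float]:
    """Per-component fractional contribution to biomass mass (sums to 1)."""
    total = composition.total_mass()
    return {
        c.metabolite_id: c.coefficient * c.molecular_weight / 1000.0 / total
        for c in composition.components
    }


def carbon_fraction(composition: BiomassComposition) -> dict[str, float]:
    """Per-component fractional contribution of carbon atoms (sums to 1)."""
    missing = [c.metabolite_id for c in composition.components if c.carbon_atoms is None]
    if missing:
        raise ValueError(f"components missing carbon counts: {missing}")
    total = sum(c.coefficient * c.carbon_atoms for c in composition.components)
    if total <= 0:
        raise ValueError("composition carries no carbon")
    return {
        c.metabolite_id: c.coefficient * c.carbon_atoms / total
        for c in composition.components
    }


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_HEADER = ["metabolite_id", "coefficient_mmol_per_gDW", "macro_class",
           "mw_g_per_mol", "carbon_atoms"]


def read_composition(path: str | Path, id: str | None = None, gam: float = 0.0,
                     delimiter: str = "\t") -> BiomassComposition:
    """Read a composition table (TSV by default) with the standard header."""
    path = Path(path)
    components = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = set(_HEADER[:3]) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
        for row in reader:
            mw = row.get("mw_g_per_mol")
            nc = row.get("carbon_atoms")
            components.append(BiomassComponent(
                metabolite_id=row["metabolite_id"],
                coefficient=float(row["coefficient_mmol_per_gDW"]),
                macro_class=row["macro_class"],
                molecular_weight=float(mw) if mw not in (None, "", "NA") else None,
                carbon_atoms=int(nc) if nc not in (None, "", "NA") else None,
            ))
    return BiomassComposition(id=id or path.stem, components=components, gam=gam)


def write_composition(composition: BiomassComposition, path: str | Path,
                      delimiter: str = "\t") -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_HEADER)
        for c in composition.components:
            writer.writerow([
                c.metabolite_id, repr(c.coefficient), c.macro_class,
                "" if c.molecular_weight is None else repr(c.molecular_weight),
                "" if c.carbon_atoms is None else c.carbon_atoms,
            ])


def write_class_table(compositions: Sequence[BiomassComposition], path: str | Path) -> None:
    """CSV of class weight percentages, one column per composition."""
    tables = {comp.id: class_weight_percent(comp) for comp in compositions}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["macro_class", *tables])
        for cls in MACRO_CLASSES:
            if any(cls in t for t in tables.values()):
                writer.writerow([cls, *(f"{t.get(cls, 0.0):.4f}" for t in tables.values())])
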