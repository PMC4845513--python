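"""Synthetic toy metabolic networks with known analytic optima.

These generators produce the miniature counterparts of genome-scale models
on which every pipeline stage is testable without external downloads: a
substrate uptake, one or more parallel catabolic routes converting the
substrate into an ATP-like energy currency (parallel copies make the FBA
optimum degenerate, exercising geometric centering), a fixed maintenance
drain, and a two-component biomass reaction.

For the canonical topology the growth optimum has a closed form.  With
uptake bound ``u``, energy yield ``y`` per substrate, maintenance ``n`` and
biomass coefficients ``c_G`` (substrate) and ``c_E`` (energy):

    substrate balance:  u - C - c_G * v = 0
    energy balance:     y * C - n - c_E * v = 0
    =>  v* = (y * u - n) / (y * c_G + c_E)

which the generator returns alongside the model for use as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biomass import (
    MACRO_CLASSES,
    BiomassComponent,
    BiomassComposition,
    build_biomass_reaction,
    normalize_by_weight,
)
from .model_io import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

SUBSTRATE = "G"     # glucose-like substrate
ENERGY = "E"        # ATP-like energy currency
UPTAKE_ID = "EX_G"
NGAM_ID = "NGAM"


@dataclass
class ToySpec:
    """Parameters of a toy network; all positive, ``seed`` pins any randomness."""

    n_pathways: int = 1
    energy_yield: float = 3.0
    uptake_bound: float = 10.0
    ngam: float = 2.0
    substrate_coeff: float = 0.5
    energy_coeff: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        for name in ("energy_yield", "uptake_bound", "substrate_coeff", "energy_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ngam < 0:
            raise ValueError("ngam must be >= 0")

    @property
    def analytic_optimum(self) -> float:
        """Closed-form growth optimum (negative => infeasible by design)."""
        return (self.energy_yield * self.uptake_bound - self.ngam) / (
            self.energy_yield * self.substrate_coeff + self.energy_coeff
        )


@dataclass
class ToyNetwork:
    """A generated toy model with its composition and analytic optimum."""

    model: MetabolicModel
    composition: BiomassComposition
    analytic_optimum: float
    spec: ToySpec = field(repr=False, default=None)

    @property
    def infeasible_by_design(self) -> bool:
        return self.analytic_optimum < 0


def make_toy(spec: ToySpec = ToySpec(), model_id: str = "toy") -> ToyNetwork:
    """Build the canonical toy network for a spec.

    Structure: uptake (0 <= v <= uptake_bound) imports the substrate;
    ``n_pathways`` interchangeable catabolic reactions each convert one
    substrate into ``energy_yield`` energy units; a maintenance drain fixes
    ``ngam`` units of energy consumption; the biomass reaction consumes
    ``substrate_coeff`` substrate + ``energy_coeff`` energy per unit growth.
    """
    metabolites = [
        Metabolite(id=SUBSTRATE, name="substrate", compartment="c"),
        Metabolite(id=ENERGY, name="energy currency", compartment="c"),
    ]
    reactions = [
        Reaction(id=UPTAKE_ID, name="substrate uptake",
                 stoichiometry={SUBSTRATE: 1.0},
                 lower_bound=0.0, upper_bound=spec.uptake_bound, is_exchange=True),
    ]
    for k in range(spec.n_pathways):
        rid = "C" if k == 0 else f"C{k + 1}"
        reactions.append(
            Reaction(id=rid, name=f"catabolic pathway {k + 1}",
                     stoichiometry={SUBSTRATE: -1.0, ENERGY: spec.energy_yield},
                     lower_bound=0.0, upper_bound=DEFAULT_BOUND)
        )
    # the drain is a maintenance pseudo-reaction, not an exchange: it must
    # survive exchange-wide edits (opening, replacement) untouched
    reactions.append(
        Reaction(id=NGAM_ID, name="non-growth maintenance drain",
                 stoichiometry={ENERGY: -1.0},
                 lower_bound=spec.ngam, upper_bound=spec.ngam)
    )
    model = MetabolicModel(metabolites=metabolites, reactions=reactions, id=model_id)

    composition = BiomassComposition(
        id=f"{model_id}BOF",
        components=[
            BiomassComponent(SUBSTRATE, spec.substrate_coeff,
                             macro_class="carbohydrate", molecular_weight=180.0,
                             carbon_atoms=6),
            BiomassComponent(ENERGY, spec.energy_coeff,
                             macro_class="other", molecular_weight=507.0,
                             carbon_atoms=10),
        ],
        gam=0.0,
    )
    model = build_biomass_reaction(model, composition)
    return ToyNetwork(model=model, composition=composition,
                      analytic_optimum=spec.analytic_optimum, spec=spec)


def make_futile_cycle_model(
    base: ToyNetwork | ToySpec | None = None,
    cycle_yield: float = 10.0,
) -> ToyNetwork:
    """Toy network plus a zero-cost energy-generating cycle.

    The loop M1 -> M2 (+ ``cycle_yield``*E via the generating branch FC1,
    or for free via the plain branch FC3) and M2 -> M1 (FC2) produces
    energy currency at zero cost, so maintenance constraints become
    non-binding — the synthetic analogue of a futile cycle in a published
    network.  ``cycle_yield`` sets the energy output per generating turn;
    at the default the cycle's capacity (yield times the magnitude cap)
    exceeds any toy network's energy demand, which is what makes it
    genuinely non-binding, and the plain branch lets the circulation flux
    vary freely at the optimum (an FVA range running up to the cap).
    Growth is then limited by the substrate balance alone:
    v* = uptake / substrate_coeff.
    """
    if base is None:
        base = ToySpec()
    if isinstance(base, ToySpec):
        base = make_toy(base)
    spec = base.spec
    model = base.model.copy()
    model.id = f"{model.id}_futile"
    model.metabolites.extend([
        Metabolite(id="M1", name="cycle carrier 1", compartment="c"),
        Metabolite(id="M2", name="cycle carrier 2", compartment="c"),
    ])
    model.reactions.extend([
        Reaction(id="FC1", name="futile cycle forward",
                 stoichiometry={"M1": -1.0, "M2": 1.0, ENERGY: cycle_yield},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND),
        Reaction(id="FC2", name="futile cycle return",
                 stoichiometry={"M2": -1.0, "M1": 1.0},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND),
        Reaction(id="FC3", name="futile cycle forward (no yield)",
                 stoichiometry={"M1": -1.0, "M2": 1.0},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND),
    ])
    optimum = spec.uptake_bound / spec.substrate_coeff
    return ToyNetwork(model=model, composition=base.composition,
                      analytic_optimum=optimum, spec=spec)


def make_branched_toy(
    n_components: int = 6,
    seed: int = 0,
    spec: ToySpec | None = None,
    gam: float = 0.0,
    model_id: str = "branched",
) -> ToyNetwork:
    """Toy network with many biomass precursors, each built from substrate.

    Each precursor X_i is synthesized by k_i G + e_i E -> X_i (k_i glucose
    equivalents, e_i energy units), carries 6*k_i carbon atoms and weighs
    180*k_i g/mol, and enters the biomass reaction with coefficient c_i.
    Eliminating the substrate and energy balances gives the closed-form
    optimum

        v* = (y*u - ngam) / (y * sum_i c_i k_i + sum_i c_i e_i + gam),

    so growth responds to a coefficient c_i in proportion to the
    component's carbon (and weight) share when synthesis is carbon-
    dominated — the regime in which growth-rate changes track the
    fractional carbon coefficient.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    spec = spec or ToySpec()
    rng = np.random.default_rng(seed)
    metabolites = [
        Metabolite(id=SUBSTRATE, name="substrate", compartment="c"),
        Metabolite(id=ENERGY, name="energy currency", compartment="c"),
    ]
    reactions = [
        Reaction(id=UPTAKE_ID, name="substrate uptake",
                 stoichiometry={SUBSTRATE: 1.0},
                 lower_bound=0.0, upper_bound=spec.uptake_bound, is_exchange=True),
        Reaction(id="C", name="catabolic pathway",
                 stoichiometry={SUBSTRATE: -1.0, ENERGY: spec.energy_yield},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND),
        Reaction(id=NGAM_ID, name="non-growth maintenance drain",
                 stoichiometry={ENERGY: -1.0},
                 lower_bound=spec.ngam, upper_bound=spec.ngam),
    ]
    components = []
    for i in range(n_components):
        k = int(rng.integers(1, 5))
        e = float(rng.uniform(0.0, 1.0))
        c = float(10.0 ** rng.uniform(-1.5, -0.5))
        xid = f"X{i:02d}"
        metabolites.append(Metabolite(id=xid, name=f"precursor {i}", compartment="c"))
        reactions.append(Reaction(
            id=f"S{i:02d}", name=f"synthesis of {xid}",
            stoichiometry={SUBSTRATE: -float(k), ENERGY: -e, xid: 1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND,
        ))
        components.append(BiomassComponent(
            metabolite_id=xid, coefficient=c,
            macro_class=MACRO_CLASSES[i % len(MACRO_CLASSES)],
            molecular_weight=180.0 * k, carbon_atoms=6 * k,
        ))
    model = MetabolicModel(metabolites=metabolites, reactions=reactions, id=model_id)
    composition = BiomassComposition(id=f"{model_id}BOF", components=components,
                                     gam=gam)
    from .biomass import GAMRecipe

    model = build_biomass_reaction(model, composition, energy=GAMRecipe(atp=ENERGY))
    carbon_cost = sum(
        c.coefficient * model.reaction(f"S{i:02d}").stoichiometry[SUBSTRATE] * -1
        for i, c in enumerate(components)
    )
    energy_cost = sum(
        c.coefficient * -model.reaction(f"S{i:02d}").stoichiometry.get(ENERGY, 0.0)
        for i, c in enumerate(components)
    )
    optimum = (spec.energy_yield * spec.uptake_bound - spec.ngam) / (
        spec.energy_yield * carbon_cost + energy_cost + gam
    )
    return ToyNetwork(model=model, composition=composition,
                      analytic_optimum=optimum, spec=spec)


def make_random_composition(
    n_components: int,
    class_mix: dict[str, float],
    seed: int,
    id: str = "randomBOF",
) -> BiomassComposition:
    """Random weight-normalized composition mimicking real macro-class skew.

    ``class_mix`` gives the target *weight share* of each macromolecule
    class (compositions in the field are reported as weight percentages, so
    that is the quantity a class mix should pin down).  Component counts
    per class are allocated by largest remainder; coefficients are drawn
    log-uniformly over one decade, molecular weights uniformly in
    60-800 g/mol and carbon counts uniformly in 2-40; each class is then
    rescaled so its weight share matches the mix, and the whole composition
    is weight-normalized so sum c_i * MW_i / 1000 = 1 exactly.  Fully
    reproducible from ``seed``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix proportions must sum to 1, got {total}")
    unknown = set(class_mix) - set(MACRO_CLASSES)
    if unknown:
        raise ValueError(f"unknown macro classes: {sorted(unknown)}")
    classes = sorted(c for c in class_mix if class_mix[c] > 0)
    if n_components < len(classes):
        raise ValueError(
            f"need at least one component per class: {n_components} < {len(classes)}"
        )
    # largest-remainder allocation of component counts, >= 1 per class
    quotas = {c: max(1, int(n_components * class_mix[c])) for c in classes}
    while sum(quotas.values()) != n_components:
        remainders = {c: n_components * class_mix[c] - quotas[c] for c in classes}
        if sum(quotas.values()) < n_components:
            quotas[max(remainders, key=remainders.get)] += 1
        else:
            eligible = [c for c in classes if quotas[c] > 1]
            quotas[min(eligible, key=lambda c: remainders[c])] -= 1

    rng = np.random.default_rng(seed)
    components = []
    i = 0
    for cls in classes:
        draws = [
            BiomassComponent(
                metabolite_id=f"X{i + k:03d}",
                coefficient=float(10.0 ** rng.uniform(-1.5, -0.5)),
                macro_class=cls,
                molecular_weight=float(rng.uniform(60.0, 800.0)),
                carbon_atoms=int(rng.integers(2, 41)),
            )
            for k in range(quotas[cls])
        ]
        i += quotas[cls]
        # pin the class weight share to the requested mix
        mass = sum(c.coefficient * c.molecular_weight / 1000.0 for c in draws)
        for c in draws:
            c.coefficient *= class_mix[cls] / mass
        components.extend(draws)
    comp = BiomassComposition(id=id, components=components)
    return normalize_by_weight(comp)


def random_toy_spec(rng: np.random.Generator) -> ToySpec:
    """A random feasible toy spec for property sweeps (<= 8 reactions)."""
    n_pathways = int(rng.integers(1, 4))  # 1..3 -> at most 3+3=6..? reactions
    energy_yield = float(rng.uniform(1.0, 5.0))
    uptake = float(rng.uniform(2.0, 20.0))
    # keep the drain below the maximal energy supply so the toy stays feasible
    ngam = float(rng.uniform(0.0, 0.5 * energy_yield * uptake))
    return ToySpec(
        n_pathways=n_pathways,
        energy_yield=energy_yield,
        uptake_bound=uptake,
        ngam=ngam,
        substrate_coeff=float(rng.uniform(0.1, 2.0)),
        energy_coeff=float(rng.uniform(0.1, 2.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_fixtures(outdir) -> list[str]:
    """Emit SBML + composition TSV fixtures (TOY1, TOY2, futile cycle)."""
    from pathlib import Path

    from .biomass import write_composition
    from .model_io import write_sbml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    toy1 = make_toy(ToySpec(), model_id="toy1")
    toy2 = make_toy(ToySpec(n_pathways=2), model_id="toy2")
    futile = make_futile_cycle_model(ToySpec())
    for net, name in ((toy1, "toy1"), (toy2, "toy2"), (futile, "toy_futile")):
        sbml = outdir / f"{name}.xml"
        tsv = outdir / f"{name}_bof.tsv"
        write_sbml(net.model, sbml)
        write_composition(net.composition, tsv)
        written += [str(sbml), str(tsv)]
    return written
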