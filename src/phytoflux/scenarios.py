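"""Model x biomass-composition scenario matrix and dispersion statistics.

Each scenario pairs a stoichiometric model with a biomass objective
function under a shared constraint set (fixed carbon uptake, open N/S/P
sources, a fixed non-growth maintenance drain), is solved in geometric
mode, and contributes one column to a central-reaction flux table.  The
scenario in which a model carries its own composition is its *reference*
scenario.  Dispersion across scenarios is summarized by the per-reaction
standard deviation and its median, grouped either by shared composition
(model axis varies) or shared model (composition axis varies); flux
variability ranges are compared pairwise to decide which central reactions
differ unambiguously between scenarios.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import lp_core
from .biomass import BiomassComposition, GAMRecipe, build_biomass_reaction
from .lp_core import FBAResult, FVARange
from .model_io import DEFAULT_BOUND, MetabolicModel, fix_flux, set_bounds

logger = logging.getLogger(__name__)


@dataclass
class ConstraintSet:
    """The shared simulation constraints for every scenario.

    ``carbon_uptake`` caps the sole carbon/energy source at a fixed rate;
    ``nutrient_exchanges`` (N, S, P sources) are opened to the default
    magnitude bound; ``ngam`` fixes the non-growth maintenance flux;
    ``closed_exchanges`` are shut entirely.  Exported products remain
    freely exchangeable — the constraint set never closes what it is not
    told to close.
    """

    carbon_uptake: tuple[str, float]
    nutrient_exchanges: Sequence[str] = ()
    ngam: tuple[str, float] | None = None
    closed_exchanges: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.ngam is not None and self.ngam[1] < 0:
            raise ValueError("ngam value must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConstraintSet":
        raw = yaml.safe_load(Path(path).read_text())
        ngam = raw.get("ngam")
        return cls(
            carbon_uptake=(raw["carbon_uptake"]["exchange"],
                           float(raw["carbon_uptake"]["value"])),
            nutrient_exchanges=tuple(raw.get("nutrient_exchanges", ())),
            ngam=None if ngam is None else (ngam["reaction"], float(ngam["value"])),
            closed_exchanges=tuple(raw.get("closed_exchanges", ())),
        )


def apply_constraints(model: MetabolicModel, constraints: ConstraintSet) -> MetabolicModel:
    """Return a copy of the model under the scenario constraint set (idempotent)."""
    exchange_id, value = constraints.carbon_uptake
    model.reaction(exchange_id)  # raise early with the missing id
    new = set_bounds(model, exchange_id, 0.0, value)
    for ex in constraints.nutrient_exchanges:
        new = set_bounds(new, ex, 0.0, DEFAULT_BOUND)
    if constraints.ngam is not None:
        rid, v = constraints.ngam
        new = fix_flux(new, rid, v)
    for ex in constraints.closed_exchanges:
        new = set_bounds(new, ex, 0.0, 0.0)
    return new


@dataclass
class ScenarioResult:
    """One cell of the matrix: a solved (model, composition) pair."""

    scenario_id: str
    growth_rate: float
    central_fluxes: dict[str, float]
    full_solution: FBAResult
    fva: list[FVARange] | None = None
    is_reference: bool = False
    status: str = lp_core.OPTIMAL


def run_matrix(
    models: Mapping[str, MetabolicModel],
    bofs: Mapping[str, BiomassComposition],
    constraints: ConstraintSet,
    central_map: Mapping[str, Sequence[str]] | None = None,
    energy: GAMRecipe | Mapping[str, GAMRecipe] | None = None,
    with_fva: bool = False,
    reference_pairs: Mapping[str, str] | None = None,
    geometric: bool = True,
) -> list[ScenarioResult]:
    """Solve every (model, composition) pair and collect scenario results.

    Scenario ids follow the ``"<Model>-<BOF>"`` convention.  A scenario is
    flagged as reference when the composition name equals the model name or
    ``"<model>BOF"`` (override via ``reference_pairs``).  Compositions are
    assumed restricted to the producibility intersection beforehand
    (see :func:`phytoflux.biomass.intersect_components`).  Infeasible pairs
    are recorded with their status; the run continues.
    """
    results = []
    for mname, model in models.items():
        recipe = energy.get(mname) if isinstance(energy, Mapping) else energy
        for bname, comp in bofs.items():
            sid = f"{mname}-{bname}"
            ref = (reference_pairs.get(mname) == bname if reference_pairs
                   else bname in (mname, f"{mname}BOF"))
            scenario_model = build_biomass_reaction(model, comp, energy=recipe)
            scenario_model = apply_constraints(scenario_model, constraints)
            try:
                sol = (lp_core.geometric_fba(scenario_model) if geometric
                       else lp_core.solve_fba(scenario_model))
            except lp_core.GeometricFBAError as exc:
                logger.warning("%s: %s", sid, exc)
                sol = exc.last_result or FBAResult(
                    float("nan"), pd.Series(dtype=float), lp_core.INFEASIBLE,
                    method="geometric_fba", model=scenario_model)
            central = ({} if central_map is None or not sol.optimal
                       else dict(extract_central_fluxes(sol, central_map)))
            fva = None
            if with_fva and sol.optimal:
                fva = lp_core.flux_variability(scenario_model)
            results.append(ScenarioResult(
                scenario_id=sid,
                growth_rate=sol.objective_value if sol.optimal else float("nan"),
                central_fluxes=central,
                full_solution=sol,
                fva=fva,
                is_reference=ref,
                status=sol.status,
            ))
            logger.info("%s: %s growth=%.6g", sid, sol.status,
                        results[-1].growth_rate)
    return results


def extract_central_fluxes(
    result: FBAResult,
    reaction_map: Mapping[str, Sequence[str] | str],
) -> pd.Series:
    """Signed fluxes for labelled central reactions; absent ids give NaN.

    A label maps to one reaction id or a list of ids whose fluxes are
    summed (lumped alternative routes).  A label none of whose ids exist in
    the solved model is reported as NaN — genuinely absent, not zero.
    """
    out = {}
    for label, ids in reaction_map.items():
        if isinstance(ids, str):
            ids = [ids]
        present = [rid for rid in ids if rid in result.fluxes.index]
        out[label] = sum(result.fluxes[rid] for rid in present) if present else np.nan
    return pd.Series(out, dtype=float)


def central_flux_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Labels x scenarios matrix of central fluxes (the flux-map table)."""
    return pd.DataFrame(
        {r.scenario_id: pd.Series(r.central_fluxes, dtype=float) for r in results}
    )


@dataclass
class DispersionSummary:
    """Per-reaction SD across a scenario group and the median over reactions."""

    per_reaction_sd: dict[str, float]
    median_sd: float
    grouping: str
    n_scenarios: int = 0


def dispersion_summary(
    results: Sequence[ScenarioResult],
    grouping: str = "group",
    ddof: int = 1,
) -> DispersionSummary:
    """Sample SD (n-1 denominator by default) of each central flux across scenarios.

    NaN entries are excluded per reaction; a reaction needs at least two
    observed values to contribute.  The median is taken over per-reaction
    SDs and the result is invariant to scenario order.
    """
    if len(results) < 2:
        raise ValueError("dispersion needs at least two scenarios in the group")
    table = central_flux_table(results)
    sds: dict[str, float] = {}
    for label, row in table.iterrows():
        vals = row.dropna()
        if len(vals) >= 2:
            sds[label] = float(np.std(vals, ddof=ddof))
    if not sds:
        raise ValueError("no reaction has two or more observed fluxes")
    return DispersionSummary(
        per_reaction_sd=sds,
        median_sd=float(statistics.median(sds.values())),
        grouping=grouping,
        n_scenarios=len(results),
    )


def fva_label_ranges(
    result: ScenarioResult,
    reaction_map: Mapping[str, Sequence[str] | str],
) -> dict[str, tuple[float, float]]:
    """Collapse a scenario's per-reaction FVA to per-label [min, max] sums."""
    if result.fva is None:
        raise ValueError(f"scenario {result.scenario_id} has no FVA")
    by_id = {fr.reaction_id: fr for fr in result.fva}
    out = {}
    for label, ids in reaction_map.items():
        if isinstance(ids, str):
            ids = [ids]
        present = [by_id[rid] for rid in ids if rid in by_id]
        if present:
            out[label] = (sum(fr.min_flux for fr in present),
                          sum(fr.max_flux for fr in present))
    return out


def fva_overlap_classification(
    fva_by_scenario: Mapping[str, Mapping[str, tuple[float, float]]],
    reaction_labels: Sequence[str] | None = None,
) -> tuple[dict[str, str], dict[str, dict[tuple[str, str], bool]]]:
    """Classify each label's FVA intervals across scenarios as overlapping or not.

    A label is ``"non_overlapping"`` iff its intervals are *pairwise*
    disjoint over all compared scenarios (touching endpoints count as
    overlapping).  Returns the per-label verdicts and, for transparency,
    the per-pair disjointness detail.
    """
    scenario_ids = sorted(fva_by_scenario)
    if len(scenario_ids) < 2:
        raise ValueError("overlap classification needs at least two scenarios")
    if reaction_labels is None:
        reaction_labels = sorted({
            lbl for s in scenario_ids for lbl in fva_by_scenario[s]
        })
    verdicts: dict[str, str] = {}
    detail: dict[str, dict[tuple[str, str], bool]] = {}
    for label in reaction_labels:
        missing = [s for s in scenario_ids if label not in fva_by_scenario[s]]
        if missing:
            raise KeyError(f"label {label!r} missing FVA in scenarios {missing}")
        pairs = {}
        all_disjoint = True
        for i, a in enumerate(scenario_ids):
            for b in scenario_ids[i + 1:]:
                lo_a, hi_a = fva_by_scenario[a][label]
                lo_b, hi_b = fva_by_scenario[b][label]
                disjoint = hi_a < lo_b or hi_b < lo_a
                pairs[(a, b)] = disjoint
                all_disjoint &= disjoint
        verdicts[label] = "non_overlapping" if all_disjoint else "overlapping"
        detail[label] = pairs
    return verdicts, detail


def load_central_map(path: str | Path) -> dict[str, list[str]]:
    """Load a label -> reaction-id(s) central-reaction map from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    return {str(k): ([v] if isinstance(v, str) else list(v)) for k, v in raw.items()}
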