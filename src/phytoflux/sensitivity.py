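"""Single-component biomass perturbations, maintenance scans, correlations.

The robustness questions addressed here: how much does the predicted growth
rate move when one biomass coefficient is varied 30 % up or down with the
rest of the composition held fixed (no re-normalization); how much do the
growth-associated and non-growth-associated maintenance terms contribute;
and how strongly do the growth-rate responses track each component's
fractional coefficient, expressed either in carbon atoms or in weight
(Pearson correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import lp_core
from .biomass import (
    BiomassComposition,
    GAMRecipe,
    build_biomass_reaction,
    carbon_fraction,
    weight_fraction,
)
from .model_io import MetabolicModel
from .scenarios import ConstraintSet, apply_constraints

logger = logging.getLogger(__name__)

#: default perturbation factors: 30 % down and up
DEFAULT_FACTORS = (0.7, 1.3)

MAINTENANCE_LABELS = ("none", "gam_only", "ngam_only", "both")


def perturb_component(
    composition: BiomassComposition,
    component_id: str,
    factor: float,
) -> BiomassComposition:
    """Multiply one component's coefficient by ``factor``; everything else fixed.

    Deliberately no re-normalization and no GAM change: the perturbed
    composition's grams-per-flux-unit drifts away from 1, which is part of
    what the sensitivity records measure.
    """
    if factor <= 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    comp = composition.copy()
    comp.component(component_id).coefficient *= factor
    return comp


@dataclass
class SensitivityRecord:
    """Growth response to one single-component perturbation."""

    component_id: str
    factor: float
    growth_rate: float
    relative_change: float  # percent vs the reference growth
    status: str = lp_core.OPTIMAL

    @property
    def direction(self) -> str:
        return "down" if self.factor < 1 else ("up" if self.factor > 1 else "unchanged")


def _growth(model: MetabolicModel, composition: BiomassComposition,
            constraints: ConstraintSet | None, energy: GAMRecipe | None,
            geometric: bool = False) -> lp_core.FBAResult:
    m = build_biomass_reaction(model, composition, energy=energy)
    if constraints is not None:
        m = apply_constraints(m, constraints)
    return lp_core.geometric_fba(m) if geometric else lp_core.solve_fba(m)


def component_sensitivity(
    model: MetabolicModel,
    composition: BiomassComposition,
    constraints: ConstraintSet | None = None,
    factors: tuple[float, ...] = DEFAULT_FACTORS,
    energy: GAMRecipe | None = None,
) -> list[SensitivityRecord]:
    """One record per (component, factor): growth and % change vs reference.

    The reference growth is computed once from the unperturbed composition;
    each perturbed LP is independent.  Infeasible perturbations are recorded
    with their status (growth NaN) and the scan continues.
    """
    ref = _growth(model, composition, constraints, energy)
    if not ref.optimal:
        raise RuntimeError(f"reference scenario not solvable: {ref.status}")
    g0 = ref.objective_value
    records = []
    for comp_c in composition.components:
        for factor in factors:
            perturbed = perturb_component(composition, comp_c.metabolite_id, factor)
            sol = _growth(model, perturbed, constraints, energy)
            if sol.optimal:
                g = sol.objective_value
                rel = (g - g0) / g0 * 100.0
            else:
                g, rel = float("nan"), float("nan")
            records.append(SensitivityRecord(
                component_id=comp_c.metabolite_id, factor=factor,
                growth_rate=g, relative_change=rel, status=sol.status,
            ))
    return records


@dataclass
class MaintenanceScan:
    """Growth under the four maintenance configurations and % differences.

    ``pct_difference`` maps each configuration to its signed growth
    difference in percent of the full ("both") scenario's growth.  A model
    whose growth ignores maintenance entirely (all differences ~0, as a
    free energy-generating cycle allows) is flagged
    ``maintenance_insensitive``.
    """

    growth: dict[str, float]
    pct_difference: dict[str, float]
    gam_value: float
    ngam_value: float
    maintenance_insensitive: bool
    statuses: dict[str, str]


def maintenance_scan(
    model: MetabolicModel,
    composition: BiomassComposition,
    constraints: ConstraintSet,
    gam_ref: float,
    ngam_ref: float,
    energy: GAMRecipe | None = None,
    geometric: bool = True,
    insensitive_tol: float = 1e-6,
) -> MaintenanceScan:
    """Solve the four maintenance configurations and compare against "both".

    Configurations: no maintenance, GAM only, NGAM only, GAM and NGAM.
    GAM enters through the biomass reaction's ATP term; NGAM through the
    fixed drain named in ``constraints``.  Differences are
    ``(g_variant - g_both) / g_both * 100``.
    """
    if constraints.ngam is None:
        raise ValueError("constraints must name the NGAM reaction to scan")
    ngam_rid = constraints.ngam[0]
    configs = {
        "none": (0.0, 0.0),
        "gam_only": (gam_ref, 0.0),
        "ngam_only": (0.0, ngam_ref),
        "both": (gam_ref, ngam_ref),
    }
    growth: dict[str, float] = {}
    statuses: dict[str, str] = {}
    for label, (gam, ngam) in configs.items():
        comp = composition.copy()
        comp.gam = gam
        cs = ConstraintSet(
            carbon_uptake=constraints.carbon_uptake,
            nutrient_exchanges=constraints.nutrient_exchanges,
            ngam=(ngam_rid, ngam),
            closed_exchanges=constraints.closed_exchanges,
        )
        sol = _growth(model, comp, cs, energy, geometric=geometric)
        statuses[label] = sol.status
        growth[label] = sol.objective_value if sol.optimal else float("nan")
        logger.info("maintenance %s (gam=%g, ngam=%g): %s growth=%.6g",
                    label, gam, ngam, sol.status, growth[label])
    if statuses["both"] != lp_core.OPTIMAL:
        raise RuntimeError(f"'both' maintenance scenario not solvable: {statuses['both']}")
    g_both = growth["both"]
    pct = {label: (g - g_both) / g_both * 100.0 for label, g in growth.items()}
    insensitive = all(
        abs(p) <= insensitive_tol for lbl, p in pct.items() if np.isfinite(p)
    )
    return MaintenanceScan(
        growth=growth, pct_difference=pct,
        gam_value=gam_ref, ngam_value=ngam_ref,
        maintenance_insensitive=insensitive, statuses=statuses,
    )


@dataclass
class CorrelationResult:
    """Pearson correlation between growth response and coefficient fraction."""

    r: float | None
    n: int
    basis: str
    signed: bool
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.r is not None


def growth_coefficient_correlation(
    records: list[SensitivityRecord],
    composition: BiomassComposition,
    basis: str = "carbon",
    signed: bool = False,
) -> CorrelationResult:
    """Pearson r between growth-rate changes and fractional coefficients.

    ``basis`` selects the component's fractional coefficient in carbon-atom
    terms (:func:`carbon_fraction`) or weight terms (:func:`weight_fraction`).
    By default the magnitude ``|relative_change|`` is used and up/down
    records are pooled; pass ``signed=True`` for the signed variant.  Zero
    variance on either axis makes the correlation undefined, which is
    reported as such rather than coerced to 0.
    """
    if basis == "carbon":
        fractions = carbon_fraction(composition)
    elif basis == "weight":
        fractions = weight_fraction(composition)
    else:
        raise ValueError(f"unknown basis {basis!r} (expected 'carbon' or 'weight')")
    usable = [r for r in records if np.isfinite(r.relative_change)]
    if len(usable) < 3:
        return CorrelationResult(None, len(usable), basis, signed,
                                 undefined_reason="fewer than 3 finite records")
    x = np.array([fractions[r.component_id] for r in usable])
    y = np.array([r.relative_change if signed else abs(r.relative_change)
                  for r in usable])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(None, len(usable), basis, signed,
                                 undefined_reason="zero variance on one axis")
    r, _ = stats.pearsonr(x, y)
    return CorrelationResult(float(r), len(usable), basis, signed)


def records_to_frame(records: list[SensitivityRecord]):
    """Tidy DataFrame (component, direction, factor, growth, pct_change)."""
    import pandas as pd

    return pd.DataFrame(
        [{"component": r.component_id, "direction": r.direction,
          "factor": r.factor, "growth_rate": r.growth_rate,
          "pct_change": r.relative_change, "status": r.status}
         for r in records]
    )
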