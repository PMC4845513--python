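"""Constraint-based solvers: FBA, flux variability and geometric FBA.

All three solve linear programs over the steady-state flux cone

    S v = 0,    lb <= v <= ub,

with the biomass (objective) reaction maximized.  Plain FBA returns *an*
optimal vertex and makes no uniqueness claim about individual fluxes: on a
degenerate optimum, only the objective value is meaningful.  Flux
variability analysis (FVA) pins the objective at its optimum and reports,
per reaction, the attainable [min, max] flux over the optimal face.
Geometric FBA resolves the degeneracy by iterating FVA with an L1
projection onto range midpoints until every range collapses, producing a
unique central flux distribution — the mode the study's simulations use
throughout.

The LP backend is scipy's HiGHS solver behind a single helper
(:func:`solve_lp`); it is deterministic given identical input ordering.

Two surfaces are offered: the functional API (:func:`solve_fba`,
:func:`flux_variability`, :func:`geometric_fba`) and an estimator-style
wrapper (:class:`FluxBalanceModel` whose :meth:`~FluxBalanceModel.fit`
returns an :class:`FBAResult` with ``summary()`` and ``fva()``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

#: componentwise feasibility tolerance on |S v| and bound violation
FEAS_TOL = 1e-7
#: half-width of the equality window used to pin the objective at its optimum
PIN_TOL = 1e-9

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


class GeometricFBAError(RuntimeError):
    """Geometric FBA failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_result: "FBAResult | None", n_unconverged: int):
        super().__init__(message)
        self.last_result = last_result
        self.n_unconverged = n_unconverged


@dataclass
class FVARange:
    """Attainable flux interval for one reaction at the fixed optimum."""

    reaction_id: str
    min_flux: float
    max_flux: float

    @property
    def width(self) -> float:
        return self.max_flux - self.min_flux

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min_flux + self.max_flux)


def solve_lp(
    c: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    sense: str = "min",
):
    """Solve min/max ``c @ v`` s.t. ``S v = 0``, ``lb <= v <= ub`` (+ optional A_ub v <= b_ub).

    This is the solver contract every routine in this module goes through;
    the backend is scipy's HiGHS and is deterministic for a fixed input
    ordering.  Returns the scipy result with ``status`` in {0, 2, 3}.
    """
    if sense not in ("min", "max"):
        raise ValueError("sense must be 'min' or 'max'")
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if sense == "max" and res.status == 0:
        res.fun = -res.fun
    return res


@dataclass
class FBAResult:
    """A flux distribution with its objective value and solver status.

    ``fluxes`` is a reaction-id-indexed :class:`pandas.Series`; for
    ``status != "optimal"`` it is empty and ``objective_value`` is NaN.
    """

    objective_value: float
    fluxes: pd.Series
    status: str
    method: str = "fba"
    model: MetabolicModel | None = field(default=None, repr=False)
    n_iterations: int = 0

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])

    def fva(self, optimum_fraction: float = 1.0) -> pd.DataFrame:
        """FVA around this solution's objective; columns ``min_flux``/``max_flux``."""
        if self.model is None:
            raise ValueError("result carries no model reference")
        ranges = flux_variability(self.model, optimum_fraction=optimum_fraction)
        return pd.DataFrame(
            {"min_flux": [r.min_flux for r in ranges],
             "max_flux": [r.max_flux for r in ranges]},
            index=[r.reaction_id for r in ranges],
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable summary table of the solve."""
        lines = [
            f"{'Flux balance analysis':^58}",
            "=" * 58,
            f"method:            {self.method}",
            f"status:            {self.status}",
            f"objective reaction: {self.model.objective_id if self.model else '?'}",
            f"objective value:   {self.objective_value:.6g}",
            f"reactions:         {len(self.fluxes)}",
        ]
        if self.optimal and len(self.fluxes):
            lines.append("-" * 58)
            lines.append(f"{'largest |flux|':<40}{'value':>18}")
            order = self.fluxes.abs().sort_values(ascending=False).index[:top]
            for rid in order:
                lines.append(f"{rid:<40}{self.fluxes[rid]:>18.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)


def _result(model, rxn_ids, res, method, n_iter=0) -> FBAResult:
    status = _STATUS.get(res.status, INFEASIBLE)
    if status == OPTIMAL:
        fluxes = pd.Series(res.x, index=rxn_ids, dtype=float)
        obj = float(fluxes[model.objective_id])
    else:
        fluxes = pd.Series(dtype=float)
        obj = float("nan")
    return FBAResult(objective_value=obj, fluxes=fluxes, status=status,
                     method=method, model=model, n_iterations=n_iter)


def solve_fba(model: MetabolicModel) -> FBAResult:
    """Maximize the objective reaction's flux subject to ``S v = 0`` and bounds.

    Infeasibility and unboundedness are reported through ``status``, not
    raised; a missing objective is a caller error and raises.
    """
    if model.objective_id is None:
        raise ValueError("model has no objective reaction")
    S, _, rxn_ids, lb, ub = model.to_arrays()
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective_id)] = 1.0
    res = solve_lp(c, S, lb, ub, sense="max")
    out = _result(model, rxn_ids, res, "fba")
    logger.debug("solve_fba %s: %s obj=%g", model.id, out.status, out.objective_value)
    return out


def _fva_on_arrays(S, lb, ub, indices, rxn_ids) -> list[FVARange]:
    n = S.shape[1]
    out = []
    for j in indices:
        c = np.zeros(n)
        c[j] = 1.0
        lo = solve_lp(c, S, lb, ub, sense="min")
        hi = solve_lp(c, S, lb, ub, sense="max")
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem for {rxn_ids[j]} not optimal "
                               f"(status {lo.status}/{hi.status})")
        out.append(FVARange(rxn_ids[j], float(lo.fun), float(hi.fun)))
    return out


def flux_ranges(model: MetabolicModel, reactions: Sequence[str] | None = None) -> list[FVARange]:
    """Per-reaction [min, max] flux with *no* objective constraint.

    Used for blocked-reaction detection; plain variability of the flux cone.
    """
    S, _, rxn_ids, lb, ub = model.to_arrays()
    idx = range(len(rxn_ids)) if reactions is None else [rxn_ids.index(r) for r in reactions]
    return _fva_on_arrays(S, lb, ub, idx, rxn_ids)


def flux_variability(
    model: MetabolicModel,
    optimum_fraction: float = 1.0,
    reactions: Sequence[str] | None = None,
) -> list[FVARange]:
    """FVA: per-reaction flux range while holding the objective at its optimum.

    With ``optimum_fraction == 1`` the objective is pinned as an equality
    (within ``PIN_TOL``), so every range lies on the optimal face; with a
    fraction in (0, 1) the objective is only required to reach that fraction
    of the optimum; 0 removes the constraint entirely.  Solves 2 LPs per
    reaction.
    """
    if not 0 <= optimum_fraction <= 1:
        raise ValueError("optimum_fraction must be in [0, 1]")
    base = solve_fba(model)
    if not base.optimal:
        raise RuntimeError(f"FVA requires an optimal base solution, got {base.status}")
    S, _, rxn_ids, lb, ub = model.to_arrays()
    jobj = rxn_ids.index(model.objective_id)
    opt = base.objective_value
    lb, ub = lb.copy(), ub.copy()
    if optimum_fraction == 1.0:
        lb[jobj] = max(lb[jobj], opt - PIN_TOL)
        ub[jobj] = min(ub[jobj], opt + PIN_TOL)
    elif optimum_fraction > 0:
        lb[jobj] = max(lb[jobj], optimum_fraction * opt)
    idx = range(len(rxn_ids)) if reactions is None else [rxn_ids.index(r) for r in reactions]
    return _fva_on_arrays(S, lb, ub, idx, rxn_ids)


def geometric_fba(model: MetabolicModel, tol: float = 1e-6, max_iter: int = 50) -> FBAResult:
    """Unique central flux distribution at the FBA optimum.

    The objective is pinned at the plain-FBA optimum, then iteratively:

    1. compute FVA ranges over the current optimal face;
    2. solve an LP minimizing the total L1 deviation of v from the range
       midpoints (auxiliary-variable formulation);
    3. shrink every unconverged reaction's bounds to the middle half of its
       current range ([lo + w/4, hi - w/4]); reactions whose range width
       fell below ``tol`` keep their collapsed range.

    The iteration stops as soon as every flux lies within ``tol`` of its
    range midpoint (for a unique optimum that is immediate; on a symmetric
    degenerate face the first L1 projection already lands on the center).
    Each shrink halves the remaining range widths, so at most
    ~log2(initial width / tol) iterations are needed.  The result depends
    only on the geometry of the optimal face, not on reaction ordering
    (within ``tol``), and its objective equals the plain FBA optimum.
    """
    base = solve_fba(model)
    if not base.optimal:
        return FBAResult(float("nan"), pd.Series(dtype=float), base.status,
                         method="geometric_fba", model=model)

    S, _, rxn_ids, lb, ub = model.to_arrays()
    n = len(rxn_ids)
    jobj = rxn_ids.index(model.objective_id)
    opt = base.objective_value
    lb, ub = lb.copy(), ub.copy()
    lb[jobj] = max(lb[jobj], opt - PIN_TOL)
    ub[jobj] = min(ub[jobj], opt + PIN_TOL)

    last_result = None
    for iteration in range(1, max_iter + 1):
        try:
            ranges = _fva_on_arrays(S, lb, ub, range(n), rxn_ids)
        except RuntimeError as exc:
            raise GeometricFBAError(
                f"FVA on the restricted face failed at iteration {iteration}: {exc}",
                last_result, n) from None
        mids = np.array([r.midpoint for r in ranges])
        widths = np.array([r.width for r in ranges])
        lo = np.array([r.min_flux for r in ranges])
        hi = np.array([r.max_flux for r in ranges])

        # L1 projection onto the midpoint vector:
        # min sum d  s.t.  -d_i <= v_i - mid_i <= d_i, S v = 0, bounds
        c = np.concatenate([np.zeros(n), np.ones(n)])
        S_ext = np.hstack([S, np.zeros((S.shape[0], n))])
        A_ub = np.zeros((2 * n, 2 * n))
        b_ub = np.zeros(2 * n)
        for i in range(n):
            A_ub[2 * i, i] = 1.0
            A_ub[2 * i, n + i] = -1.0
            b_ub[2 * i] = mids[i]
            A_ub[2 * i + 1, i] = -1.0
            A_ub[2 * i + 1, n + i] = -1.0
            b_ub[2 * i + 1] = -mids[i]
        lb_ext = np.concatenate([lb, np.zeros(n)])
        ub_ext = np.concatenate([ub, np.full(n, np.inf)])
        res = solve_lp(c, S_ext, lb_ext, ub_ext, A_ub=A_ub, b_ub=b_ub, sense="min")
        if res.status != 0:
            raise GeometricFBAError(
                f"L1 centering LP returned status {res.status} at iteration {iteration}",
                last_result, int((widths >= tol).sum()))
        v = res.x[:n].copy()
        last_result = _resultify(model, rxn_ids, v, opt, iteration)
        deviation = np.abs(v - mids).max()
        logger.debug("geometric_fba iter %d: max width %.3g, max deviation %.3g",
                     iteration, widths.max(), deviation)
        if deviation < tol or widths.max() < tol:
            return last_result

        # shrink unconverged ranges to their middle half; converged ones
        # keep their (collapsed) range so later LPs hold them in place
        wide = widths >= tol
        lb[wide] = lo[wide] + widths[wide] / 4.0
        ub[wide] = hi[wide] - widths[wide] / 4.0
        lb[~wide] = lo[~wide]
        ub[~wide] = hi[~wide]

    raise GeometricFBAError(
        f"geometric FBA did not converge in {max_iter} iterations "
        f"({int((widths >= tol).sum())} reactions unconverged)",
        last_result, int((widths >= tol).sum()))


def _resultify(model, rxn_ids, v, opt, n_iter, final=False) -> FBAResult:
    fluxes = pd.Series(v, index=rxn_ids, dtype=float)
    return FBAResult(objective_value=float(opt), fluxes=fluxes, status=OPTIMAL,
                     method="geometric_fba", model=model, n_iterations=n_iter)


class FluxBalanceModel:
    """Estimator-style wrapper: build from a model, ``fit`` to get results.

    Examples
    --------
    >>> fbm = FluxBalanceModel(toy.model)
    >>> res = fbm.fit(method="geometric")
    >>> res.objective_value
    11.2
    """

    def __init__(self, model: MetabolicModel, constraints=None):
        if constraints is not None:
            from .scenarios import apply_constraints

            model = apply_constraints(model, constraints)
        self.model = model

    @classmethod
    def from_sbml(cls, path, constraints=None, **parse_kwargs) -> "FluxBalanceModel":
        from .model_io import parse_sbml

        return cls(parse_sbml(path, **parse_kwargs), constraints=constraints)

    def fit(self, method: str = "geometric", tol: float = 1e-6, max_iter: int = 50) -> FBAResult:
        """Solve the model; ``method`` is ``"fba"`` or ``"geometric"``."""
        if method == "fba":
            return solve_fba(self.model)
        if method == "geometric":
            return geometric_fba(self.model, tol=tol, max_iter=max_iter)
        raise ValueError(f"unknown method {method!r}")

    def fva(self, optimum_fraction: float = 1.0) -> pd.DataFrame:
        ranges = flux_variability(self.model, optimum_fraction=optimum_fraction)
        return pd.DataFrame(
            {"min_flux": [r.min_flux for r in ranges],
             "max_flux": [r.max_flux for r in ranges]},
            index=[r.reaction_id for r in ranges],
        )


def check_steady_state(model: MetabolicModel, result: FBAResult, tol: float = FEAS_TOL) -> float:
    """Return max |S v| for a solution (diagnostic; small for valid solves)."""
    S, _, rxn_ids, _, _ = model.to_arrays()
    v = result.fluxes.reindex(rxn_ids).to_numpy()
    return float(np.abs(S @ v).max()) if len(v) else float("nan")
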