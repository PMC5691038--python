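"""Linear-programming engine: FBA, FVA, flux-sum, scans, flux sampling.

Flux balance analysis solves

    max  Z = sum_j c_j v_j
    s.t. sum_j S_ij v_j = 0   for every metabolite i
         v_min_j <= v_j <= v_max_j

with scipy's HiGHS solver.  Alternate optima are resolved, where a
deterministic answer matters, by a parsimonious tie-break: among flux
vectors within a relative 1e-9 of the optimum, return the one minimising
total absolute flux (an LP after splitting each flux into positive and
negative parts).

Tolerances: LP feasibility 1e-9; reported fluxes are rounded at 1e-6 so
true zeros survive yield-ratio arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .core import MetabolicModel, Reaction, build_stoichiometric_matrix
from .gpr import evaluate_gpr

FEAS_TOL = 1e-9
FLUX_ROUND = 1e-6


class InfeasibleModelError(RuntimeError):
    """Raised when an operation requires an optimal solution but the LP
    is infeasible or unbounded."""


@dataclass
class FluxSolution:
    """Result of one FBA solve."""

    objective_value: float | None
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a stated fraction of the optimum."""

    fraction_of_optimum: float
    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


@dataclass
class FluxSampleSet:
    """Uniform samples of the steady-state flux polytope."""

    reaction_ids: list[str]
    points: np.ndarray  # n_samples x n_reactions
    n_points: int
    thinning_steps: int
    seed: int

    def column(self, rxn_id: str) -> np.ndarray:
        return self.points[:, self.reaction_ids.index(rxn_id)]

    def mean(self) -> dict[str, float]:
        m = self.points.mean(axis=0)
        return dict(zip(self.reaction_ids, m))


def _clean(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).copy()
    v[np.abs(v) < FLUX_ROUND] = 0.0
    return v


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                   bounds=bounds, method="highs",
                   options={"primal_feasibility_tolerance": FEAS_TOL,
                            "dual_feasibility_tolerance": FEAS_TOL})


def _lp_parts(model: MetabolicModel):
    S = build_stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, bounds


def _objective_vector(model: MetabolicModel, objective_reaction_id: str | None) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    if objective_reaction_id is not None:
        c[model.reaction_index(objective_reaction_id)] = 1.0
    else:
        for j, r in enumerate(model.reactions):
            c[j] = r.objective_coefficient
        if not np.any(c):
            raise ValueError("no objective: all c_j are zero and no objective reaction given")
    return c


def fba(model: MetabolicModel, objective_reaction_id: str | None = None,
        direction: str = "max") -> FluxSolution:
    """Solve the flux-balance LP; status is reported faithfully."""
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    S, bounds = _lp_parts(model)
    c = _objective_vector(model, objective_reaction_id)
    sign = -1.0 if direction == "max" else 1.0
    res = _solve_lp(sign * c, S, np.zeros(S.shape[0]), bounds)
    if res.status == 2:
        return FluxSolution(None, {}, "infeasible")
    if res.status == 3:
        return FluxSolution(None, {}, "unbounded")
    if not res.success:  # pragma: no cover - solver hiccup
        return FluxSolution(None, {}, "infeasible")
    v = _clean(res.x)
    return FluxSolution(float(c @ v), dict(zip(model.reaction_ids, v)), "optimal")


def parsimonious_tiebreak(model: MetabolicModel, objective_reaction_id: str | None = None,
                          direction: str = "max") -> FluxSolution:
    """FBA with deterministic resolution of alternate optima.

    Among solutions achieving the optimum (to relative 1e-9), minimise
    sum_j |v_j| via flux splitting.  Deterministic for a fixed reaction
    order.
    """
    base = fba(model, objective_reaction_id, direction)
    if not base.optimal:
        return base
    S, bounds = _lp_parts(model)
    n = len(model.reactions)
    c = _objective_vector(model, objective_reaction_id)
    zstar = base.objective_value
    # variables: v (n), t (n) with t >= |v|; minimise sum t
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
    b_eq = np.zeros(S.shape[0])
    I = np.eye(n)
    rows = [np.hstack([I, -I]), np.hstack([-I, -I])]
    rhs = [np.zeros(n), np.zeros(n)]
    slack = 1e-9 * max(1.0, abs(zstar))
    if direction == "max":
        rows.append(np.hstack([-c[None, :], np.zeros((1, n))]))
        rhs.append(np.array([-(zstar - slack)]))
    else:
        rows.append(np.hstack([c[None, :], np.zeros((1, n))]))
        rhs.append(np.array([zstar + slack]))
    A_ub = np.vstack(rows)
    b_ub = np.concatenate(rhs)
    var_bounds = bounds + [(0, None)] * n
    res = _solve_lp(cost, A_eq, b_eq, var_bounds, A_ub, b_ub)
    if not res.success:  # fall back to the plain solution
        return base
    v = _clean(res.x[:n])
    return FluxSolution(float(c @ v), dict(zip(model.reaction_ids, v)), "optimal")


def fva(model: MetabolicModel, fraction_of_optimum: float = 1.0,
        objective_reaction_id: str | None = None,
        reactions: list[str] | None = None) -> FVAResult:
    """Flux variability: per-reaction min/max subject to Z >= fraction * Z*."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    S, bounds = _lp_parts(model)
    b_eq = np.zeros(S.shape[0])
    A_ub = None
    b_ub = None
    if fraction_of_optimum > 0.0:
        c = _objective_vector(model, objective_reaction_id)
        base = fba(model, objective_reaction_id, "max")
        if not base.optimal:
            raise InfeasibleModelError(f"FVA reference FBA is {base.status}")
        zstar = base.objective_value
        target = fraction_of_optimum * zstar
        # small slack keeps the optimal vertex inside the constraint set
        target -= 1e-9 * max(1.0, abs(zstar))
        A_ub = -c[None, :]
        b_ub = np.array([-target])
    todo = reactions if reactions is not None else model.reaction_ids
    ranges: dict[str, tuple[float, float]] = {}
    for rxn_id in todo:
        j = model.reaction_index(rxn_id)
        obj = np.zeros(len(model.reactions))
        obj[j] = 1.0
        lo = _solve_lp(obj, S, b_eq, bounds, A_ub, b_ub)
        hi = _solve_lp(-obj, S, b_eq, bounds, A_ub, b_ub)
        if not (lo.success and hi.success):
            raise InfeasibleModelError(f"FVA subproblem for {rxn_id} failed")
        vmin, vmax = float(lo.x[j]), float(hi.x[j])
        if abs(vmin) < FLUX_ROUND:
            vmin = 0.0
        if abs(vmax) < FLUX_ROUND:
            vmax = 0.0
        ranges[rxn_id] = (min(vmin, vmax), max(vmin, vmax))
    return FVAResult(fraction_of_optimum, ranges)


def find_blocked_reactions(model: MetabolicModel) -> list[str]:
    """Reactions unable to carry flux under any steady state (FVA at
    fraction 0 with every exchange opened)."""
    if not model.exchanges:
        raise ValueError("model has no exchange reactions")
    m = model.copy()
    for r in m.reactions:
        if r.is_exchange:
            r.lower_bound = min(r.lower_bound, -1000.0)
            r.upper_bound = max(r.upper_bound, 1000.0)
    probe = fba(m, m.reaction_ids[0], "max")
    if probe.status == "infeasible":  # pragma: no cover - all-open model
        raise InfeasibleModelError("model infeasible with all exchanges open")
    result = fva(m, fraction_of_optimum=0.0)
    return [rid for rid, (lo, hi) in result.ranges.items()
            if abs(lo) < FLUX_ROUND and abs(hi) < FLUX_ROUND]


def flux_sum(solution: FluxSolution, metabolite_id: str, model: MetabolicModel) -> float:
    """Metabolite turnover: half the sum of |S_ij v_j| over reactions j.

    For a mass-balanced metabolite this equals both its total production
    and total consumption rate.
    """
    if not solution.optimal:
        raise InfeasibleModelError("flux_sum requires an optimal solution")
    model.metabolite(metabolite_id)  # raises KeyError if unknown
    total = 0.0
    for rxn in model.reactions:
        coef = rxn.stoichiometry.get(metabolite_id)
        if coef:
            total += abs(coef * solution.fluxes[rxn.id])
    return 0.5 * total


def knockout_model(model: MetabolicModel, deleted_genes: set[str]) -> MetabolicModel:
    """Copy of the model with reactions whose GPR evaluates false forced to
    zero flux."""
    m = model.copy()
    for r in m.reactions:
        if r.gpr is not None and not evaluate_gpr(r.gpr, deleted_genes):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return m


def single_gene_deletion_scan(model: MetabolicModel,
                              threshold: float = 0.9) -> dict[str, tuple[float, bool]]:
    """Per-gene growth after deletion; essential iff growth falls by more
    than ``threshold`` (default: the >90 % reduction rule)."""
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    wt = fba(model, model.biomass_reaction_id, "max")
    if not wt.optimal:
        raise InfeasibleModelError("wild-type FBA not optimal")
    out: dict[str, tuple[float, bool]] = {}
    for gene in sorted(model.genes):
        ko = fba(knockout_model(model, {gene}), model.biomass_reaction_id, "max")
        growth = ko.objective_value if ko.optimal else 0.0
        out[gene] = (growth, growth < (1.0 - threshold) * wt.objective_value)
    return out


def nutrient_omission_scan(model: MetabolicModel, exchange_ids: list[str],
                           threshold: float = 0.9) -> dict[str, tuple[float, bool]]:
    """Close each listed exchange's uptake individually; auxotroph iff
    growth drops by more than ``threshold`` relative to the reference."""
    missing = [e for e in exchange_ids if not model.has_reaction(e)]
    if missing:
        raise KeyError(f"unknown exchange reaction(s): {missing}")
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    ref = fba(model, model.biomass_reaction_id, "max")
    if not ref.optimal:
        raise InfeasibleModelError("reference FBA not optimal")
    out: dict[str, tuple[float, bool]] = {}
    for ex in exchange_ids:
        m = model.copy()
        r = m.reaction(ex)
        r.lower_bound = max(r.lower_bound, 0.0)  # no uptake
        sol = fba(m, m.biomass_reaction_id, "max")
        growth = sol.objective_value if sol.optimal else 0.0
        out[ex] = (growth, growth < (1.0 - threshold) * ref.objective_value)
    return out


# ---------------------------------------------------------------------------
# uniform flux sampling (artificial-centering hit-and-run)
# ---------------------------------------------------------------------------

def _warmup_points(model: MetabolicModel, cap: float) -> tuple[np.ndarray, list[tuple[float, float]]]:
    m = model.copy()
    for r in m.reactions:
        r.lower_bound = max(r.lower_bound, -cap)
        r.upper_bound = min(r.upper_bound, cap)
    S, bounds = _lp_parts(m)
    b_eq = np.zeros(S.shape[0])
    pts = []
    for j in range(len(m.reactions)):
        obj = np.zeros(len(m.reactions))
        obj[j] = 1.0
        for sign in (1.0, -1.0):
            res = _solve_lp(sign * obj, S, b_eq, bounds)
            if res.status == 2:
                raise InfeasibleModelError("sampling polytope is empty")
            if not res.success:
                raise InfeasibleModelError("warm-up LP failed (unbounded polytope?)")
            pts.append(res.x)
    return np.array(pts), bounds


def sample_fluxes(model: MetabolicModel, n_points: int = 5000, thinning: int = 500,
                  seed: int = 0, bound_cap: float = 1000.0) -> FluxSampleSet:
    """Uniform sampling of the flux polytope by artificial-centering
    hit-and-run.

    5000 points with 500 steps of thinning between kept points is the
    convergence setting used for the regulation Z-scores.  Open bounds are
    capped at ``bound_cap`` so the polytope is bounded.  Every kept point
    satisfies S v = 0 (chords stay inside the null-space affine set) and
    the bounds to 1e-6.
    """
    rng = np.random.default_rng(seed)
    warm, bounds = _warmup_points(model, bound_cap)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    n = warm.shape[1]
    center = warm.mean(axis=0)
    x = center.copy()
    stored = [w.copy() for w in warm]
    n_warmup = 10 * n
    kept = np.empty((n_points, n), dtype=float)
    total_steps = n_warmup + n_points * max(1, thinning)
    k = 0
    step_count = 0
    eps = 1e-12
    while k < n_points:
        ref = stored[rng.integers(len(stored))]
        d = ref - center
        norm = np.linalg.norm(d)
        if norm < eps:
            continue
        d /= norm
        # largest step interval keeping lb <= x + a*d <= ub
        with np.errstate(divide="ignore", invalid="ignore"):
            a_lo = np.where(np.abs(d) > eps, (lb - x) / d, -np.inf)
            a_hi = np.where(np.abs(d) > eps, (ub - x) / d, np.inf)
        lo = np.minimum(a_lo, a_hi).max(initial=-np.inf)
        hi = np.maximum(a_lo, a_hi).min(initial=np.inf)
        lo = max(lo, -1e6)
        hi = min(hi, 1e6)
        if hi - lo < eps:
            step_count += 1
            continue
        a = rng.uniform(lo, hi)
        # no clipping: it would leave the S v = 0 affine subspace; the
        # chord interval already respects the box to float precision
        x = x + a * d
        step_count += 1
        center += (x - center) / (len(stored) + 1.0)
        if step_count > n_warmup and (step_count - n_warmup) % max(1, thinning) == 0:
            kept[k] = x
            k += 1
        if step_count > total_steps * 50:  # pragma: no cover - safety valve
            raise RuntimeError("hit-and-run failed to make progress")
    return FluxSampleSet(model.reaction_ids, kept, n_points, thinning, seed)
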