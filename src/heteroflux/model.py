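"""Model/Results surface over the flux-balance engine.

`FluxBalanceModel` wraps a :class:`~heteroflux.core.MetabolicModel` plus
an objective; ``fit()`` solves the LP (parsimonious by default) and
returns a :class:`FluxResults` carrying the flux estimates, their FVA
interval "uncertainties", steady-state diagnostics and a ``summary()``
table, in the spirit of statsmodels' Model/Results pairs.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .core import MetabolicModel, build_stoichiometric_matrix
from .fba import (FluxSolution, InfeasibleModelError, fba, flux_sum, fva,
                  parsimonious_tiebreak, sample_fluxes)


class FluxBalanceModel:
    """Flux-balance analysis model for a stoichiometric network.

    Parameters
    ----------
    model : MetabolicModel
        The stoichiometric network (data).
    objective : str, optional
        Reaction id to optimize; defaults to the model's declared
        objective (biomass).
    direction : {'max', 'min'}
    """

    def __init__(self, model: MetabolicModel, objective: str | None = None,
                 direction: str = "max"):
        self.model = model
        self.objective = objective or model.biomass_reaction_id
        self.direction = direction

    @classmethod
    def from_dataframe(cls, reactions: pd.DataFrame,
                       metabolites: pd.DataFrame | None = None,
                       objective: str | None = None) -> "FluxBalanceModel":
        """Build from the tabular dialect held in DataFrames
        (columns: id, equation, lb, ub, gpr, subsystem)."""
        from .core import Metabolite, Reaction
        from .io_tabular import parse_equation
        m = MetabolicModel()
        if metabolites is not None:
            from .core import parse_formula
            for _, row in metabolites.iterrows():
                formula = row.get("formula")
                m.add_metabolite(Metabolite(
                    id=row["id"],
                    formula=parse_formula(formula) if isinstance(formula, str)
                    and formula else None,
                    charge=int(row["charge"]) if "charge" in row
                    and pd.notna(row.get("charge")) else None,
                    compartment=row.get("compartment", "c") or "c"))
        for _, row in reactions.iterrows():
            stoich, reversible = parse_equation(row["equation"])
            for met in stoich:
                if met not in m._met_index:
                    m.add_metabolite(Metabolite(id=met))
            lb = row.get("lb")
            ub = row.get("ub")
            m.add_reaction(Reaction(
                id=row["id"], stoichiometry=stoich,
                lower_bound=float(lb) if pd.notna(lb) else
                (-1000.0 if reversible else 0.0),
                upper_bound=float(ub) if pd.notna(ub) else 1000.0,
                gpr=row.get("gpr") or None,
                subsystem=row.get("subsystem", "") or ""))
        return cls(m, objective=objective)

    def fit(self, parsimonious: bool = True,
            compute_fva: bool = False,
            fva_fraction: float = 1.0 - 1e-9) -> "FluxResults":
        solve = parsimonious_tiebreak if parsimonious else fba
        sol = solve(self.model, self.objective, self.direction)
        if not sol.optimal:
            raise InfeasibleModelError(
                f"optimization of {self.objective} is {sol.status}")
        intervals = None
        if compute_fva:
            intervals = fva(self.model, fraction_of_optimum=fva_fraction,
                            objective_reaction_id=self.objective).ranges
        return FluxResults(self, sol, intervals)

    def sample(self, n_points: int = 5000, thinning: int = 500, seed: int = 0):
        """Uniformly sample the feasible flux polytope."""
        return sample_fluxes(self.model, n_points=n_points,
                             thinning=thinning, seed=seed)


class FluxResults:
    """Fitted flux state: point estimates, FVA intervals, diagnostics."""

    def __init__(self, model: FluxBalanceModel, solution: FluxSolution,
                 intervals: dict[str, tuple[float, float]] | None = None):
        self.model = model
        self.solution = solution
        self.objective_value = solution.objective_value
        self.fluxes = pd.Series(solution.fluxes, name="flux")
        self.intervals = intervals

    def flux_range(self, fraction_of_optimum: float = 1.0 - 1e-9
                   ) -> pd.DataFrame:
        """FVA intervals (the flux uncertainty under near-optimality)."""
        ranges = fva(self.model.model, fraction_of_optimum=fraction_of_optimum,
                     objective_reaction_id=self.model.objective).ranges
        return pd.DataFrame(ranges, index=["min_flux", "max_flux"]).T

    def flux_sum(self, metabolite_id: str) -> float:
        """Turnover rate of a metabolite at the fitted state."""
        return flux_sum(self.solution, metabolite_id, self.model.model)

    @property
    def steady_state_residual(self) -> float:
        """‖S v‖∞ at the fitted fluxes (should be ~1e-9)."""
        S = build_stoichiometric_matrix(self.model.model)
        v = np.array([self.solution.fluxes[r] for r in
                      self.model.model.reaction_ids])
        return float(np.max(np.abs(S @ v), initial=0.0))

    def summary(self, top: int = 15) -> str:
        m = self.model.model
        counts = m.reaction_counts()
        buf = io.StringIO()
        w = buf.write
        w("Flux balance analysis results\n")
        w("=============================\n")
        w(f"Model:               {m.id}\n")
        w(f"Metabolites:         {len(m.metabolites)}\n")
        w(f"Reactions:           {counts['total']} "
          f"({counts['exchange']} exchanges)\n")
        w(f"Genes:               {len(m.genes)}\n")
        w(f"Objective:           {self.model.direction} {self.model.objective}\n")
        w(f"Objective value:     {self.objective_value:.6g}\n")
        w(f"Steady-state resid.: {self.steady_state_residual:.2e}\n")
        active = self.fluxes[self.fluxes.abs() > 1e-9]
        w(f"Active reactions:    {len(active)} / {counts['total']}\n\n")
        w(f"Largest fluxes (top {top}):\n")
        sel = active.reindex(active.abs().sort_values(ascending=False).index)
        for rxn_id, v in sel.head(top).items():
            line = f"  {rxn_id:<16s} {v:>12.4f}"
            if self.intervals and rxn_id in self.intervals:
                lo, hi = self.intervals[rxn_id]
                line += f"   [{lo:.4f}, {hi:.4f}]"
            w(line + "\n")
        return buf.getvalue()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"flux": self.fluxes})
        if self.intervals:
            df["min_flux"] = pd.Series({k: v[0] for k, v in self.intervals.items()})
            df["max_flux"] = pd.Series({k: v[1] for k, v in self.intervals.items()})
        return df
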