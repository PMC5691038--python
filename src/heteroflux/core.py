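"""Stoichiometric model containers and structural checks.

Conventions follow the COBRA community standard: exchange (boundary)
reactions are written ``met_e <->`` with negative flux meaning uptake and
positive flux secretion; default bounds are (-1000, 1000) for reversible
and (0, 1000) for irreversible reactions, in mmol gDCW^-1 h^-1.  Protons
and water are ordinary metabolites so proton-motive energetics are
explicit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .gpr import GprNode, parse_gpr

DEFAULT_UB = 1000.0
DEFAULT_LB = -1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula string (``C6H12O6``) into element counts.

    Counts may be non-integer (lumped biomass-style species).
    """
    counts: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        counts[elem] = counts.get(elem, 0.0) + (float(num) if num else 1.0)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class Metabolite:
    """A chemical species in a compartment.

    ``formula`` maps element symbol to (possibly fractional) count;
    ``charge`` is the net charge at the model's reference pH.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, float] | None = None
    charge: int | None = None

    @classmethod
    def from_formula_string(cls, id: str, formula: str, charge: int = 0,
                            compartment: str = "c", name: str = "") -> "Metabolite":
        return cls(id=id, name=name or id, compartment=compartment,
                   formula=parse_formula(formula), charge=charge)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and GPR.

    ``stoichiometry`` maps metabolite id -> coefficient (negative =
    consumed).  Bounds are in mmol gDCW^-1 h^-1; ``objective_coefficient``
    is the weight c_j in the linear objective.
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_LB
    upper_bound: float = DEFAULT_UB
    objective_coefficient: float = 0.0
    gpr: GprNode | None = None
    subsystem: str = ""
    name: str = ""

    def __setattr__(self, name, value):
        # GPR strings are parsed on assignment so `rxn.gpr = "g1 and g2"`
        # always yields a tree
        if name == "gpr" and isinstance(value, str):
            value = parse_gpr(value)
        super().__setattr__(name, value)

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower_bound) or not np.isfinite(self.upper_bound):
            raise ModelValidationError(f"reaction {self.id}: bounds must be finite")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} > upper bound {self.upper_bound}")
        for met, coef in self.stoichiometry.items():
            if not np.isfinite(coef):
                raise ModelValidationError(f"reaction {self.id}: non-finite coefficient for {met}")

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction: a single metabolite crossing the system edge."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()

    def copy(self) -> "Reaction":
        return Reaction(id=self.id, stoichiometry=dict(self.stoichiometry),
                        lower_bound=self.lower_bound, upper_bound=self.upper_bound,
                        objective_coefficient=self.objective_coefficient,
                        gpr=self.gpr, subsystem=self.subsystem, name=self.name)


class MetabolicModel:
    """Ordered collection of metabolites and reactions with a gene set."""

    def __init__(self, id: str = "model",
                 metabolites: list[Metabolite] | None = None,
                 reactions: list[Reaction] | None = None,
                 biomass_reaction_id: str | None = None,
                 compartments: dict[str, str] | None = None):
        self.id = id
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}
        self.biomass_reaction_id = biomass_reaction_id
        self.compartments = compartments or {"c": "cytosol", "e": "extracellular"}
        for m in metabolites or []:
            self.add_metabolite(m)
        for r in reactions or []:
            self.add_reaction(r)

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}")
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)

    def remove_reaction(self, rxn_id: str) -> None:
        idx = self._rxn_index.pop(rxn_id)
        del self.reactions[idx]
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookup -------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return out

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def reaction_counts(self) -> dict[str, int]:
        """Counts with exchanges reported separately (either counting
        convention for 'metabolic and transport reactions' can then be
        checked)."""
        n_ex = sum(1 for r in self.reactions if r.is_exchange)
        return {"total": len(self.reactions),
                "exchange": n_ex,
                "non_exchange": len(self.reactions) - n_ex}

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(id=self.id, biomass_reaction_id=self.biomass_reaction_id,
                           compartments=dict(self.compartments))
        for met in self.metabolites:
            m.add_metabolite(Metabolite(id=met.id, name=met.name, compartment=met.compartment,
                                        formula=dict(met.formula) if met.formula else None,
                                        charge=met.charge))
        for rxn in self.reactions:
            m.add_reaction(rxn.copy())
        return m

    def __repr__(self) -> str:  # pragma: no cover
        c = self.reaction_counts()
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{c['total']} reactions ({c['exchange']} exchanges), "
                f"{len(self.genes)} genes>")


def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S matrix (metabolites x reactions) in declared order."""
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[model.metabolite_index(met_id), j] = coef
    return S


@dataclass
class BalanceReport:
    """Per-reaction elemental/charge balance residuals."""

    reaction_id: str
    element_residuals: dict[str, float]
    charge_residual: float | None
    boundary: bool
    uncheckable: list[str]

    @property
    def balanced(self) -> bool:
        if self.boundary or self.uncheckable:
            return False
        ok_elem = all(abs(v) < 1e-9 for v in self.element_residuals.values())
        ok_charge = self.charge_residual is None or abs(self.charge_residual) < 1e-9
        return ok_elem and ok_charge


def check_mass_charge_balance(reaction: Reaction, model: MetabolicModel) -> BalanceReport:
    """Elemental and charge residuals of one reaction.

    Boundary (single-metabolite) reactions are intentionally unbalanced
    and flagged as such; metabolites lacking a formula make the reaction
    'uncheckable' rather than raising.
    """
    if reaction.is_exchange:
        return BalanceReport(reaction.id, {}, None, boundary=True, uncheckable=[])
    residuals: dict[str, float] = {}
    charge: float | None = 0.0
    uncheckable: list[str] = []
    for met_id, coef in reaction.stoichiometry.items():
        met = model.metabolite(met_id)
        if met.formula is None:
            uncheckable.append(met_id)
            continue
        for elem, n in met.formula.items():
            residuals[elem] = residuals.get(elem, 0.0) + coef * n
        if met.charge is None:
            charge = None
        elif charge is not None:
            charge += coef * met.charge
    residuals = {e: v for e, v in residuals.items()}
    return BalanceReport(reaction.id, residuals, charge, boundary=False,
                         uncheckable=uncheckable)
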