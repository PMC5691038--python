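"""Transformed Gibbs energies, reaction directionality, pathway net ΔG.

The transformed reaction energy at concentrations c is

    ΔrG' = ΔrG'° + RT Σ_i S_i ln c_i

with water and protons excluded (standard transformed convention).
Extremizing over a physiological concentration box (1 µM – 10 mM by
default) gives a ΔrG' range; a reaction is called forward-irreversible
when even the most favourable concentrations cannot make it run
backwards (ΔG'max < 0), reverse-irreversible when ΔG'min > 0, and
reversible otherwise — reactions with conflicting evidence default to
reversible.

Group-contribution estimation is out of scope: ΔrG'° values are inputs.
A packaged table covers the fixture's phosphoketolase (PKP) and
Embden-Meyerhof-Parnas (EMP) routes; its pathway definitions include an
ATP-recycling step with multiplicity equal to the route's net ATP yield
so that a pathway's net ΔrG'° equals its overall fermentative
conversion (glucose → lactate + ethanol + CO2, respectively
glucose → 2 lactate), which is how the classic PKP-vs-EMP comparison is
stated.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Reaction

R_GAS = 8.314462618e-3   # kJ mol^-1 K^-1
T_STANDARD = 298.15
RT = R_GAS * T_STANDARD  # 2.4789 kJ/mol

FIXED_ACTIVITY_DEFAULT = frozenset({"h", "h2o", "h_e", "h2o_e"})


@dataclass
class ConcentrationBounds:
    """Physiological metabolite concentration box (molar)."""

    c_min: float = 1e-6
    c_max: float = 1e-2
    exclusions: frozenset[str] = FIXED_ACTIVITY_DEFAULT

    def __post_init__(self):
        if not 0 < self.c_min <= self.c_max:
            raise ValueError("require 0 < c_min <= c_max")


@dataclass
class ThermoTable:
    """Per-reaction ΔrG'° (kJ/mol) at stated conditions."""

    values: dict[str, float]
    ph: float = 7.2
    ionic_strength: float = 0.1
    temperature: float = T_STANDARD
    provenance: str = ""

    def __getitem__(self, rxn_id: str) -> float:
        return self.values[rxn_id]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.values


def read_thermo_table(path: str | Path, provenance: str = "") -> ThermoTable:
    text = Path(path).read_text(encoding="utf-8")
    return _parse_thermo(text, provenance or str(path))


def _parse_thermo(text: str, provenance: str) -> ThermoTable:
    values: dict[str, float] = {}
    ph = 7.2
    ionic = 0.1
    for row in csv.reader(io.StringIO(text), delimiter="\t"):
        if not row or row[0].lstrip().startswith("#"):
            continue
        rxn, dg = row[0], float(row[1])
        if len(row) > 2:
            ph = float(row[2])
        if len(row) > 3:
            ionic = float(row[3])
        if not np.isfinite(dg):
            raise ValueError(f"non-finite ΔrG'° for {rxn}")
        values[rxn] = dg
    return ThermoTable(values, ph=ph, ionic_strength=ionic,
                       provenance=provenance)


def write_thermo_table(table: ThermoTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# reaction_id\tdG0_prime_kJ_per_mol\tpH\tionic_strength\tsource\n")
        for rxn, dg in table.values.items():
            fh.write(f"{rxn}\t{dg:g}\t{table.ph:g}\t{table.ionic_strength:g}\t"
                     f"{table.provenance}\n")


def packaged_pkp_emp_table() -> ThermoTable:
    """The committed PKP/EMP fixture table (synthetic stand-in compiled
    from literature values; see the data file header)."""
    text = (importlib.resources.files("heteroflux") / "data" /
            "thermo_pkp_emp.tsv").read_text(encoding="utf-8")
    return _parse_thermo(text, "packaged literature-compiled table")


def reaction_dg_range(dg0: float,
                      stoichiometry: dict[str, float] | Reaction,
                      bounds: ConcentrationBounds | None = None
                      ) -> tuple[float, float]:
    """Extremes of ΔrG' over the concentration box.

    The minimum puts products at c_min and substrates at c_max; the
    maximum the reverse.  Fixed-activity species (water, protons) do not
    contribute.
    """
    bounds = bounds or ConcentrationBounds()
    if isinstance(stoichiometry, Reaction):
        stoichiometry = stoichiometry.stoichiometry
    lo = hi = dg0
    ln_min, ln_max = np.log(bounds.c_min), np.log(bounds.c_max)
    for met, coef in stoichiometry.items():
        if met in bounds.exclusions or coef == 0:
            continue
        lo += RT * coef * (ln_min if coef > 0 else ln_max)
        hi += RT * coef * (ln_max if coef > 0 else ln_min)
    return (lo, hi)


def assign_directionality(dg_range: tuple[float, float]) -> str:
    """forward_irreversible / reverse_irreversible / reversible."""
    lo, hi = dg_range
    if hi < 0:
        return "forward_irreversible"
    if lo > 0:
        return "reverse_irreversible"
    return "reversible"


def directionality_report(reactions: list[Reaction], table: ThermoTable,
                          bounds: ConcentrationBounds | None = None
                          ) -> dict[str, str]:
    """Directionality call per reaction with a ΔrG'° entry; reactions
    without thermodynamic data stay reversible (conflict convention)."""
    out = {}
    for rxn in reactions:
        if rxn.id in table:
            out[rxn.id] = assign_directionality(
                reaction_dg_range(table[rxn.id], rxn, bounds))
        else:
            out[rxn.id] = "reversible"
    return out


def apply_directionality(model, calls: dict[str, str]) -> None:
    """Constrain a model's reaction bounds per directionality calls
    (forward: lb >= 0; reverse: ub <= 0; reversible calls left alone)."""
    for rxn_id, call in calls.items():
        rxn = model.reaction(rxn_id)
        if call == "forward_irreversible":
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        elif call == "reverse_irreversible":
            rxn.upper_bound = min(rxn.upper_bound, 0.0)


@dataclass
class PathwayNet:
    net_dg0: float
    fraction_negative: float
    members: dict[str, float] = field(default_factory=dict)


def pathway_net_dg(pathway: list[tuple[str, float]], table: ThermoTable) -> PathwayNet:
    """Multiplicity-weighted net ΔrG'° and the share of member reactions
    with negative ΔrG'°."""
    missing = [rxn for rxn, _ in pathway if rxn not in table]
    if missing:
        raise KeyError(f"reactions missing from thermodynamic table: {missing}")
    net = sum(mult * table[rxn] for rxn, mult in pathway)
    members = {rxn: table[rxn] for rxn, _ in pathway}
    frac = sum(1 for v in members.values() if v < 0) / len(members)
    return PathwayNet(net_dg0=net, fraction_negative=frac, members=members)


# packaged pathway definitions: one full glucose conversion, with the
# route's net substrate-level ATP recycled through the ATPM step
PKP_PATHWAY: list[tuple[str, float]] = [
    ("HEX1", 1), ("G6PDH", 1), ("GND", 1), ("RPE", 1), ("PKETX", 1),
    ("GAPD", 1), ("PGK", 1), ("PGM", 1), ("ENO", 1), ("PYK", 1), ("LDH", 1),
    ("PTAr", 1), ("ACALD_rev", 1), ("ALCD_rev", 1), ("ATPM", 1),
]
EMP_PATHWAY: list[tuple[str, float]] = [
    ("HEX1", 1), ("PGI_emp", 1), ("PFK", 1), ("FBA", 1), ("TPI", 1),
    ("GAPD", 2), ("PGK", 2), ("PGM", 2), ("ENO", 2), ("PYK", 2), ("LDH", 2),
    ("ATPM", 2),
]
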