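"""Biomass equation assembly from macromolecular composition.

The biomass assembly equation converts measured mass fractions
(protein, carbohydrate, RNA, DNA, lipid, in g/gDCW) and monomer tables
(amino-acid molar fractions, nucleotide fractions from genomic GC
content, lipid species) into per-monomer stoichiometric coefficients in
mmol gDCW^-1:

    coefficient = mass_fraction * monomer_fraction / residue_molar_mass

Residue masses are polymerized (water-subtracted) monomers for protein,
nucleic acids and glycogen.  Growth-associated maintenance (GAM) enters
as an ATP-hydrolysis term; non-growth maintenance (NGAM) is a standing
lower bound on a dedicated ATP drain.

For flux simulations the monomer-level equation is projected onto the
central-metabolism fixture through a coarse biosynthetic costing
(amino-acid pools plus polymerization ATP for protein; G6P + ATP for
glycogen; Ru5P + ATP for nucleotides; acetyl-CoA + NADH + ATP for
lipid), which is what the sensitivity analyses perturb.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .central import CentralModelOptions, build_central_model
from .core import MetabolicModel, parse_formula
from .fba import InfeasibleModelError, fba

ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999,
                  "P": 30.974, "S": 32.06}
WATER_MASS = 2 * ATOMIC_WEIGHTS["H"] + ATOMIC_WEIGHTS["O"]

# free (unpolymerized) monomer formulas, neutral species
AMINO_ACID_FORMULAS = {
    "gly": "C2H5NO2", "ala": "C3H7NO2", "val": "C5H11NO2", "leu": "C6H13NO2",
    "ile": "C6H13NO2", "pro": "C5H9NO2", "phe": "C9H11NO2", "trp": "C11H12N2O2",
    "met": "C5H11NO2S", "ser": "C3H7NO3", "thr": "C4H9NO3", "cys": "C3H7NO2S",
    "tyr": "C9H11NO3", "asn": "C4H8N2O3", "gln": "C5H10N2O3", "asp": "C4H7NO4",
    "glu": "C5H9NO4", "lys": "C6H14N2O2", "arg": "C6H14N4O2", "his": "C6H9N3O2",
}
RNA_NMP_FORMULAS = {"amp": "C10H14N5O7P", "gmp": "C10H14N5O8P",
                    "cmp": "C9H14N3O8P", "ump": "C9H13N2O9P"}
DNA_NMP_FORMULAS = {"damp": "C10H14N5O6P", "dgmp": "C10H14N5O7P",
                    "dcmp": "C9H14N3O7P", "dtmp": "C10H15N2O8P"}
GLYCOGEN_RESIDUE_FORMULA = "C6H10O5"            # already water-free
LIPID_FORMULAS = {"avg_phospholipid": "C39H76NO8P"}   # free species

MACROMOLECULES = ("protein", "carbohydrate", "rna", "dna", "lipid")
SENSITIVITY_COMPONENTS = ("NGAM", "GAM") + tuple(
    m.upper() if m in ("rna", "dna") else m for m in MACROMOLECULES)


def formula_mass(formula: str | dict[str, float]) -> float:
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ATOMIC_WEIGHTS[e] * n for e, n in counts.items())


def monomer_formula(monomer: str, polymerized: bool) -> dict[str, float]:
    """Elemental formula of a monomer, water-subtracted if polymerized."""
    for table in (AMINO_ACID_FORMULAS, RNA_NMP_FORMULAS, DNA_NMP_FORMULAS,
                  LIPID_FORMULAS):
        if monomer in table:
            counts = parse_formula(table[monomer])
            if polymerized and table is not LIPID_FORMULAS:
                counts["H"] -= 2.0
                counts["O"] -= 1.0
            return counts
    if monomer == "glycogen":
        return parse_formula(GLYCOGEN_RESIDUE_FORMULA)
    raise KeyError(f"unknown monomer {monomer!r}")


def dna_composition_from_gc(gc_fraction: float) -> dict[str, float]:
    """Nucleotide molar fractions of double-stranded DNA from GC content."""
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError(f"GC fraction must be in (0, 1), got {gc_fraction}")
    return {"dgmp": gc_fraction / 2, "dcmp": gc_fraction / 2,
            "damp": (1 - gc_fraction) / 2, "dtmp": (1 - gc_fraction) / 2}


def _uniform(keys) -> dict[str, float]:
    return {k: 1.0 / len(keys) for k in keys}


@dataclass
class EnergeticParameters:
    """Growth-associated and non-growth-associated ATP maintenance."""

    gam: float = 13.613    # mmol gDCW^-1
    ngam: float = 1.104    # mmol gDCW^-1 h^-1

    def __post_init__(self):
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("maintenance parameters must be non-negative")


@dataclass
class MacromolecularComposition:
    """Measured macromolecular composition of the cell.

    Mass fractions are g/gDCW and may sum to less than 1 (remainder =
    ash/other); monomer tables are molar fractions summing to 1.
    """

    mass_fractions: dict[str, float] = field(default_factory=lambda: {
        # literature-typical lactic acid bacterium grown in rich medium
        "protein": 0.40, "carbohydrate": 0.25, "rna": 0.08,
        "dna": 0.03, "lipid": 0.10})
    amino_acid_fractions: dict[str, float] = field(
        default_factory=lambda: _uniform(AMINO_ACID_FORMULAS))
    rna_fractions: dict[str, float] = field(
        default_factory=lambda: _uniform(RNA_NMP_FORMULAS))
    dna_fractions: dict[str, float] | None = None
    lipid_fractions: dict[str, float] = field(
        default_factory=lambda: {"avg_phospholipid": 1.0})
    gc_content: float = 0.378

    def __post_init__(self):
        if self.dna_fractions is None:
            self.dna_fractions = dna_composition_from_gc(self.gc_content)
        for name, frac in self.mass_fractions.items():
            if name not in MACROMOLECULES:
                raise ValueError(f"unknown macromolecule {name!r}")
            if frac < 0:
                raise ValueError(f"negative mass fraction for {name}")
        if sum(self.mass_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("mass fractions exceed 1 g/gDCW")
        for label, table in (("amino_acid", self.amino_acid_fractions),
                             ("rna", self.rna_fractions),
                             ("dna", self.dna_fractions),
                             ("lipid", self.lipid_fractions)):
            s = sum(table.values())
            if table and abs(s - 1.0) > 1e-6:
                raise ValueError(f"{label} fractions sum to {s}, expected 1")

    @property
    def ash_fraction(self) -> float:
        return 1.0 - sum(self.mass_fractions.values())


@dataclass
class BiomassEquation:
    """Monomer-level biomass stoichiometry, mmol gDCW^-1 (negative =
    consumed), plus the GAM ATP-hydrolysis terms."""

    coefficients: dict[str, float]
    gam: float
    monomer_macromolecule: dict[str, str]

    def consumed_mass(self) -> float:
        """Grams of polymerized monomer consumed per gDCW."""
        total = 0.0
        for monomer, coef in self.coefficients.items():
            if monomer in ("atp", "h2o", "adp", "pi", "h") or coef >= 0:
                continue
            mass = formula_mass(monomer_formula(
                monomer, polymerized=self.monomer_macromolecule[monomer] != "lipid"))
            total += -coef * mass / 1000.0
        return total


def assemble_biomass(composition: MacromolecularComposition,
                     energetics: EnergeticParameters | None = None) -> BiomassEquation:
    """Monomer coefficients from mass fractions and monomer tables."""
    energetics = energetics or EnergeticParameters()
    coeffs: dict[str, float] = {}
    origin: dict[str, str] = {}
    tables = {"protein": composition.amino_acid_fractions,
              "carbohydrate": {"glycogen": 1.0},
              "rna": composition.rna_fractions,
              "dna": composition.dna_fractions,
              "lipid": composition.lipid_fractions}
    for macro, table in tables.items():
        mass_frac = composition.mass_fractions.get(macro, 0.0)
        if mass_frac == 0.0:
            continue
        for monomer, mono_frac in table.items():
            if mono_frac == 0.0:
                continue
            mass = formula_mass(monomer_formula(monomer,
                                                polymerized=macro != "lipid"))
            coeffs[monomer] = coeffs.get(monomer, 0.0) - \
                1000.0 * mass_frac * mono_frac / mass
            origin[monomer] = macro
    gam = energetics.gam
    for met, coef in (("atp", -gam), ("h2o", -gam), ("adp", gam),
                      ("pi", gam), ("h", gam)):
        coeffs[met] = coeffs.get(met, 0.0) + coef
        origin.setdefault(met, "maintenance")
    return BiomassEquation(coeffs, gam, origin)


def elemental_formula(equation: BiomassEquation) -> dict[str, float]:
    """Per-carbon elemental formula C H_x N_y O_z ... of the biomass.

    Sums coefficient-weighted element counts of the consumed monomers
    (GAM hydrolysis nets to zero atoms) and normalizes to one carbon.
    Invariant to uniform rescaling of the equation.
    """
    totals: dict[str, float] = {}
    for monomer, coef in equation.coefficients.items():
        macro = equation.monomer_macromolecule.get(monomer)
        if macro in (None, "maintenance") or coef >= 0:
            continue
        counts = monomer_formula(monomer, polymerized=macro != "lipid")
        for elem, n in counts.items():
            totals[elem] = totals.get(elem, 0.0) + (-coef) * n
    carbon = totals.get("C")
    if not carbon:
        raise ValueError("biomass contains no carbon")
    return {elem: v / carbon for elem, v in totals.items()}


# ---------------------------------------------------------------------------
# projection onto the central fixture
# ---------------------------------------------------------------------------

# coarse biosynthetic costing per mmol of monomer, in fixture currencies.
# Protein residues come from the amino-acid pools (grouped by family)
# plus polymerization GTP/ATP; glycogen from G6P + ADP-glucose ATP;
# nucleotides from Ru5P plus lumped synthesis+polymerization ATP (DNA
# additionally reduced); lipid from acetyl-CoA chains (2 NADPH + 1 ATP
# per C2 unit) with a G6P-derived glycerol head.
_PROTEIN_ATP_PER_RESIDUE = 4.306
# ADP-glucose pyrophosphorylase + PPi hydrolysis: 2 ATP equivalents per
# glucosyl residue
_CARB_COST = {"g6p": 1.0, "atp": 2.0}
_RNA_COST = {"ru5p": 1.0, "atp": 7.0}
_DNA_COST = {"ru5p": 1.0, "atp": 8.5, "nadh": 1.0}
_LIPID_COST = {"accoa": 17.0, "atp": 16.0, "nadh": 34.0, "g6p": 0.5}
_AA_POOL = {"asp": "asp", "asn": "asp", "glu": "glu", "gln": "gln"}
# all other amino acids are supplied through the bulk glutamate pool


def composition_to_precursor_draws(composition: MacromolecularComposition
                                   ) -> dict[str, dict[str, float]]:
    """Per-macromolecule precursor demands (mmol/gDCW) on the fixture."""
    eq = assemble_biomass(composition, EnergeticParameters(gam=0.0, ngam=0.0))
    draws: dict[str, dict[str, float]] = {m: {} for m in MACROMOLECULES}

    def bump(macro, met, amount):
        draws[macro][met] = draws[macro].get(met, 0.0) + amount

    for monomer, coef in eq.coefficients.items():
        macro = eq.monomer_macromolecule.get(monomer)
        if macro in (None, "maintenance") or coef >= 0:
            continue
        n = -coef
        if macro == "protein":
            bump(macro, _AA_POOL.get(monomer, "glu"), n)
            bump(macro, "atp", n * _PROTEIN_ATP_PER_RESIDUE)
        elif macro == "carbohydrate":
            for met, c in _CARB_COST.items():
                bump(macro, met, n * c)
        elif macro == "rna":
            for met, c in _RNA_COST.items():
                bump(macro, met, n * c)
        elif macro == "dna":
            for met, c in _DNA_COST.items():
                bump(macro, met, n * c)
        elif macro == "lipid":
            for met, c in _LIPID_COST.items():
                bump(macro, met, n * c)
    return draws


_RELEASED = {"atp": [("adp", 1.0), ("pi", 1.0), ("h", 1.0)],
             "nadh": [("nad", 1.0)],
             "accoa": [("coa", 1.0)]}


def build_growth_model(composition: MacromolecularComposition,
                       energetics: EnergeticParameters | None = None,
                       options: CentralModelOptions | None = None,
                       component_scales: dict[str, float] | None = None,
                       coefficient_overrides: dict[str, dict[str, float]] | None = None,
                       ) -> MetabolicModel:
    """Central fixture with a composition-derived biomass equation.

    ``component_scales`` multiplies one or more macromolecule demands or
    GAM/NGAM (the sensitivity-scan knob); other components are NOT
    renormalized, so the total drawn mass may deviate from 1 g.

    A fructose feed is opened as a pure electron sink (fructokinase shut,
    so fructose can only be reduced to mannitol): the organism's own
    redox-valve strategy.  The lumped fixture needs this flexibility
    because biosynthetic draws perturb the otherwise hard-wired anaerobic
    NAD(H) closure in both directions.
    """
    energetics = energetics or EnergeticParameters()
    scales = component_scales or {}
    for comp, s in scales.items():
        if comp not in SENSITIVITY_COMPONENTS:
            raise ValueError(f"unknown component {comp!r}")
        if s < 0:
            raise ValueError(f"scale for {comp} would make coefficients negative")
    opt = options or CentralModelOptions()
    opt = replace(opt, ngam=energetics.ngam * scales.get("NGAM", 1.0))
    model = build_central_model(opt)
    draws = composition_to_precursor_draws(composition)
    if coefficient_overrides:
        for macro, extra in coefficient_overrides.items():
            for met, val in extra.items():
                draws[macro][met] = val
    stoich: dict[str, float] = {"biomass": 1.0}

    def consume(met: str, amount: float) -> None:
        stoich[met] = stoich.get(met, 0.0) - amount
        for rel, ratio in _RELEASED.get(met, []):
            stoich[rel] = stoich.get(rel, 0.0) + amount * ratio

    for macro in MACROMOLECULES:
        scale = scales.get(macro.upper() if macro in ("rna", "dna") else macro, 1.0)
        for met, amount in draws[macro].items():
            consume(met, amount * scale)
    gam = energetics.gam * scales.get("GAM", 1.0)
    consume("atp", gam)
    stoich["h2o"] = stoich.get("h2o", 0.0) - gam
    biomass = model.reaction("BIOMASS")
    biomass.stoichiometry = {k: v for k, v in stoich.items() if v != 0.0}
    # pseudo-species composition no longer matches the default fixture draw
    model.metabolite("biomass").formula = None
    model.metabolite("biomass").charge = None
    # fructose as electron sink only (mannitol valve)
    model.reaction("EX_fru").lower_bound = -50.0
    fruk = model.reaction("FRUK")
    fruk.lower_bound = fruk.upper_bound = 0.0
    return model


def _growth(model: MetabolicModel, glucose_uptake: float) -> float:
    m = model.copy()
    m.reaction("EX_glc").lower_bound = -glucose_uptake
    sol = fba(m, "BIOMASS", "max")
    return sol.objective_value if sol.optimal else 0.0


def estimate_maintenance(batch_points: list[tuple[float, float]],
                         composition: MacromolecularComposition | None = None,
                         options: CentralModelOptions | None = None
                         ) -> EnergeticParameters:
    """Regress maintenance parameters from (growth rate, glucose uptake).

    At each measured point the maximal ATP-drain flux is computed with
    growth fixed and GAM removed from the biomass equation; the ATP thus
    available for maintenance is linear in growth with slope GAM and
    intercept NGAM.  Both are clamped at zero.
    """
    if len(batch_points) < 2:
        raise ValueError("need at least two batch points")
    comp = composition or MacromolecularComposition()
    mus, atps = [], []
    for mu, uptake in batch_points:
        model = build_growth_model(comp, EnergeticParameters(gam=0.0, ngam=0.0),
                                   options)
        model.reaction("EX_glc").lower_bound = -uptake
        model.reaction("EX_glc").upper_bound = -uptake
        b = model.reaction("BIOMASS")
        b.lower_bound = b.upper_bound = mu
        sol = fba(model, "ATPM", "max")
        if not sol.optimal:
            raise InfeasibleModelError(
                f"maintenance point (mu={mu}, uptake={uptake}) is {sol.status}")
        mus.append(mu)
        atps.append(sol.fluxes["ATPM"])
    mus_a = np.asarray(mus)
    if np.ptp(mus_a) < 1e-12:
        raise ValueError("degenerate regression: all growth rates identical")
    slope, intercept = np.polyfit(mus_a, np.asarray(atps), 1)
    return EnergeticParameters(gam=max(0.0, float(slope)),
                               ngam=max(0.0, float(intercept)))


def sensitivity_scan(composition: MacromolecularComposition | None = None,
                     energetics: EnergeticParameters | None = None,
                     components: tuple[str, ...] = SENSITIVITY_COMPONENTS,
                     scales: np.ndarray | None = None,
                     glucose_uptake_grid: np.ndarray | None = None,
                     options: CentralModelOptions | None = None
                     ) -> list[dict[str, float]]:
    """Growth surface under +/-50 % variation of each component.

    Each component is adjusted individually (no renormalization of the
    others); rows are (component, scale, uptake, growth).
    """
    comp = composition or MacromolecularComposition()
    energ = energetics or EnergeticParameters()
    if scales is None:
        scales = np.linspace(0.5, 1.5, 5)
    if glucose_uptake_grid is None:
        glucose_uptake_grid = np.array([5.0, 10.0, 15.0])
    rows = []
    for component in components:
        for s in np.asarray(scales, dtype=float):
            model = build_growth_model(comp, energ, options,
                                       component_scales={component: float(s)})
            for uptake in np.asarray(glucose_uptake_grid, dtype=float):
                rows.append({"component": component, "scale": float(s),
                             "uptake": float(uptake),
                             "growth": _growth(model, uptake)})
    return rows


def sensitivity_coefficients(composition: MacromolecularComposition | None = None,
                             energetics: EnergeticParameters | None = None,
                             components: tuple[str, ...] = SENSITIVITY_COMPONENTS,
                             glucose_uptake_grid: np.ndarray | None = None,
                             options: CentralModelOptions | None = None,
                             mode: str = "absolute",
                             rel_step: float = 0.01) -> list[dict[str, float]]:
    """Central-difference growth sensitivities per component.

    ``mode='absolute'`` reports d(growth)/d(coefficient) per unit
    mmol gDCW^-1 of the component's total monomer demand — the
    convention under which lipid (heavy, expensive monomers, tiny
    coefficient) is the most sensitive component and protein (cheap
    abundant residues) the least.  ``mode='relative'`` reports
    d(growth)/d(relative scale).  The step is 1 % of nominal, central.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError("mode must be 'absolute' or 'relative'")
    comp = composition or MacromolecularComposition()
    energ = energetics or EnergeticParameters()
    if glucose_uptake_grid is None:
        glucose_uptake_grid = np.array([10.0])
    draws = composition_to_precursor_draws(comp)
    eq = assemble_biomass(comp, energ)
    rows = []
    for component in components:
        # nominal mmol/gDCW of the component (monomer demand, GAM or NGAM)
        if component == "GAM":
            nominal = energ.gam
        elif component == "NGAM":
            nominal = energ.ngam
        else:
            macro = component.lower()
            nominal = sum(-c for m, c in eq.coefficients.items()
                          if eq.monomer_macromolecule.get(m) == macro and c < 0)
        for uptake in np.asarray(glucose_uptake_grid, dtype=float):
            if nominal == 0.0:
                rows.append({"component": component, "uptake": float(uptake),
                             "coefficient": 0.0})
                continue
            hi = build_growth_model(comp, energ, options,
                                    component_scales={component: 1.0 + rel_step})
            lo = build_growth_model(comp, energ, options,
                                    component_scales={component: 1.0 - rel_step})
            dgrowth = _growth(hi, float(uptake)) - _growth(lo, float(uptake))
            denom = (2 * rel_step * nominal) if mode == "absolute" else (2 * rel_step)
            rows.append({"component": component, "uptake": float(uptake),
                         "coefficient": dgrowth / denom})
    return rows


# ---------------------------------------------------------------------------
# composition file I/O  ([macromolecules] / [amino_acids] / [rna] / [dna] /
# [lipids] sections, key = value, '#' comments)
# ---------------------------------------------------------------------------

def read_composition(path: str | Path) -> MacromolecularComposition:
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",),
                                   comment_prefixes=("#",))
    cp.read_string(Path(path).read_text(encoding="utf-8"))

    def section(name):
        if not cp.has_section(name):
            return None
        return {k: float(v) for k, v in cp.items(name)}

    macro = section("macromolecules") or {}
    gc = macro.pop("gc_content", 0.378)
    kwargs = dict(mass_fractions=macro, gc_content=gc)
    for sec, attr in (("amino_acids", "amino_acid_fractions"),
                      ("rna", "rna_fractions"), ("dna", "dna_fractions"),
                      ("lipids", "lipid_fractions")):
        vals = section(sec)
        if vals:
            kwargs[attr] = vals
    return MacromolecularComposition(**kwargs)


def write_composition(composition: MacromolecularComposition,
                      path: str | Path) -> None:
    cp = configparser.ConfigParser()
    cp["macromolecules"] = {k: repr(v) for k, v in
                            composition.mass_fractions.items()}
    cp["macromolecules"]["gc_content"] = repr(composition.gc_content)
    cp["amino_acids"] = {k: repr(v) for k, v in
                         composition.amino_acid_fractions.items()}
    cp["rna"] = {k: repr(v) for k, v in composition.rna_fractions.items()}
    cp["dna"] = {k: repr(v) for k, v in composition.dna_fractions.items()}
    cp["lipids"] = {k: repr(v) for k, v in composition.lipid_fractions.items()}
    with open(path, "w", encoding="utf-8") as fh:
        cp.write(fh)
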