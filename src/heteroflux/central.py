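"""Curated central-metabolism fixture of *Leuconostoc mesenteroides*.

An ~50-reaction, fully mass- and charge-balanced model of obligate
heterofermentative (phosphoketolase-pathway) glucose catabolism with the
species' signature energy-conservation routes: malolactic fermentation
(MLF), fructose reduction to mannitol, aerobic pyruvate-oxidase /
NADH-peroxidase redox relief, and PTS vs permease glucose transport.
Scenario functions reproduce the classic analyses: pathway ATP yields,
the oxygen titration of fermentation products, MLF mechanism comparison,
glucose-transport scenarios and byproduct flux-control scans.

Proton-closure convention
-------------------------
Protons and water are ordinary metabolites and every non-boundary
reaction is elementally and charge balanced.  There is no free
transmembrane proton leak (one would let the reversible F0F1-ATPase make
ATP from nothing).  The ledger closes through: proton-coupled efflux of
the acids lactate and acetate (equivalently, export of the undissociated
acid), passive ethanol/CO2 diffusion, a malate-H+ symporter, and the
F0F1-ATPase written with its true chemistry

    adp + pi + h + n h_e  <->  atp + h2o + n h      (n = 4 by default)

so that one full synthesis-hydrolysis cycle translocates exactly n
protons per ATP.  Glucose entry (the `symporter` option) is modelled as
a proton-neutral permease: in a model without a membrane potential a
proton-symporting stoichiometry would make the co-transported proton a
hard cytosolic burden and drive the anaerobic ATP yield to zero rather
than the substrate-level value of 1.  With this convention the textbook
yields are exact: 1 ATP/glucose (PKP), 2 (EMP), and MLF yields
1/n ATP per malate (0.25 at n = 4) because the decarboxylation consumes
one cytosolic proton per malate, worth one ATPase translocation cycle.

The small biomass equation draws G6P, PEP, PYR, OAA, acetyl-CoA,
NAD(P)H-equivalent reducing power, three amino acids and GAM ATP.  Its
coefficients satisfy two structural identities (acetyl-CoA draw equals
the PEP+OAA+PYR draws; NADH draw equals three times the acetyl-CoA
draw) under which the redox-forced end-product proportions are exactly
1:1:0 (lactate:ethanol:acetate) anaerobically and 1:0:1 at an O2 uptake
equal to the glucose uptake.  The biomass product is a pseudo-metabolite
whose formula is computed from the consumed precursors, so even the
biomass reaction passes the balance check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction, parse_formula
from .fba import (FluxSolution, InfeasibleModelError, fba, flux_sum, fva,
                  parsimonious_tiebreak)
from .io_tabular import parse_equation

# charged-species formulas at reference pH (BiGG conventions)
_FORMULAS: dict[str, tuple[str, int]] = {
    "glc": ("C6H12O6", 0), "g6p": ("C6H11O9P", -2), "f6p": ("C6H11O9P", -2),
    "fdp": ("C6H10O12P2", -4), "dhap": ("C3H5O6P", -2), "g3p": ("C3H5O6P", -2),
    "13dpg": ("C3H4O10P2", -4), "3pg": ("C3H4O7P", -3), "2pg": ("C3H4O7P", -3),
    "pep": ("C3H2O6P", -3), "pyr": ("C3H3O3", -1), "lac": ("C3H5O3", -1),
    "6pg": ("C6H10O10P", -3), "ru5p": ("C5H9O8P", -2), "x5p": ("C5H9O8P", -2),
    "actp": ("C2H3O5P", -2), "ac": ("C2H3O2", -1), "acald": ("C2H4O", 0),
    "etoh": ("C2H6O", 0), "co2": ("CO2", 0), "o2": ("O2", 0),
    "h2o2": ("H2O2", 0), "h2o": ("H2O", 0), "h": ("H", 1), "pi": ("HO4P", -2),
    "atp": ("C10H12N5O13P3", -4), "adp": ("C10H12N5O10P2", -3),
    "nad": ("C21H26N7O14P2", -1), "nadh": ("C21H27N7O14P2", -2),
    "nadp": ("C21H25N7O17P3", -3), "nadph": ("C21H26N7O17P3", -4),
    "coa": ("C21H32N7O16P3S", -4), "accoa": ("C23H34N7O17P3S", -4),
    "mal": ("C4H4O5", -2), "oaa": ("C4H2O5", -2), "fru": ("C6H12O6", 0),
    "mnt": ("C6H14O6", 0), "glu": ("C5H8NO4", -1), "gln": ("C5H10N2O3", 0),
    "asp": ("C4H6NO4", -1), "akg": ("C5H4O5", -2), "nh4": ("H4N", 1),
}

# biomass precursor draws, mmol per gram dry weight produced.
# Structural identities (see module docstring): ACCOA = PEP + OAA + PYR
# and NADH = 3 * ACCOA; no pentose draw.  The central-carbon draws are
# kept small so growth stays ATP-limited and the O2 freed by biomass
# assimilation (which pyruvate oxidase can convert to extra acetate at
# the aerobic endpoint) remains a ~1% perturbation of the 1:0:1 state.
BIOMASS_G6P = 0.030
BIOMASS_PEP = 0.004
BIOMASS_PYR = 0.004
BIOMASS_OAA = 0.002
BIOMASS_ACCOA = BIOMASS_PEP + BIOMASS_OAA + BIOMASS_PYR   # 0.010
BIOMASS_NADH = 3.0 * BIOMASS_ACCOA                        # 0.030
BIOMASS_ASP = 0.20
BIOMASS_GLU = 0.30
BIOMASS_GLN = 0.10

DEFAULT_GAM = 13.613    # mmol ATP per gDCW
DEFAULT_NGAM = 0.0      # mmol gDCW^-1 h^-1 standing ATP drain

AMINO_ACID_EXCHANGES = ["EX_glu", "EX_gln", "EX_asp"]


@dataclass(frozen=True)
class CentralModelOptions:
    """Configuration of the central fixture.

    glucose_transport: 'symporter' (proton-neutral permease), 'pts'
    (PEP-dependent phosphotransferase) or 'both'.  mlf_mechanism:
    'one_step' malolactic enzyme, 'three_step' MDH + OAA decarboxylase +
    LDH, or 'none'.  glycolysis: 'pkp' phosphoketolase or 'emp'
    PFK/aldolase variant.  nad_pools: 'lumped' uses one NAD(H) pool for
    all dehydrogenases; 'split' gives the oxidative pentose-phosphate
    steps NADP isoforms and draws biomass reducing power as NADPH.
    """

    glucose_transport: str = "symporter"
    mlf_mechanism: str = "none"
    pyruvate_oxidase: bool = True
    nadh_peroxidase: bool = True
    nadh_oxidase: bool = True
    atpase_h_per_atp: int = 4
    glycolysis: str = "pkp"
    nad_pools: str = "lumped"
    gam: float = DEFAULT_GAM
    ngam: float = DEFAULT_NGAM
    glucose_uptake: float = 10.0
    medium: str = "rich"        # rich opens all amino-acid exchanges
    glns_repressed: bool = False  # GlnR repression preset

    def __post_init__(self):
        if self.glucose_transport not in ("symporter", "pts", "both"):
            raise ValueError(f"bad glucose_transport {self.glucose_transport!r}")
        if self.mlf_mechanism not in ("one_step", "three_step", "none"):
            raise ValueError(f"bad mlf_mechanism {self.mlf_mechanism!r}")
        if self.glycolysis not in ("pkp", "emp"):
            raise ValueError(f"bad glycolysis {self.glycolysis!r}")
        if self.nad_pools not in ("lumped", "split"):
            raise ValueError(f"bad nad_pools {self.nad_pools!r}")
        if self.atpase_h_per_atp < 1:
            raise ValueError("atpase_h_per_atp must be >= 1")


@dataclass
class ScenarioResult:
    """Yields and key fluxes of one scenario solve."""

    growth_rate: float | None
    atp_yield: float | None
    product_yields: dict[str, float] = field(default_factory=dict)
    key_fluxes: dict[str, float] = field(default_factory=dict)
    nadh_flux_sum: float | None = None
    status: str = "optimal"


def _biomass_formula_charge() -> tuple[dict[str, float], float]:
    """Elemental composition of 1 g of biomass from its precursor draws."""
    total: dict[str, float] = {}
    charge = 0.0
    terms = [(BIOMASS_G6P, "g6p", 1), (BIOMASS_PEP, "pep", 1),
             (BIOMASS_PYR, "pyr", 1), (BIOMASS_OAA, "oaa", 1),
             (BIOMASS_ACCOA, "accoa", 1), (BIOMASS_ACCOA, "coa", -1),
             (BIOMASS_NADH, "nadh", 1), (BIOMASS_NADH, "nad", -1),
             (BIOMASS_ASP, "asp", 1), (BIOMASS_GLU, "glu", 1),
             (BIOMASS_GLN, "gln", 1)]
    for coef, met, sign in terms:
        formula, q = _FORMULAS[met]
        for elem, n in parse_formula(formula).items():
            total[elem] = total.get(elem, 0.0) + sign * coef * n
        charge += sign * coef * q
    total = {e: round(v, 9) for e, v in total.items() if abs(v) > 1e-12}
    return total, charge


def build_central_model(options: CentralModelOptions | None = None) -> MetabolicModel:
    """Assemble the fixture for the given options."""
    opt = options or CentralModelOptions()
    model = MetabolicModel(id=f"leuconostoc_central_{opt.glycolysis}")

    cytosolic = set(_FORMULAS)
    external = ["glc", "fru", "mal", "lac", "ac", "etoh", "co2", "o2",
                "h2o", "h", "pi", "nh4", "mnt", "glu", "gln", "asp", "pyr"]
    for met in sorted(cytosolic):
        formula, charge = _FORMULAS[met]
        model.add_metabolite(Metabolite.from_formula_string(met, formula, charge, "c"))
    for met in external:
        formula, charge = _FORMULAS[met]
        model.add_metabolite(Metabolite.from_formula_string(
            f"{met}_e", formula, charge, "e"))
    bm_formula, bm_charge = _biomass_formula_charge()
    # the pseudo-species carries the (fractional) composite charge so the
    # assembly reaction balances exactly
    model.add_metabolite(Metabolite(id="biomass", name="biomass pseudo-species",
                                    compartment="c", formula=bm_formula,
                                    charge=bm_charge))  # type: ignore[arg-type]

    n_h = opt.atpase_h_per_atp

    # (id, equation, lb, ub, gpr, subsystem)
    R: list[tuple[str, str, float | None, float | None, str, str]] = []

    def add(rid, eq, lb=None, ub=None, gpr="", subsystem=""):
        R.append((rid, eq, lb, ub, gpr, subsystem))

    pkp = "Phosphoketolase pathway"
    lower = "Lower glycolysis"
    pyrmet = "Pyruvate metabolism"
    redox = "Oxidative stress"
    transport = "Transport"
    aamet = "Amino acid metabolism"
    energy = "Energy metabolism"

    # -- glucose entry ------------------------------------------------
    if opt.glucose_transport in ("symporter", "both"):
        # proton-neutral permease (see module docstring)
        add("GLCt", "glc_e <-> glc", None, None, "glcU", transport)
    if opt.glucose_transport in ("pts", "both"):
        add("GLCpts", "glc_e + pep -> g6p + pyr", 0, None,
            "ptsI and ptsH and manX", transport)
    add("HEX1", "glc + atp -> g6p + adp + h", 0, None, "glk", pkp)

    # -- oxidative PPP / phosphoketolase or EMP -----------------------
    if opt.nad_pools == "lumped":
        add("G6PDH", "g6p + nad + h2o -> 6pg + nadh + 2 h", 0, None, "zwf", pkp)
        add("GND", "6pg + nad -> ru5p + co2 + nadh", 0, None, "gnd", pkp)
    else:
        # dual-specificity oxidative branch: NAD and NADP isoforms
        add("G6PDH", "g6p + nad + h2o -> 6pg + nadh + 2 h", 0, None, "zwf", pkp)
        add("G6PDH_nadp", "g6p + nadp + h2o -> 6pg + nadph + 2 h", 0, None, "zwf", pkp)
        add("GND", "6pg + nad -> ru5p + co2 + nadh", 0, None, "gnd", pkp)
        add("GND_nadp", "6pg + nadp -> ru5p + co2 + nadph", 0, None, "gnd", pkp)
    add("RPE", "ru5p <-> x5p", None, None, "rpe", pkp)
    if opt.glycolysis == "pkp":
        add("PKETX", "x5p + pi -> actp + g3p + h2o", 0, None, "xfp", pkp)
    else:
        add("PGI_emp", "g6p <-> f6p", None, None, "pgi", "EMP glycolysis")
        add("PFK", "f6p + atp -> fdp + adp + h", 0, None, "pfkA", "EMP glycolysis")
        add("FBA", "fdp <-> dhap + g3p", None, None, "fba", "EMP glycolysis")
        add("TPI", "dhap <-> g3p", None, None, "tpiA", "EMP glycolysis")
    if opt.glycolysis == "pkp":
        # PGI links fructose entry (f6p) to g6p for PPP catabolism
        add("PGI", "f6p <-> g6p", None, None, "pgi", pkp)

    # -- lower glycolysis ---------------------------------------------
    add("GAPD", "g3p + nad + pi <-> 13dpg + nadh + h", None, None, "gap", lower)
    add("PGK", "13dpg + adp <-> 3pg + atp", None, None, "pgk", lower)
    add("PGM", "3pg <-> 2pg", None, None, "gpmA", lower)
    add("ENO", "2pg <-> pep + h2o", None, None, "eno", lower)
    add("PYK", "pep + adp + h -> pyr + atp", 0, None, "pyk", lower)

    # -- fermentative branches ----------------------------------------
    add("LDH", "pyr + nadh + h -> lac + nad", 0, None, "ldhD or ldhL", pyrmet)
    add("PTAr", "actp + coa <-> accoa + pi", None, None, "pta", pyrmet)
    add("ACKr", "actp + adp <-> ac + atp", None, None, "ackA", pyrmet)
    add("ACALD", "accoa + nadh + h <-> acald + coa + nad", None, None, "adhE", pyrmet)
    add("ALCD", "acald + nadh + h <-> etoh + nad", None, None, "adhE", pyrmet)
    if opt.pyruvate_oxidase:
        add("POX", "pyr + pi + o2 + h -> actp + co2 + h2o2", 0, None, "pox", redox)
    if opt.nadh_peroxidase:
        add("NPX", "nadh + h + h2o2 -> nad + 2 h2o", 0, None, "npr", redox)
    if opt.nadh_oxidase:
        add("NOX", "nadh + h + o2 -> nad + h2o2", 0, None, "nox", redox)

    # -- fructose / mannitol branch -----------------------------------
    add("FRUK", "fru + atp -> f6p + adp + h", 0, None, "frk", pkp)
    add("MNTD", "fru + nadh + h -> mnt + nad", 0, None, "mdh", pyrmet)

    # -- malolactic fermentation --------------------------------------
    if opt.mlf_mechanism == "one_step":
        add("MLF", "mal + h -> lac + co2", 0, None, "mleA", pyrmet)
    elif opt.mlf_mechanism == "three_step":
        add("MDH_mlf", "mal + nad -> oaa + nadh + h", 0, None, "mdh2", pyrmet)
        add("OAADC", "oaa + h -> pyr + co2", 0, None, "oad", pyrmet)

    # -- anaplerosis & amino acids ------------------------------------
    add("PPC", "pep + co2 + h2o -> oaa + pi + h", 0, None, "ppc", aamet)
    add("AAT", "oaa + glu <-> asp + akg", None, None, "aspC", aamet)
    add("GDH", "akg + nh4 + nadh + h -> glu + h2o + nad", 0, None, "gdhA", aamet)
    glns_ub = 0.0 if opt.glns_repressed else None
    add("GLNS", "glu + nh4 + atp -> gln + adp + pi + h", 0, glns_ub, "glnA", aamet)

    # -- energy --------------------------------------------------------
    add("ATPS", f"adp + pi + h + {n_h} h_e <-> atp + h2o + {n_h} h",
        None, None, "atpA and atpB and atpD", energy)
    add("ATPM", "atp + h2o -> adp + pi + h", opt.ngam, None, "", energy)

    # -- transport -----------------------------------------------------
    add("LACt", "lac + h -> lac_e + h_e", 0, None, "", transport)
    add("ACt", "ac + h -> ac_e + h_e", 0, None, "", transport)
    add("ETOHt", "etoh <-> etoh_e", None, None, "", transport)
    add("CO2t", "co2 <-> co2_e", None, None, "", transport)
    add("O2t", "o2_e <-> o2", None, None, "", transport)
    add("H2Ot", "h2o <-> h2o_e", None, None, "", transport)
    add("PIt", "pi_e <-> pi", None, None, "", transport)
    add("NH4t", "nh4_e <-> nh4", None, None, "", transport)
    add("MNTt", "mnt -> mnt_e", 0, None, "", transport)
    add("FRUt", "fru_e <-> fru", None, None, "", transport)
    if opt.mlf_mechanism != "none":
        add("MALt", "mal_e + h_e -> mal + h", 0, None, "mleP", transport)
    add("GLUt", "glu_e <-> glu", None, None, "", transport)
    add("GLNt", "gln_e <-> gln", None, None, "", transport)
    add("ASPt", "asp_e <-> asp", None, None, "", transport)
    add("PYRt", "pyr_e <-> pyr", 0, 0, "", transport)

    # -- biomass -------------------------------------------------------
    gam = opt.gam
    biomass_eq = (
        f"{BIOMASS_G6P} g6p + {BIOMASS_PEP} pep + {BIOMASS_PYR} pyr + "
        f"{BIOMASS_OAA} oaa + {BIOMASS_ACCOA} accoa + {BIOMASS_NADH} nadh + "
        f"{BIOMASS_ASP} asp + {BIOMASS_GLU} glu + {BIOMASS_GLN} gln + "
        f"{gam} atp + {gam} h2o -> "
        f"{BIOMASS_ACCOA} coa + {BIOMASS_NADH} nad + "
        f"{gam} adp + {gam} pi + {gam} h + biomass")
    add("BIOMASS", biomass_eq, 0, None, "", "Biomass")

    # -- exchanges (negative flux = uptake) ----------------------------
    ex_bounds = {
        "EX_glc": (-opt.glucose_uptake, 0.0),
        "EX_fru": (0.0, 0.0),
        "EX_mal": (0.0, 0.0),
        "EX_o2": (0.0, 0.0),
        "EX_co2": (0.0, 1000.0),
        "EX_lac": (0.0, 1000.0),
        "EX_ac": (0.0, 1000.0),
        "EX_etoh": (0.0, 1000.0),
        "EX_mnt": (0.0, 1000.0),
        "EX_h2o": (-1000.0, 1000.0),
        "EX_h": (-1000.0, 1000.0),
        "EX_pi": (-1000.0, 1000.0),
        "EX_nh4": (-1000.0, 1000.0),
        "EX_pyr": (0.0, 0.0),
        "EX_biomass": (0.0, 1000.0),
    }
    # rich medium: amino-acid uptake unconstrained; minimal medium
    # supplies only the auxotrophic glutamate (no 2-oxoglutarate source)
    for ex in AMINO_ACID_EXCHANGES:
        if opt.medium == "minimal" and ex != "EX_glu":
            ex_bounds[ex] = (0.0, 0.0)
        else:
            ex_bounds[ex] = (-1000.0, 0.0)

    ex_met = {"EX_biomass": "biomass"}
    for rid, (lb, ub) in ex_bounds.items():
        met = ex_met.get(rid, rid[3:] + "_e")
        model.add_reaction(Reaction(id=rid, stoichiometry={met: -1.0},
                                    lower_bound=lb, upper_bound=ub,
                                    subsystem="Exchange"))

    for rid, eq, lb, ub, gpr, subsystem in R:
        stoich, reversible = parse_equation(eq)
        model.add_reaction(Reaction(
            id=rid, stoichiometry=stoich,
            lower_bound=(-1000.0 if reversible else 0.0) if lb is None else lb,
            upper_bound=1000.0 if ub is None else ub,
            gpr=gpr or None, subsystem=subsystem))

    model.reaction("BIOMASS").objective_coefficient = 1.0
    model.biomass_reaction_id = "BIOMASS"
    return model


# ---------------------------------------------------------------------------
# scenario analyses
# ---------------------------------------------------------------------------

def _per_glucose(sol: FluxSolution, rxn: str, glc_uptake: float) -> float:
    return sol.fluxes.get(rxn, 0.0) / glc_uptake if glc_uptake else 0.0


def _product_yields(sol: FluxSolution, glc_uptake: float) -> dict[str, float]:
    return {p: _per_glucose(sol, f"EX_{p}", glc_uptake)
            for p in ("lac", "etoh", "ac", "co2", "mnt")}


def pathway_atp_yield(options: CentralModelOptions | None = None,
                      open_amino_acids: bool = False,
                      glucose_uptake: float = 1.0) -> float:
    """Max ATP-drain flux per glucose, anaerobic, biomass off.

    1.0 on the phosphoketolase pathway, 2.0 on the EMP variant; opening
    amino-acid exchanges leaves the yield unchanged because the network
    has no amino-acid catabolism.
    """
    opt = replace(options or CentralModelOptions(),
                  glucose_uptake=glucose_uptake,
                  medium="rich" if open_amino_acids else "minimal")
    model = build_central_model(opt)
    model.reaction("BIOMASS").upper_bound = 0.0
    if not open_amino_acids:
        for ex in AMINO_ACID_EXCHANGES:
            r = model.reaction(ex)
            r.lower_bound = 0.0
    sol = fba(model, "ATPM", "max")
    if not sol.optimal:
        raise InfeasibleModelError(f"ATP-yield FBA {sol.status}")
    uptake = -sol.fluxes["EX_glc"]
    if uptake <= 0:
        return 0.0
    return sol.fluxes["ATPM"] / uptake


def oxygen_titration(options: CentralModelOptions | None = None,
                     o2_grid: np.ndarray | list[float] | None = None,
                     glucose_uptake: float = 10.0) -> list[ScenarioResult]:
    """Growth-maximizing states along an O2-uptake grid.

    The O2 bound is capped at the glucose uptake rate: beyond that the
    LP can reroute everything through pyruvate oxidase and the classic
    1:0:1 aerobic end-state is no longer the optimum.  Alternate optima
    are resolved parsimoniously.
    """
    opt = replace(options or CentralModelOptions(), glucose_uptake=glucose_uptake)
    if o2_grid is None:
        o2_grid = np.linspace(0.0, glucose_uptake, 21)
    results = []
    for o2 in np.asarray(o2_grid, dtype=float):
        if o2 > glucose_uptake + 1e-9:
            raise ValueError("O2 grid exceeds the glucose uptake cap")
        model = build_central_model(opt)
        model.reaction("EX_o2").lower_bound = -float(o2)
        sol = parsimonious_tiebreak(model, "BIOMASS", "max")
        if not sol.optimal:
            results.append(ScenarioResult(None, None, status=sol.status))
            continue
        uptake = -sol.fluxes["EX_glc"]
        phi = flux_sum(sol, "nadh", model)
        results.append(ScenarioResult(
            growth_rate=sol.objective_value,
            atp_yield=None,
            product_yields=_product_yields(sol, uptake),
            key_fluxes={"EX_o2": sol.fluxes["EX_o2"],
                        "LDH": sol.fluxes["LDH"],
                        "POX": sol.fluxes.get("POX", 0.0),
                        "ACKr": sol.fluxes["ACKr"]},
            nadh_flux_sum=phi))
    return results


def mlf_compare(mechanism: str = "one_step", medium: str = "rich",
                malate_uptake: float = 1.0,
                options: CentralModelOptions | None = None) -> ScenarioResult:
    """MLF flux and ATP gain per malate for one mechanism and medium.

    Growth is first maximized without malate; the ATP gain is then the
    increase in spare ATP-drain capacity at that fixed growth when the
    stated malate uptake is supplied — the paper's 'reduced
    F0F1-ATPase burden' measured as ATP equivalents.  With the default
    4 H+/ATP coupling the gain is exactly 0.25 ATP per malate.
    """
    opt = replace(options or CentralModelOptions(),
                  mlf_mechanism=mechanism, medium=medium)
    base_model = build_central_model(opt)
    base = parsimonious_tiebreak(base_model, "BIOMASS", "max")
    if not base.optimal:
        raise InfeasibleModelError(f"baseline FBA {base.status}")
    g0 = base.objective_value

    def spare_atp(with_malate: bool) -> tuple[float, FluxSolution]:
        m = build_central_model(opt)
        if with_malate:
            r = m.reaction("EX_mal")
            r.lower_bound = -malate_uptake
            r.upper_bound = -malate_uptake
        b = m.reaction("BIOMASS")
        b.lower_bound = g0
        b.upper_bound = g0
        s = parsimonious_tiebreak(m, "ATPM", "max")
        if not s.optimal:
            raise InfeasibleModelError(f"MLF ATP-drain FBA {s.status}")
        return s.fluxes["ATPM"], s

    atp0, _ = spare_atp(False)
    atp1, sol1 = spare_atp(True)
    delta_atp = ((atp1 - atp0) / malate_uptake) if malate_uptake else 0.0

    growth_with = parsimonious_tiebreak(
        _with_malate(opt, malate_uptake), "BIOMASS", "max")
    mlf_flux = (sol1.fluxes.get("MLF", 0.0) if mechanism == "one_step"
                else sol1.fluxes.get("MDH_mlf", 0.0))
    return ScenarioResult(
        growth_rate=growth_with.objective_value if growth_with.optimal else None,
        atp_yield=delta_atp,
        key_fluxes={"mlf_flux": mlf_flux, "growth_without_malate": g0,
                    "malate_uptake": malate_uptake},
        status="optimal")


def _with_malate(opt: CentralModelOptions, uptake: float) -> MetabolicModel:
    m = build_central_model(opt)
    if uptake:
        r = m.reaction("EX_mal")
        r.lower_bound = -uptake
        r.upper_bound = -uptake
    return m


def pts_scenarios(glucose_uptake: float = 10.0,
                  options: CentralModelOptions | None = None
                  ) -> dict[str, ScenarioResult]:
    """Growth under symporter-only, PTS-only and combined glucose entry.

    PTS-only growth is zero: every PEP is spent on transport, leaving
    none for the PEP-derived biomass demand.
    """
    out: dict[str, ScenarioResult] = {}
    for mode in ("symporter", "pts", "both"):
        opt = replace(options or CentralModelOptions(),
                      glucose_transport=mode, glucose_uptake=glucose_uptake)
        model = build_central_model(opt)
        sol = parsimonious_tiebreak(model, "BIOMASS", "max")
        if not sol.optimal or sol.objective_value < 1e-9:
            out[mode] = ScenarioResult(0.0, None,
                                       status=sol.status if not sol.optimal
                                       else "optimal")
            continue
        uptake = -sol.fluxes["EX_glc"]
        key = {"pts_flux": sol.fluxes.get("GLCpts", 0.0),
               "symporter_flux": sol.fluxes.get("GLCt", 0.0)}
        if uptake > 0:
            key["pts_fraction"] = key["pts_flux"] / uptake
        out[mode] = ScenarioResult(sol.objective_value, None,
                                   product_yields=_product_yields(sol, uptake)
                                   if uptake else {},
                                   key_fluxes=key)
    return out


def byproduct_control_scan(controlled_reaction: str,
                           options: CentralModelOptions | None = None,
                           fructose_uptake: float = 5.0,
                           glucose_uptake: float = 10.0,
                           n_points: int = 6,
                           min_growth_fraction: float = 0.5) -> list[dict[str, float]]:
    """Mannitol response to forcing a controlled flux below its optimum.

    With a fructose co-feed, the flux through the controlled reaction
    (PGI, RPE or ACALD) is fixed on a grid from its growth-optimal value
    down to its FVA minimum; at each point growth is re-maximized and
    the growth-maximal mannitol efflux recorded.  The FVA minimum is
    taken over states retaining at least ``min_growth_fraction`` (default
    half) of the optimal growth: below that, total NADH supply rather
    than the controlled reaction limits mannitol and the negative
    correlation trivially inverts (at a literal zero of an obligatory
    catabolic flux the cell makes neither biomass nor NADH).
    """
    if controlled_reaction not in ("PGI", "RPE", "ACALD"):
        raise ValueError("controlled reaction must be PGI, RPE or ACALD")
    opt = replace(options or CentralModelOptions(), glucose_uptake=glucose_uptake)
    base_model = build_central_model(opt)
    base_model.reaction("EX_fru").lower_bound = -fructose_uptake
    ref = parsimonious_tiebreak(base_model, "BIOMASS", "max")
    if not ref.optimal:
        raise InfeasibleModelError(f"reference FBA {ref.status}")
    v_opt = ref.fluxes[controlled_reaction]
    lo = fva(base_model, fraction_of_optimum=min_growth_fraction,
             reactions=[controlled_reaction]).ranges[controlled_reaction][0]
    curve = []
    for v in np.linspace(v_opt, lo, n_points):
        m = build_central_model(opt)
        m.reaction("EX_fru").lower_bound = -fructose_uptake
        r = m.reaction(controlled_reaction)
        r.lower_bound = r.upper_bound = float(v)
        sol = parsimonious_tiebreak(m, "BIOMASS", "max")
        if not sol.optimal:
            curve.append({"controlled_flux": float(v), "feasible": 0.0,
                          "mannitol_flux": float("nan"), "growth": float("nan")})
            continue
        # at the growth optimum, maximize mannitol efflux
        m2 = build_central_model(opt)
        m2.reaction("EX_fru").lower_bound = -fructose_uptake
        r2 = m2.reaction(controlled_reaction)
        r2.lower_bound = r2.upper_bound = float(v)
        b = m2.reaction("BIOMASS")
        b.lower_bound = sol.objective_value * (1 - 1e-9)
        msol = fba(m2, "EX_mnt", "max")
        mnt = msol.fluxes["EX_mnt"] if msol.optimal else float("nan")
        curve.append({"controlled_flux": float(v), "feasible": 1.0,
                      "mannitol_flux": mnt, "growth": sol.objective_value})
    return curve
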