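"""Plain-text tabular model dialect.

Two tab-separated files describe a model:

* reactions file — columns ``id, equation, lb, ub, gpr, subsystem``;
  equation grammar ``"2 A + B -> C"`` (irreversible) or ``"A <-> B"``
  (reversible); an empty right-hand side makes an exchange
  (``"A_e <->"``).
* metabolites file — columns ``id, formula, charge, compartment``.

Lines starting with ``#`` are comments; files are UTF-8.
"""

from __future__ import annotations

import csv
import io
import re
from pathlib import Path

from .core import (DEFAULT_LB, DEFAULT_UB, MetabolicModel, Metabolite,
                   Reaction, parse_formula)

_ARROWS = ("<->", "<=>", "->", "=>")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` into (stoichiometry, reversible)."""
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise ValueError(f"no arrow in equation {eq!r}")
    reversible = arrow in ("<->", "<=>")
    lhs, rhs = eq.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in equation {eq!r}")
            m = re.match(r"^(\d+\.?\d*|\.\d+)\s+(\S+)$", term)
            if m:
                coef, met = float(m.group(1)), m.group(2)
            else:
                coef, met = 1.0, term
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ValueError(f"equation {eq!r} cancels to nothing")
    return stoich, reversible


def format_equation(rxn: Reaction) -> str:
    lhs = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
    rhs = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]

    def fmt(side):
        parts = []
        for met, coef in side:
            parts.append(met if coef == 1.0 else f"{coef:g} {met}")
        return " + ".join(parts)

    arrow = "<->" if rxn.reversible else "->"
    return f"{fmt(lhs)} {arrow} {fmt(rhs)}".strip()


def _rows(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    out = []
    for row in csv.reader(io.StringIO(text), delimiter="\t"):
        if not row or row[0].lstrip().startswith("#"):
            continue
        out.append(row)
    return out


def read_tabular(reactions_path: str | Path, metabolites_path: str | Path,
                 model_id: str = "model") -> MetabolicModel:
    model = MetabolicModel(id=model_id)
    for row in _rows(metabolites_path):
        met_id, formula, charge, compartment = (row + ["", "", "", ""])[:4]
        model.add_metabolite(Metabolite(
            id=met_id,
            formula=parse_formula(formula) if formula else None,
            charge=int(charge) if charge not in ("", "NA") else None,
            compartment=compartment or "c"))
    for row in _rows(reactions_path):
        rxn_id, equation, lb, ub, gpr, subsystem = (row + [""] * 6)[:6]
        stoich, reversible = parse_equation(equation)
        lb_v = float(lb) if lb else (DEFAULT_LB if reversible else 0.0)
        ub_v = float(ub) if ub else DEFAULT_UB
        for met in stoich:
            if met not in model._met_index:
                model.add_metabolite(Metabolite(id=met))
        model.add_reaction(Reaction(id=rxn_id, stoichiometry=stoich,
                                    lower_bound=lb_v, upper_bound=ub_v,
                                    gpr=gpr or None, subsystem=subsystem))
    return model


def write_tabular(model: MetabolicModel, reactions_path: str | Path,
                  metabolites_path: str | Path) -> None:
    with open(metabolites_path, "w", encoding="utf-8") as fh:
        fh.write("# id\tformula\tcharge\tcompartment\n")
        for m in model.metabolites:
            formula = "".join(f"{e}{n:g}" if n != 1 else e
                              for e, n in (m.formula or {}).items())
            charge = "" if m.charge is None else str(m.charge)
            fh.write(f"{m.id}\t{formula}\t{charge}\t{m.compartment}\n")
    with open(reactions_path, "w", encoding="utf-8") as fh:
        fh.write("# id\tequation\tlb\tub\tgpr\tsubsystem\n")
        for r in model.reactions:
            gpr = r.gpr.to_string() if r.gpr is not None else ""
            fh.write(f"{r.id}\t{format_equation(r)}\t{r.lower_bound:g}\t"
                     f"{r.upper_bound:g}\t{gpr}\t{r.subsystem}\n")
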