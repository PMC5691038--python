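"""Synthetic fixtures with recorded ground truth.

Everything needed to exercise the pipeline without external data: small
random flux networks with analytically known optima, an independent
brute-force LP oracle, synthetic macromolecular compositions, expression
matrices with planted fold-changes and regulation classes, and paired
flux-sample sets with a known direction of change.  Every generator is
deterministic under a fixed seed and emits its truth alongside the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction, build_stoichiometric_matrix
from .fba import FluxSampleSet, sample_fluxes


@dataclass
class PlantedTruth:
    """Ground truth serialized next to generated data."""

    seed: int
    gene_fold_changes: dict[str, float] = field(default_factory=dict)
    subsystem_direction: dict[str, str] = field(default_factory=dict)
    regulation_class: dict[str, str] = field(default_factory=dict)
    flux_direction: dict[str, int] = field(default_factory=dict)

    def save(self, path) -> None:
        import dataclasses
        import json
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PlantedTruth":
        import json
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# brute-force LP oracle
# ---------------------------------------------------------------------------

def brute_force_lp_oracle(model: MetabolicModel,
                          objective_reaction_id: str,
                          direction: str = "max") -> tuple[str, float | None]:
    """Enumerate basic feasible solutions of  S v = 0, lb <= v <= ub.

    Vertices of the polytope have, for S of rank r, at least n - r
    coordinates at a bound.  For every subset B of columns with |B| = rank
    and every assignment of the remaining coordinates to their lower or
    upper bound, solve for the basic coordinates and keep feasible points.
    Exponential; intended for models with <= 8 reactions.  Returns
    (status, optimum).
    """
    S = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    if n > 12:
        raise ValueError("oracle is exponential; use <= 12 reactions")
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    j_obj = model.reaction_index(objective_reaction_id)
    sign = 1.0 if direction == "max" else -1.0
    r = np.linalg.matrix_rank(S) if S.size else 0
    best = None
    tol = 1e-9
    for basis in itertools.combinations(range(n), r):
        B = S[:, basis] if r else np.zeros((S.shape[0], 0))
        nonbasis = [j for j in range(n) if j not in basis]
        for corner in itertools.product(*[(lb[j], ub[j]) for j in nonbasis]):
            v = np.empty(n)
            for j, val in zip(nonbasis, corner):
                v[j] = val
            rhs = -S[:, nonbasis] @ np.array(corner) if nonbasis else np.zeros(S.shape[0])
            if r:
                sol, res, rank, _ = np.linalg.lstsq(B, rhs, rcond=None)
                v[list(basis)] = sol
            if np.max(np.abs(S @ v), initial=0.0) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = v[j_obj]
            if best is None or sign * val > sign * best:
                best = val
    if best is None:
        return "infeasible", None
    return "optimal", float(best)


# ---------------------------------------------------------------------------
# toy model suite
# ---------------------------------------------------------------------------

def make_chain_model(uptake: float = 10.0, n_internal: int = 2) -> MetabolicModel:
    """EX_A <-> | T: A_e -> M1 | R_i: M_i -> M_{i+1} | EX_B: last ->."""
    model = MetabolicModel(id="chain")
    model.add_metabolite(Metabolite(id="A_e", compartment="e"))
    for i in range(n_internal):
        model.add_metabolite(Metabolite(id=f"M{i}"))
    model.add_reaction(Reaction(id="EX_A", stoichiometry={"A_e": -1},
                                lower_bound=-uptake, upper_bound=0.0))
    model.add_reaction(Reaction(id="T", stoichiometry={"A_e": -1, "M0": 1},
                                lower_bound=0.0))
    for i in range(n_internal - 1):
        model.add_reaction(Reaction(id=f"R{i}",
                                    stoichiometry={f"M{i}": -1, f"M{i+1}": 1},
                                    lower_bound=0.0))
    model.add_reaction(Reaction(id="EX_B",
                                stoichiometry={f"M{n_internal-1}": -1},
                                lower_bound=0.0))
    return model


def make_toy_models(n: int, max_reactions: int = 8, seed: int = 0
                    ) -> list[tuple[MetabolicModel, str, float | None]]:
    """Random bounded networks plus their oracle optimum.

    Each entry is (model, objective_reaction_id, optimum).  Topologies mix
    chains, branches and loops; bounds are small integers so vertices are
    well separated.
    """
    rng = np.random.default_rng(seed)
    suite = []
    for k in range(n):
        n_mets = int(rng.integers(1, 4))
        model = MetabolicModel(id=f"toy{k}")
        model.add_metabolite(Metabolite(id="X_e", compartment="e"))
        for i in range(n_mets):
            model.add_metabolite(Metabolite(id=f"M{i}"))
        uptake = float(rng.integers(1, 11))
        model.add_reaction(Reaction(id="EX_in", stoichiometry={"X_e": -1},
                                    lower_bound=-uptake, upper_bound=0.0))
        model.add_reaction(Reaction(id="T", stoichiometry={"X_e": -1, "M0": 1},
                                    lower_bound=0.0, upper_bound=float(rng.integers(5, 20))))
        n_extra = int(rng.integers(1, max(2, max_reactions - 3)))
        for j in range(n_extra):
            a, b = rng.integers(0, n_mets, size=2)
            if a == b:
                continue
            coef_a = float(rng.integers(1, 3))
            coef_b = float(rng.integers(1, 3))
            rev = bool(rng.random() < 0.3)
            model.add_reaction(Reaction(
                id=f"R{j}", stoichiometry={f"M{a}": -coef_a, f"M{b}": coef_b},
                lower_bound=-float(rng.integers(1, 15)) if rev else 0.0,
                upper_bound=float(rng.integers(1, 15))))
        drain_met = f"M{int(rng.integers(0, n_mets))}"
        model.add_reaction(Reaction(id="EX_out", stoichiometry={drain_met: -1},
                                    lower_bound=0.0, upper_bound=1000.0))
        status, opt = brute_force_lp_oracle(model, "EX_out")
        suite.append((model, "EX_out", opt if status == "optimal" else None))
    return suite


# ---------------------------------------------------------------------------
# synthetic expression data
# ---------------------------------------------------------------------------

def simulate_expression(model: MetabolicModel,
                        subsystem_effects: dict[str, float] | None = None,
                        gene_effects: dict[str, float] | None = None,
                        n_replicates: int = 2,
                        noise_cv: float = 0.1,
                        base_intensity: float = 1000.0,
                        n_highcv_genes: int = 0,
                        n_background_genes: int = 0,
                        seed: int = 0):
    """Two-condition log-normal expression with planted fold changes.

    Condition 1 is the reference; condition 2 multiplies each gene's mean
    by its planted fold change (from ``gene_effects`` directly, or by the
    subsystem-level fold change of any reaction whose GPR contains the
    gene).  Replicate noise is log-normal with linear-scale coefficient of
    variation ``noise_cv``.  ``n_highcv_genes`` extra genes get noise far
    above the CV < 0.3 filter so filtering is exercised, and
    ``n_background_genes`` adds unchanged genes outside the model
    (microarrays probe the whole genome, not just reconstructed
    reactions), which keeps the quantile-normalization grid realistic.

    Returns (E1, E2, truth): gene -> replicate arrays per condition.
    """
    rng = np.random.default_rng(seed)
    subsystem_effects = subsystem_effects or {}
    gene_effects = dict(gene_effects or {})
    truth = PlantedTruth(seed=seed)
    for rxn in model.reactions:
        fc = subsystem_effects.get(rxn.subsystem)
        if fc is None:
            continue
        for g in rxn.genes():
            gene_effects.setdefault(g, fc)
    genes = sorted(model.genes)
    genes += [f"bg{i}" for i in range(n_background_genes)]
    for g in genes:
        gene_effects.setdefault(g, 1.0)
    truth.gene_fold_changes = dict(gene_effects)
    truth.subsystem_direction = {
        s: ("up" if fc > 1 else "down" if fc < 1 else "flat")
        for s, fc in subsystem_effects.items()}
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    else:
        sigma = 0.0

    def draw(mean: float, n: int) -> np.ndarray:
        if sigma == 0.0:
            return np.full(n, mean)
        # log-normal with linear-scale mean `mean` and CV `noise_cv`
        mu = np.log(mean) - sigma ** 2 / 2
        return rng.lognormal(mu, sigma, size=n)

    E1: dict[str, np.ndarray] = {}
    E2: dict[str, np.ndarray] = {}
    for g in genes:
        base = base_intensity * float(rng.lognormal(0.0, 0.5))
        E1[g] = draw(base, n_replicates)
        E2[g] = draw(base * gene_effects[g], n_replicates)
    for i in range(n_highcv_genes):
        g = f"noisy{i}"
        base = base_intensity
        big = float(np.sqrt(np.log1p(0.8 ** 2)))
        E1[g] = rng.lognormal(np.log(base), big, size=n_replicates)
        E2[g] = rng.lognormal(np.log(base), big, size=n_replicates)
        truth.gene_fold_changes[g] = 1.0
    return E1, E2, truth


def simulate_flux_samples(model: MetabolicModel,
                          perturbed_exchange_bounds: dict[str, tuple[float, float]],
                          n_points: int = 1000, thinning: int = 50,
                          seed: int = 0) -> tuple[FluxSampleSet, FluxSampleSet, PlantedTruth]:
    """Paired flux-sample sets for a reference and a perturbed condition.

    The perturbation changes exchange bounds only, keeping the polytope
    comparison interpretable.  Truth records sign(mean2 - mean1) per
    reaction from the sample means.
    """
    m2 = model.copy()
    for ex_id, (lo, hi) in perturbed_exchange_bounds.items():
        r = m2.reaction(ex_id)
        r.lower_bound, r.upper_bound = lo, hi
    s1 = sample_fluxes(model, n_points=n_points, thinning=thinning, seed=seed)
    s2 = sample_fluxes(m2, n_points=n_points, thinning=thinning, seed=seed + 1)
    truth = PlantedTruth(seed=seed)
    m1_mean, m2_mean = s1.mean(), s2.mean()
    for rid in model.reaction_ids:
        d = m2_mean[rid] - m1_mean[rid]
        truth.flux_direction[rid] = int(np.sign(d)) if abs(d) > 1e-9 else 0
    return s1, s2, truth
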