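"""LP engine: FBA, parsimonious tie-break, FVA, flux-sum, scans, sampling."""

import numpy as np
import pytest

from heteroflux.core import (MetabolicModel, Metabolite, Reaction,
                             build_stoichiometric_matrix)
from heteroflux.fba import (InfeasibleModelError, fba, flux_sum, fva,
                            nutrient_omission_scan, parsimonious_tiebreak,
                            sample_fluxes, single_gene_deletion_scan)
from heteroflux.synth import brute_force_lp_oracle, make_chain_model


class TestFBA:
    def test_chain_throughput(self, chain_model):
        sol = fba(chain_model, "EX_B", "max")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_internal_bottleneck(self, chain_model):
        chain_model.reaction("R0").upper_bound = 4.0
        sol = fba(chain_model, "EX_B", "max")
        assert sol.objective_value == pytest.approx(4.0, abs=1e-9)

    def test_matches_oracle_on_random_models(self, toy_suite):
        for model, obj, optimum in toy_suite:
            sol = fba(model, obj, "max")
            if optimum is None:
                assert sol.status != "optimal" or \
                    sol.objective_value == pytest.approx(0.0, abs=1e-9)
            else:
                assert sol.objective_value == pytest.approx(optimum, abs=1e-7)

    def test_infeasible_reported_without_fluxes(self):
        m = MetabolicModel(metabolites=[Metabolite(id="A")])
        m.add_reaction(Reaction(id="in", stoichiometry={"A": 1},
                                lower_bound=5.0, upper_bound=10.0))
        m.add_reaction(Reaction(id="out", stoichiometry={"A": -1},
                                lower_bound=0.0, upper_bound=1.0))
        sol = fba(m, "out", "max")
        assert sol.status == "infeasible" and sol.fluxes == {}

    def test_steady_state_residual(self, toy_suite):
        for model, obj, optimum in toy_suite:
            if optimum is None:
                continue
            sol = fba(model, obj, "max")
            S = build_stoichiometric_matrix(model)
            v = np.array([sol.fluxes[r] for r in model.reaction_ids])
            assert np.max(np.abs(S @ v), initial=0.0) <= 1e-6


class TestParsimoniousTiebreak:
    def _parallel_paths(self):
        """Two equal-yield routes: direct (1 reaction) vs detour (3)."""
        m = MetabolicModel()
        for mid in ("A_e", "A", "X", "Y", "B"):
            m.add_metabolite(Metabolite(id=mid, compartment="e" if
                                        mid.endswith("_e") else "c"))
        m.add_reaction(Reaction(id="EX_A", stoichiometry={"A_e": -1},
                                lower_bound=-10, upper_bound=0))
        m.add_reaction(Reaction(id="T", stoichiometry={"A_e": -1, "A": 1},
                                lower_bound=0))
        m.add_reaction(Reaction(id="direct", stoichiometry={"A": -1, "B": 1},
                                lower_bound=0))
        m.add_reaction(Reaction(id="d1", stoichiometry={"A": -1, "X": 1},
                                lower_bound=0))
        m.add_reaction(Reaction(id="d2", stoichiometry={"X": -1, "Y": 1},
                                lower_bound=0))
        m.add_reaction(Reaction(id="d3", stoichiometry={"Y": -1, "B": 1},
                                lower_bound=0))
        m.add_reaction(Reaction(id="EX_B", stoichiometry={"B": -1},
                                lower_bound=0))
        return m

    def test_shorter_path_carries_all_flux(self):
        m = self._parallel_paths()
        sol = parsimonious_tiebreak(m, "EX_B")
        assert sol.objective_value == pytest.approx(10.0, abs=1e-7)
        assert sol.fluxes["direct"] == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["d1"] == pytest.approx(0.0, abs=1e-6)

    def test_unique_optimum_unchanged(self, chain_model):
        plain = fba(chain_model, "EX_B")
        tied = parsimonious_tiebreak(chain_model, "EX_B")
        # the tie-break admits a 1e-9 relative slack on the objective
        assert tied.objective_value == pytest.approx(plain.objective_value,
                                                     rel=1e-7)
        for r in chain_model.reaction_ids:
            assert tied.fluxes[r] == pytest.approx(plain.fluxes[r], abs=1e-6)

    def test_zero_objective_gives_zero_vector(self, chain_model):
        chain_model.reaction("EX_B").upper_bound = 0.0
        sol = parsimonious_tiebreak(chain_model, "EX_B")
        assert all(v == pytest.approx(0.0, abs=1e-6)
                   for v in sol.fluxes.values())


class TestFVA:
    def test_degenerate_intervals_at_full_optimum(self, chain_model):
        res = fva(chain_model, 1.0, objective_reaction_id="EX_B")
        for rxn_id, (lo, hi) in res.ranges.items():
            assert hi - lo < 1e-6

    def test_loop_spans_bounds_at_fraction_zero(self):
        m = MetabolicModel(metabolites=[Metabolite(id="A"),
                                        Metabolite(id="B")])
        m.add_reaction(Reaction(id="f", stoichiometry={"A": -1, "B": 1},
                                lower_bound=-5, upper_bound=5))
        m.add_reaction(Reaction(id="b", stoichiometry={"B": -1, "A": 1},
                                lower_bound=-5, upper_bound=5))
        m.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1},
                                lower_bound=0, upper_bound=0))
        res = fva(m, 0.0)
        assert res.ranges["f"] == pytest.approx((-5.0, 5.0))

    def test_contains_optimum_and_widens_monotonically(self, toy_suite):
        for model, obj, optimum in toy_suite[:8]:
            if not optimum:
                continue
            sol = fba(model, obj)
            tight = fva(model, 1.0 - 1e-9, objective_reaction_id=obj)
            loose = fva(model, 0.5, objective_reaction_id=obj)
            for rxn_id in model.reaction_ids:
                lo_t, hi_t = tight.ranges[rxn_id]
                lo_l, hi_l = loose.ranges[rxn_id]
                assert lo_t - 1e-6 <= sol.fluxes[rxn_id] <= hi_t + 1e-6
                assert lo_l <= lo_t + 1e-6 and hi_l >= hi_t - 1e-6


class TestFluxSum:
    def test_chain_turnover(self, chain_model):
        sol = fba(chain_model, "EX_B")
        assert flux_sum(sol, "M0", chain_model) == pytest.approx(10.0)

    def test_untouched_metabolite_zero(self, chain_model):
        chain_model.add_metabolite(Metabolite(id="idle"))
        chain_model.add_reaction(Reaction(id="r_idle",
                                          stoichiometry={"idle": 1, "M0": -1},
                                          lower_bound=0, upper_bound=0))
        sol = fba(chain_model, "EX_B")
        assert flux_sum(sol, "idle", chain_model) == 0.0

    def test_equals_production_and_consumption(self, central_model):
        sol = parsimonious_tiebreak(central_model, "BIOMASS")
        for met in ("atp", "nadh", "pyr", "h"):
            produced = sum(c * sol.fluxes[r.id]
                           for r in central_model.reactions
                           for m_id, c in r.stoichiometry.items()
                           if m_id == met and c * sol.fluxes[r.id] > 0)
            phi = flux_sum(sol, met, central_model)
            assert phi == pytest.approx(produced, rel=1e-6, abs=1e-6)

    def test_unknown_metabolite_raises(self, chain_model):
        sol = fba(chain_model, "EX_B")
        with pytest.raises(KeyError):
            flux_sum(sol, "nope", chain_model)


class TestDeletionScans:
    def _gpr_chain(self):
        m = make_chain_model()
        m.biomass_reaction_id = "EX_B"
        m.reaction("T").gpr = "g_only"
        m.reaction("R0").gpr = "iso1 or iso2"
        return m

    def test_single_path_gene_essential(self):
        res = single_gene_deletion_scan(self._gpr_chain())
        assert res["g_only"][1] is True

    def test_isoenzyme_pair_non_essential(self):
        res = single_gene_deletion_scan(self._gpr_chain())
        assert res["iso1"][1] is False and res["iso2"][1] is False

    def test_agrees_with_direct_resolve(self, central_model):
        from heteroflux.fba import knockout_model
        res = single_gene_deletion_scan(central_model)
        for gene in list(sorted(central_model.genes))[:6]:
            direct = fba(knockout_model(central_model, {gene}), "BIOMASS")
            growth = direct.objective_value if direct.optimal else 0.0
            assert res[gene][0] == pytest.approx(growth, abs=1e-6)

    def test_deleting_full_gpr_of_essential_reaction_kills_growth(
            self, central_model):
        from heteroflux.fba import knockout_model
        wt = fba(central_model, "BIOMASS").objective_value
        genes = central_model.reaction("PKETX").genes()
        ko = fba(knockout_model(central_model, genes), "BIOMASS")
        growth = ko.objective_value if ko.optimal else 0.0
        assert growth < 0.1 * wt


class TestNutrientOmission:
    def test_biosynthesizable_nutrient_not_auxotrophic(self, central_model):
        res = nutrient_omission_scan(central_model, ["EX_asp", "EX_gln"])
        assert res["EX_asp"][1] is False
        assert res["EX_gln"][1] is False

    def test_glutamate_auxotrophy(self, central_model):
        res = nutrient_omission_scan(central_model, ["EX_glu"])
        assert res["EX_glu"][1] is True

    def test_glutamine_call_flips_under_glns_repression(self):
        from heteroflux.central import CentralModelOptions, build_central_model
        repressed = build_central_model(
            CentralModelOptions(glns_repressed=True))
        res = nutrient_omission_scan(repressed, ["EX_gln"])
        assert res["EX_gln"][1] is True

    def test_unknown_exchange_listed(self, central_model):
        with pytest.raises(KeyError, match="EX_nope"):
            nutrient_omission_scan(central_model, ["EX_nope"])


class TestSampling:
    def _interval_model(self):
        """1-D feasible set: flux through a two-reaction chain in [0, 10]."""
        m = MetabolicModel(metabolites=[Metabolite(id="A")])
        m.add_reaction(Reaction(id="in", stoichiometry={"A": 1},
                                lower_bound=0, upper_bound=10))
        m.add_reaction(Reaction(id="out", stoichiometry={"A": -1},
                                lower_bound=0, upper_bound=1000))
        return m

    def test_uniform_interval_mean(self):
        ss = sample_fluxes(self._interval_model(), n_points=2000, thinning=5,
                           seed=11)
        mean = ss.column("in").mean()
        se = ss.column("in").std() / np.sqrt(len(ss.points))
        # generous Monte-Carlo band (samples are autocorrelated)
        assert abs(mean - 5.0) < max(0.5, 10 * se)

    def test_points_feasible(self, chain_model):
        ss = sample_fluxes(chain_model, n_points=300, thinning=20, seed=3)
        S = build_stoichiometric_matrix(chain_model)
        assert np.max(np.abs(S @ ss.points.T)) <= 1e-6
        lb = np.array([r.lower_bound for r in chain_model.reactions])
        ub = np.array([r.upper_bound for r in chain_model.reactions])
        assert np.all(ss.points >= lb - 1e-6)
        assert np.all(ss.points <= ub + 1e-6)

    def test_seed_reproducibility_and_agreement(self, chain_model):
        a = sample_fluxes(chain_model, n_points=400, thinning=10, seed=1)
        b = sample_fluxes(chain_model, n_points=400, thinning=10, seed=1)
        c = sample_fluxes(chain_model, n_points=400, thinning=10, seed=2)
        assert np.array_equal(a.points, b.points)
        assert not np.array_equal(a.points, c.points)
        col = "EX_B"
        se = a.column(col).std() / np.sqrt(400)
        assert abs(a.column(col).mean() - c.column(col).mean()) < \
            max(0.5, 10 * se)

    def test_empty_polytope_raises(self):
        m = MetabolicModel(metabolites=[Metabolite(id="A")])
        m.add_reaction(Reaction(id="in", stoichiometry={"A": 1},
                                lower_bound=5, upper_bound=10))
        m.add_reaction(Reaction(id="out", stoichiometry={"A": -1},
                                lower_bound=0, upper_bound=1))
        with pytest.raises(InfeasibleModelError):
            sample_fluxes(m, n_points=10, thinning=2, seed=0)
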