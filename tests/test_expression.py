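"""Transcriptome integration: normalization, filtering, mapping, calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from heteroflux.core import MetabolicModel, Metabolite, Reaction
from heteroflux.expression import (ExpressionDataset, classify_regulation,
                                   read_expression_matrix,
                                   write_enrichment_table,
                                   write_regulation_calls,
                                   cv_filter, gene_to_reaction_fold_change,
                                   quantile_normalize,
                                   reaction_replicate_levels,
                                   regulation_zscores, subsystem_enrichment)
from heteroflux.fba import FluxSampleSet


def _ds(values: dict[str, list[float]], cond="c") -> ExpressionDataset:
    return ExpressionDataset({g: np.asarray(v, dtype=float)
                              for g, v in values.items()}, cond)


def _gpr_model(gprs: dict[str, str], subsystems: dict[str, str] | None = None):
    m = MetabolicModel(metabolites=[Metabolite(id="A"), Metabolite(id="B")])
    for rid, gpr in gprs.items():
        m.add_reaction(Reaction(id=rid, stoichiometry={"A": -1, "B": 1},
                                gpr=gpr,
                                subsystem=(subsystems or {}).get(rid, "")))
    return m


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        d = _ds({"a": [1.0, 1.0], "b": [5.0, 5.0], "c": [9.0, 9.0]})
        (out,) = quantile_normalize(d)
        for g in "abc":
            assert out.intensities[g] == pytest.approx(d.intensities[g])

    def test_two_column_worked_example(self):
        d1 = _ds({"a": [1.0], "b": [2.0], "c": [3.0]})
        d2 = _ds({"a": [4.0], "b": [5.0], "c": [6.0]})
        n1, n2 = quantile_normalize(d1, d2)
        assert [n1.intensities[g][0] for g in "abc"] == \
            pytest.approx([2.5, 3.5, 4.5])
        assert [n2.intensities[g][0] for g in "abc"] == \
            pytest.approx([2.5, 3.5, 4.5])

    def test_per_gene_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        vals = {f"g{i}": rng.lognormal(3, 1, size=4) for i in range(50)}
        d = _ds(vals)
        (out,) = quantile_normalize(d)
        for j in range(4):
            before = np.argsort([vals[f"g{i}"][j] for i in range(50)])
            after = np.argsort([out.intensities[f"g{i}"][j]
                                for i in range(50)])
            assert np.array_equal(before, after)

    def test_missing_values_rejected(self):
        d = _ds({"a": [1.0, np.nan]})
        with pytest.raises(ValueError):
            quantile_normalize(d)


class TestCvFilter:
    def test_zero_cv_kept(self):
        out = cv_filter([_ds({"g": [10.0, 10.0]})])
        assert out[0].genes() == ["g"]

    def test_high_cv_dropped(self):
        # sd/mean of (1, 3) = sqrt(2)/2 ≈ 0.707 >= 0.3
        out = cv_filter([_ds({"g": [1.0, 3.0]})])
        assert out[0].genes() == []

    def test_must_pass_in_every_condition(self):
        d1 = _ds({"g": [10.0, 10.0]}, "c1")
        d2 = _ds({"g": [1.0, 3.0]}, "c2")
        out = cv_filter([d1, d2])
        assert out[0].genes() == []

    def test_empty_dataset(self):
        out = cv_filter([_ds({})])
        assert out[0].genes() == []


class TestGprFoldChange:
    def test_and_takes_minimum(self):
        m = _gpr_model({"r": "g1 and g2"})
        assert gene_to_reaction_fold_change(m, {"g1": 2.0, "g2": 3.0}) == \
            {"r": 2.0}

    def test_or_sums(self):
        m = _gpr_model({"r": "g1 or g2"})
        assert gene_to_reaction_fold_change(m, {"g1": 2.0, "g2": 3.0}) == \
            {"r": 5.0}

    def test_nested_composition(self):
        m = _gpr_model({"r": "(g1 and g2) or g3"})
        fc = gene_to_reaction_fold_change(m, {"g1": 2.0, "g2": 3.0, "g3": 4.0})
        assert fc == {"r": 6.0}

    def test_unmeasured_gene_dropped_from_tree(self):
        m = _gpr_model({"r": "g1 and gX", "r2": "gX or gY"})
        fc = gene_to_reaction_fold_change(m, {"g1": 2.0})
        assert fc == {"r": 2.0}   # AND of one child; r2 fully unmeasured

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.01, 1.0))
    def test_monotone_in_every_gene(self, f1, f2, bump):
        m = _gpr_model({"r": "(g1 and g2) or (g1 and g3)"})
        base = {"g1": f1, "g2": f2, "g3": 1.0}
        lo = gene_to_reaction_fold_change(m, base)["r"]
        base["g1"] = f1 + bump
        hi = gene_to_reaction_fold_change(m, base)["r"]
        assert hi >= lo - 1e-12


class TestSubsystemEnrichment:
    def test_five_uniform_upshifts_exact_p(self):
        fc = {f"r{i}": 2.0 for i in range(5)}
        subs = {f"r{i}": "S" for i in range(5)}
        rows = subsystem_enrichment(fc, subs)
        assert rows[0]["direction"] == "up"
        assert rows[0]["p_value"] == pytest.approx(0.0625)

    def test_symmetric_pairs_give_p_one(self):
        fc = {"a": 2.0, "b": 0.5, "c": 4.0, "d": 0.25}
        subs = {k: "S" for k in fc}
        rows = subsystem_enrichment(fc, subs)
        assert rows[0]["p_value"] == pytest.approx(1.0)

    def test_all_unchanged_gives_p_one(self):
        fc = {"a": 1.0, "b": 1.0, "c": 1.0}
        rows = subsystem_enrichment(fc, {k: "S" for k in fc})
        assert rows[0]["p_value"] == 1.0

    def test_small_subsystems_skipped(self):
        rows = subsystem_enrichment({"a": 2.0, "b": 2.0},
                                    {"a": "S", "b": "S"})
        assert rows == []

    def test_planted_upshift_detected_reliably(self):
        """A 4-fold planted subsystem (n=20, CV 0.1 noise) is flagged up
        with p < 0.05 in at least 95% of seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            fc = {f"r{i}": 4.0 * rng.lognormal(0, 0.1) for i in range(20)}
            rows = subsystem_enrichment(fc, {f"r{i}": "S" for i in range(20)})
            if rows[0]["significant"] and rows[0]["direction"] == "up":
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_null_pvalues_follow_exact_null_distribution(self):
        """Under a symmetric-noise null the p-values match the enumerated
        exact signed-rank null distribution (discrete, so the continuous
        uniform is the wrong reference) at KS level 0.01."""
        from conftest import ks_against_discrete_null
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(1000):
            fc = {f"r{i}": float(np.exp(rng.normal(0, 0.5)))
                  for i in range(12)}
            rows = subsystem_enrichment(fc, {f"r{i}": "S" for i in range(12)})
            pvals.append(rows[0]["p_value"])
        assert ks_against_discrete_null(pvals, 12) < 1.628 / np.sqrt(1000)
        # and the p-values are valid (not anti-conservative)
        for t in (0.01, 0.05, 0.1):
            assert np.mean(np.asarray(pvals) <= t) <= t + 0.02


def _samples(cols: dict[str, np.ndarray], seed=0) -> FluxSampleSet:
    ids = sorted(cols)
    pts = np.column_stack([cols[r] for r in ids])
    return FluxSampleSet(ids, pts, pts.shape[0], 1, seed)


class TestRegulationZscores:
    def test_worked_example(self):
        # replicate values with mean 6 vs 10 and sample variance 2 each
        m = _gpr_model({"r": "g1"})
        e1 = _ds({"g1": [6 - 1, 6 + 1, 6 - 1, 6 + 1]})          # var 4/3
        e2 = _ds({"g1": [10 - 1, 10 + 1, 10 - 1, 10 + 1]})
        rng = np.random.default_rng(1)
        f = rng.normal(0, 1, size=100)
        zs = regulation_zscores(m, e1, e2, _samples({"r": f}),
                                _samples({"r": f}))
        ze, zf = zs["r"]
        var = np.var([5, 7, 5, 7], ddof=1)
        assert ze == pytest.approx(4 / np.sqrt(2 * var))
        assert zf == pytest.approx(0.0)

    def test_identical_distributions_give_zero(self):
        m = _gpr_model({"r": "g1"})
        e = _ds({"g1": [5.0, 5.0]})
        f = np.zeros(10)
        zs = regulation_zscores(m, e, e, _samples({"r": f}), _samples({"r": f}))
        assert zs["r"] == (0.0, 0.0)

    def test_swapping_conditions_negates_z(self):
        m = _gpr_model({"r": "g1"})
        e1 = _ds({"g1": [4.0, 6.0]})
        e2 = _ds({"g1": [9.0, 11.0]})
        f1 = np.array([0.0, 1.0, 2.0])
        f2 = np.array([5.0, 6.0, 7.0])
        a = regulation_zscores(m, e1, e2, _samples({"r": f1}),
                               _samples({"r": f2}))["r"]
        b = regulation_zscores(m, e2, e1, _samples({"r": f2}),
                               _samples({"r": f1}))["r"]
        assert a[0] == pytest.approx(-b[0])
        assert a[1] == pytest.approx(-b[1])

    def test_replicate_level_gpr_mapping(self):
        m = _gpr_model({"r": "g1 or g2"})
        ds = _ds({"g1": [1.0, 2.0], "g2": [10.0, 20.0]})
        levels = reaction_replicate_levels(m, ds)
        assert levels["r"] == pytest.approx([11.0, 22.0])


class TestClassifyRegulation:
    @pytest.mark.parametrize("ze,zf,expected", [
        (5.0, 5.0, "transcriptional"),
        (0.0, 5.0, "metabolic"),
        (5.0, 0.0, "post_transcriptional"),
        (-5.0, -5.0, "transcriptional"),   # coordinated down-shift
        (0.5, 0.5, "none"),
    ])
    def test_archetypes(self, ze, zf, expected):
        calls = classify_regulation({"r": (ze, zf)})
        assert calls[0].regulation_class == expected
        if expected != "none":
            assert calls[0].probability > 0.9

    def test_probability_bounded(self):
        for ze in (-4, -1, 0, 1, 4):
            for zf in (-4, -1, 0, 1, 4):
                c = classify_regulation({"r": (float(ze), float(zf))})[0]
                assert 0.0 <= c.probability <= 1.0

    def test_infinite_z_sentinels_handled(self):
        c = classify_regulation({"r": (float("inf"), 0.0)})[0]
        assert c.regulation_class == "post_transcriptional"


class TestFileInterfaces:
    def test_matrix_and_sidecar_roundtrip(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "# intensities\ngene\ts1\ts2\ts3\ts4\n"
            "gA\t1\t2\t10\t20\ngB\t3\t4\t30\t40\n")
        (tmp_path / "a.tsv").write_text(
            "s1\tG\t1\ns2\tG\t2\ns3\tS\t1\ns4\tS\t2\n")
        ds = read_expression_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv")
        assert set(ds) == {"G", "S"}
        assert ds["G"].intensities["gA"] == pytest.approx([1.0, 2.0])
        assert ds["S"].intensities["gB"] == pytest.approx([30.0, 40.0])

    def test_unannotated_sample_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\ngA\t1\n")
        (tmp_path / "a.tsv").write_text("sX\tG\t1\n")
        with pytest.raises(ValueError, match="s1"):
            read_expression_matrix(tmp_path / "m.tsv", tmp_path / "a.tsv")

    def test_output_tables_written(self, tmp_path):
        rows = subsystem_enrichment({f"r{i}": 2.0 for i in range(5)},
                                    {f"r{i}": "S" for i in range(5)})
        write_enrichment_table(rows, tmp_path / "enr.tsv")
        assert "subsystem" in (tmp_path / "enr.tsv").read_text()
        calls = classify_regulation({"r": (5.0, 5.0)})
        write_regulation_calls(calls, tmp_path / "calls.tsv")
        assert "transcriptional" in (tmp_path / "calls.tsv").read_text()
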