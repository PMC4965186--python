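"""Constraint-based engine: FBA/FVA, knockouts, categorization, sampling,
distribution shifts, essentiality."""

import numpy as np
import pandas as pd
import pytest

import varflux as vf
from varflux.flux_analysis import _categorize_pair

from conftest import enumerate_vertices, make_toy_chain


class TestFBA:
    def test_uptake_bound_forces_objective(self, toy_chain):
        res = vf.fba(toy_chain, "EX_B", "max")
        assert res.ok
        assert res.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_internal_bottleneck(self):
        model = make_toy_chain(r1_ub=4.0)
        res = vf.fba(model, "EX_B", "max")
        assert res.objective_value == pytest.approx(4.0, abs=1e-8)

    def test_infeasible_reported_not_raised(self):
        model = make_toy_chain(r1_lb=20.0, r1_ub=30.0)  # demands more than uptake
        res = vf.fba(model, "EX_B", "max")
        assert res.status == "infeasible"
        assert not res.ok

    def test_objective_matches_vertex_enumeration(self, branched):
        V = enumerate_vertices(branched)
        rids = branched.reaction_ids
        for rid in rids:
            j = rids.index(rid)
            assert vf.fba(branched, rid, "max").objective_value == pytest.approx(
                V[:, j].max(), abs=1e-6
            )
            assert vf.fba(branched, rid, "min").objective_value == pytest.approx(
                V[:, j].min(), abs=1e-6
            )


class TestFVA:
    def test_chain_mass_balance_forces_ranges(self, toy_chain):
        res = vf.fva(toy_chain)
        assert res.range_of("EX_A") == pytest.approx((-10.0, 0.0), abs=1e-8)
        assert res.range_of("R1") == pytest.approx((0.0, 10.0), abs=1e-8)
        assert res.range_of("EX_B") == pytest.approx((0.0, 10.0), abs=1e-8)

    def test_fixed_reaction_keeps_its_bound(self):
        model = make_toy_chain()
        model.reaction("R1").lower_bound = 3.0
        model.reaction("R1").upper_bound = 3.0
        res = vf.fva(model)
        assert res.range_of("R1") == (3.0, 3.0)

    def test_ranges_match_vertex_enumeration(self, branched):
        V = enumerate_vertices(branched)
        res = vf.fva(branched)
        for j, rid in enumerate(branched.reaction_ids):
            lo, hi = res.range_of(rid)
            assert lo == pytest.approx(V[:, j].min(), abs=1e-6)
            assert hi == pytest.approx(V[:, j].max(), abs=1e-6)

    def test_fba_flux_inside_fva_range(self, branched):
        res = vf.fva(branched)
        opt = vf.fba(branched, "EX_B", "max")
        for rid in branched.reaction_ids:
            lo, hi = res.range_of(rid)
            assert lo - 1e-6 <= opt.fluxes[rid] <= hi + 1e-6

    def test_matches_cobra_fva_on_toy_gem(self, toy_gem):
        # independent implementation cross-check on the full toy network
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import flux_variability_analysis

        cm = cobra.Model(toy_gem.model_id)
        mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
                for m in toy_gem.metabolites}
        rxns = []
        for r in toy_gem.reactions:
            cr = cobra.Reaction(r.id, lower_bound=r.lower_bound,
                                upper_bound=r.upper_bound)
            rxns.append(cr)
        cm.add_reactions(rxns)
        for r in toy_gem.reactions:
            cm.reactions.get_by_id(r.id).add_metabolites(
                {mets[m]: c for m, c in r.stoichiometry.items()}
            )
        cobra_fva = flux_variability_analysis(
            cm, fraction_of_optimum=0.0, processes=1
        )
        ours = vf.fva(toy_gem)
        for rid in toy_gem.reaction_ids:
            assert ours.range_of(rid)[0] == pytest.approx(
                cobra_fva.loc[rid, "minimum"], abs=1e-5
            )
            assert ours.range_of(rid)[1] == pytest.approx(
                cobra_fva.loc[rid, "maximum"], abs=1e-5
            )


class TestKnockout:
    def test_single_gene_disables_reaction(self, toy_chain):
        ko = vf.knockout_gene(toy_chain, "g1")
        assert ko.reaction("R1").lower_bound == 0.0
        assert ko.reaction("R1").upper_bound == 0.0

    def test_isozyme_survives(self, toy_gem):
        ko = vf.knockout_gene(toy_gem, "gPFK1")
        r = ko.reaction("PFK_lump")
        assert r.upper_bound > 0

    def test_original_model_untouched(self, toy_chain):
        vf.knockout_gene(toy_chain, "g1")
        assert toy_chain.reaction("R1").upper_bound == 1000.0

    def test_complex_gpr_matches_boolean_oracle(self):
        model = vf.MetabolicModel(
            model_id="gprtest",
            metabolites=[vf.Metabolite("A", "", "c"), vf.Metabolite("B", "", "c")],
            reactions=[
                vf.Reaction("EX_A", {"A": -1}, -10, 0, "", True),
                vf.Reaction("R1", {"A": -1, "B": 1}, 0, 10, "(g1 and g2) or g3"),
                vf.Reaction("EX_B", {"B": -1}, 0, 10, "", True),
            ],
        )
        for gene in ("g1", "g2", "g3"):
            ko = vf.knockout_gene(model, gene)
            states = {gene: False}
            expected_active = (states.get("g1", True) and states.get("g2", True)) or (
                states.get("g3", True)
            )
            disabled = ko.reaction("R1").upper_bound == 0
            assert disabled == (not expected_active)
        ko = vf.knockout_gene(vf.knockout_gene(model, "g3"), "g1")
        assert ko.reaction("R1").upper_bound == 0.0

    def test_unknown_gene_is_noop(self, toy_chain):
        ko = vf.knockout_gene(toy_chain, "not_a_gene")
        assert ko == toy_chain


class TestApplyVariantBounds:
    def test_ratio_one_pins_to_wt_range(self, branched):
        wt = vf.fva(branched)
        out = vf.apply_variant_bounds(branched, "R_AX", 1.0, wt)
        lo, hi = wt.range_of("R_AX")
        r = out.reaction("R_AX")
        assert (r.lower_bound, r.upper_bound) == pytest.approx((lo, hi))

    def test_linear_scaling_both_signs(self):
        wt = vf.FVAResult(
            ranges=pd.DataFrame(
                {"min_flux": [-4.0], "max_flux": [10.0]}, index=["R_YB"]
            )
        )
        model = vf.MetabolicModel(
            model_id="m",
            metabolites=[vf.Metabolite("Y", "", "c"), vf.Metabolite("B", "", "c")],
            reactions=[
                vf.Reaction("EX_Y", {"Y": -1}, -20, 20, "", True),
                vf.Reaction("R_YB", {"Y": -1, "B": 1}, -20, 20),
                vf.Reaction("EX_B", {"B": -1}, -20, 20, "", True),
            ],
        )
        out = vf.apply_variant_bounds(model, "R_YB", 0.5, wt)
        r = out.reaction("R_YB")
        assert (r.lower_bound, r.upper_bound) == pytest.approx((-2.0, 5.0))

    def test_ratio_above_one_clamped_to_physical_bounds(self, branched):
        wt = vf.fva(branched)
        out = vf.apply_variant_bounds(branched, "R_AY", 10.0, wt)
        r = out.reaction("R_AY")
        assert r.upper_bound <= 4.0 + 1e-9  # original physical cap

    def test_missing_reaction_raises(self, branched):
        wt = vf.fva(branched)
        with pytest.raises(KeyError):
            vf.apply_variant_bounds(branched, "nope", 0.5, wt)

    def test_weakened_binding_reduces_methylated_export(self, toy_gem, cfg):
        # downstream secretion capacity must drop strictly when the
        # methylation step loses capacity
        wt = vf.fva(toy_gem)
        ratio = vf.flux_ratio(vf.km_ratio_from_ddg(-1.5))
        mut = vf.apply_variant_bounds(toy_gem, "COMT_A", ratio, wt)
        mut_fva = vf.fva(mut)
        assert (
            mut_fva.range_of("EX_mdopa")[1] < wt.range_of("EX_mdopa")[1]
        )


class TestCategorizeExchanges:
    @pytest.mark.parametrize(
        "wt,mut,expected",
        [
            ((-5, 5), (-5, 5), vf.ExchangeCategory.NO_CHANGE),
            ((-5, 5), (0, 0), vf.ExchangeCategory.INACTIVATION),
            ((0, 0), (2, 5), vf.ExchangeCategory.ACTIVATION),
            ((-5, 5), (1e-7, 5), vf.ExchangeCategory.DIRECTION_FIXED),
            ((-5, 5), (-5, -1), vf.ExchangeCategory.DIRECTION_FIXED),
            # the 40%-of-wild-type-span rule, just below and just above
            ((0, 10), (0, 3.9), vf.ExchangeCategory.MAGNITUDE_CHANGE),
            ((0, 10), (0, 4.1), vf.ExchangeCategory.NO_CHANGE),
        ],
    )
    def test_pairs(self, wt, mut, expected):
        cfg = vf.AnalysisConfig()
        assert _categorize_pair(
            wt, mut, cfg.zero_flux_tol, cfg.span_fraction_threshold
        ) is expected

    def test_self_comparison_is_all_no_change(self, branched, cfg):
        res = vf.fva(branched)
        changes = vf.categorize_exchanges(res, res, cfg)
        assert all(c.category is vf.ExchangeCategory.NO_CHANGE for c in changes)

    def test_ratio_one_yields_all_no_change(self, branched, cfg):
        wt = vf.fva(branched)
        mut = vf.fva(vf.apply_variant_bounds(branched, "R_AX", 1.0, wt))
        changes = vf.categorize_exchanges(wt, mut, cfg)
        assert all(c.category is vf.ExchangeCategory.NO_CHANGE for c in changes)

    def test_mismatched_reaction_sets_raise(self, branched, cfg):
        wt = vf.fva(branched)
        mut = vf.fva(branched, reactions=["EX_A"])
        with pytest.raises(ValueError):
            vf.categorize_exchanges(wt, mut, cfg)


class TestACHRSampler:
    def test_samples_satisfy_constraints(self, toy_gem, cfg):
        samples = vf.achr_sample(toy_gem, 500, cfg)
        diag = vf.validate_samples(toy_gem, samples, cfg)
        assert diag["max_steady_state_residual"] < 1e-8
        assert diag["max_bound_violation"] < 1e-6
        assert diag["n_violations"] == 0

    def test_one_dimensional_marginal_mean(self):
        # single free flux uniform on [0, 10]: mean 5 within 3 standard errors
        model = vf.MetabolicModel(
            model_id="1d",
            metabolites=[vf.Metabolite("A", "", "c")],
            reactions=[
                vf.Reaction("IN", {"A": 1}, 0.0, 10.0),
                vf.Reaction("OUT", {"A": -1}, 0.0, 10.0),
            ],
        )
        cfg = vf.AnalysisConfig(rng_seed=7)
        n = 4000
        samples = vf.achr_sample(model, n, cfg)
        x = samples.samples["IN"].to_numpy()
        se = 10 / np.sqrt(12) / np.sqrt(n)
        # autocorrelation inflates the error of an MCMC mean; allow 10x
        assert abs(x.mean() - 5.0) < 3 * se * 10
        assert x.min() >= -1e-9 and x.max() <= 10 + 1e-9

    def test_deterministic_given_seed(self, toy_gem):
        a = vf.achr_sample(toy_gem, 200, vf.AnalysisConfig(rng_seed=5))
        b = vf.achr_sample(toy_gem, 200, vf.AnalysisConfig(rng_seed=5))
        assert np.array_equal(a.samples.to_numpy(), b.samples.to_numpy())

    def test_different_seeds_differ(self, toy_gem):
        a = vf.achr_sample(toy_gem, 100, vf.AnalysisConfig(rng_seed=5))
        b = vf.achr_sample(toy_gem, 100, vf.AnalysisConfig(rng_seed=6))
        assert not np.array_equal(a.samples.to_numpy(), b.samples.to_numpy())

    def test_degenerate_polytope_single_point(self):
        model = vf.MetabolicModel(
            model_id="fixed",
            metabolites=[vf.Metabolite("A", "", "c")],
            reactions=[
                vf.Reaction("IN", {"A": 1}, 3.0, 3.0),
                vf.Reaction("OUT", {"A": -1}, 3.0, 3.0),
            ],
        )
        samples = vf.achr_sample(model, 50, vf.AnalysisConfig(rng_seed=0))
        assert np.allclose(samples.samples.to_numpy(), 3.0)

    def test_marginal_means_inside_fva_ranges(self, toy_gem, cfg):
        samples = vf.achr_sample(toy_gem, 300, cfg)
        res = vf.fva(toy_gem)
        for rid in toy_gem.reaction_ids:
            lo, hi = res.range_of(rid)
            assert lo - 1e-6 <= samples.samples[rid].mean() <= hi + 1e-6


class TestCompareFluxDistributions:
    def _sets(self, a: np.ndarray, b: np.ndarray):
        cols = [f"r{i}" for i in range(a.shape[1])]
        return (
            vf.FluxSampleSet(pd.DataFrame(a, columns=cols), seed=0, thinning=1),
            vf.FluxSampleSet(pd.DataFrame(b, columns=cols), seed=1, thinning=1),
        )

    def test_identical_columns_not_significant(self):
        x = np.tile(np.linspace(0, 1, 50)[:, None], (1, 3))
        wt, mut = self._sets(x, x.copy())
        df = vf.compare_flux_distributions(wt, mut)
        assert not df["significant"].any()

    def test_identical_constant_columns_p_one(self):
        x = np.full((40, 2), 3.14)
        wt, mut = self._sets(x, x.copy())
        df = vf.compare_flux_distributions(wt, mut)
        assert (df["p"] == 1.0).all()

    def test_type_one_error_rate_under_null(self):
        # iid uniform null, many replicate columns: empirical significance
        # rate stays near the nominal level
        rng = np.random.default_rng(42)
        n_cols, n = 400, 200
        wt, mut = self._sets(
            rng.uniform(size=(n, n_cols)), rng.uniform(size=(n, n_cols))
        )
        df = vf.compare_flux_distributions(wt, mut)
        rate = df["significant"].mean()
        assert 0.02 <= rate <= 0.08

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(100, 2))
        b = rng.normal(size=(100, 2))
        b[:, 1] += 5.0  # five standard deviations
        wt, mut = self._sets(a, b)
        df = vf.compare_flux_distributions(wt, mut)
        assert not df.loc[0, "significant"]
        assert df.loc[1, "significant"]

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(3)
        wt, mut = self._sets(
            rng.uniform(size=(100, 50)), rng.uniform(size=(100, 50))
        )
        plain = vf.compare_flux_distributions(wt, mut)
        bh = vf.compare_flux_distributions(wt, mut, correction="bh")
        assert bh["significant"].sum() <= plain["significant"].sum()

    def test_too_few_samples_rejected(self):
        x = np.zeros((10, 1))
        wt, mut = self._sets(x, x)
        with pytest.raises(ValueError):
            vf.compare_flux_distributions(wt, mut)


class TestEssentialityScreen:
    def test_sole_path_gene_is_important(self, cfg):
        model = make_toy_chain()
        df = vf.essentiality_screen(model, cfg).set_index("gene")
        assert bool(df.loc["g1", "important"])
        assert "EX_B" in df.loc["g1", "changed_exchanges"]

    def test_toy_gem_screen_matches_manual_recomputation(self, toy_gem, cfg):
        screen = vf.essentiality_screen(toy_gem, cfg).set_index("gene")
        exchanges = toy_gem.exchange_ids
        wt = vf.fva(toy_gem, exchanges)
        for gene in toy_gem.genes:
            ko = vf.knockout_gene(toy_gem, gene)
            mut = vf.fva(ko, exchanges)
            changes = vf.categorize_exchanges(wt, mut, cfg, reactions=exchanges)
            expected = any(
                c.category is not vf.ExchangeCategory.NO_CHANGE for c in changes
            )
            assert bool(screen.loc[gene, "important"]) == expected

    def test_isozyme_gene_not_important(self, toy_gem, cfg):
        screen = vf.essentiality_screen(toy_gem, cfg).set_index("gene")
        assert not bool(screen.loc["gPFK1", "important"])
        assert not bool(screen.loc["gPFK2", "important"])

    def test_g6pd_knockout_flags_oxidant_exchange(self, toy_gem, cfg):
        screen = vf.essentiality_screen(toy_gem, cfg).set_index("gene")
        assert bool(screen.loc["gG6PD", "important"])
        changed = screen.loc["gG6PD", "changed_exchanges"].split(";")
        assert "EX_oxid" in changed
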