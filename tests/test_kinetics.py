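"""Kinetic engine: PERC calibration, enzyme modules, steady states, loads."""

import numpy as np
import pandas as pd
import pytest

import varflux as vf
from varflux.kinetics import (
    CalibrationError,
    InfeasibilityCause,
    KineticReaction,
    RateLaw,
    calibrate_percs,
    find_load_reaction,
    simulate,
)


class TestCalibration:
    def test_two_species_arithmetic(self):
        # A <-> B with Keq 2, x = (2, 1), v = 3: kf = 3/(2 - 1/2) = 2
        model = calibrate_percs(
            model_id="ab",
            species={"A": 2.0, "B": 1.0},
            reactions=[
                KineticReaction("R", {"A": -1, "B": 1}, reversible=True, Keq=2.0),
                KineticReaction("IN", {"A": 1}, rate_law=RateLaw.CONSTANT_FLUX),
                KineticReaction("OUT", {"B": -1}),
            ],
            ss_flux={"R": 3.0, "IN": 3.0, "OUT": 3.0},
        )
        r = model.reaction("R")
        assert r.kf == pytest.approx(2.0)
        assert r.kf / r.Keq == pytest.approx(1.0)  # reverse constant

    def test_reference_is_fixed_point_of_ode(self, mini_rbc):
        traj = simulate(mini_rbc, np.linspace(0, 100, 11))
        drift = np.abs(traj.to_numpy() - mini_rbc.initial_state()[None, :]).max()
        assert drift < 1e-6

    def test_equilibrium_zero_flux_gets_free_perc(self):
        model = calibrate_percs(
            model_id="eq",
            species={"A": 2.0, "B": 4.0},
            reactions=[
                KineticReaction("R", {"A": -1, "B": 1}, reversible=True, Keq=2.0)
            ],
            ss_flux={"R": 0.0},
        )
        assert model.reaction("R").kf == 1.0

    def test_zero_disequilibrium_with_flux_is_error(self):
        with pytest.raises(CalibrationError, match="R"):
            calibrate_percs(
                model_id="bad",
                species={"A": 2.0, "B": 4.0},
                reactions=[
                    KineticReaction("R", {"A": -1, "B": 1}, reversible=True, Keq=2.0),
                    KineticReaction("IN", {"A": 1}, rate_law=RateLaw.CONSTANT_FLUX),
                    KineticReaction("OUT", {"B": -1}),
                ],
                ss_flux={"R": 1.0, "IN": 1.0, "OUT": 1.0},
            )

    def test_unbalanced_reference_rejected(self):
        with pytest.raises(CalibrationError, match="steady state"):
            calibrate_percs(
                model_id="bad",
                species={"A": 1.0, "B": 1.0},
                reactions=[
                    KineticReaction("IN", {"A": 1}, rate_law=RateLaw.CONSTANT_FLUX),
                    KineticReaction("OUT", {"B": -1}),
                ],
                ss_flux={"IN": 2.0, "OUT": 1.0},
            )


class TestEnzymeModule:
    def test_insertion_preserves_whole_model_fixed_point(self, mini_rbc):
        from varflux.fixtures import MINI_RBC_MODULE_PARAMS

        reaction, substrate, params = MINI_RBC_MODULE_PARAMS["G6PD"]
        model = vf.insert_enzyme_module(mini_rbc, reaction, params, substrate)
        ref = model.initial_state()
        traj = simulate(model, np.linspace(0, 100, 11))
        rel = np.abs(traj.to_numpy() - ref[None, :]) / np.maximum(ref[None, :], 1e-12)
        assert rel.max() < 1e-6

    def test_saturating_limit_rate(self):
        # S >> Km: module rate ~ kcat * E_total
        model = _isolated_module(km=0.01, s_ref=10.0, kcat=5.0, v_ref=2.0)
        mod = model.enzyme_modules["E1"]
        rate = model.rates(model.initial_state())
        turnover = rate[[r.id for r in model.reactions].index(mod.turnover_id)]
        assert turnover == pytest.approx(mod.kcat * mod.e_total, rel=0.01)

    def test_linear_limit_rate(self):
        # S << Km: module rate ~ (kcat E_total / Km) * S
        model = _isolated_module(km=10.0, s_ref=0.01, kcat=5.0, v_ref=0.002)
        mod = model.enzyme_modules["E1"]
        rate = model.rates(model.initial_state())
        turnover = rate[[r.id for r in model.reactions].index(mod.turnover_id)]
        expected = mod.kcat * mod.e_total / mod.Km * 0.01
        assert turnover == pytest.approx(expected, rel=0.01)

    def test_km_kcat_realized_exactly(self, mini_rbc_modules):
        out = vf.apply_variant_kinetics(mini_rbc_modules, "G6PD", 0.5, 0.2)
        old = mini_rbc_modules.enzyme_modules["G6PD"]
        new = out.enzyme_modules["G6PD"]
        assert new.Km == pytest.approx(0.5 * old.Km, rel=1e-9)
        assert new.kcat == pytest.approx(0.2 * old.kcat, rel=1e-9)

    def test_identity_factors_change_nothing(self, mini_rbc_modules):
        out = vf.apply_variant_kinetics(mini_rbc_modules, "GAPDH", 1.0, 1.0)
        for r_old, r_new in zip(mini_rbc_modules.reactions, out.reactions):
            assert r_new.kf == pytest.approx(r_old.kf, rel=1e-12)

    def test_impossible_enzyme_total_rejected(self, mini_rbc):
        params = vf.MichaelisParameters(Km=0.052, kcat=10.0, enzyme_total=1e-6)
        with pytest.raises(ValueError, match="saturation"):
            vf.insert_enzyme_module(mini_rbc, "G6PD", params, "g6p")

    def test_unknown_enzyme_rejected(self, mini_rbc_modules):
        with pytest.raises(KeyError):
            vf.apply_variant_kinetics(mini_rbc_modules, "nope", 1.0, 1.0)


def _isolated_module(km, s_ref, kcat, v_ref):
    """A minimal source -> enzyme -> sink chain housing one module."""
    base = calibrate_percs(
        model_id="iso",
        species={"S": s_ref, "P": 1.0},
        reactions=[
            KineticReaction("IN", {"S": 1}, rate_law=RateLaw.CONSTANT_FLUX),
            KineticReaction("CAT", {"S": -1, "P": 1}),
            KineticReaction("OUT", {"P": -1}),
        ],
        ss_flux={"IN": v_ref, "CAT": v_ref, "OUT": v_ref},
    )
    return vf.insert_enzyme_module(
        base, "CAT", vf.MichaelisParameters(Km=km, kcat=kcat), "S", enzyme="E1"
    )


class TestSteadyState:
    def test_reference_state_is_feasible_fixed_point(self, mini_rbc_modules, cfg):
        res = vf.steady_state(mini_rbc_modules, cfg)
        assert res.feasible
        ref = mini_rbc_modules.initial_state()
        assert np.abs(res.state.to_numpy() - ref).max() < 1e-6

    def test_moiety_pools_conserved_along_trajectory(self, mini_rbc_modules):
        # kick the system off its fixed point, then integrate
        x0 = mini_rbc_modules.initial_state() * 1.0
        x0[0] *= 1.5  # extra glucose
        traj = simulate(mini_rbc_modules, np.linspace(0, 200, 51), x0=x0)
        drift = vf.check_moiety_conservation(mini_rbc_modules, traj)
        assert max(drift.values()) < 1e-8

    def test_overwhelming_atp_demand_collapses_atp(self, mini_rbc_modules, cfg):
        model = mini_rbc_modules.copy()
        load = model.reaction(find_load_reaction(model, vf.LoadType.ENERGY))
        load.kf = load.kf * 50.0
        res = vf.steady_state(model, cfg)
        assert not res.feasible
        assert res.cause is InfeasibilityCause.SPECIES_COLLAPSE
        # the energy crisis takes down a cofactor or a glycolytic intermediate
        assert res.collapsed_species in ("atp", "g3p", "g6p", "nadph")

    def test_integration_failure_never_raises(self, mini_rbc_modules, cfg):
        model = mini_rbc_modules.copy()
        # absurd demand: guaranteed collapse, must come back as a result
        load = model.reaction(find_load_reaction(model, vf.LoadType.OXIDATIVE))
        load.kf = load.kf * 1e6
        res = vf.steady_state(model, cfg)
        assert res.status is vf.SteadyStateStatus.INFEASIBLE


class TestLoadTitration:
    def test_wt_tolerates_more_than_baseline(self, mini_rbc_modules, cfg):
        res = vf.titrate_load(mini_rbc_modules, vf.LoadType.OXIDATIVE, cfg=cfg)
        assert res.baseline_feasible
        assert res.max_load > 1.0
        # feasibility is monotone along the probed grid
        feas = [f for _, f in res.feasible_grid]
        assert feas == sorted(feas, reverse=True)

    def test_nadph_ratio_non_increasing_with_load(self, mini_rbc_modules, cfg):
        from varflux.kinetics import _scaled_load_model

        lr = find_load_reaction(mini_rbc_modules, vf.LoadType.OXIDATIVE)
        ratios = []
        x = None
        for m in [1.0, 1.5, 2.0]:
            ss = vf.steady_state(_scaled_load_model(mini_rbc_modules, lr, m), cfg, x0=x)
            assert ss.feasible
            x = ss.state.to_numpy()
            ratios.append(ss.state["nadph"] / ss.state["nadp"])
        assert ratios[0] > ratios[1] > ratios[2]

    def test_infeasible_baseline_reports_zero(self, mini_rbc_modules, cfg):
        lethal = vf.apply_variant_kinetics(mini_rbc_modules, "GAPDH", 400.0, 1.0)
        res = vf.titrate_load(lethal, vf.LoadType.OXIDATIVE, cfg=cfg)
        assert not res.baseline_feasible
        assert res.max_load == 0.0

    def test_missing_load_reaction_raises(self, mini_rbc):
        model = mini_rbc.copy()
        model.reactions = [r for r in model.reactions if r.id != "LOAD_NADPH"]
        model.reference_fluxes.pop("LOAD_NADPH")
        with pytest.raises(KeyError):
            vf.titrate_load(model, vf.LoadType.OXIDATIVE)


class TestParameterRecovery:
    def test_grid_search_recovers_true_factors(self, mini_rbc_modules):
        truth = (0.5, 0.3)
        perturbed = vf.apply_variant_kinetics(
            mini_rbc_modules, "G6PD", truth[0], truth[1]
        )
        t_eval = np.linspace(0, 20, 40)
        observed = simulate(perturbed, t_eval)
        grid = np.geomspace(0.2, 2.0, 11)
        km_hat, kcat_hat = vf.infer_kinetic_factors(
            mini_rbc_modules, "G6PD", observed, grid, grid
        )
        assert abs(km_hat - truth[0]) / truth[0] < 0.10
        assert abs(kcat_hat - truth[1]) / truth[1] < 0.10
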