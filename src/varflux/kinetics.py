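"""Mass-action kinetic simulator with a calibrated reference steady state.

The model is built in the MASS (mass-action stoichiometric simulation)
style: every network reaction is an elementary or pseudo-elementary rate
law whose forward constant (PERC) is fixed by the reference flux, the
reference concentrations and the equilibrium constant

    kf = v_ref / (Π x_sub^|coef|  −  Π x_prod^|coef| / Keq),

so the reference state is a fixed point of the ODE system by construction.
Variant enzymes are housed in explicit enzyme modules

    E + S ⇌ ES → E + P      (k1, k-1, k2)

with Km = (k-1 + k2)/k1 and kcat = k2, so Michaelis parameters predicted
from binding free-energy differences can be integrated directly.
Co-substrates of a module's turnover step enter through a bounded
saturation factor g(x) = 2x/(x + x_ref), normalized to 1 at the reference
state: the realized kcat at reference is exactly k2, and turnover stalls as
a co-substrate is exhausted.

Oxidative load is an imposed NADPH→NADP⁺ demand flux and energy load an
ATP→ADP demand flux; both are constant-flux (zero-order) drains scaled as
multiples of the baseline. A demand exceeding what the network can supply
drives the cofactor to collapse, which the steady-state solver reports as
an infeasible state (the model's notion of cell lysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .datamodel import AnalysisConfig, logger
from .thermo import MichaelisParameters


class RateLaw(Enum):
    MASS_ACTION = "mass_action"
    CONSTANT_FLUX = "constant_flux"  # zero-order demand (load drains)
    TURNOVER = "turnover"  # enzyme-module catalytic step


class LoadType(Enum):
    OXIDATIVE = "oxidative"
    ENERGY = "energy"


class SteadyStateStatus(Enum):
    FEASIBLE = "feasible"
    INFEASIBLE = "infeasible"


class InfeasibilityCause(Enum):
    NO_CONVERGENCE = "no_convergence"
    SPECIES_COLLAPSE = "species_collapse"


class CalibrationError(ValueError):
    """Raised when a PERC cannot be determined for a reaction."""


@dataclass
class KineticReaction:
    id: str
    stoichiometry: dict[str, float]
    kf: float | None = None
    Keq: float | None = None
    reversible: bool = False
    rate_law: RateLaw = RateLaw.MASS_ACTION
    #: reference concentrations of turnover-step co-substrates (TURNOVER only)
    cofactor_refs: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "KineticReaction":
        return replace(
            self,
            stoichiometry=dict(self.stoichiometry),
            cofactor_refs=dict(self.cofactor_refs),
        )


@dataclass
class MoietyPool:
    name: str
    species: tuple[str, ...]
    total: float


@dataclass
class EnzymeModule:
    enzyme: str
    reaction_id: str  # id of the original lumped reaction (now the turnover step)
    binding_id: str
    turnover_id: str
    substrate: str
    enzyme_species: str
    complex_species: str
    k1: float
    k_minus1: float
    k2: float
    e_total: float

    @property
    def Km(self) -> float:
        return (self.k_minus1 + self.k2) / self.k1

    @property
    def kcat(self) -> float:
        return self.k2


@dataclass
class KineticModel:
    """Species, calibrated rate constants, moiety pools and enzyme modules."""

    model_id: str
    species: dict[str, float]  # id -> initial (reference) concentration, mM
    reactions: list[KineticReaction]
    pools: list[MoietyPool] = field(default_factory=list)
    enzyme_modules: dict[str, EnzymeModule] = field(default_factory=dict)
    reference_fluxes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for sid, conc in self.species.items():
            if conc < 0:
                raise ValueError(f"negative initial concentration for {sid}")
        known = set(self.species)
        for rxn in self.reactions:
            bad = set(rxn.stoichiometry) - known
            if bad:
                raise ValueError(f"reaction {rxn.id} references unknown species {bad}")
            if rxn.kf is not None and rxn.kf <= 0:
                raise ValueError(f"kf must be > 0 for {rxn.id}")
            if rxn.reversible and (rxn.Keq is None or rxn.Keq <= 0):
                raise ValueError(f"reversible reaction {rxn.id} needs Keq > 0")
        for pool in self.pools:
            total = sum(self.species[s] for s in pool.species)
            if abs(total - pool.total) > 1e-9 * max(1.0, abs(pool.total)):
                raise ValueError(
                    f"moiety pool {pool.name}: declared total {pool.total} != "
                    f"sum of members {total}"
                )
        for mod in self.enzyme_modules.values():
            if mod.Km <= 0:
                raise ValueError(f"enzyme module {mod.enzyme}: Km must be > 0")

    @property
    def species_ids(self) -> list[str]:
        return list(self.species)

    def reaction(self, rid: str) -> KineticReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def copy(self) -> "KineticModel":
        return KineticModel(
            model_id=self.model_id,
            species=dict(self.species),
            reactions=[r.copy() for r in self.reactions],
            pools=[replace(p) for p in self.pools],
            enzyme_modules={k: replace(v) for k, v in self.enzyme_modules.items()},
            reference_fluxes=dict(self.reference_fluxes),
        )

    # -- rate evaluation ----------------------------------------------------
    def _index(self) -> dict[str, int]:
        idx = getattr(self, "_idx_cache", None)
        if idx is None or len(idx) != len(self.species):
            idx = {s: i for i, s in enumerate(self.species)}
            object.__setattr__(self, "_idx_cache", idx)
        return idx

    def _compiled(self):
        """Vectorized rate-law tensors (built lazily, per model instance)."""
        cache = getattr(self, "_rate_cache", None)
        if cache is not None:
            return cache
        idx = self._index()
        n_rxn, n_sp = len(self.reactions), len(self.species)
        kf = np.zeros(n_rxn)
        keq_inv = np.zeros(n_rxn)  # 0 for irreversible: no reverse term
        const = np.zeros(n_rxn, dtype=bool)
        A = np.zeros((n_rxn, n_sp))  # forward mass-action exponents
        B = np.zeros((n_rxn, n_sp))  # reverse mass-action exponents
        G = np.zeros((n_rxn, n_sp))  # saturation-factor exponents (turnover)
        REF = np.ones((n_rxn, n_sp))  # reference conc for saturation factors
        for k, rxn in enumerate(self.reactions):
            kf[k] = rxn.kf if rxn.kf is not None else 0.0
            if rxn.rate_law is RateLaw.CONSTANT_FLUX:
                const[k] = True
                continue
            for sid, coef in rxn.stoichiometry.items():
                j = idx[sid]
                if coef < 0:
                    if rxn.rate_law is RateLaw.TURNOVER and sid in rxn.cofactor_refs:
                        G[k, j] = -coef
                        REF[k, j] = rxn.cofactor_refs[sid]
                    else:
                        A[k, j] = -coef
                elif coef > 0 and rxn.rate_law is RateLaw.MASS_ACTION and rxn.reversible:
                    B[k, j] = coef
            if rxn.rate_law is RateLaw.MASS_ACTION and rxn.reversible:
                keq_inv[k] = 1.0 / rxn.Keq
        cache = (kf, keq_inv, const, A, B, G, REF)
        object.__setattr__(self, "_rate_cache", cache)
        return cache

    def rates(self, x: np.ndarray) -> np.ndarray:
        kf, keq_inv, const, A, B, G, REF = self._compiled()
        xc = np.maximum(np.asarray(x, dtype=float), 0.0)  # clip round-off negatives
        xb = xc[None, :]
        fwd = np.prod(xb**A, axis=1)
        rev = np.prod(xb**B, axis=1)
        g = np.prod((2.0 * xb / (xb + REF)) ** G, axis=1)
        out = kf * (fwd * g - keq_inv * rev)
        out[const] = kf[const]
        return out

    def stoichiometric_matrix(self) -> np.ndarray:
        idx = self._index()
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sid, coef in rxn.stoichiometry.items():
                S[idx[sid], j] = coef
        return S

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.stoichiometric_matrix() @ self.rates(x)

    def initial_state(self) -> np.ndarray:
        return np.array(list(self.species.values()), dtype=float)


@dataclass
class SteadyStateResult:
    status: SteadyStateStatus
    cause: InfeasibilityCause | None = None
    collapsed_species: str | None = None
    state: pd.Series | None = None
    t_reached: float = 0.0

    @property
    def feasible(self) -> bool:
        return self.status is SteadyStateStatus.FEASIBLE


@dataclass
class LoadTitrationResult:
    load_type: LoadType
    max_load: float
    ratio_at_baseline: float | None
    ratio_at_max: float | None
    feasible_grid: list[tuple[float, bool]]
    baseline_feasible: bool = True


# ---------------------------------------------------------------------------
# PERC calibration
# ---------------------------------------------------------------------------

def calibrate_percs(
    model_id: str,
    species: dict[str, float],
    reactions: list[KineticReaction],
    ss_flux: dict[str, float],
    ss_conc: dict[str, float] | None = None,
    pools: list[MoietyPool] | None = None,
    steady_state_tol: float = 1e-8,
) -> KineticModel:
    """Fix every reaction's forward constant from the reference state.

    For a reversible mass-action reaction the PERC is
    ``kf = v_ref / (Π x_sub − Π x_prod / Keq)`` and the reverse constant is
    ``kf / Keq``; irreversible reactions drop the product term; constant-flux
    demands take ``kf = v_ref`` directly. A reaction sitting exactly at
    equilibrium with zero flux keeps a free ``kf = 1`` (flagged); zero
    disequilibrium with nonzero flux is a calibration error naming the
    reaction. The reference must satisfy ``S v_ref = 0``.
    """
    conc = dict(ss_conc) if ss_conc is not None else dict(species)
    cal_reactions = []
    for rxn in reactions:
        if rxn.id not in ss_flux:
            raise CalibrationError(f"no reference flux for reaction {rxn.id}")
    # steady-state consistency of the reference
    tmp = KineticModel(
        model_id="_check",
        species=dict(species),
        reactions=[r.copy() for r in reactions],
        pools=[],
    )
    S = tmp.stoichiometric_matrix()
    v = np.array([ss_flux[r.id] for r in reactions])
    resid = np.abs(S @ v).max()
    if resid > max(steady_state_tol, 1e-9):
        raise CalibrationError(
            f"reference fluxes are not at steady state (|S v| = {resid:.3g})"
        )
    for rxn in reactions:
        r = rxn.copy()
        v_ref = ss_flux[r.id]
        if r.rate_law is RateLaw.CONSTANT_FLUX:
            r.kf = v_ref
        else:
            sub = 1.0
            prod = 1.0
            for sid, coef in r.stoichiometry.items():
                if coef < 0:
                    sub *= conc[sid] ** (-coef)
                else:
                    prod *= conc[sid] ** coef
            diseq = sub - (prod / r.Keq if r.reversible else 0.0)
            if abs(diseq) < 1e-30:
                if abs(v_ref) < 1e-30:
                    logger.warning(
                        "reaction %s at equilibrium with zero flux; kf left free at 1",
                        r.id,
                    )
                    r.kf = 1.0
                else:
                    raise CalibrationError(
                        f"reaction {r.id}: zero mass-action disequilibrium with "
                        f"nonzero reference flux {v_ref}"
                    )
            else:
                kf = v_ref / diseq
                if kf <= 0:
                    raise CalibrationError(
                        f"reaction {r.id}: reference flux {v_ref} opposes the "
                        f"disequilibrium sign (kf = {kf:.3g})"
                    )
                r.kf = kf
        cal_reactions.append(r)
    return KineticModel(
        model_id=model_id,
        species=dict(conc),
        reactions=cal_reactions,
        pools=list(pools or []),
        reference_fluxes=dict(ss_flux),
    )


# ---------------------------------------------------------------------------
# Enzyme modules
# ---------------------------------------------------------------------------

def insert_enzyme_module(
    model: KineticModel,
    reaction: str,
    params: MichaelisParameters,
    substrate: str,
    enzyme: str | None = None,
) -> KineticModel:
    """Replace a lumped reaction with an explicit E + S ⇌ ES → E + P module.

    ``substrate`` is the Michaelis ligand; remaining reactants of the lumped
    reaction become turnover co-substrates (entering through bounded,
    reference-normalized saturation factors). k2 = kcat; k-1 is set to
    4 kcat and k1 to (k-1 + k2)/Km; the enzyme total is chosen (or checked)
    so the module's steady-state rate at the reference concentrations equals
    the reference flux, which leaves the whole-model fixed point unchanged.
    """
    enzyme = enzyme or reaction
    rxn = model.reaction(reaction)  # KeyError if absent
    if substrate not in rxn.stoichiometry or rxn.stoichiometry[substrate] >= 0:
        raise ValueError(
            f"{substrate!r} is not a reactant of {reaction!r}"
        )
    v_ref = model.reference_fluxes.get(reaction)
    if v_ref is None:
        raise ValueError(f"no reference flux recorded for {reaction!r}")
    s_ref = params.substrate_ref if params.substrate_ref is not None else model.species[substrate]
    Km, kcat = params.Km, params.kcat
    saturation = s_ref / (Km + s_ref)
    needed_e_total = v_ref / (kcat * saturation)
    if params.enzyme_total is not None:
        e_total = params.enzyme_total
        required = v_ref / (kcat * e_total)
        if required > saturation + 1e-12:
            raise ValueError(
                f"module for {reaction!r} cannot reproduce the reference flux: "
                f"required saturation {required:.3g} exceeds attainable "
                f"{saturation:.3g} (raise enzyme_total, kcat, or lower Km)"
            )
        if abs(e_total - needed_e_total) > 1e-6 * needed_e_total:
            raise ValueError(
                f"module for {reaction!r}: enzyme_total {e_total:.6g} does not "
                f"reproduce the reference flux at the reference substrate level "
                f"(need {needed_e_total:.6g})"
            )
    else:
        e_total = needed_e_total

    k2 = kcat
    k_minus1 = 4.0 * k2
    k1 = (k_minus1 + k2) / Km
    es_ref = e_total * s_ref / (Km + s_ref)
    e_free = e_total - es_ref
    if e_free <= 0:
        raise ValueError(f"module for {reaction!r}: free enzyme non-positive")

    out = model.copy()
    e_id = f"enz_{enzyme}"
    es_id = f"enz_{enzyme}_complex"
    if e_id in out.species:
        raise ValueError(f"enzyme module for {enzyme!r} already present")
    out.species[e_id] = e_free
    out.species[es_id] = es_ref

    binding_id = f"{reaction}_binding"
    turnover_id = f"{reaction}_turnover"
    # binding: E + S <-> ES, Keq = k1/k_minus1
    binding = KineticReaction(
        id=binding_id,
        stoichiometry={e_id: -1.0, substrate: -1.0, es_id: 1.0},
        kf=k1,
        Keq=k1 / k_minus1,
        reversible=True,
        rate_law=RateLaw.MASS_ACTION,
    )
    # turnover: ES (+ cosubstrates) -> E + products
    stoich = {es_id: -1.0, e_id: 1.0}
    cofactor_refs = {}
    for sid, coef in rxn.stoichiometry.items():
        if sid == substrate:
            continue
        stoich[sid] = stoich.get(sid, 0.0) + coef
        if coef < 0:
            cofactor_refs[sid] = model.species[sid]
    stoich = {s: c for s, c in stoich.items() if c != 0}
    turnover = KineticReaction(
        id=turnover_id,
        stoichiometry=stoich,
        kf=k2,
        rate_law=RateLaw.TURNOVER,
        cofactor_refs=cofactor_refs,
    )
    out.reactions = [r for r in out.reactions if r.id != reaction]
    out.reactions.extend([binding, turnover])
    out.pools.append(MoietyPool(name=f"enzyme_{enzyme}", species=(e_id, es_id), total=e_total))
    out.reference_fluxes[binding_id] = v_ref
    out.reference_fluxes[turnover_id] = v_ref
    out.enzyme_modules[enzyme] = EnzymeModule(
        enzyme=enzyme,
        reaction_id=reaction,
        binding_id=binding_id,
        turnover_id=turnover_id,
        substrate=substrate,
        enzyme_species=e_id,
        complex_species=es_id,
        k1=k1,
        k_minus1=k_minus1,
        k2=k2,
        e_total=e_total,
    )
    out.validate()
    return out


def apply_variant_kinetics(
    model: KineticModel, enzyme: str, km_factor: float, kcat_factor: float
) -> KineticModel:
    """Scale an enzyme module's realized Km and kcat by the given factors.

    k2 is scaled first (kcat), then k1 is recomputed against the unchanged
    k-1 so the realized Km is exactly ``km_factor`` times the old one.
    """
    if km_factor <= 0 or kcat_factor <= 0:
        raise ValueError("factors must be > 0")
    if enzyme not in model.enzyme_modules:
        raise KeyError(f"no enzyme module for {enzyme!r}")
    out = model.copy()
    mod = out.enzyme_modules[enzyme]
    km_old = mod.Km
    k2_new = kcat_factor * mod.k2
    k1_new = (mod.k_minus1 + k2_new) / (km_factor * km_old)
    mod.k2 = k2_new
    mod.k1 = k1_new
    out.enzyme_modules[enzyme] = mod
    binding = out.reaction(mod.binding_id)
    binding.kf = k1_new
    binding.Keq = k1_new / mod.k_minus1
    out.reaction(mod.turnover_id).kf = k2_new
    return out


# ---------------------------------------------------------------------------
# Steady-state solving
# ---------------------------------------------------------------------------

def steady_state(
    model: KineticModel,
    cfg: AnalysisConfig | None = None,
    t_max: float | None = None,
    x0: np.ndarray | None = None,
) -> SteadyStateResult:
    """Integrate the stiff ODE system to a fixed point or declare infeasibility.

    Feasible when ``||dx/dt||_inf < steady_state_tol * max(1, ||x||_inf)``;
    infeasible when a species collapses below the extinction threshold
    (named in the result) or when ``t_max`` passes without convergence.
    Moiety pools are conserved by the stoichiometry; integration failures
    are reported as non-convergence, never raised.

    Because the integrator's own tolerance bounds the attainable residual,
    the relaxation is finished with a Newton polish: once the integrated
    residual is small, the exact fixed point is located by root finding and
    accepted only if it lies next to the integrated state and is
    nonnegative.
    """
    cfg = cfg or AnalysisConfig()
    t_max = t_max if t_max is not None else cfg.t_max
    x = model.initial_state() if x0 is None else np.asarray(x0, dtype=float)
    sids = model.species_ids
    S = model.stoichiometric_matrix()

    def rhs(t, y):
        return S @ model.rates(y)

    # species that start above the extinction threshold are watched for
    # collapse; species legitimately at ~0 initially are not
    watched = np.array([xi > 10 * cfg.extinction_threshold for xi in x])

    def collapse_event(t, y):
        vals = y[watched]
        return (vals.min() - cfg.extinction_threshold) if vals.size else 1.0

    collapse_event.terminal = True
    collapse_event.direction = -1

    # runaway accumulation (e.g. an unconsumed input piling up) has no
    # steady state; cut the integration short once it is unambiguous
    def ceiling_event(t, y):
        return cfg.concentration_ceiling - y.max()

    ceiling_event.terminal = True
    ceiling_event.direction = -1

    t = 0.0
    # geometric checkpoints: fixed points are detected early, divergence late
    checkpoints = []
    tc = min(1.0, t_max)
    while tc < t_max:
        checkpoints.append(tc)
        tc *= 3.0
    checkpoints.append(t_max)

    def polish(y: np.ndarray) -> np.ndarray | None:
        from scipy.optimize import root

        scale = max(1.0, np.abs(y).max())
        sol = root(lambda z: rhs(0.0, z), y, method="hybr", tol=1e-12)
        z = sol.x
        if np.abs(z - y).max() > 1e-4 * scale + 1e-9:
            return None  # jumped to a different fixed point
        if z.min() < -1e-9:
            return None
        z = np.maximum(z, 0.0)
        if np.abs(rhs(0.0, z)).max() >= cfg.steady_state_tol * max(1.0, np.abs(z).max()):
            return None
        return z

    res_norm = np.abs(rhs(0.0, x)).max()
    if res_norm < cfg.steady_state_tol * max(1.0, np.abs(x).max()):
        return SteadyStateResult(
            status=SteadyStateStatus.FEASIBLE,
            state=pd.Series(x, index=sids),
            t_reached=0.0,
        )

    for tc in checkpoints:
        try:
            sol = solve_ivp(
                rhs,
                (t, tc),
                x,
                method="LSODA",
                rtol=1e-8,
                atol=1e-10,
                events=(collapse_event, ceiling_event),
            )
        except Exception:  # integrator blow-up counts as non-convergence
            return SteadyStateResult(
                status=SteadyStateStatus.INFEASIBLE,
                cause=InfeasibilityCause.NO_CONVERGENCE,
                t_reached=t,
            )
        if sol.status == 1:  # a terminal event fired
            y_end = sol.y[:, -1]
            if len(sol.t_events[1]):  # runaway accumulation
                return SteadyStateResult(
                    status=SteadyStateStatus.INFEASIBLE,
                    cause=InfeasibilityCause.NO_CONVERGENCE,
                    state=pd.Series(y_end, index=sids),
                    t_reached=float(sol.t[-1]),
                )
            low = [
                sids[i]
                for i in range(len(sids))
                if watched[i] and y_end[i] <= cfg.extinction_threshold * 1.01
            ]
            return SteadyStateResult(
                status=SteadyStateStatus.INFEASIBLE,
                cause=InfeasibilityCause.SPECIES_COLLAPSE,
                collapsed_species=low[0] if low else None,
                state=pd.Series(y_end, index=sids),
                t_reached=float(sol.t[-1]),
            )
        if not sol.success:
            return SteadyStateResult(
                status=SteadyStateStatus.INFEASIBLE,
                cause=InfeasibilityCause.NO_CONVERGENCE,
                t_reached=t,
            )
        x = sol.y[:, -1]
        t = tc
        scale = max(1.0, np.abs(x).max())
        res_norm = np.abs(rhs(t, x)).max()
        if res_norm < cfg.steady_state_tol * scale:
            return SteadyStateResult(
                status=SteadyStateStatus.FEASIBLE,
                state=pd.Series(x, index=sids),
                t_reached=t,
            )
        if res_norm < 1e-5 * scale:
            polished = polish(x)
            if polished is not None:
                return SteadyStateResult(
                    status=SteadyStateStatus.FEASIBLE,
                    state=pd.Series(polished, index=sids),
                    t_reached=t,
                )
    return SteadyStateResult(
        status=SteadyStateStatus.INFEASIBLE,
        cause=InfeasibilityCause.NO_CONVERGENCE,
        state=pd.Series(x, index=sids),
        t_reached=t,
    )


def simulate(
    model: KineticModel,
    t_eval: np.ndarray,
    x0: np.ndarray | None = None,
) -> pd.DataFrame:
    """Trajectory of all species at the requested time points."""
    x = model.initial_state() if x0 is None else np.asarray(x0, dtype=float)
    S = model.stoichiometric_matrix()
    sol = solve_ivp(
        lambda t, y: S @ model.rates(y),
        (float(t_eval[0]), float(t_eval[-1])),
        x,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
        t_eval=np.asarray(t_eval, dtype=float),
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    return pd.DataFrame(sol.y.T, index=sol.t, columns=model.species_ids)


def check_moiety_conservation(
    model: KineticModel, trajectory: pd.DataFrame
) -> dict[str, float]:
    """Max relative drift of each declared pool total along a trajectory."""
    out = {}
    for pool in model.pools:
        totals = trajectory[list(pool.species)].sum(axis=1).to_numpy()
        out[pool.name] = float(
            np.abs(totals - pool.total).max() / max(abs(pool.total), 1e-300)
        )
    return out


# ---------------------------------------------------------------------------
# Load titration
# ---------------------------------------------------------------------------

_LOAD_SPECIES = {
    LoadType.OXIDATIVE: ("nadph", "nadp"),
    LoadType.ENERGY: ("atp", "adp"),
}


def find_load_reaction(model: KineticModel, load_type: LoadType) -> str:
    """Locate the demand reaction draining the load cofactor.

    The load reaction converts exactly one unit of the reduced/charged
    cofactor into its counterpart and touches nothing else.
    """
    consumed, produced = _LOAD_SPECIES[load_type]
    for rxn in model.reactions:
        if rxn.stoichiometry == {consumed: -1.0, produced: 1.0} or rxn.stoichiometry == {
            consumed: -1, produced: 1
        }:
            return rxn.id
    raise KeyError(f"model has no {load_type.value} load (demand) reaction")


def _scaled_load_model(model: KineticModel, load_rxn: str, multiple: float) -> KineticModel:
    out = model.copy()
    rxn = out.reaction(load_rxn)
    base = model.reaction(load_rxn).kf
    rxn.kf = base * multiple
    return out


def _cofactor_ratio(state: pd.Series | None, load_type: LoadType) -> float | None:
    if state is None:
        return None
    consumed, produced = _LOAD_SPECIES[load_type]
    denom = float(state[produced])
    return float(state[consumed]) / denom if denom > 0 else math.inf


def titrate_load(
    model: KineticModel,
    load_type: LoadType | str,
    grid: list[float] | None = None,
    cfg: AnalysisConfig | None = None,
    bisect_rel_width: float = 1e-2,
) -> LoadTitrationResult:
    """Find the maximum tolerable load multiple along an increasing grid.

    Each grid point scales the load demand rate and solves for a steady
    state; the feasibility boundary between the last feasible and first
    infeasible grid point is refined by bisection to the requested relative
    width. Reports the NADPH/NADP⁺ (or ATP/ADP) ratio at baseline and at
    the maximum tolerated load. An infeasible baseline yields max_load 0.
    """
    cfg = cfg or AnalysisConfig()
    load_type = LoadType(load_type)
    load_rxn = find_load_reaction(model, load_type)
    grid = sorted(grid) if grid else [1.0, 1.1, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 4.0]
    if grid[0] > 1.0:
        grid = [1.0] + grid

    results: dict[float, SteadyStateResult] = {}
    # continuation: each solve starts from the last feasible steady state,
    # mirroring a gradually increasing stress rather than an instantaneous
    # jump from the unstressed reference
    x_start: list[np.ndarray | None] = [None]

    def solve_at(multiple: float) -> SteadyStateResult:
        if multiple not in results:
            res = steady_state(
                _scaled_load_model(model, load_rxn, multiple), cfg, x0=x_start[0]
            )
            if res.feasible:
                x_start[0] = res.state.to_numpy()
            results[multiple] = res
        return results[multiple]

    baseline = solve_at(1.0)
    if not baseline.feasible:
        return LoadTitrationResult(
            load_type=load_type,
            max_load=0.0,
            ratio_at_baseline=None,
            ratio_at_max=None,
            feasible_grid=[(1.0, False)],
            baseline_feasible=False,
        )

    feasible_grid: list[tuple[float, bool]] = []
    last_ok = 1.0
    first_bad: float | None = None
    for m in grid:
        res = solve_at(m)
        feasible_grid.append((m, res.feasible))
        if res.feasible:
            last_ok = max(last_ok, m)
        else:
            first_bad = m
            break
    if first_bad is not None:
        lo, hi = last_ok, first_bad
        while (hi - lo) / lo > bisect_rel_width:
            mid = 0.5 * (lo + hi)
            if solve_at(mid).feasible:
                lo = mid
            else:
                hi = mid
        last_ok = lo
    max_state = solve_at(last_ok).state if solve_at(last_ok).feasible else None
    return LoadTitrationResult(
        load_type=load_type,
        max_load=last_ok,
        ratio_at_baseline=_cofactor_ratio(baseline.state, load_type),
        ratio_at_max=_cofactor_ratio(max_state, load_type),
        feasible_grid=feasible_grid,
    )


# ---------------------------------------------------------------------------
# Parameter recovery by grid search
# ---------------------------------------------------------------------------

def infer_kinetic_factors(
    base_model: KineticModel,
    enzyme: str,
    observed: pd.DataFrame,
    km_grid: np.ndarray,
    kcat_grid: np.ndarray,
) -> tuple[float, float]:
    """Recover (km_factor, kcat_factor) from an observed trajectory.

    Simulates the base model under every candidate factor pair on the grid
    and returns the pair whose trajectory minimizes the summed squared
    relative deviation from the observation (time points taken from the
    observation's index).
    """
    t_eval = observed.index.to_numpy(dtype=float)
    cols = list(observed.columns)
    obs = observed.to_numpy()
    scale = np.maximum(np.abs(obs).max(axis=0), 1e-12)
    best = (float(km_grid[0]), float(kcat_grid[0]))
    best_sse = math.inf
    for km_f in km_grid:
        for kcat_f in kcat_grid:
            candidate = apply_variant_kinetics(base_model, enzyme, float(km_f), float(kcat_f))
            try:
                traj = simulate(candidate, t_eval)
            except RuntimeError:
                continue
            sim = traj[cols].to_numpy()
            if sim.shape != obs.shape:
                continue
            sse = float((((sim - obs) / scale) ** 2).sum())
            if sse < best_sse:
                best_sse = sse
                best = (float(km_f), float(kcat_f))
    return best
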