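"""Bridge between molecular and systems scales.

Interconverts binding free-energy differences (ΔΔG = ΔG_WT − ΔG_mut),
Michaelis-constant ratios, and flux-capacity ratios.

Sign convention: a *negative* ΔΔG means the wild type binds the ligand more
strongly (lower, i.e. more favourable, binding free energy), so the mutant
Km is larger and — other things equal — the mutant carries less flux.
Treating Km as a proxy for the dissociation constant (rapid-equilibrium
assumption),

    ΔΔG = R T ln(Km_wt / Km_mut),   Km_mut / Km_wt = exp(−ΔΔG / (R T)).

The flux-capacity ratio v_mut/v_wt assumes equal substrate and enzyme
concentration in the two states and is evaluated in one of three kinetic
regimes of the Michaelis–Menten rate law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .datamodel import R_KCAL, T_STANDARD


class FluxRegime(Enum):
    """Kinetic regime used to turn (Km, kcat) ratios into a flux ratio.

    SUBSATURATING: [S] << Km, v ∝ kcat/Km (the default reading of "equal
    substrate and enzyme concentration"). SATURATING: [S] >> Km, v ∝ kcat.
    EXPLICIT_S: full Michaelis–Menten quotient at a stated [S]/Km_wt.
    """

    SUBSATURATING = "subsaturating"
    SATURATING = "saturating"
    EXPLICIT_S = "explicit_s"


@dataclass
class BindingPerturbation:
    """A wild-type vs. mutant binding free-energy difference for one ligand.

    Either both absolute ΔG values or the difference ``ddg`` may be given;
    when all three are present they must be consistent.
    """

    enzyme: str
    ligand: str
    dg_wt: float | None = None
    dg_mut: float | None = None
    ddg: float | None = None
    temperature: float = T_STANDARD

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.dg_wt is not None and self.dg_mut is not None:
            implied = self.dg_wt - self.dg_mut
            if self.ddg is None:
                self.ddg = implied
            elif abs(self.ddg - implied) > 1e-9:
                raise ValueError(
                    f"inconsistent ddg for {self.enzyme}/{self.ligand}: "
                    f"stated {self.ddg}, dg_wt - dg_mut = {implied}"
                )
        if self.ddg is None:
            raise ValueError(
                f"{self.enzyme}/{self.ligand}: need ddg or both dg_wt and dg_mut"
            )


@dataclass
class MichaelisParameters:
    """Michaelis–Menten parameters of one enzyme-catalysed reaction."""

    Km: float  # μM on the molecular side; mM inside the kinetic model
    kcat: float  # 1/s (unit-agnostic downstream)
    enzyme_total: float | None = None
    substrate_ref: float | None = None

    def __post_init__(self):
        if self.Km <= 0:
            raise ValueError("Km must be > 0")
        if self.kcat <= 0:
            raise ValueError("kcat must be > 0")


def ddg_from_km(km_wt: float, km_mut: float, T: float = T_STANDARD) -> float:
    """ΔΔG (kcal/mol) implied by a wild-type / mutant Km pair.

    Antisymmetric under argument swap; zero for identical Km.
    """
    if km_wt <= 0 or km_mut <= 0:
        raise ValueError("Km values must be > 0")
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return R_KCAL * T * math.log(km_wt / km_mut)


def km_ratio_from_ddg(ddg: float, T: float = T_STANDARD) -> float:
    """Km_mut / Km_wt implied by ΔΔG; inverse of :func:`ddg_from_km`."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return math.exp(-ddg / (R_KCAL * T))


def flux_ratio(
    km_ratio: float,
    kcat_ratio: float = 1.0,
    regime: FluxRegime = FluxRegime.SUBSATURATING,
    s_over_km_wt: float | None = None,
) -> float:
    """Flux-capacity ratio v_mut / v_wt at equal [S] and [E].

    Monotone decreasing in ``km_ratio`` and increasing in ``kcat_ratio`` in
    every regime; all regimes agree when ``km_ratio`` is 1.
    """
    if km_ratio <= 0 or kcat_ratio <= 0:
        raise ValueError("ratios must be > 0")
    regime = FluxRegime(regime)
    if regime is FluxRegime.SUBSATURATING:
        return kcat_ratio / km_ratio
    if regime is FluxRegime.SATURATING:
        return kcat_ratio
    if s_over_km_wt is None:
        raise ValueError("EXPLICIT_S regime requires s_over_km_wt")
    if s_over_km_wt <= 0:
        raise ValueError("s_over_km_wt must be > 0")
    s = s_over_km_wt
    # MM quotient at equal [S]: (kcat_mut S/(Km_mut+S)) / (kcat_wt S/(Km_wt+S))
    return kcat_ratio * (1.0 + s) / (km_ratio + s)


def perturbations_from_table(df: pd.DataFrame) -> list[BindingPerturbation]:
    out = []
    for _, row in df.iterrows():
        def opt(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        out.append(
            BindingPerturbation(
                enzyme=row["enzyme"],
                ligand=row["ligand"],
                dg_wt=opt("dg_wt"),
                dg_mut=opt("dg_mut"),
                ddg=opt("ddg"),
                temperature=opt("temperature_K") or T_STANDARD,
            )
        )
    return out


def convert_perturbations(
    perturbations: list[BindingPerturbation],
    kcat_ratio: float = 1.0,
    regime: FluxRegime = FluxRegime.SUBSATURATING,
    s_over_km_wt: float | None = None,
) -> pd.DataFrame:
    """Tabulate Km and flux ratios for a list of binding perturbations."""
    rows = []
    for p in perturbations:
        km_r = km_ratio_from_ddg(p.ddg, p.temperature)
        rows.append(
            {
                "enzyme": p.enzyme,
                "ligand": p.ligand,
                "ddg": p.ddg,
                "temperature_K": p.temperature,
                "km_ratio": km_r,
                "flux_ratio": flux_ratio(km_r, kcat_ratio, regime, s_over_km_wt),
            }
        )
    return pd.DataFrame(rows)
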