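"""Constraint-based analysis of the steady-state flux polytope.

FBA and FVA by linear programming (HiGHS), GPR-aware gene knockouts,
variant flux-bound adjustment, exchange-flux change categorization
(activation / inactivation / direction fixed / magnitude change / no
change, with the <40%-of-wild-type-span rule for magnitude calls),
artificial-centering hit-and-run (ACHR) sampling of uniformly distributed
flux states, Kolmogorov–Smirnov testing of per-reaction flux-distribution
shifts, and a per-gene essentiality screen over exchange biomarkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from .datamodel import (
    AnalysisConfig,
    MetabolicModel,
    evaluate_gpr,
    gpr_genes,
    logger,
)


class ExchangeCategory(Enum):
    ACTIVATION = "activation"
    INACTIVATION = "inactivation"
    DIRECTION_FIXED = "direction_fixed"
    MAGNITUDE_CHANGE = "magnitude_change"
    NO_CHANGE = "no_change"


@dataclass
class FBAResult:
    status: str  # optimal / infeasible / unbounded
    objective_value: float | None = None
    fluxes: pd.Series | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux minima and maxima over the steady-state polytope."""

    ranges: pd.DataFrame  # index: reaction id; columns: min_flux, max_flux
    status: str = "optimal"

    def __post_init__(self):
        if self.status == "optimal" and "span" not in self.ranges.columns:
            self.ranges["span"] = self.ranges["max_flux"] - self.ranges["min_flux"]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def range_of(self, reaction: str) -> tuple[float, float]:
        if reaction not in self.ranges.index:
            raise KeyError(f"reaction {reaction!r} not in FVA result")
        row = self.ranges.loc[reaction]
        return float(row["min_flux"]), float(row["max_flux"])


@dataclass
class ExchangeChange:
    reaction: str
    category: ExchangeCategory
    wt_range: tuple[float, float]
    mut_range: tuple[float, float]


@dataclass
class FluxSampleSet:
    """Uniform-ish samples from the flux polytope (rows: samples)."""

    samples: pd.DataFrame
    seed: int
    thinning: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------

def _solve_lp(model: MetabolicModel, c: np.ndarray, sense: str):
    """Optimize c·v over {S v = 0, lb <= v <= ub}. Returns scipy result."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    sign = -1.0 if sense == "max" else 1.0
    return linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )


def fba(model: MetabolicModel, objective: str, sense: str = "max") -> FBAResult:
    """Flux balance analysis: optimize one reaction's flux.

    The returned flux vector is an optimal vertex; the objective value is
    unique even when the vertex is not. Infeasibility and unboundedness are
    reported in the result status rather than raised.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    rids = model.reaction_ids
    if objective not in rids:
        raise KeyError(f"objective reaction {objective!r} not in model")
    c = np.zeros(len(rids))
    c[rids.index(objective)] = 1.0
    res = _solve_lp(model, c, sense)
    if res.status == 2:
        return FBAResult(status="infeasible")
    if res.status == 3:
        return FBAResult(status="unbounded")
    if not res.success:
        return FBAResult(status="infeasible")
    sign = -1.0 if sense == "max" else 1.0
    return FBAResult(
        status="optimal",
        objective_value=float(sign * res.fun),
        fluxes=pd.Series(res.x, index=rids),
    )


def fva(model: MetabolicModel, reactions: list[str] | None = None) -> FVAResult:
    """Flux variability analysis: two LPs (min, max) per reaction."""
    rids = model.reaction_ids
    targets = rids if reactions is None else list(reactions)
    unknown = set(targets) - set(rids)
    if unknown:
        raise KeyError(f"unknown reactions in FVA request: {sorted(unknown)}")
    rows = {}
    for rid in targets:
        rxn = model.reaction(rid)
        if rxn.lower_bound == rxn.upper_bound:
            rows[rid] = (rxn.lower_bound, rxn.upper_bound)
            continue
        lo = fba(model, rid, "min")
        hi = fba(model, rid, "max")
        if not (lo.ok and hi.ok):
            status = lo.status if not lo.ok else hi.status
            return FVAResult(
                ranges=pd.DataFrame(columns=["min_flux", "max_flux"]), status=status
            )
        rows[rid] = (lo.objective_value, hi.objective_value)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["min_flux", "max_flux"])
    df.index.name = "reaction"
    return FVAResult(ranges=df.loc[targets])


# ---------------------------------------------------------------------------
# Knockouts and variant bounds
# ---------------------------------------------------------------------------

def knockout_gene(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Return a copy with every reaction whose GPR fails without ``gene``
    constrained to zero flux. AND requires all genes, OR any; empty GPRs are
    untouched. Knockouts accumulate: previously disabled genes stay off.
    Unknown genes are a warning no-op."""
    out = model.copy()
    if gene not in model.genes:
        logger.warning("knockout of unknown gene %r is a no-op", gene)
        return out
    out.disabled_genes.add(gene)
    states = {g: False for g in out.disabled_genes}
    for rxn in out.reactions:
        if rxn.gpr and not evaluate_gpr(rxn.gpr, states):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def apply_variant_bounds(
    model: MetabolicModel,
    reaction: str,
    ratio: float,
    wt_fva: FVAResult,
) -> MetabolicModel:
    """Scale a reaction's feasible range by a variant flux-capacity ratio.

    The wild-type FVA range is scaled by ``ratio`` symmetrically in both
    flow directions and clamped inside the model's original physical
    bounds; a ratio of 1 pins the bounds to the wild-type FVA range, and a
    ratio > 1 cannot push capacity beyond the model's physical limits.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    lo_wt, hi_wt = wt_fva.range_of(reaction)  # KeyError if absent
    out = model.copy()
    rxn = out.reaction(reaction)
    lo, hi = ratio * lo_wt, ratio * hi_wt
    lo = min(max(lo, rxn.lower_bound), rxn.upper_bound)
    hi = max(min(hi, rxn.upper_bound), rxn.lower_bound)
    if lo > hi:
        lo, hi = hi, lo
    rxn.lower_bound, rxn.upper_bound = lo, hi
    return out


# ---------------------------------------------------------------------------
# Exchange categorization
# ---------------------------------------------------------------------------

def _categorize_pair(
    wt: tuple[float, float],
    mut: tuple[float, float],
    eps: float,
    span_fraction: float,
) -> ExchangeCategory:
    wt_lo, wt_hi = wt
    mut_lo, mut_hi = mut
    if abs(mut_lo - wt_lo) <= eps and abs(mut_hi - wt_hi) <= eps:
        return ExchangeCategory.NO_CHANGE
    wt_active = wt_hi > eps or wt_lo < -eps
    mut_zeroed = -eps <= mut_lo and mut_hi <= eps
    if wt_active and mut_zeroed:
        return ExchangeCategory.INACTIVATION
    wt_zeroed = -eps <= wt_lo and wt_hi <= eps
    mut_forced = mut_lo > eps or mut_hi < -eps
    if wt_zeroed and mut_forced:
        return ExchangeCategory.ACTIVATION
    wt_straddles = wt_lo < -eps and wt_hi > eps
    mut_one_side = mut_lo >= -eps or mut_hi <= eps
    if wt_straddles and mut_one_side:
        return ExchangeCategory.DIRECTION_FIXED
    wt_span = wt_hi - wt_lo
    mut_span = mut_hi - mut_lo
    if mut_span < span_fraction * wt_span:
        return ExchangeCategory.MAGNITUDE_CHANGE
    return ExchangeCategory.NO_CHANGE


def categorize_exchanges(
    wt: FVAResult,
    mut: FVAResult,
    cfg: AnalysisConfig | None = None,
    reactions: list[str] | None = None,
) -> list[ExchangeChange]:
    """Categorize per-reaction FVA range changes between wild type and mutant.

    A mutant span below ``span_fraction_threshold`` (default 40%) of the
    wild-type span is a significant magnitude change; activation,
    inactivation and direction-fixing are detected against the zero-flux
    tolerance to absorb LP round-off. By default all reactions present in
    the wild-type result are categorized; pass ``reactions`` to restrict
    (e.g. to the exchange subset).
    """
    cfg = cfg or AnalysisConfig()
    wt_set = set(wt.ranges.index)
    mut_set = set(mut.ranges.index)
    targets = list(wt.ranges.index) if reactions is None else list(reactions)
    missing = (set(targets) - wt_set) | (set(targets) - mut_set)
    if missing:
        raise ValueError(f"reaction sets mismatch; missing: {sorted(missing)}")
    out = []
    for rid in targets:
        wt_range = wt.range_of(rid)
        mut_range = mut.range_of(rid)
        out.append(
            ExchangeChange(
                reaction=rid,
                category=_categorize_pair(
                    wt_range, mut_range, cfg.zero_flux_tol,
                    cfg.span_fraction_threshold,
                ),
                wt_range=wt_range,
                mut_range=mut_range,
            )
        )
    return out


def changes_to_table(changes: list[ExchangeChange]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reaction": c.reaction,
                "category": c.category.value,
                "wt_min": c.wt_range[0],
                "wt_max": c.wt_range[1],
                "mut_min": c.mut_range[0],
                "mut_max": c.mut_range[1],
            }
            for c in changes
        ]
    )


# ---------------------------------------------------------------------------
# ACHR sampling
# ---------------------------------------------------------------------------

def achr_sample(
    model: MetabolicModel,
    n_samples: int,
    cfg: AnalysisConfig | None = None,
    thinning: int = 10,
) -> FluxSampleSet:
    """Artificial-centering hit-and-run sampling of the flux polytope.

    Warmup points are LP optima of random objectives (at most
    ``min(2 n_reactions, 200)``); each step draws a direction from a random
    previous point toward the running center (a difference of feasible
    points, hence inside the null space of S), line-searches the chord
    inside the bounds with endpoints shrunk to stay strictly interior, and
    draws the next point uniformly on the chord. Every ``thinning``-th point
    is kept. Each kept point is re-projected onto ``S v = 0`` so samples
    satisfy the steady-state constraint to tight tolerance. Fully
    deterministic given ``cfg.rng_seed``.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    rids = model.reaction_ids
    n_rxn = len(rids)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    free = (ub - lb) > cfg.zero_flux_tol

    # Degenerate polytope: all reactions fixed -> the single feasible point.
    if not free.any():
        v = lb.copy()
        samples = np.tile(v, (n_samples, 1))
        return FluxSampleSet(
            samples=pd.DataFrame(samples, columns=rids), seed=cfg.rng_seed,
            thinning=thinning,
        )

    S_pinv = np.linalg.pinv(S)

    def project(x):
        return x - S_pinv @ (S @ x)

    # FVA-style warmup (min and max of each free reaction) guarantees both
    # ends of every free direction; random objectives fill the remainder
    n_warmup = min(2 * n_rxn, 200)
    objectives: list[np.ndarray] = []
    for j in range(n_rxn):
        if not free[j] or len(objectives) + 2 > max(n_warmup, 2):
            continue
        e = np.zeros(n_rxn)
        e[j] = 1.0
        objectives.extend([e, -e])
    while len(objectives) < n_warmup:
        objectives.append(rng.standard_normal(n_rxn))
    warmup = []
    for c in objectives:
        res = _solve_lp(model, c, "max")
        if res.success:
            warmup.append(res.x)
    if not warmup:
        raise RuntimeError("ACHR warmup failed: model is infeasible")
    pts = np.array(warmup)
    center = pts.mean(axis=0)
    center = project(np.clip(center, lb, ub))
    x = center.copy()

    shrink = 1e-9
    samples = np.empty((n_samples, n_rxn))
    kept = 0
    step = 0
    n_store = len(pts)
    max_steps = max(n_samples * thinning * 50, 1000)
    while kept < n_samples and step < max_steps:
        step += 1
        d = pts[rng.integers(n_store)] - center
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d = d / norm
        # chord limits: lb <= x + t d <= ub on free coordinates
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lb - x) / d
            t_hi = (ub - x) / d
        pos = d > 1e-12
        neg = d < -1e-12
        t_max = np.inf
        t_min = -np.inf
        if pos.any():
            t_max = min(t_max, np.min(t_hi[pos]))
            t_min = max(t_min, np.max(t_lo[pos]))
        if neg.any():
            t_max = min(t_max, np.min(t_lo[neg]))
            t_min = max(t_min, np.max(t_hi[neg]))
        if not np.isfinite(t_max) or not np.isfinite(t_min) or t_max <= t_min:
            continue
        width = t_max - t_min
        t = rng.uniform(t_min + shrink * width, t_max - shrink * width)
        x_new = x + t * d
        x_new = project(x_new)
        x_new = np.clip(x_new, lb, ub)
        x = x_new
        # artificial centering: running mean over the whole chain
        center = center + (x - center) / (step + 1)
        if step % thinning == 0:
            samples[kept] = x
            kept += 1
    if kept < n_samples:
        raise RuntimeError("ACHR failed to collect the requested samples")
    return FluxSampleSet(
        samples=pd.DataFrame(samples, columns=rids), seed=cfg.rng_seed,
        thinning=thinning,
    )


def validate_samples(
    model: MetabolicModel, sample_set: FluxSampleSet, cfg: AnalysisConfig | None = None
) -> dict:
    """Constraint-violation diagnostics for a sample set."""
    cfg = cfg or AnalysisConfig()
    X = sample_set.samples.to_numpy()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    steady = np.abs(S @ X.T).max(axis=0)
    below = (lb[None, :] - X).max(axis=1)
    above = (X - ub[None, :]).max(axis=1)
    return {
        "max_steady_state_residual": float(steady.max()),
        "max_bound_violation": float(np.maximum(below, above).max()),
        "n_violations": int(
            (
                (steady > cfg.steady_state_tol)
                | (np.maximum(below, above) > cfg.zero_flux_tol)
            ).sum()
        ),
    }


# ---------------------------------------------------------------------------
# Distribution-shift testing
# ---------------------------------------------------------------------------

def compare_flux_distributions(
    wt: FluxSampleSet,
    mut: FluxSampleSet,
    cfg: AnalysisConfig | None = None,
    correction: str | None = None,
) -> pd.DataFrame:
    """Two-sample Kolmogorov–Smirnov test per reaction column.

    ``significant`` is ``p < alpha``; no multiplicity correction by default
    (a plain 0.05 rule), with optional Benjamini–Hochberg via
    ``correction='bh'``. Identical constant columns get p = 1.
    """
    cfg = cfg or AnalysisConfig()
    if list(wt.samples.columns) != list(mut.samples.columns):
        raise ValueError("sample sets have mismatched reaction columns")
    if len(wt.samples) < 30 or len(mut.samples) < 30:
        raise ValueError("need at least 30 samples per set")
    rows = []
    for rid in wt.samples.columns:
        a = wt.samples[rid].to_numpy()
        b = mut.samples[rid].to_numpy()
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            stat, p = 0.0, 1.0
        else:
            res = stats.ks_2samp(a, b, method="asymp")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"reaction": rid, "statistic": stat, "p": p})
    df = pd.DataFrame(rows)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < cfg.alpha
    else:
        df["significant"] = df["p"] < cfg.alpha
    return df


# ---------------------------------------------------------------------------
# Essentiality screen
# ---------------------------------------------------------------------------

def essentiality_screen(
    model: MetabolicModel, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Knock out every gene; flag the gene important if any exchange-flux
    range changes category relative to wild type.

    An infeasible knockout model is itself an important systemic change and
    is reported as such.
    """
    cfg = cfg or AnalysisConfig()
    exchanges = model.exchange_ids
    wt = fva(model, exchanges)
    if not wt.ok:
        raise RuntimeError("wild-type model is infeasible")
    rows = []
    for gene in sorted(model.genes):
        ko = knockout_gene(model, gene)
        mut = fva(ko, exchanges)
        if not mut.ok:
            rows.append(
                {"gene": gene, "important": True, "changed_exchanges": "<infeasible>"}
            )
            continue
        changes = categorize_exchanges(wt, mut, cfg, reactions=exchanges)
        changed = [
            c.reaction for c in changes if c.category is not ExchangeCategory.NO_CHANGE
        ]
        rows.append(
            {
                "gene": gene,
                "important": bool(changed),
                "changed_exchanges": ";".join(changed),
            }
        )
    return pd.DataFrame(rows)
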