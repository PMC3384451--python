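"""The analysis pipeline over crowding-coefficient ensembles.

Every experiment follows the same scheme: draw a random set of per-reaction
crowding coefficients, solve the crowding-constrained flux balance problem,
and record growth, yield, excretion pattern and — along a glucose scan —
how much the high-yield pathway is throttled at maximal growth.  Repeating
this over many draws turns single-point predictions into distributions,
which is where the switching phenotypes (bimodal yield distributions,
full vs. partial shutdown of respiration) become visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    FluxSolution,
    SolverConfig,
    compute_yield,
    solve_fbawmc,
)
from .crowding import CrowdingAssignment, CrowdingDistribution, sample_crowding
from .model_io import MetabolicModel, Metabolite, Reaction

__all__ = [
    "GrowthCurvePoint",
    "GrowthCurve",
    "SwitchStatistics",
    "EnsembleSample",
    "EnsembleResult",
    "ObservedGrowth",
    "LOW_YIELD_THRESHOLD",
    "classify_low_yield",
    "growth_curve",
    "flux_decrease_statistic",
    "excretion_profile",
    "run_ensemble",
    "knockout_exchange",
    "add_overexpression",
    "nox_reaction",
    "aox_reaction",
    "fit_vprot",
    "count_metabolic_modes",
    "derive_seeds",
]

#: Growth yields strictly below this (gDW per g glucose) count as
#: low-yield metabolism.
LOW_YIELD_THRESHOLD = 0.3


def classify_low_yield(growth_yield: float, threshold: float = LOW_YIELD_THRESHOLD) -> bool:
    """True iff the yield is strictly below the low-yield threshold."""
    if growth_yield < 0:
        raise ValueError(f"negative yield {growth_yield}")
    return growth_yield < threshold


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible per-sample seeds (each < 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# growth curves and the switch statistic
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurvePoint:
    glucose_bound: float
    growth_rate: float
    growth_yield: float
    reporter_fluxes: dict[str, float] = field(default_factory=dict)
    feasible: bool = True


@dataclass
class GrowthCurve:
    points: list[GrowthCurvePoint]
    crowding_seed: int = 0

    def reporter_series(self, reporter: str) -> np.ndarray:
        """Magnitude of the reporter flux along the curve (uptake or efflux)."""
        return np.array([abs(p.reporter_fluxes[reporter]) for p in self.points])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {
                "glucose_bound": p.glucose_bound,
                "growth_rate": p.growth_rate,
                "growth_yield": p.growth_yield,
                "feasible": p.feasible,
            }
            row.update({f"flux_{k}": v for k, v in p.reporter_fluxes.items()})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SwitchStatistics:
    """How far the high-yield reporter flux drops at maximal growth.

    ``flux_decrease`` = (max reporter flux - reporter flux at max growth)
    / max reporter flux, in [0, 1]: 0 means the high-yield pathway stays
    fully active (overflow-like behavior), 1 means a complete shutdown
    (full metabolic switch).
    """

    flux_decrease: float
    reporter: str
    max_reporter_flux: float
    reporter_flux_at_max_growth: float
    reporter_active: bool = True


_DEFAULT_REPORTERS = ("EX_o2", "EX_ac", "EX_waste", "EX_lac", "EX_etoh", "EX_for")


def growth_curve(
    model: MetabolicModel,
    crowding: CrowdingAssignment,
    config: SolverConfig,
    glucose_grid: Sequence[float],
    glucose_exchange: str = "EX_glc",
    reporter_ids: Sequence[str] | None = None,
) -> GrowthCurve:
    """One crowding-constrained solve per glucose uptake bound.

    Infeasible points are recorded with zero growth and ``feasible=False``.
    """
    grid = list(glucose_grid)
    if not grid:
        raise ValueError("empty glucose grid")
    if any(b > a for a, b in zip(grid[1:], grid)):
        raise ValueError("glucose grid must be ascending")
    if reporter_ids is None:
        present = set(model.reaction_ids)
        reporter_ids = [r for r in _DEFAULT_REPORTERS if r in present]
    points = []
    for bound in grid:
        m = model.copy()
        m.set_uptake_bound(glucose_exchange, bound)
        sol = solve_fbawmc(m, crowding, config)
        if sol.optimal:
            y = compute_yield(sol, m, glucose_exchange)
            points.append(
                GrowthCurvePoint(
                    glucose_bound=bound,
                    growth_rate=sol.growth_rate,
                    growth_yield=y,
                    reporter_fluxes={r: sol.fluxes[r] for r in reporter_ids},
                    feasible=True,
                )
            )
        else:
            points.append(
                GrowthCurvePoint(
                    glucose_bound=bound,
                    growth_rate=0.0,
                    growth_yield=0.0,
                    reporter_fluxes={r: 0.0 for r in reporter_ids},
                    feasible=False,
                )
            )
    return GrowthCurve(points=points, crowding_seed=crowding.seed)


def flux_decrease_statistic(
    curve: GrowthCurve,
    reporter: str,
    tol: float = 1e-9,
) -> SwitchStatistics:
    """Relative drop of the reporter flux at the point of maximal growth.

    The statistic is evaluated at the maximal-growth point of the scan
    (the last such point when growth plateaus, i.e. the crowding-limited
    regime).  A reporter that never carries flux gives 0 with
    ``reporter_active=False``.
    """
    series = curve.reporter_series(reporter)
    growth = np.array([p.growth_rate for p in curve.points])
    mu_max = growth.max()
    at_max = int(np.flatnonzero(growth >= mu_max - tol * max(1.0, abs(mu_max)))[-1])
    peak = float(series.max())
    if peak <= tol:
        return SwitchStatistics(0.0, reporter, peak, float(series[at_max]), reporter_active=False)
    dec = (peak - float(series[at_max])) / peak
    return SwitchStatistics(float(dec), reporter, peak, float(series[at_max]))


# ---------------------------------------------------------------------------
# excretion classification
# ---------------------------------------------------------------------------

def excretion_profile(
    solution: FluxSolution,
    tol: float = 1e-6,
    acetate_exchange: str = "EX_ac",
    lactate_exchange: str | None = "EX_lac",
    ethanol_exchange: str | None = "EX_etoh",
) -> str:
    """Classify fermentation products: acetate vs. NADH-consuming waste.

    Returns ``acetate_only``, ``lactate_or_ethanol``, ``mixed`` or ``none``.
    Missing exchanges count as zero flux; only positive (excreting) flux
    above ``tol`` counts.
    """
    def efflux(rid: str | None) -> float:
        if rid is None:
            return 0.0
        return max(0.0, solution.fluxes.get(rid, 0.0))

    ac = efflux(acetate_exchange) > tol
    waste = efflux(lactate_exchange) > tol or efflux(ethanol_exchange) > tol
    if ac and waste:
        return "mixed"
    if ac:
        return "acetate_only"
    if waste:
        return "lactate_or_ethanol"
    return "none"


# ---------------------------------------------------------------------------
# model edits: knockouts and overexpression
# ---------------------------------------------------------------------------

def knockout_exchange(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Copy of the model with the reaction's efflux blocked (upper bound 0)."""
    out = model.copy()
    r = out.reaction(reaction_id)
    r.upper_bound = min(r.upper_bound, 0.0)
    r.lower_bound = min(r.lower_bound, r.upper_bound)
    return out


def nox_reaction(
    nadh: str = "nadh", o2: str = "o2", rid: str = "NOX", big_bound: float = 1e8
) -> Reaction:
    """Water-forming NADH oxidase: NADH + 0.5 O2 -> NAD+ (no ATP)."""
    return Reaction(rid, {nadh: -1.0, o2: -0.5}, 0.0, big_bound, enzymatic=True)


def aox_reaction(
    nadh: str = "nadh", o2: str = "o2", rid: str = "AOX", big_bound: float = 1e8
) -> Reaction:
    """Alternative oxidase: reoxidizes NADH-derived electrons on O2 without
    proton pumping, i.e. the same net redox chemistry as NOX at zero ATP."""
    return Reaction(rid, {nadh: -1.0, o2: -0.5}, 0.0, big_bound, enzymatic=True)


def add_overexpression(
    model: MetabolicModel, reaction_spec: Reaction, min_flux: float = 0.0
) -> MetabolicModel:
    """Append a reaction and force at least ``min_flux`` through it.

    Mimics overexpression of an enzyme (e.g. NOX): the new reaction is
    added with its lower bound raised to ``min_flux``.  Metabolites the
    spec references but the model lacks are added.  A ``min_flux`` that
    makes the model infeasible is reported by the downstream solve, not
    here.
    """
    if min_flux < 0:
        raise ValueError("min_flux must be >= 0")
    out = model.copy()
    if reaction_spec.id in set(out.reaction_ids):
        raise ValueError(f"reaction {reaction_spec.id!r} already in model")
    known = set(out.metabolite_ids)
    for met in reaction_spec.stoichiometry:
        if met not in known:
            out.metabolites.append(Metabolite(met))
    new = replace(
        reaction_spec,
        stoichiometry=dict(reaction_spec.stoichiometry),
        lower_bound=max(reaction_spec.lower_bound, min_flux),
    )
    out.reactions.append(new)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSample:
    seed: int
    growth_rate: float
    glucose_uptake: float
    growth_yield: float
    low_yield: bool
    excretion_class: str
    status: str
    switch: SwitchStatistics | None = None


@dataclass
class EnsembleResult:
    samples: list[EnsembleSample]
    v_prot: float
    model_name: str
    master_seed: int

    @property
    def yields(self) -> np.ndarray:
        return np.array([s.growth_yield for s in self.samples])

    @property
    def low_yield_fraction(self) -> float:
        return float(np.mean([s.low_yield for s in self.samples]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "seed": s.seed,
                "growth_rate": s.growth_rate,
                "glucose_uptake": s.glucose_uptake,
                "growth_yield": s.growth_yield,
                "low_yield": s.low_yield,
                "excretion_class": s.excretion_class,
                "status": s.status,
            }
            if s.switch is not None:
                row["flux_decrease"] = s.switch.flux_decrease
                row["reporter"] = s.switch.reporter
            rows.append(row)
        return pd.DataFrame(rows)


def run_ensemble(
    model: MetabolicModel,
    dist: CrowdingDistribution,
    config: SolverConfig,
    n: int,
    master_seed: int,
    glucose_exchange: str = "EX_glc",
    acetate_exchange: str = "EX_ac",
    lactate_exchange: str | None = "EX_lac",
    ethanol_exchange: str | None = "EX_etoh",
    glucose_grid: Sequence[float] | None = None,
    reporter: str | None = None,
) -> EnsembleResult:
    """n independent crowding draws, each solved at unconstrained glucose.

    The glucose uptake bound is lifted to ``config.big_bound`` so the
    crowding constraint, not glucose supply, limits growth; the recorded
    yield is then the maximal-growth-rate yield for that coefficient draw.
    When ``glucose_grid`` and ``reporter`` are given, a full glucose scan is
    run per sample and the flux-decrease switch statistic is recorded.
    Fully reproducible from ``master_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if lactate_exchange not in model.reaction_ids and lactate_exchange is not None:
        # fall back to a lumped waste exchange when the model has one
        lactate_exchange = "EX_waste" if "EX_waste" in model.reaction_ids else None
    unconstrained = model.copy()
    unconstrained.set_uptake_bound(glucose_exchange, config.big_bound)
    samples = []
    for seed in derive_seeds(master_seed, n):
        assignment = sample_crowding(model, dist, seed)
        sol = solve_fbawmc(unconstrained, assignment, config)
        if sol.optimal:
            y = compute_yield(sol, unconstrained, glucose_exchange)
            uptake = -sol.fluxes[glucose_exchange]
            cls = excretion_profile(
                sol,
                acetate_exchange=acetate_exchange,
                lactate_exchange=lactate_exchange,
                ethanol_exchange=ethanol_exchange,
            )
            switch = None
            if glucose_grid is not None and reporter is not None:
                curve = growth_curve(
                    model, assignment, config, glucose_grid, glucose_exchange
                )
                switch = flux_decrease_statistic(curve, reporter)
            samples.append(
                EnsembleSample(
                    seed=seed,
                    growth_rate=sol.growth_rate,
                    glucose_uptake=float(uptake),
                    growth_yield=float(y),
                    low_yield=classify_low_yield(y),
                    excretion_class=cls,
                    status=sol.status,
                    switch=switch,
                )
            )
        else:
            samples.append(
                EnsembleSample(
                    seed=seed,
                    growth_rate=0.0,
                    glucose_uptake=0.0,
                    growth_yield=0.0,
                    low_yield=True,
                    excretion_class="none",
                    status=sol.status,
                )
            )
    return EnsembleResult(
        samples=samples,
        v_prot=config.v_prot,
        model_name=model.name,
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# V_prot fitting
# ---------------------------------------------------------------------------

@dataclass
class ObservedGrowth:
    mu_max_obs: float
    gup_max_obs: float

    def validate(self) -> None:
        if self.mu_max_obs <= 0 or self.gup_max_obs <= 0:
            raise ValueError("observed growth and uptake must be > 0")


def fit_vprot(
    model: MetabolicModel,
    dist: CrowdingDistribution,
    observed: ObservedGrowth,
    grid: Sequence[float],
    n: int,
    master_seed: int,
    config: SolverConfig | None = None,
    glucose_exchange: str = "EX_glc",
    return_profile: bool = False,
):
    """Grid search for the crowding budget matching observed growth physiology.

    For each candidate V_prot an ensemble of ``n`` crowding draws is run at
    unconstrained glucose; the fitted maximal growth rate and glucose
    uptake are the ensemble means, and the returned V_prot minimizes

        ((mu_fit - mu_obs)/mu_obs)^2 + ((gup_fit - gup_obs)/gup_obs)^2.

    The same master seed (hence the same coefficient draws) is used at
    every grid value, so the criterion profile is not jittered by sampling
    noise across the grid.  Ties go to the smallest V_prot.
    """
    observed.validate()
    grid = sorted(grid)
    if not grid:
        raise ValueError("empty V_prot grid")
    base = config or SolverConfig()
    best_v, best_crit = None, math.inf
    rows = []
    for v in grid:
        ens = run_ensemble(
            model, dist, base.with_v_prot(v), n, master_seed, glucose_exchange
        )
        feasible = [s for s in ens.samples if s.status == "optimal"]
        if not feasible:
            rows.append({"v_prot": v, "criterion": math.inf})
            continue
        mu_fit = float(np.mean([s.growth_rate for s in feasible]))
        gup_fit = float(np.mean([s.glucose_uptake for s in feasible]))
        crit = ((mu_fit - observed.mu_max_obs) / observed.mu_max_obs) ** 2 + (
            (gup_fit - observed.gup_max_obs) / observed.gup_max_obs
        ) ** 2
        rows.append(
            {"v_prot": v, "criterion": crit, "mu_fit": mu_fit, "gup_fit": gup_fit}
        )
        if crit < best_crit:
            best_v, best_crit = v, crit
    if best_v is None:
        raise ValueError("all V_prot grid values were infeasible")
    if return_profile:
        return best_v, pd.DataFrame(rows)
    return best_v


# ---------------------------------------------------------------------------
# mode counting
# ---------------------------------------------------------------------------

def count_metabolic_modes(
    ensemble: EnsembleResult | Sequence[float] | np.ndarray,
    rel_tol: float = 0.01,
    min_freq: float = 0.01,
) -> int:
    """Number of distinct growth-yield modes in an ensemble.

    Yields are clustered by single linkage: sorted values are split
    wherever the gap between neighbours exceeds ``rel_tol`` relative to
    the larger neighbour.  Clusters holding fewer than ``min_freq`` of the
    samples are discarded as LP noise.  Under one binding crowding
    constraint each optimum sits on a single elementary mode, so this
    count estimates how many distinct modes win across coefficient draws.
    """
    values = ensemble.yields if isinstance(ensemble, EnsembleResult) else np.asarray(ensemble, float)
    if values.size == 0:
        raise ValueError("empty ensemble")
    v = np.sort(values)
    clusters: list[int] = [1]
    for prev, cur in zip(v, v[1:]):
        scale = max(abs(prev), abs(cur), 1e-12)
        if (cur - prev) > rel_tol * scale:
            clusters.append(1)
        else:
            clusters[-1] += 1
    min_count = min_freq * values.size
    return int(sum(1 for c in clusters if c >= min_count))
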