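"""Linear-programming core: flux balance analysis with and without crowding.

Plain FBA maximizes the objective flux over the steady-state cone
S.f = 0 subject to per-reaction bounds.  The crowding-constrained variant
adds a single coupling constraint

    sum_i c_i |f_i|  <=  V_prot,

limiting the total enzyme volume the flux distribution requires to the
fraction ``V_prot`` of cell volume available to metabolic enzymes.  The
absolute value is realized by splitting every reversible reaction into two
non-negative directional variables that share the same coefficient, so a
reverse flux can never subsidize the crowding budget.

Both solves go through scipy's HiGHS backend.  Because the optimal flux
vector of an LP need not be unique, an optional secondary optimization
("min_crowding_usage" tie-break) re-solves at the fixed optimal objective
while minimizing total crowding usage, which makes reported flux vectors
reproducible and strips futile directional cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .crowding import CrowdingAssignment
from .model_io import MetabolicModel

__all__ = [
    "SolverConfig",
    "FluxSolution",
    "CrowdingCoverageError",
    "MassBalanceError",
    "solve_fba",
    "solve_fbawmc",
    "compute_yield",
    "GLUCOSE_MOLAR_MASS",
]

#: Molar mass of glucose in g/mmol, used to express yields per gram.
GLUCOSE_MOLAR_MASS = 0.18016


class CrowdingCoverageError(KeyError):
    """A model reaction has no crowding coefficient in the assignment."""


class MassBalanceError(ValueError):
    """Growth without substrate uptake: the solution violates mass balance."""


@dataclass
class SolverConfig:
    """Solver parameters.

    ``v_prot`` is the crowding budget (volume fraction, 0 < v_prot <= 1;
    organism fits land around 0.15-0.2, and 0.2 is the default when no fit
    is requested).  ``big_bound`` is the sentinel flux used for
    "unconstrained" exchanges such as unlimited glucose influx; it must
    exceed V_prot divided by the smallest crowding coefficient in play, so
    that the crowding constraint, never the sentinel, limits the optimum.
    """

    v_prot: float = 0.2
    feasibility_tolerance: float = 1e-9
    objective_tolerance: float = 1e-6
    tie_break: str = "min_crowding_usage"  # or "none"
    big_bound: float = 1e8

    def __post_init__(self) -> None:
        if not 0.0 < self.v_prot <= 1.0:
            raise ValueError(f"v_prot must be in (0, 1], got {self.v_prot}")
        if self.feasibility_tolerance <= 0 or self.objective_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.tie_break not in ("none", "min_crowding_usage"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")

    def with_v_prot(self, v_prot: float) -> "SolverConfig":
        return replace(self, v_prot=v_prot)


@dataclass
class FluxSolution:
    fluxes: dict[str, float] = field(default_factory=dict)
    growth_rate: float = float("nan")
    crowding_usage: float = float("nan")
    status: str = "infeasible"  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------


class _SplitLP:
    """Directional-split LP data for one model."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rids = model.reaction_ids
        met_index = {m.id: j for j, m in enumerate(model.metabolites)}
        n_mets = len(model.metabolites)

        cols: list[sp.coo_matrix] = []
        self.var_reaction: list[int] = []  # reaction index per variable
        self.var_sign: list[float] = []  # +1 forward, -1 reverse
        self.bounds: list[tuple[float, float]] = []
        rows, col_ids, data = [], [], []
        col = 0
        for i, r in enumerate(model.reactions):
            # forward direction
            self.var_reaction.append(i)
            self.var_sign.append(1.0)
            self.bounds.append((max(0.0, r.lower_bound), max(0.0, r.upper_bound)))
            for met, coef in r.stoichiometry.items():
                rows.append(met_index[met])
                col_ids.append(col)
                data.append(coef)
            col += 1
            if r.lower_bound < 0:
                # reverse direction
                self.var_reaction.append(i)
                self.var_sign.append(-1.0)
                self.bounds.append((max(0.0, -r.upper_bound), -r.lower_bound))
                for met, coef in r.stoichiometry.items():
                    rows.append(met_index[met])
                    col_ids.append(col)
                    data.append(-coef)
                col += 1
        self.n_vars = col
        self.A_eq = sp.csr_matrix(
            (data, (rows, col_ids)), shape=(n_mets, self.n_vars)
        )
        self.b_eq = np.zeros(n_mets)
        obj_idx = self.rids.index(model.objective_reaction)
        self.obj_vec = np.zeros(self.n_vars)
        for v, (ri, sign) in enumerate(zip(self.var_reaction, self.var_sign)):
            if ri == obj_idx:
                self.obj_vec[v] = sign

    def cost_vector(self, coefficients: Mapping[str, float]) -> np.ndarray:
        c = np.empty(self.n_vars)
        per_reaction = []
        for rid in self.rids:
            try:
                per_reaction.append(float(coefficients[rid]))
            except KeyError as exc:
                raise CrowdingCoverageError(
                    f"no crowding coefficient for reaction {rid!r}"
                ) from exc
        for v, ri in enumerate(self.var_reaction):
            c[v] = per_reaction[ri]
        return c

    def net_fluxes(self, x: np.ndarray) -> dict[str, float]:
        net = np.zeros(len(self.rids))
        for v, (ri, sign) in enumerate(zip(self.var_reaction, self.var_sign)):
            net[ri] += sign * x[v]
        return dict(zip(self.rids, net.tolist()))


def _linprog(c, lp: _SplitLP, A_ub=None, b_ub=None, A_eq=None, b_eq=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=lp.A_eq if A_eq is None else A_eq,
        b_eq=lp.b_eq if b_eq is None else b_eq,
        bounds=lp.bounds,
        method="highs",
    )


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(
    model: MetabolicModel,
    config: SolverConfig,
    crowding: CrowdingAssignment | None,
) -> FluxSolution:
    lp = _SplitLP(model)
    A_ub = b_ub = None
    cost = None
    if crowding is not None:
        cost = lp.cost_vector(crowding.coefficients)
        A_ub = sp.csr_matrix(cost.reshape(1, -1))
        b_ub = np.array([config.v_prot])
    res = _linprog(-lp.obj_vec, lp, A_ub, b_ub)
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxSolution(status=status)
    mu = float(lp.obj_vec @ res.x)
    x = res.x
    if config.tie_break == "min_crowding_usage" and cost is not None:
        # pin the objective at its optimum (equality), minimize crowding usage
        A_eq2 = sp.vstack([lp.A_eq, sp.csr_matrix(lp.obj_vec.reshape(1, -1))])
        b_eq2 = np.concatenate([lp.b_eq, [mu]])
        res2 = _linprog(cost, lp, A_ub, b_ub, A_eq=A_eq2, b_eq=b_eq2)
        if res2.status == 0:
            x = res2.x
    fluxes = lp.net_fluxes(x)
    if cost is not None:
        usage = float(
            sum(
                crowding.coefficients[rid] * abs(f)
                for rid, f in fluxes.items()
            )
        )
    else:
        usage = float("nan")
    return FluxSolution(fluxes=fluxes, growth_rate=mu, crowding_usage=usage, status="optimal")


def solve_fba(model: MetabolicModel, config: SolverConfig | None = None) -> FluxSolution:
    """Maximize the objective flux subject to S.f = 0 and flux bounds."""
    return _solve(model, config or SolverConfig(), None)


def solve_fbawmc(
    model: MetabolicModel,
    crowding: CrowdingAssignment,
    config: SolverConfig | None = None,
) -> FluxSolution:
    """FBA under the additional crowding constraint sum c_i |f_i| <= v_prot."""
    return _solve(model, config or SolverConfig(), crowding)


def compute_yield(
    solution: FluxSolution,
    model: MetabolicModel,
    glucose_exchange: str = "EX_glc",
    glucose_molar_mass: float = GLUCOSE_MOLAR_MASS,
    tol: float = 1e-9,
) -> float:
    """Growth yield: growth rate over glucose uptake, in gDW per g glucose.

    Uptake is the magnitude of the (negative) glucose-exchange flux.  Zero
    uptake with zero growth gives yield 0 by convention; zero uptake with
    positive growth is a mass-balance violation and raises.
    """
    if not solution.optimal:
        raise ValueError("compute_yield requires an optimal solution")
    uptake = -solution.fluxes[glucose_exchange]
    mu = solution.growth_rate
    if uptake <= tol:
        if mu <= tol:
            return 0.0
        raise MassBalanceError(
            f"growth rate {mu} with no glucose uptake ({uptake})"
        )
    return mu / (uptake * glucose_molar_mass)
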