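"""Brute-force elementary flux mode enumeration for small networks.

An elementary flux mode (EFM) is a steady-state flux pattern whose support
(set of active reactions) cannot be reduced without losing feasibility.
Under a single binding crowding constraint and otherwise unconstrained
exchanges, the optimum of the crowding-constrained LP lies on one EFM, and
its objective value is

    V_prot * max over modes of (objective flux / crowding cost),

which makes the enumerator an independent check on the LP path: it never
touches the LP solver, only null spaces of candidate supports.

The search enumerates supports over *internal* (non-exchange) reactions
only; exchange fluxes are implied by the net production of boundary
metabolites, and their sign feasibility (e.g. oxygen can only be taken up)
is checked afterwards.  Cost: 2^(#internal reactions) null-space solves,
fine for the toy networks this package analyses (<= ~10 internal
reactions).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import null_space

from .model_io import MetabolicModel

__all__ = ["ElementaryMode", "enumerate_elementary_modes", "best_mode", "best_ratio"]


@dataclass
class ElementaryMode:
    """One mode, normalized to unit flux through the first active internal reaction."""

    fluxes: dict[str, float]

    def support(self) -> frozenset[str]:
        return frozenset(r for r, f in self.fluxes.items() if f != 0.0)

    def objective_flux(self, objective_reaction: str) -> float:
        return self.fluxes.get(objective_reaction, 0.0)

    def crowding_cost(self, coefficients: Mapping[str, float]) -> float:
        return sum(coefficients.get(r, 0.0) * abs(f) for r, f in self.fluxes.items())

    def normalized(self, reaction: str) -> "ElementaryMode":
        """Rescale so the named reaction carries unit absolute flux."""
        scale = abs(self.fluxes[reaction])
        return ElementaryMode({r: f / scale for r, f in self.fluxes.items()})


def enumerate_elementary_modes(
    model: MetabolicModel, tol: float = 1e-9
) -> list[ElementaryMode]:
    internal = [r for r in model.reactions if not r.exchange]
    exchanges = [r for r in model.reactions if r.exchange]
    if len(internal) > 16:
        raise ValueError("brute-force enumeration is limited to small networks")
    # metabolites without an exchange must balance exactly; the rest are
    # balanced by the implied exchange flux
    exchanged_mets = {next(iter(r.stoichiometry)) for r in exchanges}
    balanced_mets = [m.id for m in model.metabolites if m.id not in exchanged_mets]
    met_index = {m: j for j, m in enumerate(balanced_mets)}

    candidates: list[tuple[frozenset[str], dict[str, float]]] = []
    n = len(internal)
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            rxns = [internal[i] for i in subset]
            S = np.zeros((len(balanced_mets), k))
            for col, r in enumerate(rxns):
                for met, coef in r.stoichiometry.items():
                    if met in met_index:
                        S[met_index[met], col] = coef
            ns = null_space(S) if balanced_mets else np.eye(k)
            if ns.shape[1] != 1:
                continue
            v = ns[:, 0]
            if np.any(np.abs(v) <= tol):
                continue  # support smaller than the subset; found elsewhere
            # orient so irreversible reactions run forward
            irrev = [i for i, r in enumerate(rxns) if r.lower_bound >= 0]
            if irrev:
                signs = np.sign(v[irrev])
                if not (np.all(signs > 0) or np.all(signs < 0)):
                    continue
                if signs[0] < 0:
                    v = -v
            # directionality against bounds (upper bound 0 forbids forward flux)
            ok = True
            for i, r in enumerate(rxns):
                if v[i] > 0 and r.upper_bound <= 0:
                    ok = False
                if v[i] < 0 and r.lower_bound >= 0:
                    ok = False
            if not ok:
                continue
            fluxes = {r.id: float(v[i]) for i, r in enumerate(rxns)}
            # implied exchange fluxes from net boundary-metabolite production
            feasible = True
            for ex in exchanges:
                met, coef = next(iter(ex.stoichiometry.items()))
                production = sum(
                    r.stoichiometry.get(met, 0.0) * fluxes[r.id] for r in rxns
                )
                ex_flux = -production / coef  # balances the boundary metabolite
                if abs(ex_flux) <= tol:
                    ex_flux = 0.0
                if ex_flux > tol and ex.upper_bound <= 0:
                    feasible = False
                    break
                if ex_flux < -tol and ex.lower_bound >= 0:
                    feasible = False
                    break
                if ex_flux != 0.0:
                    fluxes[ex.id] = float(ex_flux)
            if not feasible:
                continue
            candidates.append((frozenset(fluxes), fluxes))

    # keep support-minimal candidates only
    modes: list[ElementaryMode] = []
    seen: set[frozenset[str]] = set()
    for support, fluxes in candidates:
        if support in seen:
            continue
        if any(other < support for other, _ in candidates):
            continue
        seen.add(support)
        modes.append(ElementaryMode(fluxes))
    return modes


def best_mode(
    modes: Sequence[ElementaryMode],
    objective_reaction: str,
    coefficients: Mapping[str, float],
) -> tuple[ElementaryMode | None, float]:
    """Mode maximizing objective flux per unit crowding cost, and that ratio.

    Modes with zero objective flux are ignored; a mode with positive
    objective and zero cost makes the crowding-constrained problem
    unbounded, reported as an infinite ratio.
    """
    best: ElementaryMode | None = None
    best_r = 0.0
    for m in modes:
        obj = m.objective_flux(objective_reaction)
        if obj <= 0:
            continue
        cost = m.crowding_cost(coefficients)
        r = float("inf") if cost == 0 else obj / cost
        if r > best_r:
            best, best_r = m, r
    return best, best_r


def best_ratio(
    modes: Sequence[ElementaryMode],
    objective_reaction: str,
    coefficients: Mapping[str, float],
) -> float:
    return best_mode(modes, objective_reaction, coefficients)[1]
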