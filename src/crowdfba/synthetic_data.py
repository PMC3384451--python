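"""Synthetic inputs: toy networks, turnover/mass tables, recovery data.

These generators stand in for the external inputs of the genome-scale
analysis (downloaded stoichiometric models, database extracts of enzyme
turnover numbers and masses, measured growth physiology) so every pipeline
stage can be exercised without downloads.  Turnover numbers and masses are
drawn log-uniformly: the empirical histograms they emulate are broad,
multi-decade and of no obvious parametric family, and log-uniform is the
least-informative shape spanning the observed ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SolverConfig
from .crowding import CrowdingDistribution, KcatRecord
from .experiments import ObservedGrowth, run_ensemble
from .model_io import MetabolicModel, Metabolite, Reaction

__all__ = [
    "SyntheticKcatSpec",
    "SyntheticNetworkSpec",
    "generate_kcat_table",
    "generate_toy_network",
    "generate_observed_growth",
]


@dataclass
class SyntheticKcatSpec:
    """Shape of a synthetic turnover/mass table.

    Defaults emulate the database extracts the crowding distributions are
    built from: ~1000 enzymes, turnover numbers spanning 0.01-10^4 /s and
    masses 10^4-10^6 g/mol (so derived crowding coefficients spread over
    roughly eight decades), a tenth of enzymes carrying an extra mutant
    measurement, and a tenth falling below the 0.01/s retention floor.
    """

    n_enzymes: int = 1000
    log10_kcat_range: tuple[float, float] = (-2.0, 4.0)
    log10_mass_range: tuple[float, float] = (4.0, 6.0)
    mutant_fraction: float = 0.1
    sub_threshold_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_enzymes < 1:
            raise ValueError("n_enzymes must be >= 1")
        for lo, hi in (self.log10_kcat_range, self.log10_mass_range):
            if lo > hi:
                raise ValueError("ranges must be ordered (low, high)")
        for f in (self.mutant_fraction, self.sub_threshold_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


def generate_kcat_table(spec: SyntheticKcatSpec) -> list[KcatRecord]:
    """Raw records (pre-filtering); reproducible from ``spec.seed``.

    Each enzyme gets one wild-type record; with probability
    ``sub_threshold_fraction`` its kcat is resampled below the 0.01/s
    floor, and with probability ``mutant_fraction`` an extra mutant record
    (same mass, independently drawn kcat) is appended — so the table
    exercises both filtering rules of the reduction step.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    klo, khi = spec.log10_kcat_range
    mlo, mhi = spec.log10_mass_range
    records: list[KcatRecord] = []
    for i in range(spec.n_enzymes):
        eid = f"enz{i:05d}"
        kcat = 10.0 ** rng.uniform(klo, khi)
        mass = 10.0 ** rng.uniform(mlo, mhi)
        if rng.random() < spec.sub_threshold_fraction:
            kcat = 10.0 ** rng.uniform(-4.0, np.log10(0.01) - 1e-9)
        records.append(KcatRecord(eid, kcat, mass, wild_type=True))
        if rng.random() < spec.mutant_fraction:
            records.append(
                KcatRecord(
                    eid, 10.0 ** rng.uniform(klo, khi), mass, wild_type=False
                )
            )
    return records


@dataclass
class SyntheticNetworkSpec:
    """A glycolysis-like backbone feeding alternative ATP-yielding branches.

    ``atp_yields`` lists, per branch, the net ATP gained per glucose when
    all carbon runs through that branch; the generated network then has
    exactly one elementary mode per branch with that ATP stoichiometry.
    With ``cofactor_coupling`` the backbone produces 2 NADH per glucose and
    every branch reoxidizes its share, so each mode is redox-closed.
    """

    n_branch_pathways: int = 2
    cofactor_coupling: bool = True
    atp_yields: tuple[float, ...] = (2.0, 28.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_branch_pathways < 2:
            raise ValueError("need at least 2 branch pathways")
        if len(self.atp_yields) != self.n_branch_pathways:
            raise ValueError("atp_yields must list one yield per branch")
        if any(y <= 0 for y in self.atp_yields):
            raise ValueError("atp_yields must all be > 0")
        if len(set(self.atp_yields)) == 1:
            raise ValueError("atp_yields must not all be equal")


def generate_toy_network(spec: SyntheticNetworkSpec) -> MetabolicModel:
    """Build the branched toy model; a pure function of the spec."""
    spec.validate()
    big = 1e8
    atp_backbone = 2.0
    mets = ["glc", "pyr", "atp"] + [f"waste{k}" for k in range(spec.n_branch_pathways)]
    if spec.cofactor_coupling:
        mets.append("nadh")
    backbone_stoich = {"glc": -1.0, "pyr": 2.0, "atp": atp_backbone}
    if spec.cofactor_coupling:
        backbone_stoich["nadh"] = 2.0
    reactions = [
        Reaction("R_backbone", backbone_stoich, 0.0, big, enzymatic=True),
    ]
    for k, y in enumerate(spec.atp_yields):
        stoich = {"pyr": -1.0, f"waste{k}": 1.0}
        atp_per_pyr = (y - atp_backbone) / 2.0
        if atp_per_pyr != 0.0:
            stoich["atp"] = atp_per_pyr
        if spec.cofactor_coupling:
            stoich["nadh"] = -1.0
        reactions.append(Reaction(f"R_branch{k}", stoich, 0.0, big, enzymatic=True))
    reactions.append(
        Reaction("EX_glc", {"glc": -1.0}, -10.0, 0.0, enzymatic=False, exchange=True)
    )
    for k in range(spec.n_branch_pathways):
        reactions.append(
            Reaction(
                f"EX_waste{k}", {f"waste{k}": -1.0}, 0.0, big, enzymatic=False, exchange=True
            )
        )
    reactions.append(
        Reaction("ATPM", {"atp": -1.0}, 0.0, big, enzymatic=False, exchange=True)
    )
    model = MetabolicModel(
        metabolites=[Metabolite(m) for m in mets],
        reactions=reactions,
        objective_reaction="ATPM",
        name=f"toy_network_seed{spec.seed}",
    )
    model.validate()
    return model


def generate_observed_growth(
    model: MetabolicModel,
    dist: CrowdingDistribution,
    config: SolverConfig,
    true_v_prot: float,
    n: int,
    seed: int,
    glucose_exchange: str = "EX_glc",
) -> ObservedGrowth:
    """Noiseless "observations" from an ensemble run at a known V_prot.

    Returns the ensemble-mean maximal growth rate and glucose uptake at
    ``true_v_prot``, which a fitting run on a grid containing that value
    should recover.
    """
    if not 0.0 < true_v_prot <= 1.0:
        raise ValueError("true_v_prot must be in (0, 1]")
    ens = run_ensemble(
        model, dist, config.with_v_prot(true_v_prot), n, seed, glucose_exchange
    )
    feasible = [s for s in ens.samples if s.status == "optimal"]
    if not feasible:
        raise ValueError("no feasible ensemble samples at true_v_prot")
    return ObservedGrowth(
        mu_max_obs=float(np.mean([s.growth_rate for s in feasible])),
        gup_max_obs=float(np.mean([s.glucose_uptake for s in feasible])),
    )
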