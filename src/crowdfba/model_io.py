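"""Stoichiometric model containers and file dialects.

A :class:`MetabolicModel` is the minimal object the crowding-constrained
solver needs: a stoichiometric matrix, per-reaction flux bounds, an
objective reaction, and two per-reaction annotations (``enzymatic``, which
decides whether the reaction is charged a crowding cost, and ``exchange``,
which marks boundary pseudo-reactions).  Genome-scale models are read from
SBML through cobrapy; small fixtures use a tab-separated reaction-table
dialect that round-trips losslessly.

Sign conventions follow BiGG: an exchange reaction consumes its single
metabolite (stoichiometry -1), so negative exchange flux is uptake and
positive flux is excretion.  Uptake bounds are stated as positive
magnitudes and applied as the negated exchange lower bound.
"""

from __future__ import annotations

import copy as _copy
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Medium",
    "ModelValidationError",
    "load_model",
    "write_reaction_table",
    "read_medium",
    "apply_medium",
    "build_simplified_network",
    "simplified_network_path",
]


class ModelValidationError(ValueError):
    """A model or reaction violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """One column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  Reversibility is encoded purely through the bounds: a
    negative lower bound means the reaction may run backwards.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    enzymatic: bool = True
    exchange: bool = False
    name: str = ""

    def validate(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction with empty id")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0.0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: coefficient of {met!r} is {coef}"
                )
        if self.exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} touches "
                f"{len(self.stoichiometry)} metabolites (expected 1)"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_reaction: str
    name: str = ""

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        if any(not m for m in met_ids):
            raise ModelValidationError("empty metabolite id")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            r.validate()
            dangling = set(r.stoichiometry) - known
            if dangling:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(dangling)}"
                )
        if self.objective_reaction not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    # -- indexed access -------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with S[j, i] = coefficient of metabolite j in reaction i."""
        met_index = {m.id: j for j, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for i, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[met_index[met], i] = coef
        return S

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def set_uptake_bound(self, exchange_id: str, magnitude: float) -> None:
        """Allow uptake of at most ``magnitude`` (sets the lower bound to its negation)."""
        self.reaction(exchange_id).lower_bound = -abs(magnitude)


@dataclass
class Medium:
    """Growth-medium description for genome-scale simulations.

    ``uptake_bounds`` gives maximal uptake magnitudes per exchange reaction;
    ``biomass_composition`` gives amino-acid biomass coefficients
    (mmol/gDW), from which amino-acid uptake bounds are derived as
    coefficient x 2 x observed maximal growth rate, so that amino-acid
    supply never limits growth below twice the observed maximum.
    """

    uptake_bounds: dict[str, float] = field(default_factory=dict)
    biomass_composition: dict[str, float] = field(default_factory=dict)
    observed_max_growth: float = 0.0

    def validate(self) -> None:
        for k, v in self.uptake_bounds.items():
            if v < 0:
                raise ModelValidationError(f"negative uptake bound for {k!r}")
        for k, v in self.biomass_composition.items():
            if v < 0:
                raise ModelValidationError(f"negative biomass coefficient for {k!r}")
        if self.observed_max_growth < 0:
            raise ModelValidationError("negative observed_max_growth")


# ---------------------------------------------------------------------------
# reaction-table dialect
# ---------------------------------------------------------------------------

_ARROW = re.compile(r"\s*(?:->|→|=>)\s*")

_TABLE_COLUMNS = ["id", "equation", "lb", "ub", "enzymatic", "exchange"]


def _parse_side(side: str) -> dict[str, float]:
    terms: dict[str, float] = {}
    side = side.strip()
    if not side:
        return terms
    for term in side.split("+"):
        parts = term.split()
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            coef, met = float(parts[0]), parts[1]
        else:
            raise ModelValidationError(f"cannot parse equation term {term!r}")
        terms[met] = terms.get(met, 0.0) + coef
    return terms


def parse_equation(equation: str) -> dict[str, float]:
    """Parse ``"1 glc + 2 nadh -> 1 waste"`` into signed stoichiometry."""
    pieces = _ARROW.split(equation)
    if len(pieces) != 2:
        raise ModelValidationError(f"equation {equation!r} has no single arrow")
    left, right = (_parse_side(p) for p in pieces)
    stoich: dict[str, float] = {}
    for met, coef in left.items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in right.items():
        stoich[met] = stoich.get(met, 0.0) + coef
    return {m: c for m, c in stoich.items() if c != 0.0}


def format_equation(stoichiometry: Mapping[str, float]) -> str:
    def side(items: Iterable[tuple[str, float]]) -> str:
        return " + ".join(f"{_fmt(abs(c))} {m}" for m, c in items)

    left = sorted((m, c) for m, c in stoichiometry.items() if c < 0)
    right = sorted((m, c) for m, c in stoichiometry.items() if c > 0)
    return f"{side(left)} -> {side(right)}"


def _fmt(x: float) -> str:
    return f"{x:g}"


def _read_reaction_table(path: Path) -> MetabolicModel:
    objective = None
    name = path.stem
    reactions: list[Reaction] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("objective:"):
                    objective = body.split(":", 1)[1].strip()
                elif body.startswith("name:"):
                    name = body.split(":", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if header != _TABLE_COLUMNS:
                    raise ModelValidationError(
                        f"{path}:{lineno}: expected header {_TABLE_COLUMNS}, got {header}"
                    )
                continue
            if len(fields) != len(_TABLE_COLUMNS):
                raise ModelValidationError(
                    f"{path}:{lineno}: expected {len(_TABLE_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(_TABLE_COLUMNS, fields))
            try:
                stoich = parse_equation(row["equation"])
                lb, ub = float(row["lb"]), float(row["ub"])
            except (ValueError, ModelValidationError) as exc:
                raise ModelValidationError(f"{path}:{lineno}: {exc}") from exc
            reactions.append(
                Reaction(
                    id=row["id"],
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    enzymatic=row["enzymatic"].strip().lower() in ("1", "true", "yes"),
                    exchange=row["exchange"].strip().lower() in ("1", "true", "yes"),
                )
            )
    if header is None:
        raise ModelValidationError(f"{path}: empty reaction table")
    if objective is None:
        raise ModelValidationError(f"{path}: missing '# objective:' line")
    mets = sorted({m for r in reactions for m in r.stoichiometry})
    model = MetabolicModel(
        metabolites=[Metabolite(m) for m in mets],
        reactions=reactions,
        objective_reaction=objective,
        name=name,
    )
    _autoflag_exchanges(model)
    model.validate()
    return model


def write_reaction_table(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# name: {model.name}", f"# objective: {model.objective_reaction}"]
    lines.append("\t".join(_TABLE_COLUMNS))
    for r in model.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    format_equation(r.stoichiometry),
                    _fmt(r.lower_bound),
                    _fmt(r.upper_bound),
                    str(r.enzymatic).lower(),
                    str(r.exchange).lower(),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _autoflag_exchanges(model: MetabolicModel) -> None:
    """Flag single-metabolite reactions and EX_-prefixed ids as exchanges."""
    for r in model.reactions:
        if len(r.stoichiometry) == 1 or r.id.startswith("EX_"):
            r.exchange = True
            r.enzymatic = False


def _read_sbml(path: Path) -> MetabolicModel:
    # cobrapy (via libsbml) handles level/version quirks; we only translate
    # the parts the crowding solver needs.
    import cobra.io

    cmodel = cobra.io.read_sbml_model(str(path))
    metabolites = [
        Metabolite(m.id, m.name or "", m.compartment or "") for m in cmodel.metabolites
    ]
    reactions = []
    for r in cmodel.reactions:
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                enzymatic=bool(r.genes) and not r.boundary,
                exchange=bool(r.boundary) or r.id.startswith("EX_"),
                name=r.name or "",
            )
        )
    objective = None
    for r in cmodel.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    if objective is None:
        raise ModelValidationError(f"{path}: SBML model has no objective reaction")
    model = MetabolicModel(metabolites, reactions, objective, name=cmodel.id or path.stem)
    model.validate()
    return model


def load_model(path: str | Path, format: str = "reaction-table") -> MetabolicModel:
    """Load and validate a model from ``reaction-table`` or ``sbml`` input."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "reaction-table":
        return _read_reaction_table(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

def read_medium(path: str | Path) -> Medium:
    """Read a medium file: tab-separated rows ``kind<TAB>id<TAB>value``.

    ``kind`` is one of ``uptake`` (exchange-reaction uptake magnitude),
    ``biomass`` (amino-acid biomass coefficient) or ``param`` (currently only
    ``observed_max_growth``).
    """
    medium = Medium()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ModelValidationError(f"{path}:{lineno}: expected 3 columns")
        kind, key, value = parts[0].strip(), parts[1].strip(), float(parts[2])
        if kind == "uptake":
            medium.uptake_bounds[key] = value
        elif kind == "biomass":
            medium.biomass_composition[key] = value
        elif kind == "param" and key == "observed_max_growth":
            medium.observed_max_growth = value
        else:
            raise ModelValidationError(f"{path}:{lineno}: unknown row kind {kind!r}")
    medium.validate()
    return medium


def _resolve_exchange(model: MetabolicModel, key: str) -> str | None:
    ids = set(model.reaction_ids)
    if key in ids:
        return key
    if f"EX_{key}" in ids:
        return f"EX_{key}"
    return None


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy with exchange uptake bounds set from the medium.

    Amino-acid uptake is capped at biomass coefficient x 2 x observed
    maximal growth rate, so amino-acid supply suffices for twice the
    observed maximal growth but can never drive unbounded growth.
    """
    medium.validate()
    out = model.copy()
    missing = []
    for key, bound in medium.uptake_bounds.items():
        rid = _resolve_exchange(out, key)
        if rid is None:
            missing.append(key)
            continue
        out.set_uptake_bound(rid, bound)
    for key, coef in medium.biomass_composition.items():
        rid = _resolve_exchange(out, key)
        if rid is None:
            missing.append(key)
            continue
        out.set_uptake_bound(rid, coef * 2.0 * medium.observed_max_growth)
    if missing:
        raise ModelValidationError(f"medium references unknown exchanges: {sorted(missing)}")
    return out


# ---------------------------------------------------------------------------
# the five-reaction switching fixture
# ---------------------------------------------------------------------------

def build_simplified_network(
    *,
    atp_glycolysis: float = 2.0,
    nadh_glycolysis: float = 2.0,
    atp_acetate: float = 1.0,
    nadh_waste: float = 2.0,
    nadh_tca: float = 4.0,
    atp_tca: float = 1.0,
    po_ratio: float = 2.0,
    glucose_uptake: float = 10.0,
    big_bound: float = 1e8,
) -> MetabolicModel:
    """Five-reaction caricature of glucose metabolism with an acetate branch.

    Internal reactions (all enzymatic, units mmol/gDW/h):

    * ``R_glycolysis`` -- glucose -> 2 acetyl units + 2 CO2, with
      ``atp_glycolysis`` ATP and ``nadh_glycolysis`` NADH.  The acetyl-unit
      forming step is lumped formate-lyase style, so it books no NADH of its
      own; glycolytic NADH is the only reduced currency entering the branch
      point.
    * ``R_acetate`` -- acetyl unit -> acetate + ``atp_acetate`` ATP.  The
      "cheap extra ATP" branch; it neither produces nor consumes NADH.
    * ``R_waste`` -- acetyl unit + ``nadh_waste`` NADH -> reduced waste
      (lactate/ethanol lumped).  The redox-sink fermentation branch.
    * ``R_tca`` -- acetyl unit -> ``nadh_tca`` NADH + ``atp_tca`` ATP
      + 2 CO2 (FADH2 counted as NADH, GTP as ATP).
    * ``R_oxphos`` -- NADH + 0.5 O2 -> ``po_ratio`` ATP.

    Exchanges exist for glucose, oxygen, acetate, waste and CO2; the
    objective is an ATP-drain flux standing in for growth (the toy model
    has no biomass reaction).  With the default coefficients the network
    has exactly four elementary modes (ATP per glucose 7/3, 3, 8 and 24)
    and exactly two after acetate knockout, reproducing the qualitative
    mode structure of an acetate-capable overflow metabolizer.
    """
    mets = ["ac", "accoa", "atp", "co2", "glc", "nadh", "o2", "waste"]
    reactions = [
        Reaction(
            "R_glycolysis",
            {
                "glc": -1.0,
                "accoa": 2.0,
                "co2": 2.0,
                "atp": atp_glycolysis,
                "nadh": nadh_glycolysis,
            },
            0.0,
            big_bound,
            enzymatic=True,
        ),
        Reaction(
            "R_acetate",
            {"accoa": -1.0, "ac": 1.0, "atp": atp_acetate},
            0.0,
            big_bound,
            enzymatic=True,
        ),
        Reaction(
            "R_waste",
            {"accoa": -1.0, "nadh": -nadh_waste, "waste": 1.0},
            0.0,
            big_bound,
            enzymatic=True,
        ),
        Reaction(
            "R_tca",
            {"accoa": -1.0, "nadh": nadh_tca, "atp": atp_tca, "co2": 2.0},
            0.0,
            big_bound,
            enzymatic=True,
        ),
        Reaction(
            "R_oxphos",
            {"nadh": -1.0, "o2": -0.5, "atp": po_ratio},
            0.0,
            big_bound,
            enzymatic=True,
        ),
        Reaction("EX_glc", {"glc": -1.0}, -glucose_uptake, 0.0, enzymatic=False, exchange=True),
        Reaction("EX_o2", {"o2": -1.0}, -big_bound, 0.0, enzymatic=False, exchange=True),
        Reaction("EX_ac", {"ac": -1.0}, 0.0, big_bound, enzymatic=False, exchange=True),
        Reaction("EX_waste", {"waste": -1.0}, 0.0, big_bound, enzymatic=False, exchange=True),
        Reaction("EX_co2", {"co2": -1.0}, 0.0, big_bound, enzymatic=False, exchange=True),
        Reaction("ATPM", {"atp": -1.0}, 0.0, big_bound, enzymatic=False, exchange=True),
    ]
    model = MetabolicModel(
        metabolites=[Metabolite(m) for m in mets],
        reactions=reactions,
        objective_reaction="ATPM",
        name="simplified_network",
    )
    model.validate()
    return model


def simplified_network_path() -> Path:
    """Path of the bundled reaction-table copy of the simplified network."""
    return Path(__file__).parent / "data" / "simplified_network.tsv"
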