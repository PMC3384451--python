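"""Crowding-coefficient distributions and per-reaction assignments.

The crowding coefficient of a reaction is the fraction of cytosolic volume
that must be occupied by its enzyme to sustain unit flux,

    c = (M/V) * v / b,

with M/V the cell dry-mass density (gDW/l), v the enzyme molar volume
(l/mmol, from molar mass via a specific protein volume of 0.73 ml/g) and
b the catalytic capacity (mmol substrate per mmol enzyme per hour, i.e.
kcat converted from 1/s).  Units: c carries gDW.h/mmol, so c * flux
(mmol/gDW/h) is a dimensionless volume fraction.

Because per-enzyme assignments to reactions are unknown for most of the
network, reactions are not identity-mapped to enzymes.  A pooled empirical
distribution of coefficients is built from a turnover/mass table and each
enzymatic reaction draws one coefficient from it at random; the analysis
then studies the ensemble over many such draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model_io import MetabolicModel

__all__ = [
    "KcatRecord",
    "KcatMassTable",
    "CrowdingDistribution",
    "CrowdingAssignment",
    "build_kcat_table",
    "read_kcat_table",
    "write_kcat_table",
    "compute_crowding_coefficient",
    "build_distribution",
    "sample_crowding",
    "degenerate_distribution",
    "DEFAULT_CELL_DENSITY",
    "DEFAULT_SPECIFIC_VOLUME",
    "KCAT_FLOOR",
]

#: Cell dry-mass density M/V in gDW per litre of cell volume.  Standard
#: E. coli figure; it only matters jointly with the crowding budget V_prot,
#: since both sides of the constraint scale with it.
DEFAULT_CELL_DENSITY = 340.0

#: Specific protein volume in ml per gram of enzyme.
DEFAULT_SPECIFIC_VOLUME = 0.73

#: Turnover numbers strictly below this (1/s) are discarded when building a
#: table: such values typically belong to non-metabolic activities or
#: atypical substrates and would effectively switch the reaction off.
KCAT_FLOOR = 0.01


@dataclass
class KcatRecord:
    enzyme_id: str
    kcat: float  # 1/s
    mass: float  # g/mol
    wild_type: bool = True
    substrate: str | None = None

    def validate(self) -> None:
        if self.kcat <= 0:
            raise ValueError(f"{self.enzyme_id}: kcat must be > 0, got {self.kcat}")
        if self.mass <= 0:
            raise ValueError(f"{self.enzyme_id}: mass must be > 0, got {self.mass}")


@dataclass
class KcatMassTable:
    records: list[KcatRecord]
    provenance: str = ""


def build_kcat_table(
    raw_records: Iterable[KcatRecord],
    kcat_floor: float = KCAT_FLOOR,
    provenance: str = "",
) -> KcatMassTable:
    """Reduce raw turnover measurements to one record per enzyme.

    Per enzyme: wild-type records are preferred whenever any exist; among
    the preferred records the one with the highest kcat is kept (slow
    measurements usually reflect poor substrates, not the enzyme's
    capacity); enzymes whose retained kcat is strictly below ``kcat_floor``
    are dropped entirely.
    """
    raw = list(raw_records)
    if not raw:
        raise ValueError("build_kcat_table: no input records")
    for rec in raw:
        rec.validate()
    by_enzyme: dict[str, list[KcatRecord]] = {}
    for rec in raw:
        by_enzyme.setdefault(rec.enzyme_id, []).append(rec)
    kept: list[KcatRecord] = []
    for enzyme_id, recs in by_enzyme.items():
        wt = [r for r in recs if r.wild_type]
        pool = wt if wt else recs
        best = max(pool, key=lambda r: r.kcat)
        if best.kcat < kcat_floor:
            continue
        kept.append(best)
    return KcatMassTable(records=kept, provenance=provenance)


def compute_crowding_coefficient(
    mass: float,
    kcat: float,
    cell_density: float = DEFAULT_CELL_DENSITY,
    specific_volume: float = DEFAULT_SPECIFIC_VOLUME,
) -> float:
    """Crowding coefficient (gDW.h/mmol) from enzyme mass and turnover.

    ``specific_volume`` [ml/g] x ``mass`` [g/mol] gives the molar volume;
    the 1e-6 converts ml/mol to l/mmol.  ``kcat`` [1/s] x 3600 gives the
    catalytic capacity b in mmol substrate per mmol enzyme per hour.
    """
    for name, val in (("mass", mass), ("kcat", kcat),
                      ("cell_density", cell_density),
                      ("specific_volume", specific_volume)):
        if val <= 0:
            raise ValueError(f"compute_crowding_coefficient: {name} must be > 0, got {val}")
    molar_volume = specific_volume * mass * 1e-6  # l/mmol
    b = kcat * 3600.0  # 1/h
    return cell_density * molar_volume / b


@dataclass
class CrowdingDistribution:
    """Empirical pool of crowding coefficients plus the parameters behind it."""

    coefficients: np.ndarray
    cell_density: float = DEFAULT_CELL_DENSITY
    specific_volume: float = DEFAULT_SPECIFIC_VOLUME

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size == 0:
            raise ValueError("CrowdingDistribution: empty coefficient list")
        if np.any(self.coefficients < 0):
            raise ValueError("CrowdingDistribution: negative coefficient")

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.coefficients)

    @classmethod
    def load(
        cls,
        path: str | Path,
        cell_density: float = DEFAULT_CELL_DENSITY,
        specific_volume: float = DEFAULT_SPECIFIC_VOLUME,
    ) -> "CrowdingDistribution":
        return cls(np.atleast_1d(np.loadtxt(path)), cell_density, specific_volume)


def build_distribution(
    table: KcatMassTable,
    cell_density: float = DEFAULT_CELL_DENSITY,
    specific_volume: float = DEFAULT_SPECIFIC_VOLUME,
) -> CrowdingDistribution:
    """One coefficient per retained enzyme in the table."""
    if not table.records:
        raise ValueError("build_distribution: empty table")
    coeffs = [
        compute_crowding_coefficient(r.mass, r.kcat, cell_density, specific_volume)
        for r in table.records
    ]
    return CrowdingDistribution(np.array(coeffs), cell_density, specific_volume)


def degenerate_distribution(c: float) -> CrowdingDistribution:
    """Single-valued distribution, useful for deterministic experiments."""
    return CrowdingDistribution(np.array([c]))


@dataclass
class CrowdingAssignment:
    """Sampled per-reaction crowding coefficients for one simulation."""

    coefficients: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def sample_crowding(
    model: MetabolicModel, dist: CrowdingDistribution, seed: int
) -> CrowdingAssignment:
    """Draw one coefficient per enzymatic reaction, uniformly with replacement.

    Non-enzymatic and exchange reactions (including the objective drain)
    carry coefficient 0: they are not catalysed by cytosolic enzymes in the
    crowding sense.  The same (model, dist, seed) triple always yields the
    same assignment; draws follow the model's reaction order.
    """
    rng = np.random.default_rng(seed)
    pool = dist.coefficients
    out: dict[str, float] = {}
    for r in model.reactions:
        if r.enzymatic and not r.exchange:
            out[r.id] = float(pool[rng.integers(0, pool.size)])
        else:
            out[r.id] = 0.0
    return CrowdingAssignment(coefficients=out, seed=seed)


# ---------------------------------------------------------------------------
# kcat table file dialect: TSV with header enzyme_id, kcat_per_s, mass_da,
# wild_type and an optional substrate column.
# ---------------------------------------------------------------------------

def write_kcat_table(records: Sequence[KcatRecord], path: str | Path) -> None:
    lines = ["enzyme_id\tkcat_per_s\tmass_da\twild_type\tsubstrate"]
    for r in records:
        lines.append(
            f"{r.enzyme_id}\t{r.kcat:g}\t{r.mass:g}\t{str(r.wild_type).lower()}"
            f"\t{r.substrate or ''}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_kcat_table(path: str | Path) -> list[KcatRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty kcat table")
    header = [h.strip() for h in lines[0].split("\t")]
    required = ["enzyme_id", "kcat_per_s", "mass_da", "wild_type"]
    if header[: len(required)] != required:
        raise ValueError(f"{path}: expected header starting with {required}")
    records = []
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        rec = KcatRecord(
            enzyme_id=parts[0].strip(),
            kcat=float(parts[1]),
            mass=float(parts[2]),
            wild_type=parts[3].strip().lower() in ("1", "true", "yes"),
            substrate=(parts[4].strip() or None) if len(parts) > 4 else None,
        )
        rec.validate()
        records.append(rec)
    if not records:
        raise ValueError(f"{path}: no records")
    return records
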