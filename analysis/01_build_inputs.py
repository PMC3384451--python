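#!/usr/bin/env python
"""Build the analysis inputs: turnover/mass table and crowding distribution.

Generates a synthetic enzyme table (turnover numbers 0.01-1e4 /s, masses
1e4-1e6 g/mol), applies the retention rules (wild-type preference, highest
kcat per enzyme, 0.01/s floor), converts to crowding coefficients and
writes the table, the coefficient pool and its histogram.
"""

import numpy as np

from crowdfba.cli import emit_histogram
from crowdfba.crowding import build_distribution, build_kcat_table, write_kcat_table
from crowdfba.synthetic_data import SyntheticKcatSpec, generate_kcat_table

from _util import OUTDIR, SEED

out = OUTDIR / "01_inputs"
out.mkdir(parents=True, exist_ok=True)

spec = SyntheticKcatSpec(seed=SEED)
raw = generate_kcat_table(spec)
write_kcat_table(raw, out / "kcat_table_raw.tsv")
table = build_kcat_table(raw, provenance=f"synthetic seed={SEED}")
write_kcat_table(table.records, out / "kcat_table_filtered.tsv")
dist = build_distribution(table)
dist.save(out / "crowding_coefficients.txt")
emit_histogram(np.log10(dist.coefficients), 30).to_csv(
    out / "log10_coefficient_histogram.tsv", sep="\t", index=False
)

span = np.log10(dist.coefficients.max() / dist.coefficients.min())
print(f"raw records:        {len(raw)}")
print(f"retained enzymes:   {len(table.records)}")
print(f"coefficient span:   {span:.2f} decades "
      f"({dist.coefficients.min():.3g} .. {dist.coefficients.max():.3g} gDW.h/mmol)")
print(f"wrote tables to {out}")
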