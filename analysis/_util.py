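"""Shared conventions for the analysis drivers."""

from pathlib import Path

from crowdfba.crowding import build_distribution, build_kcat_table
from crowdfba.synthetic_data import SyntheticKcatSpec, generate_kcat_table

SEED = 1
OUTDIR = Path(__file__).resolve().parent.parent / "results"


def default_distribution(seed: int = SEED):
    """The crowding-coefficient pool every driver samples from."""
    return build_distribution(
        build_kcat_table(generate_kcat_table(SyntheticKcatSpec(seed=seed)))
    )
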