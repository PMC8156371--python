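"""Shared scenario and paths for the numbered analysis scripts.

One desk-scale synthetic flora is used throughout: 600 taxa on a 30 x 30
grid of 10 km cells, a majority of narrow endemics (ranges 1-3 cells) over
a log-series tail, spatially cohesive ranges, a dated Yule phylogeny,
partial trait coverage and a ~35% protected-area mask.  Scripts must be
run in order; each reads the data written by 01 and re-derives the cheap
surfaces it needs.
"""

from pathlib import Path

from spatdiv.synth import ScenarioConfig, simulate_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

SEED = 20210517

SCENARIO = dict(
    seed=SEED,
    n_taxa=600,
    grid_rows=30,
    grid_cols=30,
    endemic_fraction=0.55,
    logseries_p=0.99,
    cohesion=0.8,
    trait_coverage=0.6,
    multi_valued_prob=0.15,
    pa_fraction=0.35,
)

N_PERM = 199


def dataset():
    """The analysis dataset, regenerated deterministically from the seed."""
    return simulate_dataset(ScenarioConfig(**SCENARIO))
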