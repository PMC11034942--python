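from pathlib import Path

import dendropy
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from qsipx import Design, RunConfig, synthetic_design
from qsipx.effects import EffectSizeRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"

FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def design() -> Design:
    return Design()


@pytest.fixture
def sim_design() -> Design:
    return synthetic_design()


@pytest.fixture
def config() -> RunConfig:
    return RunConfig(rng_seed=0, n_bootstrap=200, n_null_nti=199)


@pytest.fixture
def four_tip_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=FOUR_TIP_NEWICK, schema="newick")


@pytest.fixture
def truth_table() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "interaction_truth_table.tsv", sep="\t")


def make_record(label, measure, comparison, est, sig) -> EffectSizeRecord:
    """Effect record whose CI encodes the requested significance."""
    if sig:
        lo, hi = (est - 0.01, est + 0.01) if est != 0 else (0.01, 0.02)
        if est > 0:
            lo = max(lo, 1e-6)
        elif est < 0:
            hi = min(hi, -1e-6)
    else:
        half = abs(est) + 0.5
        lo, hi = est - half, est + half
    return EffectSizeRecord(label, measure, comparison, est, lo, hi)
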