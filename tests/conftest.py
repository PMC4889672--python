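import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import nilscape as ns

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def tiny_map() -> ns.MarkerMap:
    """Six markers per side around an indel at 500."""
    left = [100, 200, 300, 350, 400, 450]
    right = [600, 650, 700, 800, 850, 900]
    return ns.MarkerMap(
        np.array(left + right),
        np.array(["left"] * 6 + ["right"] * 6, dtype=object),
        indel_position=500)


def make_table(lengths, counts_fax, counts_lon=None, side="left",
               start=1, resolution="full") -> ns.CrossoverTable:
    lengths = np.asarray(lengths, dtype=np.int64)
    starts = start + np.concatenate([[0], np.cumsum(lengths)[:-1]])
    if counts_lon is None:
        counts_lon = np.zeros(len(lengths), dtype=int)
    sides = [side] * len(lengths) if isinstance(side, str) else list(side)
    df = pd.DataFrame(dict(
        start=starts, end=starts + lengths, side=sides, length=lengths,
        count_faxnil=np.asarray(counts_fax, dtype=int),
        count_lonnil=np.asarray(counts_lon, dtype=int), masked=False))
    return ns.CrossoverTable(df, resolution)


@pytest.fixture
def two_side_table() -> ns.CrossoverTable:
    """Both sides, unequal rates, enough counts for model fits."""
    rng = np.random.default_rng(7)
    lengths = rng.integers(2_000, 9_000, size=24)
    rates = np.concatenate([np.full(12, 3e-3), np.full(12, 1.5e-3)])
    fax = rng.poisson(lengths * rates)
    lon = rng.poisson(lengths * rates * 0.7)
    sides = ["left"] * 12 + ["right"] * 12
    starts_l = 1 + np.concatenate([[0], np.cumsum(lengths[:12])[:-1]])
    starts_r = 200_000 + np.concatenate([[0], np.cumsum(lengths[12:])[:-1]])
    starts = np.concatenate([starts_l, starts_r])
    df = pd.DataFrame(dict(
        start=starts, end=starts + lengths, side=sides, length=lengths,
        count_faxnil=fax, count_lonnil=lon, masked=False))
    return ns.CrossoverTable(df)


@pytest.fixture
def small_scenario() -> ns.SyntheticScenario:
    """A scaled-down two-cross study for fast end-to-end tests."""
    return ns.SyntheticScenario(
        seed=11, span=(100_000, 320_000), indel_position=220_000,
        n_markers_left=14, n_markers_right=12,
        totals={"faxnil": (60, 35), "lonnil": (38, 36)},
        median_gap_bp=7_000, landscape_kind="uniform")
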