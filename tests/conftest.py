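import numpy as np
import pandas as pd
import pytest

from paddyghg import WaterLevelSeries, descriptor_table, generate_landscape, standardize


def make_series(levels, field_id="f", start="2022-07-01"):
    levels = np.asarray(levels, dtype=float)
    return WaterLevelSeries(
        field_id, pd.date_range(start, periods=len(levels), freq="D"), levels
    )


@pytest.fixture
def toy_s1():
    """Ten-day toy series exercising every descriptor family."""
    return make_series([3, 6, 11, 0, -4, -8, -12, 6, -6, -2], field_id="S1")


@pytest.fixture(scope="session")
def dry_landscape():
    return generate_landscape("dry", 160, seed=1)


@pytest.fixture(scope="session")
def wet_landscape():
    return generate_landscape("wet", 160, seed=1)


@pytest.fixture(scope="session")
def dry_descriptors(dry_landscape):
    return descriptor_table(dry_landscape.series)


@pytest.fixture(scope="session")
def wet_descriptors(wet_landscape):
    return descriptor_table(wet_landscape.series)


@pytest.fixture(scope="session")
def pooled_descriptors_emissions(dry_landscape, wet_landscape):
    """Both seasons pooled, as in the combined-years classification."""
    X = pd.concat([descriptor_table(wet_landscape.series),
                   descriptor_table(dry_landscape.series)])
    emis = pd.concat([wet_landscape.emissions, dry_landscape.emissions],
                     ignore_index=True).set_index("field_id")
    return X, emis
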