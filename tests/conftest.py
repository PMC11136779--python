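"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

import hypothesis.strategies as st
import pytest
from hypothesis import HealthCheck, settings

from famefuel.fame_profile import FAProfile, FattyAcid

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# a modest panel covering all three saturation classes
PANEL = [
    FattyAcid(14, 0), FattyAcid(16, 0), FattyAcid(18, 0), FattyAcid(20, 0),
    FattyAcid(22, 0), FattyAcid(24, 0),
    FattyAcid(16, 1, 7), FattyAcid(18, 1, 9), FattyAcid(20, 1),
    FattyAcid(18, 2, 6), FattyAcid(18, 3, 3), FattyAcid(18, 4, 3), FattyAcid(20, 4, 6),
]

percents = st.floats(min_value=0.0, max_value=12.0, allow_nan=False, width=32)


@st.composite
def profiles(draw, min_acids: int = 1) -> FAProfile:
    """Random valid profile over PANEL (total <= 100 by construction)."""
    subset = draw(
        st.lists(st.sampled_from(PANEL), min_size=min_acids, max_size=8, unique=True)
    )
    comp = {acid: draw(percents) for acid in subset}
    comp = {a: v for a, v in comp.items() if v > 0}
    if not comp:  # keep profiles nonempty so every property is defined
        comp = {subset[0]: 1.0}
    return FAProfile(sample_id="hyp", composition=comp)


@pytest.fixture(scope="session")
def table1_profiles():
    from famefuel.datasets import load_table1_profiles

    return load_table1_profiles()


@pytest.fixture(scope="session")
def table2_printed():
    from famefuel.datasets import load_table2_properties

    return load_table2_properties()
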