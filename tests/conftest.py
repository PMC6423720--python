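import numpy as np
import pytest

from cyclephase import PROFILES, PhaseRecord, PhaseTable, simulate_phase_durations


@pytest.fixture
def rpe_profile():
    return PROFILES["rpe"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Three complete records with one sister pair."""
    recs = [
        PhaseRecord(
            cell_id="a", condition="c", sister_id="b",
            t_birth=0.0, t_s_onset=7.9, t_s_end=18.0, t_m_start=21.4,
            t_telophase=21.9, d_g1=7.9, d_s=10.1, d_g2=3.4, d_m=0.5,
        ),
        PhaseRecord(
            cell_id="b", condition="c", sister_id="a",
            d_g1=8.4, d_s=9.8, d_g2=3.1, d_m=0.4,
        ),
        PhaseRecord(cell_id="c", condition="c", d_g1=2.1, d_s=7.6, d_g2=4.0, d_m=0.5),
    ]
    return PhaseTable(recs)


@pytest.fixture
def rpe_table(rpe_profile):
    return simulate_phase_durations(rpe_profile, 200, seed=42)
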