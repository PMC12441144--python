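import numpy as np
import pytest

from socialbayes import build_design, design_to_frame


@pytest.fixture(scope="session")
def default_design():
    return build_design(seed=7)


@pytest.fixture(scope="session")
def default_design_frame(default_design):
    return design_to_frame(default_design)


@pytest.fixture(scope="session")
def resolved_design_frame(default_design_frame):
    """Default design with social labels filled deterministically."""
    df = default_design_frame.copy()
    social = df["block"] == "social"
    # alternate safe/risky labels over social trials
    labels = np.where(np.arange(social.sum()) % 2 == 0, "risky", "safe")
    df.loc[social, "social"] = labels
    return df


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small complete synthetic study reused across tests."""
    from socialbayes import simulate_dataset

    subjects, choices = simulate_dataset(n_subjects=6, n_advisors=40, seed=123)
    return subjects, choices
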