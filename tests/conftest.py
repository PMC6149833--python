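import numpy as np
import pandas as pd
import pytest

from serotrial import AntigenParams, CohortConfig, DEFAULT_ASSAYS


@pytest.fixture(scope="session")
def assays():
    return DEFAULT_ASSAYS


@pytest.fixture
def small_config():
    """Two tiny groups, one antigen, no attrition or diary."""
    params = AntigenParams(
        mean_pre=np.log10(1.6), mean_post=np.log10(6.0),
        sd_pre=0.4, sd_post=0.3, corr=0.5,
    )
    return CohortConfig(
        group_sizes={"A": 12, "B": 20},
        antigen_params={"A": {"diphtheria": params}, "B": {"diphtheria": params}},
        seed=123,
    )


def serology_frame(concentrations, antigen="diphtheria", censored=None,
                   group="G", visit="post"):
    """Build a serology table from a list of concentrations."""
    n = len(concentrations)
    return pd.DataFrame(
        {
            "participant_id": [f"{group}-{i:03d}" for i in range(n)],
            "group": group,
            "antigen": antigen,
            "visit": visit,
            "concentration_IU_ml": concentrations,
            "censored": censored if censored is not None else [0] * n,
        }
    )
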