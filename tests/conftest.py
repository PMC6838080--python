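"""Shared fixtures.

The heavyweight session fixtures run the scaled-down ("desk") protocol
battery once and are shared by the acceptance tests: three seeds with the
reward pathway enabled, three with it disabled, and the two-location
translation variant with shared and with separate interneuron pools.
"""

import numpy as np
import pytest

from v1plasticity.experiment import (
    ProtocolConfig,
    run_full_protocol,
    run_translation_protocol,
)

DESK_SEEDS = (1, 2, 3)
TRANSLATION_SEEDS = (1, 2)


@pytest.fixture(scope="session")
def desk_summaries():
    """Scaled-down full protocol, reward enabled, three seeds."""
    return [run_full_protocol(ProtocolConfig.desk(seed=s)).summary
            for s in DESK_SEEDS]


@pytest.fixture(scope="session")
def noreward_summaries():
    """Same protocol with the top-down pathway disabled (ablation)."""
    return [run_full_protocol(
        ProtocolConfig.desk(seed=s, reward_enabled=False)).summary
        for s in DESK_SEEDS]


@pytest.fixture(scope="session")
def translation_summaries():
    """Two-location variant: shared and unshared interneuron pools."""
    out = {"shared": [], "unshared": []}
    for s in TRANSLATION_SEEDS:
        out["shared"].append(
            run_translation_protocol(ProtocolConfig.desk(seed=s)).summary)
        out["unshared"].append(
            run_translation_protocol(ProtocolConfig.desk(
                seed=s, shared_interneurons=False)).summary)
    return out


def vertical_index_gain(summary: dict, pop: str) -> np.ndarray:
    """Per-subpopulation change of the vertical tuning index.

    Index = response to the vertical bar minus the mean response to the other
    stimuli; gain = post-refinement minus post-development.
    """
    tc = summary["pc_tuning_curves"][pop]
    out = {}
    for probe in ("post_dev_probe", "post_probe"):
        m = np.asarray(tc[probe])
        out[probe] = m[:, 0] - m[:, 1:].mean(axis=1)
    return out["post_probe"] - out["post_dev_probe"]
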