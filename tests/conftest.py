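import numpy as np
import pytest

from shapeseq import FragmentCounts, RunConfig, TargetRNA

# 91-nt target: 72 probed positions, RT primer site at 73-91.  The probed
# region carries an AG-rich ribosome-binding-like stretch around 36-46 so
# window-scan fixtures use realistic coordinates.
DEMO_SEQUENCE = (
    "GGACUGCUGAAGGGCAAUCCGCUGAAGCGGAUACGGCGUUCACGCUUAUGGCUAAGGAGGACAGCUAUGAGC"
    "GAUCGUAGCUAGGCUAAGC"
)


@pytest.fixture(scope="session")
def demo_target() -> TargetRNA:
    return TargetRNA("demo", DEMO_SEQUENCE, probed_end=72,
                     rt_primer_start=73, rt_primer_end=91)


@pytest.fixture(scope="session")
def run_config(demo_target) -> RunConfig:
    return RunConfig(targets=[demo_target])


def make_counts(X, X_full, target="demo", channel="plus") -> FragmentCounts:
    return FragmentCounts(target, channel, np.asarray(X, dtype=np.int64), X_full)
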