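import numpy as np
import pandas as pd
import pytest

from chromastress.responsiveness import DifferenceMap


def make_diffmap(values: np.ndarray, mutants, times, probes=None) -> DifferenceMap:
    """Assemble a DifferenceMap from a probes x (mutant*time) array.

    ``values`` columns are ordered mutant-major: all times of mutant 0,
    then mutant 1, ...
    """
    values = np.asarray(values, dtype=float)
    if probes is None:
        probes = [f"p{i}" for i in range(values.shape[0])]
    cols = pd.MultiIndex.from_tuples(
        [(m, t) for m in mutants for t in times], names=["mutant", "time_min"])
    df = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                      columns=cols)
    return DifferenceMap(values=df, mask=~np.isfinite(df))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
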