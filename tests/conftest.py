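import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from coresort.io import AbundanceTable, GroupDesign


def make_table(values, accessions=None, samples=None, confidence=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    accessions = accessions or [f"P{i:03d}" for i in range(n)]
    samples = samples or [f"S{j}" for j in range(m)]
    data = pd.DataFrame(values, index=accessions, columns=samples)
    symbols = pd.Series([a.upper() for a in accessions], index=accessions)
    conf = None
    if confidence is not None:
        conf = pd.Series(confidence, index=accessions)
    return AbundanceTable(data, symbols, conf, scale=scale)


def make_design(n_ref=5, n_comp=5, ref="MACS", comp="FACS"):
    assignment = {f"S{j}": ref for j in range(n_ref)}
    assignment.update({f"S{j + n_ref}": comp for j in range(n_comp)})
    return GroupDesign(assignment, ref, comp)


@pytest.fixture
def two_group_design():
    return make_design()


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
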