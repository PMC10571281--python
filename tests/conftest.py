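import numpy as np
import pytest

from mscua import CostUtilityAnalysis, Strategy, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def analysis(params):
    return CostUtilityAnalysis(params)


@pytest.fixture(scope="session")
def base_case(analysis):
    """Deterministic base-case evaluation of all three strategies."""
    return analysis.run()


@pytest.fixture(scope="session")
def matrices(params):
    from mscua import build_matrix

    return {s: build_matrix(params, s) for s in Strategy}


def make_matrix(rows: dict) -> np.ndarray:
    """7x7 matrix from {from_state: {to_state: p}}; diagonal absorbs the rest."""
    m = np.zeros((7, 7))
    for i in range(7):
        out = rows.get(i, {})
        for j, p in out.items():
            m[i, j] = p
        m[i, i] = 1.0 - sum(out.values())
    return m
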