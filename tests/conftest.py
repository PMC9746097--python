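import numpy as np
import pytest

from rrmmcea import base_case


@pytest.fixture(scope="session")
def base():
    return base_case()


@pytest.fixture(scope="session")
def base_tables(base):
    """Base-case strategy results and frontier, shared across tests."""
    from rrmmcea import compute_icers, evaluate_all

    results = evaluate_all(base)
    return results, compute_icers(results)
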