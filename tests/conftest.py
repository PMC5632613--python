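import matplotlib
import pandas as pd
import pytest

matplotlib.use("Agg")

from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")

from perchflow.datasets import finch_logger_index, finch_reads, finch_visits


@pytest.fixture
def reads() -> pd.DataFrame:
    """Ten raw reads of one finch at two feeders on one evening."""
    return finch_reads()


@pytest.fixture
def visit_table() -> pd.DataFrame:
    """Fifteen consolidated visits of the example finch at three feeders."""
    return finch_visits()


@pytest.fixture
def logger_index() -> pd.DataFrame:
    return finch_logger_index()
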