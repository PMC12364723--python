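import numpy as np
import pandas as pd
import pytest

from medimr.sumstats import COLUMNS


def mk_records(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical sumstats frame from terse row dicts."""
    defaults = dict(chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                    beta=0.1, se=0.01, pval=1e-8, n=100000)
    out = []
    for i, r in enumerate(rows):
        d = {**defaults, "snp": f"rs{i + 1}", **r}
        out.append(d)
    df = pd.DataFrame(out)
    return df[COLUMNS]


@pytest.fixture
def records_factory():
    return mk_records


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)
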