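import numpy as np
import pandas as pd
import pytest

from ddgen import synthgen


def make_sumstats(rows: list[dict]) -> pd.DataFrame:
    """Build a summary-statistics frame from terse row dicts."""
    defaults = {"CHR": "1", "BP": 1000, "A1": "A", "A2": "G", "Z": 1.0, "N": 10_000}
    full = []
    for i, row in enumerate(rows):
        r = {"SNP": f"rs{i + 1}", **defaults, **row}
        full.append(r)
    columns = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N"]
    df = pd.DataFrame(full, columns=columns if not full else None)
    from ddgen.sumstats import two_tailed_p

    if "P" not in df.columns:
        df["P"] = two_tailed_p(df["Z"].to_numpy(dtype=float))
    return df


@pytest.fixture(scope="session")
def small_blocks():
    """Ten AR(1) blocks of 12 SNPs with varied decay."""
    return synthgen.simulate_ld_blocks(
        sizes=12, n_blocks=10, ld_param=(0.1, 0.9), seed=123
    )


@pytest.fixture(scope="session")
def two_trait_tables(small_blocks):
    truth = synthgen.simulate_effects(
        small_blocks, h2=(0.3, 0.3), rg=0.5, seed=7
    )
    t1 = synthgen.simulate_sumstats(truth, small_blocks, n=20_000, seed=8, trait=0)
    t2 = synthgen.simulate_sumstats(truth, small_blocks, n=20_000, seed=9, trait=1)
    return truth, t1, t2
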