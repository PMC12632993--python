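import numpy as np
import pytest

from lossycomp import synthetic as syn
from lossycomp.synthetic import MSTParams, ResponsePolicy, gen_responses


@pytest.fixture(scope="session")
def shape_images():
    """64 small parametric shape stimuli shared across training tests."""
    return syn.gen_shape_images(64, 16, seed=0)


@pytest.fixture(scope="session")
def mst_table():
    return syn.gen_task_tables("mst", seed=1)


@pytest.fixture(scope="session")
def answered_mst(mst_table):
    """MST table with a mid-discriminability simulated responder."""
    disc = {s: 0.6 for s in mst_table.loc[mst_table.condition == "lure", "stimulus"]}
    return gen_responses(mst_table, disc, ResponsePolicy(p_miss=0.05), seed=2)


def make_participants(n, seed0=0, disc_of_bin=None, policy=None, n_study=64, n_test=96):
    """Tables for n simulated participants with bin-tied discriminability."""
    tables, lossmap = [], {}
    for p in range(n):
        t = syn.gen_task_tables(
            "mst", MSTParams(n_study=n_study, n_test=n_test, participant=f"p{p:03d}"),
            seed=seed0 + p,
        )
        lures = t.loc[t.condition == "lure", ["stimulus", "lure_bin"]]
        disc = {
            r.stimulus: (disc_of_bin(r.lure_bin) if disc_of_bin else 0.5)
            for r in lures.itertuples()
        }
        tables.append(gen_responses(t, disc, policy, seed=10_000 + seed0 + p))
        lossmap.update(disc)
    return tables, lossmap
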