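import logging

import numpy as np
import pandas as pd
import pytest

from caml.genotyper import CALL_COLUMNS, CohortGenotypeTable, STATUS_CALLED
from caml.simulate import (
    SimulationConfig,
    end_to_end_fixture,
    make_planted_caml,
    simulate_reference,
)

logging.getLogger("caml").setLevel(logging.ERROR)


def make_table(rows, cohorts):
    """rows: (sample_id, locus_id, allele_a, allele_b[, status])."""
    full = []
    for row in rows:
        if len(row) == 4:
            s, l, a, b = row
            status = STATUS_CALLED
        else:
            s, l, a, b, status = row
        depth = 20 if status == STATUS_CALLED else 0
        full.append((s, l, a, b, depth, status))
    calls = pd.DataFrame(full, columns=CALL_COLUMNS)
    return CohortGenotypeTable(calls, cohorts)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small but complete simulated pipeline input set (reads on disk)."""
    out = tmp_path_factory.mktemp("fixture")
    base = SimulationConfig(seed=11, n_loci=25, n_case=8, n_control=8)
    _, truth = simulate_reference(base, np.random.default_rng(base.seed))
    config = SimulationConfig(
        seed=11,
        n_loci=25,
        n_case=8,
        n_control=8,
        depth_mean=30.0,
        planted_caml=make_planted_caml(truth, [2, 7, 12], 0.9, 0.1),
    )
    return end_to_end_fixture(config, str(out))
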