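import numpy as np
import pandas as pd
import pytest

import epimutkit as ek

GENS = list(range(2, 21, 2))


@pytest.fixture(scope="session")
def worked_examples():
    return ek.emit_worked_examples()


@pytest.fixture(scope="session")
def sim_default():
    """Moderate-size simulation with strong effects shared by several tests."""
    cfg = ek.SimConfig(n_genes=2000, n_elements=3000, seed=7, delta=4.0,
                       environmental_events=10)
    return ek.simulate(cfg)


@pytest.fixture(scope="session")
def called_statuses(sim_default):
    """Epimutation calls per (lineage, assay) for the default simulation."""
    out = {}
    for (lin, assay), ct in sim_default.counts.items():
        zt, _ = ek.ma_zscores(ek.normalize_counts(ct))
        out[(lin, assay)] = ek.call_epimutations(zt)
    return out


def make_status(vec, lineage="A", assay="atac", locus="L1", gens=None):
    gens = gens if gens is not None else GENS[: len(vec)]
    df = pd.DataFrame([vec], index=pd.Index([locus], name="locus_id"), columns=gens)
    return ek.StatusTable(lineage, assay, df)


def random_status_frame(rng, n_loci, n_gens, rate, gens=None):
    gens = gens if gens is not None else list(range(2, 2 + 2 * n_gens, 2))
    vals = np.where(
        rng.random((n_loci, n_gens)) < rate,
        np.where(rng.random((n_loci, n_gens)) < 0.5, 1, -1),
        0,
    )
    return pd.DataFrame(vals, index=[f"l{i}" for i in range(n_loci)], columns=gens)
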