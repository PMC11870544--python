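import numpy as np
import pandas as pd
import pytest

from stimqtl import simulate as sim


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale design shared by several suites (24 donors, toy genome)."""
    return sim.SimDesign(n_donors=24, n_snps=300, n_genes=60, n_peaks=80,
                         cells_per_donor_context=15, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    gm = sim.simulate_genotypes(small_design)
    cells = sim.simulate_cells(small_design)
    expr, expr_truth, gene_mod = sim.simulate_expression(gm, cells,
                                                         small_design)
    return {"design": small_design, "genotypes": gm, "cells": cells,
            "expr": expr, "expr_truth": expr_truth, "gene_mod": gene_mod}


@pytest.fixture
def rng(request):
    """Deterministic per-test generator, independent of execution order."""
    import zlib

    return np.random.default_rng(zlib.crc32(request.node.name.encode()))
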