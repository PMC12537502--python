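"""Session fixtures: one full synthetic study shared across test modules.

The study mirrors the package's reference configuration: a 2 × 1 Mb genome,
six cell types × 400 nuclei, signal-to-noise 5, 60 planted peaks (40%
broad) plus 10 nucleosomal decoys, H3K27me3 domains over 40% of broad
peaks.  Building it once keeps the suite fast while letting the calling,
specificity and silencer tests all exercise realistic inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from creevo import acr
from creevo import simulate as sim

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study():
    genome, genes, truth = sim.simulate_reference(seed=STUDY_SEED)
    h3k, nuc, meth = sim.simulate_epigenome(genome, truth, seed=STUDY_SEED + 1)
    cell_types = sorted(set(truth.peaks["peak_class"]) - {"broad"})
    plan = {ct: 400 for ct in cell_types}
    ins, cells = sim.simulate_fragments(genome, truth, plan, snr=5.0, seed=STUDY_SEED + 2)
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "h3k27me3": h3k,
        "nucleosomes": nuc,
        "methylation": meth,
        "insertions": ins,
        "cells": cells,
        "cell_types": cell_types,
    }


@pytest.fixture(scope="session")
def called_atlas(study):
    atlas, mat, per_ct = acr.call_acrs(
        study["insertions"], study["cells"], study["genome"], study["nucleosomes"],
        seed=STUDY_SEED + 3,
    )
    return {"atlas": atlas, "matrix": mat, "per_celltype": per_ct}


@pytest.fixture()
def rng():
    # fresh generator per test: results do not depend on execution order
    return np.random.default_rng(2024)
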