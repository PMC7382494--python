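from __future__ import annotations

import numpy as np
import pytest

from pantx.pipeline import run_synthetic_pipeline
from pantx.simulate import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_cds(rng, n_codons):
    """ATG + stop-free interior + TAA, so the coding frame is unambiguous."""
    inner = "".join(_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n_codons - 2))
    return "ATG" + inner + "TAA"


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """One full synthetic pipeline run at study defaults, shared across tests."""
    work = tmp_path_factory.mktemp("pipeline")
    return run_synthetic_pipeline(SimParams(), seed=42, workdir=work)


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """A scaled-down pipeline run for structural checks."""
    work = tmp_path_factory.mktemp("pipeline_small")
    return run_synthetic_pipeline(SimParams(n_loci=25), seed=7, workdir=work)
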