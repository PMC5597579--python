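import numpy as np
import pytest

import spikechip as sc


@pytest.fixture(scope="session")
def study():
    """Default simulated-study design (layout, occupancy model, bound sets)."""
    return sc.build_study_model()


@pytest.fixture(scope="session")
def layout(study):
    return study.model.layout


@pytest.fixture
def tiny_layout():
    """Two short chromosomes with a handful of genes on both strands."""
    return sc.GenomeLayout(
        chromosomes=[("chrA", 1000), ("chrB", 600)],
        domains=[sc.Domain("chrA", 400, 500, "cnt")],
        genes=[
            sc.Gene("gA1", "chrA", 100, 300, "+"),
            sc.Gene("gA2", "chrA", 600, 900, "-"),
            sc.Gene("gB1", "chrB", 100, 400, "+"),
        ],
    )


def make_track(layout, bin_width, fill=0.0, kind="count"):
    t = sc.BinnedTrack.zeros(layout, bin_width, kind=kind)
    if fill:
        for c in t.values:
            t.values[c][:] = fill
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
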