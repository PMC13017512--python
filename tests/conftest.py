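import numpy as np
import pytest

from admixkit import genodata, synthgen


@pytest.fixture
def tiny_panel():
    """Hand-written 4-site × 3-sample panel with one missing call."""
    sites = genodata.make_sites(
        ["1", "1", "1", "2"],
        [100, 200, 300, 100],
        ["A", "A", "C", "G"],
        ["C", "G", "T", "T"],
    )
    samples = genodata.make_samples(
        ["s1", "s2", "s3"], ["P1", "P1", "P2"], ploidy=[1, 2, 2]
    )
    calls = np.array(
        [
            [0, 1, 2],
            [1, 2, 0],
            [genodata.MISSING, 0, 1],
            [0, 1, 1],
        ],
        dtype=np.int8,
    )
    return genodata.GenotypePanel(sites, samples, calls)


def complete_panel_from_graph(graph, specs, n_snps, seed):
    """Panel with no missingness sampled from an admixture graph."""
    rng = np.random.default_rng(seed)
    freqs = synthgen.simulate_frequencies(graph, n_snps, rng)
    return synthgen.sample_panel(freqs, specs, rng)


@pytest.fixture
def star_graph():
    """Outgroup plus two sister populations sharing drift after the split."""
    return synthgen.AdmixtureGraph(
        [
            synthgen.DriftEdge("root", "O", 0.08),
            synthgen.DriftEdge("root", "AB", 0.06),
            synthgen.DriftEdge("AB", "A", 0.03),
            synthgen.DriftEdge("AB", "B", 0.03),
        ]
    )
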