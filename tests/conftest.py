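"""Shared fixtures: small synthetic bundles reused across test modules."""

import pytest

from kinetoedit.simulate import ankaliazontas_like, simulate_all, simulate_mt, spiralis_like


@pytest.fixture(scope="session")
def ank_bundle():
    """Pan-editing-dominant bundle (the default study conditions, seed 42)."""
    return simulate_all(ankaliazontas_like(seed=42))


@pytest.fixture(scope="session")
def small_mt_bundle():
    """A compact mitochondrial bundle for fast per-operation tests."""
    params = spiralis_like(seed=11, n_genes=4, n_minicircles=4)
    return simulate_mt(params)
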