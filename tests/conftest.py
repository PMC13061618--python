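import numpy as np
import pytest

from veiscope import (
    GaborParams,
    SynthesisConfig,
    make_complex_cell,
    make_simple_cell,
    naturalistic_images,
    synthesize_mei,
    synthesize_veis,
)

#: reduced synthesis settings used throughout the suite: same procedure,
#: smaller iteration counts and a coarser diversity-weight grid
FAST_CONFIG = dict(vei_iters=800, lambda_grid=tuple(np.geomspace(1e-4, 5e-2, 4)))


@pytest.fixture(scope="session")
def gabor_params():
    return GaborParams(sigma=6.0, wavelength=10.0, theta=0.3, phase=1.0)


@pytest.fixture(scope="session")
def simple_cell(gabor_params):
    return make_simple_cell(gabor_params)


@pytest.fixture(scope="session")
def complex_cell(gabor_params):
    return make_complex_cell(gabor_params)


@pytest.fixture(scope="session")
def image_pool():
    return naturalistic_images(60, seed=11)


@pytest.fixture(scope="session")
def simple_mei(simple_cell):
    return synthesize_mei(simple_cell, SynthesisConfig(seed=1, **FAST_CONFIG))


@pytest.fixture(scope="session")
def complex_mei(complex_cell):
    return synthesize_mei(complex_cell, SynthesisConfig(seed=1, **FAST_CONFIG))


@pytest.fixture(scope="session")
def complex_veis(complex_cell, complex_mei):
    return synthesize_veis(complex_cell, complex_mei,
                           SynthesisConfig(seed=1, **FAST_CONFIG))


@pytest.fixture(scope="session")
def simple_veis(simple_cell, simple_mei):
    return synthesize_veis(simple_cell, simple_mei,
                           SynthesisConfig(seed=1, **FAST_CONFIG))


from veiscope.bipartite import bipartite_analysis
from veiscope.synthetic import planted_bipartite_neuron

SCALED_BIPARTITE = dict(n_steps=150, n_crops=8, n_refine_iters=100)

@pytest.fixture(scope="session")
def planted_pipeline():
    """Planted bipartite neuron run through MEI -> VEIs -> bipartite series."""
    from veiscope import synthesize_mei, synthesize_veis

    planted = planted_bipartite_neuron(seed=0)
    cfg = SynthesisConfig(seed=2, vei_iters=800,
                          lambda_grid=(1e-4, 2e-3, 5e-2))
    mei = synthesize_mei(planted.neuron, cfg)
    veis = synthesize_veis(planted.neuron, mei, cfg)
    result = bipartite_analysis(planted.neuron, mei, veis,
                                fractions=(0.2, 0.3, 0.4, 0.5, 0.6),
                                config=cfg, seed=3, **SCALED_BIPARTITE)
    return planted, mei, veis, result, cfg
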