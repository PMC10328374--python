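import numpy as np
import pytest

from osteoquant.synthetic import (
    BendingTruth,
    GeometryTruth,
    IndentationTruth,
    SpectrumTruth,
    gen_bending_curve,
    gen_cross_section,
    gen_indentation_curve,
    gen_raman_spectrum,
    silica_reduced_modulus,
)


@pytest.fixture(scope="session")
def annulus_case():
    """Circular annulus r_o=0.9, r_i=0.6 mm at 6 um voxels, no pores."""
    truth = GeometryTruth((0.9, 0.9), (0.6, 0.6))
    grid, labels, truth = gen_cross_section(truth, seed=11, n_slices=2)
    return grid, labels, truth


@pytest.fixture(scope="session")
def porous_annulus_case():
    truth = GeometryTruth((0.9, 0.9), (0.6, 0.6), pore_fraction=0.05)
    grid, labels, truth = gen_cross_section(truth, seed=5, n_slices=8)
    return grid, labels, truth


@pytest.fixture(scope="session")
def bending_case():
    truth = BendingTruth(
        stiffness=110.0, yield_force=16.5, ultimate_force=18.0,
        post_yield_displacement=0.15,
    )
    curve, truth = gen_bending_curve(truth, seed=3)
    return curve, truth


@pytest.fixture(scope="session")
def silica_er():
    return silica_reduced_modulus()


@pytest.fixture(scope="session")
def silica_indent(silica_er):
    truth = IndentationTruth(reduced_modulus=silica_er, hardness=9.0)
    curve, record = gen_indentation_curve(truth, seed=21)
    return curve, record, truth


@pytest.fixture(scope="session")
def bone_spectrum_clean():
    truth = SpectrumTruth()
    spec, truth = gen_raman_spectrum(truth, step=1.0, seed=2)
    return spec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
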