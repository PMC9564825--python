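import numpy as np
import pytest

import mtlattice as mt


@pytest.fixture(scope="session")
def default_singlet():
    """Default 13-pf singlet decorated with a full non-seam lumenal spiral."""
    model, truth = mt.build_singlet()
    model, truth = mt.decorate_mips(model, truth, mt.MIPDecoration(class_name="tails"))
    return model, truth


@pytest.fixture(scope="session")
def default_annotation(default_singlet):
    model, _ = default_singlet
    return mt.annotate(model)


@pytest.fixture(scope="session")
def doublet_arc():
    """Doublet with a 3-copy striation arc on B02-B05."""
    model, truth = mt.build_doublet()
    model, truth = mt.decorate_mips(
        model, truth,
        mt.MIPDecoration(class_name="spaca9", pf_span=["B02", "B03", "B04", "B05"]),
    )
    return model, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_params(**kw):
    """Compact lattice parameters for fast parameter sweeps."""
    defaults = dict(n_repeats=4)
    defaults.update(kw)
    return mt.LatticeParams(**defaults)


def small_template(params, n_atoms=24, seed=0):
    return mt.build_dimer_template(n_atoms_per_monomer=n_atoms, seed=seed,
                                   monomer_len=params.monomer_len)
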