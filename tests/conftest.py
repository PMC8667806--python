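import numpy as np
import pandas as pd
import pytest

from sparsemeld import SyntheticSpec, generate_native, generate_peaklist
from sparsemeld.io_formats import ReferenceStructure


def reference_from_conformation(conf) -> ReferenceStructure:
    """Wrap a Cα chain as a ReferenceStructure (CA atoms only)."""
    atoms = pd.DataFrame(
        [(i + 1, "CA", *conf.coords[i]) for i in range(len(conf))],
        columns=["res", "atom", "x", "y", "z"],
    )
    return ReferenceStructure(conf.sequence, atoms)


@pytest.fixture(scope="session")
def hairpin_target():
    """20-residue helix-hairpin native plus its clean (unambiguous) peak list."""
    spec = SyntheticSpec(n_residues=20, seed=1)
    native = generate_native(spec)
    peaks, truth = generate_peaklist(native, spec)
    return spec, native, peaks, truth


@pytest.fixture(scope="session")
def noisy_target(hairpin_target):
    """Same native with ambiguous + spurious peaks."""
    spec, native, _, _ = hairpin_target
    noisy_spec = SyntheticSpec(
        n_residues=20, seed=1, ambiguity_target=3.0, p_spurious=0.2
    )
    peaks, truth = generate_peaklist(native, noisy_spec)
    return noisy_spec, native, peaks, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
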