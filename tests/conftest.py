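import numpy as np
import pytest

from flexidock.structure_io import CaTrace
from flexidock.synthetic_data import ComplexSpec, EnsembleSpec, generate_complex, generate_ensemble

#: a varied 50-residue sequence for correspondence/alignment tests
SEQ50 = "MQAIKCVVVGDGAVGKTCLLISYTTNAFPGEYIPTVFDNYSANVMVDGKP"

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def make_trace(sequence: str = SEQ50, start: int = 1, coords: np.ndarray | None = None,
               label: str = "T", chain: str = "A") -> CaTrace:
    n = len(sequence)
    if coords is None:
        coords = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    return CaTrace(
        structure_id=label,
        chain_id=chain,
        residue_numbers=list(range(start, start + n)),
        icodes=[""] * n,
        residue_names=[_AA1TO3[c] for c in sequence],
        coords=coords,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def core_loop_ensemble():
    """Ensemble with a rigid core (sigma 0.1 A) and two mobile loops (2.0 A)."""
    spec = EnsembleSpec(
        n_residues=80,
        n_conformers=6,
        sigma=0.1,
        sigma_ranges=[(20, 32, 2.0), (60, 70, 2.0)],
        seed=5,
    )
    return generate_ensemble(spec), spec


@pytest.fixture
def toy_complex():
    spec = ComplexSpec(
        n_residues=60,
        contacts={5: 3.0, 39: 3.0, 41: 3.2, 52: 2.8},
        hbond=(56, 2.9, 170.0),
        seed=2,
    )
    return generate_complex(spec)
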