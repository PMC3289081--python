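import numpy as np
import pytest

from sprot.calibration import build_ecdf_table
from sprot.fixtures import FixtureSpec, make_family_dataset
from sprot.global_alignment import SProtMeasure
from sprot.sphere_similarity import SphereParams
from sprot.structure_io import Atom, ProteinStructure, Residue


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The standard labeled fixture set: 3 families x 4 members, sigma=0.5 A."""
    return make_family_dataset(FixtureSpec(n_families=3, members_per_family=4, sigma=0.5, seed=1))


@pytest.fixture(scope="session")
def calibration_table():
    """ECDF table calibrated on a disjoint synthetic set (seed 99)."""
    cal = make_family_dataset(FixtureSpec(n_families=3, members_per_family=2, sigma=0.5, seed=99))
    return build_ecdf_table(cal, SphereParams(), sampling=50_000, seed=0, max_total_pairs=20_000)


@pytest.fixture(scope="session")
def measure(calibration_table):
    return SProtMeasure(calibration_table)


def make_ca_chain(coords, chain_id="chain", heavy_offsets=None):
    """Build a CA-only structure from raw coordinates (test helper).

    ``heavy_offsets`` optionally adds one extra heavy atom per residue at
    CA + offset.
    """
    coords = np.asarray(coords, dtype=float)
    residues = []
    for i, ca in enumerate(coords):
        atoms = [Atom("CA", "C", ca.copy())]
        if heavy_offsets is not None:
            atoms.append(Atom("CB", "C", ca + heavy_offsets[i]))
        residues.append(Residue(i, "A", ca.copy(), atoms))
    return ProteinStructure(chain_id, residues)
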