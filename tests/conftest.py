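import numpy as np
import pytest

from pinmap.interface import classify_contacts, interface_report, partition_from_chains
from pinmap.synthetic import ComplexSpec, build_complex


MINIMAL_GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00 91.30           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00 91.30           C
ATOM      3  C   GLY A   1      10.729   6.768  -4.123  1.00 91.30           C
ATOM      4  O   GLY A   1       9.580   7.106  -4.430  1.00 91.30           O
TER
END
"""


@pytest.fixture(scope="session")
def gly_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "gly.pdb"
    path.write_text(MINIMAL_GLY_PDB)
    return path


@pytest.fixture(scope="session")
def complex_bundle():
    """Default synthetic 2:1 complex with PAE and ground truth (built once)."""
    return build_complex(ComplexSpec())


@pytest.fixture(scope="session")
def dimer_partition():
    return partition_from_chains(["A", "B"], ["C"])


@pytest.fixture(scope="session")
def complex_contacts(complex_bundle, dimer_partition):
    model, _pae, _truth = complex_bundle
    return classify_contacts(model, dimer_partition)


@pytest.fixture(scope="session")
def complex_report(complex_bundle, dimer_partition):
    model, _pae, _truth = complex_bundle
    return interface_report(model, dimer_partition)


def res_pairs(contacts):
    """(chain,res)-(chain,res)-kind triples of a contact list."""
    return {((c.atom_a.chain_id, c.atom_a.res_seq),
             (c.atom_b.chain_id, c.atom_b.res_seq), c.kind)
            for c in contacts}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
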