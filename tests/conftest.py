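import numpy as np
import pytest

from quatfun import coevolution as cv
from quatfun.structure_annotation import annotate_structure, parse_structure
from quatfun.synthetic_data import (
    DimerSpec,
    SignalSpec,
    generate_couplings,
    generate_dimer,
)

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LEU B   1       0.000   0.000   3.800  1.00  0.00           C
ATOM      4  CA  VAL B   2       3.800   0.000   3.800  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def sbs_spec():
    return DimerSpec(ligand_mode="SBS", seed=7)


@pytest.fixture(scope="session")
def sbs_dimer(sbs_spec):
    pdb_text, truth = generate_dimer(sbs_spec)
    return pdb_text, truth


@pytest.fixture(scope="session")
def sbs_annotated(sbs_dimer):
    """(structure, truth, topology, annotations, sites, contacts)."""
    pdb_text, truth = sbs_dimer
    s = parse_structure(pdb_text, "sbs_toy")
    topology, annotations, sites, contacts = annotate_structure(
        s, rsa_reference=truth["rsa_reference"]
    )
    return s, truth, topology, annotations, sites, contacts


@pytest.fixture(scope="session")
def mbs_annotated():
    pdb_text, truth = generate_dimer(DimerSpec(ligand_mode="MBS", seed=7))
    s = parse_structure(pdb_text, "mbs_toy")
    topology, annotations, sites, contacts = annotate_structure(
        s, rsa_reference=truth["rsa_reference"]
    )
    return s, truth, topology, annotations, sites, contacts


@pytest.fixture(scope="session")
def region_sets(sbs_annotated):
    s, truth, topology, annotations, sites, contacts = sbs_annotated
    interface = {k for ks in topology.interface_residues.values() for k in ks}
    surface = {k for k, a in annotations.items() if a.is_surface}
    non_interface = {k for k in annotations if k not in interface}
    return interface, surface, non_interface


def coupling_matrix_for(structure, truth, signal: SignalSpec):
    df, stats = generate_couplings(signal, truth)
    return cv.read_coupling_scores(
        df, cv.homodimer_position_map(structure),
        length=stats["L"], neff=stats["neff"],
    )


@pytest.fixture(scope="session")
def null_cm(sbs_annotated):
    s, truth = sbs_annotated[0], sbs_annotated[1]
    return coupling_matrix_for(s, truth, SignalSpec(lbr_lbr=3.0, seed=99))


@pytest.fixture(scope="session")
def strong_cm(sbs_annotated):
    s, truth = sbs_annotated[0], sbs_annotated[1]
    return coupling_matrix_for(
        s, truth,
        SignalSpec(cross_interface=2.0, lbr_interface=3.0, lbr_lbr=3.0,
                   conservation_shift=1.0, seed=99),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
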