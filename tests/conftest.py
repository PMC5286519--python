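import numpy as np
import pytest

from loopstab import synthetic
from loopstab.structure import AtomRecord, StructureModel


@pytest.fixture(scope="session")
def toy_model_and_truth():
    """30-residue chain, helix 1-10 / strand 21-30, B rising 10..39."""
    return synthetic.make_toy_structure(
        30, [("helix", 1, 10), ("strand", 21, 30)], b_profile=np.arange(30) + 10.0
    )


@pytest.fixture(scope="session")
def toy_model(toy_model_and_truth):
    return toy_model_and_truth[0]


def make_atom(serial, name, element, chain, resnum, resname, xyz, b=10.0, hetero=False):
    return AtomRecord(
        serial=serial, name=name, element=element, alt_loc="", chain_id=chain,
        residue_number=resnum, residue_name=resname, coordinates=tuple(xyz),
        b_factor=b, is_hetero=hetero,
    )


@pytest.fixture()
def scene_builder():
    """Build a StructureModel from (name, element, chain, resnum, resname, xyz) rows."""

    def build(rows):
        return StructureModel(
            [make_atom(i + 1, *row) for i, row in enumerate(rows)]
        )

    return build
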