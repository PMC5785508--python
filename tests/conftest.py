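import pytest

from ifacecons.io_formats import AtomRecord, Structure
from ifacecons.synthetic import ComplexSpec, make_complex


def atom(serial, chain, res_seq, x, y, z, element="C", name="CA",
         res_name="ALA", alt_loc="", i_code="", is_het=False, occupancy=1.0):
    return AtomRecord(serial=serial, atom_name=name, alt_loc=alt_loc,
                      res_name=res_name, chain_id=chain, res_seq=res_seq,
                      i_code=i_code, x=x, y=y, z=z, element=element,
                      occupancy=occupancy, is_het=is_het)


@pytest.fixture
def dimer_structure():
    """Two overlapping carbon atoms in one chain (the convergence fixture)."""
    return Structure(atoms=[
        atom(1, "A", 1, 0.0, 0.0, 0.0),
        atom(2, "A", 2, 4.0, 0.0, 0.0),
    ])


@pytest.fixture
def planted_complex():
    spec = ComplexSpec(n_res_target=20, n_res_partner=8,
                       patch_residues=(5, 6, 7), seed=0)
    structure, patch = make_complex(spec)
    return structure, patch
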