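import pytest

from memorient import potential, synthetic
from memorient.structure_io import AtomRecord, Residue, Structure

# Training fixture used across the suite: deliberately generous so the
# trained table is low-noise (see the parameter-recovery tolerances).
TRAIN_SEED = 1
TRAIN_N = 100
TRAIN_HELICES = 7
TRAIN_RES = 41


@pytest.fixture(scope="session")
def alpha_dist():
    return synthetic.DepthDistributionSpec.default_alpha()


@pytest.fixture(scope="session")
def training_structures(alpha_dist):
    return synthetic.sample_structures(alpha_dist, TRAIN_N, seed=TRAIN_SEED,
                                       n_helices=TRAIN_HELICES,
                                       residues_per_helix=TRAIN_RES)


@pytest.fixture(scope="session")
def alpha_table(training_structures):
    return potential.train_from_structures([s for s, _ in training_structures],
                                           meta={"kind": "alpha"})


def make_residue(chain_id, res_seq, res_name, atoms):
    """atoms: list of (name, (x, y, z)) tuples."""
    records = [
        AtomRecord(serial=i + 1, name=name, alt_loc=" ", res_name=res_name,
                   chain_id=chain_id, res_seq=res_seq, i_code=" ",
                   x=float(p[0]), y=float(p[1]), z=float(p[2]), element=name[0])
        for i, (name, p) in enumerate(atoms)
    ]
    return Residue(chain_id, res_seq, " ", res_name, records)


def make_structure(residue_specs, structure_id="test", het=()):
    """residue_specs: list of (chain_id, res_seq, res_name, atoms)."""
    chains = {}
    order = []
    for chain_id, res_seq, res_name, atoms in residue_specs:
        if chain_id not in chains:
            chains[chain_id] = []
            order.append(chain_id)
        chains[chain_id].append(make_residue(chain_id, res_seq, res_name, atoms))
    return Structure(id=structure_id, chains=[chains[c] for c in order],
                     het_molecules=list(het))
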