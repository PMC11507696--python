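import numpy as np
import pytest

from rnadecoy.consensus import run_turbo
from rnadecoy.core import SequenceGroup, SequenceRecord
from rnadecoy.decoygen import ShuffleSpec, shuffle_decoy
from rnadecoy.foldengine import EnergyModel
from rnadecoy.synthetic import FamilySpec, family_identity, generate_family, random_consensus_structure


@pytest.fixture(scope="session")
def energy_model():
    return EnergyModel()


@pytest.fixture(scope="session")
def small_family():
    """A compact synthetic family with a known consensus structure."""
    consensus = random_consensus_structure(60, seed=7)
    fam = generate_family(FamilySpec(seed=7, n_members=8, length=60,
                                     target_identity=0.65, name="demo",
                                     consensus_structure=consensus))
    return fam, consensus


@pytest.fixture(scope="session")
def group_with_decoy(small_family):
    """Five homologs plus one shuffled decoy, with truth labels."""
    fam, _ = small_family
    keep = family_identity(fam)
    decoy = shuffle_decoy(fam.members[7], ShuffleSpec(keep_fraction=keep, seed=3))
    members = list(fam.members[:5]) + [decoy]
    labels = ["homolog"] * 5 + ["decoy:shuffled"]
    return SequenceGroup(members=members, labels=labels)


@pytest.fixture(scope="session")
def turbo_result(group_with_decoy):
    """One consensus run shared by feature and classifier tests."""
    return run_turbo(group_with_decoy)


def random_sequence(rng: np.random.Generator, length: int) -> SequenceRecord:
    return SequenceRecord(id=f"r{length}_{rng.integers(1 << 20)}",
                          residues="".join(rng.choice(list("ACGU"), size=length)))
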