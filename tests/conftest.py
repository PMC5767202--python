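import numpy as np
import pytest

from lieflow import (
    CompoundEnergetics,
    LIEParameters,
    SimulationRecord,
    SyntheticSpec,
    TrainingCompound,
    UnboundReference,
    generate_training_set,
)


def make_energetics(compound_id, dv_pairs, unbound=(-35.0, -120.0)):
    """CompoundEnergetics whose delta interactions equal the given pairs."""
    ub = UnboundReference(mean_vdw=unbound[0], mean_ele=unbound[1])
    records = tuple(
        SimulationRecord(
            pose_id=f"p{i}",
            replicate_id="r0",
            mean_vdw=ub.mean_vdw + dv[0],
            mean_ele=ub.mean_ele + dv[1],
        )
        for i, dv in enumerate(dv_pairs)
    )
    return CompoundEnergetics(compound_id=compound_id, bound=records, unbound=ub)


@pytest.fixture
def benzimidazole_params():
    """Published parameter set for one congeneric-series LIE model."""
    return LIEParameters(alpha=0.33, beta=0.12, gamma=-13.0, temperature=300.0)


@pytest.fixture(scope="session")
def noisy_training():
    return generate_training_set(SyntheticSpec(n_compounds=15, seed=11))


@pytest.fixture(scope="session")
def noiseless_training():
    return generate_training_set(SyntheticSpec(n_compounds=15, seed=11, noise_sigma=0.0))
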