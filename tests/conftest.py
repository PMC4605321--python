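import numpy as np
import pytest

from rloopkmc.thermo import (
    AAVS1_PROTOSPACER,
    AAVS1_SGRNA,
    AAVS1_TRU_GRNA,
    EnergyModel,
    GuideTargetPair,
    load_energy_model,
)


@pytest.fixture(scope="session")
def model() -> EnergyModel:
    """The packaged 1 M NaCl / 37 C parameter set."""
    return load_energy_model()


@pytest.fixture(scope="session")
def degenerate_model(model) -> EnergyModel:
    """RNA:DNA table forced equal to DNA:DNA step-for-step: ddG == 0."""
    rna = {}
    for a in "ACGU":
        for b in "ACGU":
            dna_key = (a + b).replace("U", "T")
            rna[a + b] = model.dna_step(dna_key)
    return EnergyModel(
        nn_dna_dna=model.nn_dna_dna,
        nn_rna_dna=rna,
        nn_mismatch=model.nn_mismatch,
        dg_init=model.dg_init,
    )


@pytest.fixture(scope="session")
def aavs1_pair() -> GuideTargetPair:
    return GuideTargetPair(guide=AAVS1_SGRNA, protospacer=AAVS1_PROTOSPACER)


@pytest.fixture(scope="session")
def aavs1_tru_pair() -> GuideTargetPair:
    return GuideTargetPair(guide=AAVS1_TRU_GRNA, protospacer=AAVS1_PROTOSPACER)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_915)
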