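import numpy as np
import pytest

from chromotopo import synthgen, topo


@pytest.fixture(scope="session")
def noiseless_fe_record():
    """Noiseless bare-DNA force–extension series (Lp=34 nm, Lc=1716.66 nm)."""
    truth = synthgen.ForceExtensionTruth(seed=11, extension_noise_sd=0.0)
    return truth, synthgen.gen_force_extension(truth)


@pytest.fixture(scope="session")
def detected_ladder():
    """Noiseless rendered lane (center 0.4) run through detection + indexing."""
    truth = synthgen.LadderTruth(seed=21, center=0.4, concentration_param=0.3, noise_sd=0.0)
    lane = synthgen.gen_topo_lane(truth)
    return truth, topo.assign_linking_indices(topo.detect_bands(lane))


def lane_morse_fit(seed: int, center: float, noise_sd: float = 5.0) -> topo.MorseFit:
    """Full lane pipeline: generate -> detect -> index -> Morse."""
    truth = synthgen.LadderTruth(seed=seed, center=center, noise_sd=noise_sd)
    ladder = topo.assign_linking_indices(topo.detect_bands(synthgen.gen_topo_lane(truth)))
    return topo.morse_center(ladder)
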