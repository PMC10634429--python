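import numpy as np
import pytest

import culm3d
from culm3d.segmentation import params_for_intensity_model


@pytest.fixture(scope="session")
def phantoms():
    """The three reference phantoms: clean, noisy, branched."""
    return {name: culm3d.generate_phantom(spec) for name, spec in culm3d.suite().items()}


@pytest.fixture(scope="session")
def segmentations(phantoms):
    """End-to-end pipeline runs on each reference phantom."""
    out = {}
    for name, ph in phantoms.items():
        params = params_for_intensity_model(
            ph.spec.intensity_model, noise_sd=ph.spec.noise_sd
        )
        labels, log = culm3d.run_pipeline(ph.grid, params)
        out[name] = (labels, log, params)
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * int((a & b).sum()) / denom if denom else 1.0
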