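import warnings

import numpy as np
import pytest

from oirpipe.synth import SyntheticParams, apply_oir_phenotype, generate_vessel_tree

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def oir_sample():
    """One mouse-model OIR wholemount with full ground truth (256²)."""
    params = SyntheticParams(
        image_size=256,
        seed=3,
        target_obliteration_fraction=0.25,
        obliteration_mode="central",
        tuft_density=0.6,
        tortuosity=0.4,
        branch_rate=0.012,
        haemorrhage_rate=2.0,
    )
    tree = generate_vessel_tree(params)
    image, truth = apply_oir_phenotype(tree, params, group="oir", sample_id="oir_fix")
    return params, image, truth


@pytest.fixture(scope="session")
def control_sample():
    """A healthy control wholemount (no lesions), 256²."""
    params = SyntheticParams(image_size=256, seed=11)
    tree = generate_vessel_tree(params)
    image, truth = apply_oir_phenotype(
        tree, params, group="control", sample_id="ctrl_fix"
    )
    return params, image, truth


@pytest.fixture(scope="session")
def disc_image():
    """Noiseless two-level image: bright disc on dark background."""
    yy, xx = np.mgrid[0:128, 0:128]
    disc = np.hypot(yy - 64, xx - 64) <= 30
    return np.where(disc, 1.0, 0.0), disc
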