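import numpy as np
import pytest

import protoshift as ps


@pytest.fixture(scope="session")
def gt_noiseless():
    """Default band model with noise switched off."""
    return ps.load_default_ground_truth(noise_rel=0.0)


@pytest.fixture(scope="session")
def reference_25C(gt_noiseless):
    """Noise-free species extinction curves at 25 degC in water."""
    return ps.generate_species_references(gt_noiseless)


@pytest.fixture()
def small_box_frames():
    """A small enriched solvent box trajectory for solvation tests."""
    gt = ps.BoxGroundTruth(
        box_edge=3.0, n_water=60, n_cosolvent=8, enrichment=5.0,
        shell_radius=1.0, n_frames=10, seed=11,
    )
    return ps.generate_solvation_box(gt)
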