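import numpy as np
import pytest

from ncx import (
    ApSimConfig,
    ProfileSmoother,
    SliceMassCalibrator,
    paper_like_complexome_config,
    simulate_apms_study,
    simulate_complexome,
)
from ncx.pipeline import run_apms_pipeline


@pytest.fixture(scope="session")
def mini_config():
    """A reduced study design (3 antibodies, 80 background proteins) that
    keeps the full pipeline fast while preserving the study structure."""
    return ApSimConfig(
        n_background_proteins=80,
        n_antibodies_target=3,
        n_tuc_controls=3,
        include_ko_controls=True,
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_study(mini_config):
    return simulate_apms_study(mini_config)


@pytest.fixture(scope="session")
def mini_result(mini_study):
    bundle, truth = mini_study
    return run_apms_pipeline(bundle, bait_id=truth.bait_id), truth


@pytest.fixture(scope="session")
def bn_bundle():
    config = paper_like_complexome_config(seed=3)
    return simulate_complexome(config), config


@pytest.fixture(scope="session")
def bn_calibrated(bn_bundle):
    (bundle, truth), config = bn_bundle
    smoothed = ProfileSmoother(window=5).transform(bundle.matrix)
    slices = [
        int(np.argmax(smoothed.loc[pid].to_numpy())) + 1
        for pid in bundle.markers["protein_id"]
    ]
    calib = SliceMassCalibrator().fit(slices, bundle.markers["mass_kda"].to_numpy())
    return bundle, truth, smoothed, calib
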