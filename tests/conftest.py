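import pytest

import gliomaseg as gs

SEED = 1


@pytest.fixture(scope="session")
def suite():
    """The canonical phantom fixtures at full clinical-style scale."""
    return gs.phantom_suite(seed=SEED)


@pytest.fixture(scope="session")
def rg_results(suite):
    """Region-growing segmentations of every suite case: {name: (mask, diag)}."""
    return {name: gs.segment_rg(vol) for name, (vol, _) in suite.items()}


@pytest.fixture(scope="session")
def fcm_results(suite):
    """FCM segmentations of every suite case: {name: mask}."""
    return {name: gs.segment_fcm(vol, gs.FCMParams(seed=SEED))
            for name, (vol, _) in suite.items()}


@pytest.fixture(scope="session")
def components_phantom():
    """Noise-free clinical-style phantom whose core cross-sections all exceed
    the cleanup resolution (min_area), so exact recovery is attainable."""
    return gs.make_phantom(gs.clinical_spec(noise_sigma=0.0, core_radius=14.0))
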