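import numpy as np
import pytest

from gonadscan import panels
from gonadscan.synth import ProfileConfig


@pytest.fixture(scope="session")
def fig3_zero_noise():
    """fig3 genotype panel with noise disabled: exactly recoverable."""
    return panels.load_panel("fig3", noise_sd_pct=0.0)


@pytest.fixture(scope="session")
def fig6_zero_noise():
    return panels.load_panel("fig6", noise_sd_pct=0.0)


@pytest.fixture(scope="session")
def figs3_zero_noise():
    return panels.load_panel("figS3", noise_sd_pct=0.0)


@pytest.fixture
def flat_profile_cfg():
    def make(level=50.0, label="flat", tagged=True, noise_sd=0.0, n=1, max_cd=25, background=0.0):
        return ProfileConfig(
            genotype_label=label,
            breakpoints=[(1.0, level), (float(max_cd), level)],
            tagged=tagged,
            noise_sd=noise_sd,
            background_level=background,
            n_germlines=n,
            max_cd=max_cd,
        )

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
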