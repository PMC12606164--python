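import numpy as np
import pytest

from ligfit.constitutive import MaterialParameters
from ligfit.synthetic import LIGAMENTS, GeneratorConfig, specimen_curve


@pytest.fixture(scope="session")
def all_stats():
    return LIGAMENTS["ALL"]


@pytest.fixture(scope="session")
def nh_params():
    """NH+P4 at mu = 1 MPa with ligament-like fiber coefficients."""
    return MaterialParameters("NH", mu=1.0, C10=0.5, C4=3.55, C5=0.419)


@pytest.fixture(scope="session")
def mr_params():
    return MaterialParameters("MR", mu=1.0, C10=0.0005, C01=0.4995, C4=3.5, C5=0.3)


@pytest.fixture(scope="session")
def yeoh_params():
    return MaterialParameters("Yeoh", mu=1.0, C10=0.5, C20=0.2, C30=0.1, C4=1.0, C5=0.5)


@pytest.fixture(scope="session")
def three_laws(nh_params, mr_params, yeoh_params):
    return [nh_params, mr_params, yeoh_params]


@pytest.fixture(scope="session")
def clean_all_curve(all_stats):
    """Noise-free synthetic ALL curve built from the cohort mean points."""
    return specimen_curve(all_stats.mean_points(), GeneratorConfig(noise_sd_rel=0.0))
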