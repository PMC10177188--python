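import numpy as np
import pytest

from cpoct.attenuation import attenuation_volume, estimate_noise_floor
from cpoct.enface import detect_surface, enface_maps
from cpoct.synth import PhantomSpec, default_class_table, synthesize_volume


@pytest.fixture(scope="session")
def class_table():
    return default_class_table()


def single_class_spec(label: str, seed: int = 7, **kw) -> PhantomSpec:
    defaults = dict(depth_mm=4.0, nx=40, ny=40, heterogeneity="uniform", seed=seed)
    defaults.update(kw)
    defaults["layout"] = ((label, (0, 0, defaults["nx"], defaults["ny"])),)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def nct_phantom():
    """Homogeneous NCT phantom with speckle and a 1% noise floor."""
    spec = single_class_spec("NCT")
    vol, truth, noise_true = synthesize_volume(spec)
    return spec, vol, truth, noise_true


@pytest.fixture(scope="session")
def nct_attvol(nct_phantom):
    spec, vol, truth, noise_true = nct_phantom
    surf = detect_surface(vol)
    noise = estimate_noise_floor(vol, surface=surf)
    att = attenuation_volume(vol, noise=noise, surface=surf)
    return spec, truth, att


@pytest.fixture(scope="session")
def nct_maps(nct_attvol):
    spec, truth, att = nct_attvol
    return spec, truth, enface_maps(att)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, speckle-free homogeneous phantom (exact exponential)."""
    spec = single_class_spec("NCT", speckle=False, noise_floor_frac=0.0, nx=8, ny=8)
    vol, truth, noise_true = synthesize_volume(spec)
    return spec, vol, truth, noise_true
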