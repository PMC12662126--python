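import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecvatlas as ea

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_phantom():
    """The default full-resolution LV shell (0.4 x 0.4 x 1.0 mm), noise-free."""
    spec = ea.PhantomSpec()
    iodine, truth = ea.generate_phantom(spec)
    return spec, iodine, truth


@pytest.fixture(scope="session")
def coarse_phantom():
    """Uniform noise-free shell at 0.8 x 0.8 x 1.0 mm — fast shared fixture."""
    spec = ea.PhantomSpec(voxel_spacing=(0.8, 0.8, 1.0))
    iodine, truth = ea.generate_phantom(spec)
    return spec, iodine, truth


@pytest.fixture(scope="session")
def coarse_ecv(coarse_phantom):
    spec, iodine, _ = coarse_phantom
    return ea.compute_ecv(ea.IodineStudy(iodine, spec.blood_iodine, spec.hematocrit))


def build_study(lesions=(), noise_sigma=0.0, seed=0, spacing=(0.8, 0.8, 1.0), **spec_kw):
    """Phantom + ECV + compartments for a custom lesion layout (coarse grid)."""
    spec = ea.PhantomSpec(
        voxel_spacing=spacing,
        noise_sigma=noise_sigma,
        seed=seed,
        lesions=[ea.LesionSpec(**l) if isinstance(l, dict) else l for l in lesions],
        **spec_kw,
    )
    iodine, truth = ea.generate_phantom(spec)
    ecv = ea.compute_ecv(ea.IodineStudy(iodine, spec.blood_iodine, spec.hematocrit))
    return spec, ecv, truth


@pytest.fixture
def study_factory():
    return build_study
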