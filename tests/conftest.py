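import dataclasses

import pytest

import qspect as q


@pytest.fixture(scope="session")
def nema_spec():
    return q.nema_iec_body_phantom()


@pytest.fixture(scope="session")
def nema_truth(nema_spec):
    """Antialiased default-spacing ground truth (built once per session)."""
    return q.build_ground_truth(nema_spec)


@pytest.fixture(scope="session")
def nema_truth_nn(nema_spec):
    """Nearest-neighbor (voxel-center) rasterization: boundary voxels carry
    the full structure concentration, so VOI means are exact."""
    return q.build_ground_truth(nema_spec, supersample=1)


@pytest.fixture(scope="session")
def symbia_quiet():
    """Symbia profile with the Poisson noise switched off."""
    return dataclasses.replace(q.SYMBIA_LEHR, noise=False)


@pytest.fixture(scope="session")
def ideal_profile():
    """Perfect system: no blur, no noise, unit bias."""
    return q.ScannerProfile(name="symbia_lehr", psf_fwhm_mm=0.0, noise=False)
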