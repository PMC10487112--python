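"""Shared fixtures: simulated voxels processed once per session."""

import numpy as np
import pytest

from hgmrs import peakfit, specproc, synthspec
from hgmrs.containers import AcquisitionParams, Spectrum


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def healthy_truth():
    return synthspec.VoxelTruth(
        concentrations=synthspec.tissue_concentrations("gray"), noise_sd=0.0)


@pytest.fixture(scope="session")
def healthy_spec(healthy_truth, acq):
    """Noiseless, distortion-free gray-matter voxel through the full chain."""
    fid = synthspec.simulate_fid(healthy_truth, acq, seed=1)
    return specproc.process(fid)


@pytest.fixture(scope="session")
def healthy_panel(healthy_spec):
    return peakfit.fit_panel(healthy_spec, voxel_id="healthy")


@pytest.fixture(scope="session")
def healthy_ref_ratio(healthy_panel):
    return healthy_panel.area("Glx3") / healthy_panel.area("Glx4")


@pytest.fixture(scope="session")
def tumor15_panel(acq):
    """Noiseless tumor voxel carrying a true 15 % Glx3 elevation.

    [2-HG] = 2.235 mmoles/kg against gray-matter Glu+Gln = 14.9.
    """
    truth = synthspec.VoxelTruth(
        concentrations=synthspec.tissue_concentrations("gray", hg=2.235),
        noise_sd=0.0, label="tumor")
    fid = synthspec.simulate_fid(truth, acq, seed=2)
    return peakfit.fit_panel(specproc.process(fid), voxel_id="tumor15")


def make_gaussian_spectrum(acq, components, n=2048) -> Spectrum:
    """Purely real spectrum built from (height, center_ppm, sigma_ppm) triples."""
    ppm = acq.ppm_axis(n)
    y = np.zeros(n)
    for h, c, s in components:
        y += h * np.exp(-((ppm - c) ** 2) / (2.0 * s ** 2))
    return Spectrum(values=y.astype(complex), ppm_axis=ppm, acq=acq)
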