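"""Synthetic FID / spectrum generator with known ground truth.

Simulates single-voxel free-induction decays for the eight metabolite
resonance groups quantified by the pipeline (NAA, two creatine and two
myo-inositol groups, choline, the glutamate+glutamine C3 and C4 composites
Glx3 and Glx4) plus 2-hydroxyglutarate (2-HG), whose C4-proton multiplet
overlaps the Glx3 region near 2.25 ppm. Each group is modeled as one
Gaussian-decaying complex exponential; J-coupling fine structure is
deliberately collapsed, mirroring the one-Gaussian-per-window
quantification downstream.

Calibration: in a healthy voxel the effective Glx3/Glx4 signal ratio is
0.81 by construction, with a configurable per-voxel value so that cohorts
reproduce the 0.81 +/- 0.06 between-voxel spread observed contralaterally.
The 2-HG signal enters the Glx3 region scaled so that the percentage
elevation of Glx3 over Glx4 equals 100 * [2-HG] / ([Glu] + [Gln]) exactly
in truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FID, AcquisitionParams

__all__ = [
    "Resonance",
    "VoxelTruth",
    "CSIGrid",
    "build_basis",
    "tissue_concentrations",
    "simulate_fid",
    "simulate_water_reference",
    "simulate_healthy_voxels",
    "simulate_cohort",
    "HEALTHY_GLX_RATIO",
    "HEALTHY_GLX_RATIO_SD",
    "DEFAULT_CONCENTRATIONS",
]

#: Healthy-tissue Glx3/Glx4 area ratio (mean and between-voxel SD).
HEALTHY_GLX_RATIO = 0.81
HEALTHY_GLX_RATIO_SD = 0.06

#: Default metabolite linewidth (FWHM, Hz). Narrower than the 12 Hz shimmed
#: water line; typical for metabolites in a well-shimmed 3 T voxel.
DEFAULT_LINEWIDTH_HZ = 6.0

#: Water linewidth used for the reference scan (Hz).
WATER_LINEWIDTH_HZ = 12.0

# Canonical in vivo chemical shifts (ppm) for each fitted group. Each value
# lies strictly inside its quantification window.
GROUP_CENTERS_PPM = {
    "NAA": 2.008,
    "Cr1": 3.03,
    "Cr2": 3.91,
    "Cho": 3.19,
    "Ins1": 3.55,
    "Ins2": 3.64,
    "Glx3": 2.29,
    "Glx4": 2.35,
    "2-HG": 2.25,
}

# Effective signal factor per unit concentration (arbitrary units). These
# absorb proton counts and relaxation weighting; Glx3 and 2-HG are tied to
# the Glx4 factor by the healthy-ratio calibration (see build_basis).
_GLX4_REL = 0.30
_BASE_REL = {
    "NAA": 1.0,
    "Cr1": 1.0,
    "Cr2": 0.667,
    "Cho": 3.0,
    "Ins1": 0.6,
    "Ins2": 0.4,
    "Glx4": _GLX4_REL,
}

# Which concentration key feeds each resonance group.
_GROUP_METABOLITE = {
    "NAA": "NAA",
    "Cr1": "Cr",
    "Cr2": "Cr",
    "Cho": "Cho",
    "Ins1": "Ins",
    "Ins2": "Ins",
    "Glx3": "Glx",
    "Glx4": "Glx",
    "2-HG": "2-HG",
}

# Gray / white matter glutamate and glutamine concentrations (mmoles/kg).
_TISSUE_GLX = {
    "gray": {"Glu": 11.7, "Gln": 3.2},
    "white": {"Glu": 7.1, "Gln": 1.7},
}

#: Default healthy-voxel concentrations (mmoles/kg); Glu/Gln are
#: tissue-dependent and filled in by :func:`tissue_concentrations`.
DEFAULT_CONCENTRATIONS = {
    "NAA": 12.0,
    "Cr": 8.0,
    "Cho": 2.0,
    "Ins": 6.0,
    "2-HG": 0.0,
}


@dataclass(frozen=True)
class Resonance:
    """One Gaussian resonance group of the simulation basis."""

    metabolite: str          # concentration key (NAA, Cr, Cho, Ins, Glx, 2-HG)
    group: str               # fitted-window label (NAA, Cr1, ..., Glx3, 2-HG)
    center_ppm: float
    rel_signal: float        # effective signal per unit concentration
    linewidth_hz: float = DEFAULT_LINEWIDTH_HZ
    lineshape: str = "gaussian"

    def __post_init__(self) -> None:
        if not (0.0 < self.center_ppm < 5.0):
            raise ValueError(f"center_ppm must be in (0, 5), got {self.center_ppm}")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be > 0")
        if self.rel_signal < 0:
            raise ValueError("rel_signal must be >= 0")
        if self.lineshape != "gaussian":
            raise ValueError(f"unsupported lineshape {self.lineshape!r}")

    @property
    def decay_rate_s(self) -> float:
        """Gaussian damping rate a (1/s) such that the envelope is exp(-(a t)^2).

        The real part of the spectrum of exp(-(a t)^2) for t >= 0 is a
        Gaussian of FWHM = 2 a sqrt(ln 2) / pi, so a = pi FWHM / (2 sqrt(ln 2)).
        """
        return np.pi * self.linewidth_hz / (2.0 * np.sqrt(np.log(2.0)))


@dataclass
class VoxelTruth:
    """Ground truth for one simulated voxel.

    ``glx3_glx4_ratio`` is the voxel's intrinsic healthy Glx3/Glx4 signal
    ratio (population mean 0.81); it scales both the Glx3 and the 2-HG
    effective signals so the elevation relation stays exact regardless of
    the voxel's draw.
    """

    concentrations: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    baseline_coeffs: tuple = (0.0,) * 7
    phase0_deg: float = 0.0
    shift_ppm: float = 0.0
    label: str = "contralateral"
    glx3_glx4_ratio: float = HEALTHY_GLX_RATIO

    def __post_init__(self) -> None:
        for k, v in self.concentrations.items():
            if v < 0:
                raise ValueError(f"negative concentration for {k}: {v}")
        if len(self.baseline_coeffs) != 7:
            raise ValueError("baseline_coeffs must have exactly 7 entries (degree 6)")
        if self.label not in {"tumor", "contralateral", "excluded"}:
            raise ValueError(f"unknown voxel label {self.label!r}")
        if self.glx3_glx4_ratio <= 0:
            raise ValueError("glx3_glx4_ratio must be > 0")

    @property
    def glx_total(self) -> float:
        return self.concentrations.get("Glu", 0.0) + self.concentrations.get("Gln", 0.0)

    @property
    def true_elevation_pct(self) -> float:
        """Percentage elevation of Glx3 over Glx4 implied by the 2-HG load."""
        hg = self.concentrations.get("2-HG", 0.0)
        glx = self.glx_total
        if glx == 0:
            return 0.0
        return 100.0 * hg / glx


@dataclass
class CSIGrid:
    """A chemical-shift-imaging voxel grid (default 16 x 16, 10x10x20 mm)."""

    nx: int = 16
    ny: int = 16
    voxels: dict = field(default_factory=dict)   # (ix, iy) -> VoxelTruth or FID
    voxel_size_mm: tuple = (10.0, 10.0, 20.0)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be positive")
        if len(self.voxel_size_mm) != 3:
            raise ValueError("voxel_size_mm must have three extents")
        for (ix, iy) in self.voxels:
            if not (0 <= ix < self.nx and 0 <= iy < self.ny):
                raise ValueError(f"voxel index {(ix, iy)} outside {self.nx}x{self.ny} grid")


def tissue_concentrations(tissue: str, hg: float = 0.0) -> dict:
    """Default healthy-voxel concentrations for gray or white matter."""
    if tissue not in _TISSUE_GLX:
        raise ValueError(f"unknown tissue {tissue!r}; expected 'gray' or 'white'")
    conc = dict(DEFAULT_CONCENTRATIONS)
    conc.update(_TISSUE_GLX[tissue])
    conc["2-HG"] = hg
    return conc


def build_basis(tissue: str = "gray",
                glx3_glx4_ratio: float = HEALTHY_GLX_RATIO,
                linewidth_hz: float = DEFAULT_LINEWIDTH_HZ) -> list[Resonance]:
    """Resonance basis: one group per fitted window plus 2-HG.

    The Glx3 effective signal per unit (Glu+Gln) is ``glx3_glx4_ratio``
    times the Glx4 factor, so a 2-HG-free voxel has exactly that area
    ratio. The 2-HG factor uses the same scaling, which makes the
    percentage elevation equal 100 * [2-HG]/([Glu]+[Gln]) identically.
    """
    if tissue not in _TISSUE_GLX:
        raise ValueError(f"unknown tissue {tissue!r}; expected 'gray' or 'white'")
    rel = dict(_BASE_REL)
    rel["Glx3"] = glx3_glx4_ratio * _GLX4_REL
    rel["2-HG"] = glx3_glx4_ratio * _GLX4_REL
    return [
        Resonance(
            metabolite=_GROUP_METABOLITE[g],
            group=g,
            center_ppm=GROUP_CENTERS_PPM[g],
            rel_signal=rel[g],
            linewidth_hz=linewidth_hz,
        )
        for g in GROUP_CENTERS_PPM
    ]


def _effective_concentrations(concentrations: dict) -> dict:
    eff = dict(concentrations)
    eff["Glx"] = concentrations.get("Glu", 0.0) + concentrations.get("Gln", 0.0)
    return eff


def simulate_fid(truth: VoxelTruth, acq: AcquisitionParams, seed: int,
                 basis: list[Resonance] | None = None) -> FID:
    """Forward-model one voxel's FID from its ground truth.

    The signal is a sum of Gaussian-decaying complex exponentials, one per
    resonance group, at offset frequencies (center + shift - ref) * f0,
    with a global zero-order phase, an additive smooth baseline component
    (the inverse transform of a degree-6 polynomial on the spectral grid),
    and complex white Gaussian noise. Identical seeds give identical output.
    """
    if basis is None:
        basis = build_basis(glx3_glx4_ratio=truth.glx3_glx4_ratio)
    eff = _effective_concentrations(truth.concentrations)
    for k, v in eff.items():
        if v < 0:
            raise ValueError(f"negative concentration for {k}: {v}")

    t = acq.time_axis_s()
    sig = np.zeros(acq.n_points, dtype=complex)
    for res in basis:
        amp = eff.get(res.metabolite, 0.0) * res.rel_signal
        if amp == 0.0:
            continue
        f_hz = (res.center_ppm + truth.shift_ppm - acq.ref_ppm) * acq.f0_mhz
        a = res.decay_rate_s
        sig += amp * np.exp(2j * np.pi * f_hz * t - (a * t) ** 2)

    sig *= np.exp(1j * np.deg2rad(truth.phase0_deg))

    if any(c != 0.0 for c in truth.baseline_coeffs):
        ppm = acq.ppm_axis()
        u = _normalize_axis(ppm)
        base = np.polynomial.polynomial.polyval(u, np.asarray(truth.baseline_coeffs))
        sig += np.fft.ifft(np.fft.ifftshift(base))

    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig += truth.noise_sd * (rng.standard_normal(acq.n_points)
                                 + 1j * rng.standard_normal(acq.n_points))
    return FID(samples=sig, acq=acq)


def _normalize_axis(ppm: np.ndarray) -> np.ndarray:
    """Map a ppm axis onto [-1, 1] for numerically stable polynomials."""
    lo, hi = float(ppm.min()), float(ppm.max())
    return (2.0 * ppm - (lo + hi)) / (hi - lo)


def simulate_water_reference(acq: AcquisitionParams, seed: int,
                             phase0_deg: float = 0.0, shift_ppm: float = 0.0,
                             noise_sd: float = 0.0, amplitude: float = 100.0,
                             linewidth_hz: float = WATER_LINEWIDTH_HZ) -> FID:
    """Unsuppressed water reference scan at 4.7 ppm.

    Pass the same ``phase0_deg`` / ``shift_ppm`` as the metabolite voxel to
    emulate shared eddy-current and frequency distortions, enabling
    phase-deconvolution (eddy-current) correction.
    """
    t = acq.time_axis_s()
    a = np.pi * linewidth_hz / (2.0 * np.sqrt(np.log(2.0)))
    f_hz = (4.7 + shift_ppm - acq.ref_ppm) * acq.f0_mhz
    sig = amplitude * np.exp(2j * np.pi * f_hz * t - (a * t) ** 2)
    sig = sig * np.exp(1j * np.deg2rad(phase0_deg))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig += noise_sd * (rng.standard_normal(acq.n_points)
                           + 1j * rng.standard_normal(acq.n_points))
    return FID(samples=sig, acq=acq)


def simulate_healthy_voxels(n: int, noise_sd: float, seed: int,
                            tissue: str = "gray",
                            acq: AcquisitionParams | None = None,
                            ratio_mean: float = HEALTHY_GLX_RATIO,
                            ratio_sd: float = HEALTHY_GLX_RATIO_SD):
    """n contralateral voxels with Glx3/Glx4 drawn Normal(mean, sd), truncated > 0.

    Returns (list of VoxelTruth, list of FID).
    """
    rng = np.random.default_rng(seed)
    truths, fids = [], []
    for i in range(n):
        ratio = _draw_truncated_ratio(rng, ratio_mean, ratio_sd)
        truth = VoxelTruth(
            concentrations=tissue_concentrations(tissue, hg=0.0),
            noise_sd=noise_sd,
            glx3_glx4_ratio=ratio,
            label="contralateral",
        )
        truths.append(truth)
        fids.append(simulate_fid(truth, acq or AcquisitionParams(),
                                 seed=int(rng.integers(2 ** 31))))
    return truths, fids


def _draw_truncated_ratio(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100):
        r = rng.normal(mean, sd)
        if r > 0:
            return float(r)
    raise RuntimeError("could not draw a positive ratio")  # pragma: no cover


# Cohort defaults: modest zero-order phase, sub-bin to few-bin frequency
# drift, and a weak smooth baseline, as seen in automated 3 T CSI.
_COHORT_PHASE_RANGE_DEG = 20.0
_COHORT_SHIFT_RANGE_PPM = 0.03
_COHORT_BASELINE_SCALE = 0.5
#: Default time-domain complex-noise SD: gives a spectral SNR (NAA peak
#: height over spectral noise SD) of roughly 20, typical for this voxel size.
DEFAULT_COHORT_NOISE_SD = 0.04


def simulate_cohort(n_patients: int,
                    hg_range: tuple[float, float] = (0.0, 4.0),
                    tissue: str = "gray",
                    noise_sd: float = DEFAULT_COHORT_NOISE_SD,
                    seed: int = 0,
                    acq: AcquisitionParams | None = None):
    """Synthetic patient cohort with paired tumor / contralateral voxels.

    Per patient: a true [2-HG] drawn uniformly from ``hg_range`` mmoles/kg,
    a per-patient healthy ratio drawn Normal(0.81, 0.06) truncated positive
    and shared by both voxels, and random phase / shift / baseline
    distortions. The true elevation is 100*[2-HG]/([Glu]+[Gln]) exactly.

    Returns (truth table as DataFrame, list of (tumor FID, contralateral FID)).
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if tissue not in _TISSUE_GLX:
        raise ValueError(f"unknown tissue {tissue!r}; expected 'gray' or 'white'")
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)
    rows, pairs = [], []
    for pid in range(1, n_patients + 1):
        hg = float(rng.uniform(*hg_range))
        ratio = _draw_truncated_ratio(rng, HEALTHY_GLX_RATIO, HEALTHY_GLX_RATIO_SD)
        phase0 = float(rng.uniform(-_COHORT_PHASE_RANGE_DEG, _COHORT_PHASE_RANGE_DEG))
        shift = float(rng.uniform(-_COHORT_SHIFT_RANGE_PPM, _COHORT_SHIFT_RANGE_PPM))
        coeffs = tuple(_COHORT_BASELINE_SCALE * rng.uniform(-1, 1, size=7))
        glx = _TISSUE_GLX[tissue]

        tumor = VoxelTruth(
            concentrations=tissue_concentrations(tissue, hg=hg),
            noise_sd=noise_sd, baseline_coeffs=coeffs,
            phase0_deg=phase0, shift_ppm=shift,
            label="tumor", glx3_glx4_ratio=ratio,
        )
        contra = VoxelTruth(
            concentrations=tissue_concentrations(tissue, hg=0.0),
            noise_sd=noise_sd, baseline_coeffs=coeffs,
            phase0_deg=phase0, shift_ppm=shift,
            label="contralateral", glx3_glx4_ratio=ratio,
        )
        pairs.append((
            simulate_fid(tumor, acq, seed=int(rng.integers(2 ** 31))),
            simulate_fid(contra, acq, seed=int(rng.integers(2 ** 31))),
        ))
        rows.append({
            "patient": pid,
            "tissue": tissue,
            "glu": glx["Glu"],
            "gln": glx["Gln"],
            "hg_true": hg,
            "true_elevation_pct": tumor.true_elevation_pct,
            "ref_ratio_true": ratio,
            "noise_sd": noise_sd,
            "phase0_deg": phase0,
            "shift_ppm": shift,
        })
    return pd.DataFrame(rows), pairs
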