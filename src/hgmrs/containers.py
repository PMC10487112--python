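"""Core signal containers shared across the pipeline.

An :class:`FID` is the complex time-domain free-induction decay together
with its acquisition metadata; a :class:`Spectrum` is the complex
frequency-domain signal on a chemical-shift (ppm) axis, carrying a
provenance trail of the processing steps applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionParams", "FID", "Spectrum"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings of a PRESS-localized spectroscopy measurement.

    Defaults correspond to a 3 T proton acquisition with TR/TE = 1500/40 ms,
    1024 complex points at 0.5 ms dwell (2000 Hz spectral width, 512 ms
    acquisition window), with the carrier on water at 4.7 ppm.
    """

    n_points: int = 1024
    dwell_ms: float = 0.5
    f0_mhz: float = 123.25
    ref_ppm: float = 4.7
    te_ms: float = 40.0
    tr_ms: float = 1500.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.dwell_ms <= 0:
            raise ValueError(f"dwell_ms must be > 0, got {self.dwell_ms}")
        if self.f0_mhz <= 0:
            raise ValueError(f"f0_mhz must be > 0, got {self.f0_mhz}")

    @property
    def dwell_s(self) -> float:
        return self.dwell_ms * 1e-3

    @property
    def sweep_hz(self) -> float:
        """Spectral width in Hz (reciprocal of the dwell time)."""
        return 1.0 / self.dwell_s

    @property
    def duration_ms(self) -> float:
        """Length of the acquisition window."""
        return self.n_points * self.dwell_ms

    def time_axis_s(self, n: int | None = None) -> np.ndarray:
        """Sample times in seconds, starting at t = 0."""
        return np.arange(n if n is not None else self.n_points) * self.dwell_s

    def ppm_axis(self, n: int | None = None) -> np.ndarray:
        """Strictly increasing ppm axis for an n-point spectrum.

        Frequencies are taken relative to the carrier (at ``ref_ppm``) and
        converted with delta = ref_ppm + f / f0; the axis is fftshifted so
        ppm increases with index.
        """
        n = n if n is not None else self.n_points
        freqs_hz = np.fft.fftshift(np.fft.fftfreq(n, d=self.dwell_s))
        return self.ref_ppm + freqs_hz / self.f0_mhz


@dataclass
class FID:
    """Complex time-domain signal plus acquisition metadata.

    ``samples`` may be longer than ``acq.n_points`` after zero filling.
    """

    samples: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1:
            raise ValueError("FID samples must be one-dimensional")

    def __len__(self) -> int:
        return len(self.samples)

    def copy_with(self, samples: np.ndarray) -> "FID":
        return FID(samples=np.asarray(samples, dtype=complex), acq=self.acq)


@dataclass
class Spectrum:
    """Complex frequency-domain signal on a strictly monotone ppm axis.

    ``provenance`` records each processing step as a dict with a ``step``
    key plus any applied parameters (e.g. the frequency shift or the phase
    angle); ``flags`` collects non-fatal conditions such as a failed
    frequency alignment.
    """

    values: np.ndarray
    ppm_axis: np.ndarray
    acq: AcquisitionParams | None = None
    provenance: list[dict] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.values.shape != self.ppm_axis.shape:
            raise ValueError("values and ppm_axis must have the same length")
        d = np.diff(self.ppm_axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm_axis must be strictly monotone")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dppm(self) -> float:
        """Signed ppm increment per bin."""
        return float(self.ppm_axis[1] - self.ppm_axis[0])

    @property
    def steps(self) -> list[str]:
        """Names of the processing steps applied, in order."""
        return [p["step"] for p in self.provenance]

    def window_mask(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        return (self.ppm_axis >= lo_ppm) & (self.ppm_axis <= hi_ppm)

    def copy_with(self, values: np.ndarray, extra_provenance: dict | None = None,
                  extra_flags: list[str] | None = None) -> "Spectrum":
        prov = list(self.provenance)
        if extra_provenance is not None:
            prov.append(extra_provenance)
        return Spectrum(
            values=np.asarray(values, dtype=complex),
            ppm_axis=self.ppm_axis.copy(),
            acq=self.acq,
            provenance=prov,
            flags=list(self.flags) + (extra_flags or []),
        )
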