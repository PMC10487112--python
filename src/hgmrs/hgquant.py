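"""2-HG quantification from fitted Glx3/Glx4 areas.

The 2-HG readout is the percentage elevation of the Glx3 peak (glutamate +
glutamine C3 protons plus 2-HG) over the Glx4 peak (glutamate + glutamine
C4 protons only), relative to the Glx3/Glx4 ratio of uninvolved
contralateral tissue:

    elevation % = 100 * (R_tumor / R_ref - 1),  R = area(Glx3) / area(Glx4)

An elevation strictly greater than 0 % is called positive (IDH-mutant).
Healthy contralateral tissue has R = 0.81 +/- 0.06 across individuals and
locations; that constant is available as a fallback reference when no
contralateral voxels exist. Assuming comparable relaxation of 2-HG and
Glx, an elevation e converts to an approximate tissue concentration
(e/100) * ([Glu] + [Gln]) mmoles/kg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .peakfit import MetabolitePanel

__all__ = ["HGResult", "FALLBACK_REFERENCE_RATIO", "reference_ratio",
           "elevation", "classify", "estimate_concentration", "quantify_voxel"]

#: Cohort-level healthy Glx3/Glx4 ratio, for single-voxel use without a
#: contralateral measurement.
FALLBACK_REFERENCE_RATIO = 0.81


@dataclass
class HGResult:
    """Per-voxel 2-HG quantification outcome."""

    tumor_ratio: float
    ref_ratio: float
    elevation_pct: float
    call: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        expected = classify(self.elevation_pct)
        if self.call != expected:
            raise ValueError(f"call {self.call!r} inconsistent with elevation "
                             f"{self.elevation_pct} (expected {expected!r})")


def _panel_ratio(panel: MetabolitePanel, use: str = "area") -> float:
    g3, g4 = panel["Glx3"], panel["Glx4"]
    if not (g3.converged and g4.converged):
        raise ValueError(f"voxel {panel.voxel_id!r}: Glx3/Glx4 fit did not converge; "
                         "refusing to make a call")
    num = g3.area if use == "area" else g3.amplitude
    den = g4.area if use == "area" else g4.amplitude
    if den <= 0:
        raise ValueError(f"voxel {panel.voxel_id!r}: non-positive Glx4 {use}")
    return num / den


def reference_ratio(panels: Iterable[MetabolitePanel],
                    use: str = "area") -> tuple[float, float]:
    """Mean and SD of Glx3/Glx4 ratios over contralateral voxels.

    SD is the sample standard deviation (ddof=1); a single voxel reports
    SD = 0 and its own ratio as the mean.
    """
    ratios = [_panel_ratio(p, use=use) for p in panels]
    if not ratios:
        raise ValueError("reference_ratio needs at least one panel")
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return mean, sd


def elevation(tumor_ratio: float, ref_ratio: float) -> float:
    """Percentage elevation of the tumor ratio over the reference ratio."""
    if tumor_ratio <= 0 or ref_ratio <= 0:
        raise ValueError(f"ratios must be positive, got tumor={tumor_ratio}, ref={ref_ratio}")
    return 100.0 * (tumor_ratio / ref_ratio - 1.0)


def classify(elevation_pct: float) -> str:
    """Positive iff the elevation is strictly greater than 0 %."""
    return "positive" if elevation_pct > 0.0 else "negative"


def estimate_concentration(elevation_pct: float, glu: float, gln: float) -> float:
    """Approximate [2-HG] in mmoles/kg implied by a Glx3 elevation.

    (elevation/100) * ([Glu] + [Gln]); assumes similar T1/T2 relaxation of
    2-HG and Glx so the elevation maps linearly onto concentration.
    """
    if not np.isfinite(elevation_pct):
        raise ValueError("elevation must be finite")
    if glu < 0 or gln < 0:
        raise ValueError("glutamate and glutamine concentrations must be >= 0")
    return (elevation_pct / 100.0) * (glu + gln)


def quantify_voxel(tumor_panel: MetabolitePanel, ref_ratio: float,
                   use: str = "area") -> HGResult:
    """Ratio -> elevation -> classification for one tumor voxel."""
    tumor = _panel_ratio(tumor_panel, use=use)
    elev = elevation(tumor, ref_ratio)
    return HGResult(tumor_ratio=tumor, ref_ratio=ref_ratio,
                    elevation_pct=elev, call=classify(elev))
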