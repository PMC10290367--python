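"""HU-to-mineral-density calibration against a density phantom.

A hydroxyapatite (HA) phantom with rods of known density is scanned on the
same protocol as the specimens; the mean HU inside each rod is regressed
against the known densities (ordinary least squares) and the fitted line
converts whole volumes from HU to mg HA/cm^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["Calibration", "DensityImage", "fit_calibration", "apply_calibration"]


@dataclass(frozen=True)
class Calibration:
    """Linear HU = slope * density + intercept map fitted on phantom rods."""

    slope: float  # HU per (mg HA/cm^3)
    intercept: float  # HU
    r_squared: float
    n_rods: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_rods < 2:
            raise ValueError("calibration requires at least 2 rods")

    def density_to_hu(self, rho):
        return self.slope * np.asarray(rho, dtype=float) + self.intercept

    def hu_to_density(self, hu):
        return (np.asarray(hu, dtype=float) - self.intercept) / self.slope

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
                "n_rods": self.n_rods,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Calibration":
        d = json.loads(text)
        return cls(d["slope"], d["intercept"], d["r_squared"], int(d["n_rods"]))


@dataclass
class DensityImage:
    """Calibrated 3-D volume of volumetric mineral density (mg HA/cm^3)."""

    data: np.ndarray
    spacing: float  # mm, isotropic
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing**3


def fit_calibration(phantom, rod_densities, rod_masks=None) -> Calibration:
    """Fit the HU-density line from a phantom scan.

    ``phantom`` may be a generated phantom scan object (with ``hu`` and
    ``rod_masks`` attributes) or a raw HU array, in which case
    ``rod_masks`` must be given as a list of boolean volumes, one per rod.
    """
    if rod_masks is None:
        hu = np.asarray(phantom.hu, dtype=float)
        rod_masks = phantom.rod_masks
    else:
        hu = np.asarray(phantom, dtype=float)
    densities = np.asarray(rod_densities, dtype=float)
    if densities.size < 2:
        raise ValueError("calibration is underdetermined with fewer than 2 rods")
    if len(rod_masks) != densities.size:
        raise ValueError("one rod mask required per rod density")
    if np.unique(densities).size < 2:
        raise ValueError("rod densities must not all be identical (singular fit)")
    means = []
    for m in rod_masks:
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError("empty rod mask")
        means.append(float(hu[m].mean()))
    res = sps.linregress(densities, means)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n_rods=int(densities.size),
    )


def apply_calibration(hu_volume, calibration: Calibration, spacing: float,
                      provenance: dict | None = None) -> DensityImage:
    """Convert an HU volume to a density image: rho = (HU - b) / a.

    Negative densities are retained (thresholds are applied downstream);
    non-finite inputs are rejected with a count of offending voxels.
    """
    hu = np.asarray(hu_volume, dtype=float)
    bad = np.count_nonzero(~np.isfinite(hu))
    if bad:
        raise ValueError(f"HU volume contains {bad} non-finite voxels")
    rho = calibration.hu_to_density(hu)
    prov = dict(provenance or {})
    prov.setdefault("calibration", json.loads(calibration.to_json()))
    return DensityImage(rho, spacing, prov)
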