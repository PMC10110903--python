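"""RECIST v1.1 response categorization from serial lesion measurements.

Three reading modes are supported for a single treated target lesion:

* manual-style unidimensional (longest diameter, mm),
* computer-based unidimensional (longest axial diameter measured from an
  auto-segmentation mask),
* volumetric, with ellipsoid (-30% / +20%) or spherical (-65% / +73%)
  threshold presets applied to the segmented volume.

Rules (single lesion):

* CR — lesion has disappeared (measurement 0).
* PD — measurement >= nadir * 1.20 AND, for diameters, an absolute
  increase over the nadir of at least 5 mm.  The nadir is the smallest
  measurement recorded so far, including the pre-treatment baseline.
* PR — measurement <= baseline * 0.70 (diameter) / preset shrink factor
  (volume), relative to the pre-treatment baseline.
* SD — none of the above.

Precedence is CR, then PD, then PR (a vanished lesion also satisfies PR;
checking CR first resolves it), then SD as the residual class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ResponseCategory(enum.IntEnum):
    """Ordered response categories; larger value = worse response."""

    CR = 0
    PR = 1
    SD = 2
    PD = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


VOLUMETRIC_PRESETS = {
    # (fractional shrink for PR, fractional growth for PD)
    "ellipsoid": (0.30, 0.20),
    "spherical": (0.65, 0.73),
}


@dataclass(frozen=True)
class RecistParams:
    """Thresholds of the v1.1 rules; defaults are the standard ones."""

    pd_rel_increase: float = 0.20
    pd_abs_min_mm: float = 5.0
    pr_rel_decrease: float = 0.30

    def __post_init__(self):
        if not 0 < self.pd_rel_increase < 1:
            raise ValueError("pd_rel_increase must be in (0, 1)")
        if not 0 < self.pr_rel_decrease < 1:
            raise ValueError("pr_rel_decrease must be in (0, 1)")
        if self.pd_abs_min_mm < 0:
            raise ValueError("pd_abs_min_mm must be >= 0")


@dataclass
class MeasurementSeries:
    """Time-ordered measurements of one target lesion.

    The first entry is the pre-treatment baseline; times are months from
    the start of treatment and must be strictly increasing.
    """

    patient_id: str
    scan_times_months: list[float]
    diameters_mm: list[float]
    volumes_mm3: list[float] | None = None
    source: str = "manual"

    def __post_init__(self):
        t = np.asarray(self.scan_times_months, dtype=float)
        if len(t) != len(self.diameters_mm):
            raise ValueError("times and diameters must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("scan times must be strictly increasing")
        if any(d < 0 for d in self.diameters_mm):
            raise ValueError("diameters must be >= 0")
        if self.volumes_mm3 is not None:
            if len(self.volumes_mm3) != len(t):
                raise ValueError("times and volumes must align")
            if any(v < 0 for v in self.volumes_mm3):
                raise ValueError("volumes must be >= 0")
            if self.source == "auto_segmentation":
                for d, v in zip(self.diameters_mm, self.volumes_mm3):
                    if (d == 0) != (v == 0):
                        raise ValueError(
                            "diameter 0 iff volume 0 for auto source")


def _categorize(values: Sequence[float], pr_down: float, pd_up: float,
                pd_abs_min: float) -> list[ResponseCategory]:
    baseline = values[0]
    if baseline <= 0:
        raise ValueError("no measurable baseline lesion")
    cats = []
    nadir = baseline
    for v in values[1:]:
        if v == 0:
            cats.append(ResponseCategory.CR)
        elif v >= nadir * (1 + pd_up) and (v - nadir) >= pd_abs_min:
            cats.append(ResponseCategory.PD)
        elif v <= baseline * (1 - pr_down):
            cats.append(ResponseCategory.PR)
        else:
            cats.append(ResponseCategory.SD)
        nadir = min(nadir, v)
    return cats


def categorize_unidimensional(series: MeasurementSeries,
                              params: RecistParams = RecistParams(),
                              ) -> list[ResponseCategory]:
    """Per-follow-up-scan category from the longest-diameter series."""
    return _categorize(series.diameters_mm, params.pr_rel_decrease,
                       params.pd_rel_increase, params.pd_abs_min_mm)


def categorize_volumetric(series: MeasurementSeries,
                          preset: str = "ellipsoid",
                          ) -> list[ResponseCategory]:
    """Per-scan category from segmented volumes.

    No absolute floor applies to volume changes (the 5 mm rule has no
    stated volumetric analogue).
    """
    if series.volumes_mm3 is None:
        raise ValueError("series carries no volumes")
    try:
        down, up = VOLUMETRIC_PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown volumetric preset {preset!r}") from None
    return _categorize(series.volumes_mm3, down, up, 0.0)


def worst_category(categories: Sequence[ResponseCategory]) -> ResponseCategory:
    """Final categorization: the worst category on any follow-up scan."""
    if len(categories) == 0:
        raise ValueError("no follow-up categories")
    return max(categories)


def dichotomize_response(final: ResponseCategory) -> str:
    """PD vs non-PD split used for survival comparisons."""
    return "PD" if final == ResponseCategory.PD else "non-PD"


def ellipsoid_volume_mm3(diameter_mm: float, minor_mm: float,
                         height_mm: float) -> float:
    """Ellipsoid-model volume estimate pi/6 * d1*d2*d3 (optional input
    transform for volumetric reads from caliper-style measurements)."""
    return float(np.pi / 6.0 * diameter_mm * minor_mm * height_mm)


def longest_axial_diameter(mask: np.ndarray, spacing) -> float:
    """Longest in-plane diameter of a binary mask, in mm.

    The RECIST convention measures within an axial slice: for every z-slice
    the maximum pairwise distance between foreground voxel centers is taken,
    and the maximum over slices returned. Empty mask -> 0. A single voxel
    has zero extent under the voxel-center metric.
    """
    mask = np.asarray(mask).astype(bool)
    spacing = np.asarray(spacing, dtype=float)
    best = 0.0
    for z in range(mask.shape[2]):
        xs, ys = np.nonzero(mask[:, :, z])
        if xs.size < 2:
            continue
        pts = np.stack([xs * spacing[0], ys * spacing[1]], axis=1)
        # max pairwise distance over the slice's convex hull would do; the
        # point sets here are small enough for the direct computation
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        best = max(best, float(np.sqrt(d2.max())))
    return best
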