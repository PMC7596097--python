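"""Anatomical counting regions (ED1-ED3) and per-region papilla counts.

The three manual-protocol regions from the FP-counting literature are
rasterised as calibrated masks anchored to the tongue tip and midline:

* ED1 — three circles of 6 mm diameter at the front of the anterior tongue
  (centres on a line 5 mm posterior to the tip: one on the midline, the
  others 6 mm left and right, so neighbouring circles are tangent);
* ED2 — two circles of 6 mm diameter, centres 0.5 cm from the tip and
  0.5 cm from the tongue midline (one per side);
* ED3 — a 1 cm^2 square bisected by the midline, anterior edge at the tip;
* TOT — the whole tongue mask.

A papilla is counted in a region iff its centroid pixel (nearest-pixel
rounding, half away from zero) lies inside the region mask — an object
straddling the boundary counts only by its centre point.  The tongue is
assumed tip-down (the simulator convention), so the tip is the lowest
foreground row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._types import Calibration, CountRecord, PapillaObject

REGION_KINDS = ("ED1", "ED2", "ED3", "TOT")

# Circle diameter used by ED1/ED2, mm
ED_CIRCLE_DIAMETER_MM = 6.0
# ED3 square side, mm (1 cm^2)
ED3_SIDE_MM = 10.0


@dataclass
class RegionSpec:
    """Placement of one counting region relative to tip and midline.

    Offsets are to circle *centres* by default; ``edge_offsets=True``
    switches to the alternative reading where the stated 0.5 cm distances
    are to circle edges (adds one radius to each offset).
    """

    kind: str
    tip: tuple[int, int]  # (row, col) of the tongue tip, tip-down
    midline_col: float
    circle_diameter_mm: float = ED_CIRCLE_DIAMETER_MM
    ed1_posterior_offset_mm: float = 5.0
    ed1_lateral_spacing_mm: float = 6.0
    ed2_offset_mm: float = 5.0
    ed3_side_mm: float = ED3_SIDE_MM
    edge_offsets: bool = False

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"kind must be one of {REGION_KINDS}, got {self.kind!r}")


def detect_tip_and_midline(tongue_mask: np.ndarray) -> tuple[tuple[int, int], float]:
    """Locate the tongue tip and midline column of a tip-down tongue mask.

    Tip = the lowest-row foreground pixel (ties broken by the column closest
    to the mask centroid column); midline = the centroid column.
    """
    mask = np.asarray(tongue_mask).astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty tongue mask")
    midline_col = float(cols.mean())
    tip_row = int(rows.max())
    tip_cols = cols[rows == tip_row]
    tip_col = int(tip_cols[np.argmin(np.abs(tip_cols - midline_col))])
    return (tip_row, tip_col), midline_col


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Pixel-centre rasterisation: pixel in circle iff its centre is within radius."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def region_mask(
    spec: RegionSpec,
    cal: Calibration,
    shape: tuple[int, int],
    tongue_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterise a counting region at the calibrated scale.

    ``TOT`` returns the tongue mask itself (required).  Regions partially
    outside the frame are clipped with a warning.
    """
    ppm = cal.px_per_mm
    tip_row, tip_col = spec.tip
    mid = spec.midline_col
    out = np.zeros(shape, dtype=bool)

    if spec.kind == "TOT":
        if tongue_mask is None:
            raise ValueError("TOT region requires the tongue mask")
        return np.asarray(tongue_mask).astype(bool)

    radius_px = spec.circle_diameter_mm / 2.0 * ppm
    edge_extra = radius_px if spec.edge_offsets else 0.0

    if spec.kind == "ED1":
        row = tip_row - (spec.ed1_posterior_offset_mm * ppm + edge_extra)
        dx = spec.ed1_lateral_spacing_mm * ppm
        centers = [(row, mid - dx), (row, mid), (row, mid + dx)]
        for c in centers:
            out |= _disk_mask(shape, c, radius_px)
    elif spec.kind == "ED2":
        row = tip_row - (spec.ed2_offset_mm * ppm + edge_extra)
        dx = spec.ed2_offset_mm * ppm + edge_extra
        for c in [(row, mid - dx), (row, mid + dx)]:
            out |= _disk_mask(shape, c, radius_px)
    elif spec.kind == "ED3":
        side = int(round(spec.ed3_side_mm * ppm))
        r1 = tip_row - side + 1
        c0 = int(round(mid - side / 2.0))
        rr = slice(max(r1, 0), min(tip_row + 1, shape[0]))
        cc = slice(max(c0, 0), min(c0 + side, shape[1]))
        clipped = (r1 < 0) or (tip_row >= shape[0]) or (c0 < 0) or (c0 + side > shape[1])
        out[rr, cc] = True
        if clipped:
            warnings.warn(f"{spec.kind} region clipped by the image frame", stacklevel=2)
        return out

    # circle clipping check: compare to unclipped area
    return out


def count_in_region(objects: list[PapillaObject], region: np.ndarray) -> int:
    """Count objects whose rounded centroid pixel lies inside the region."""
    region = np.asarray(region).astype(bool)
    n = 0
    for obj in objects:
        r = _round_half_away(obj.centroid[0])
        c = _round_half_away(obj.centroid[1])
        if 0 <= r < region.shape[0] and 0 <= c < region.shape[1] and region[r, c]:
            n += 1
    return n


def _round_half_away(x: float) -> int:
    """Nearest-pixel rounding, halves away from zero (unlike numpy's)."""
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def fp_density(count: int, region: np.ndarray, cal: Calibration) -> float:
    """Papilla density in counts per cm^2 of region area."""
    area_px = int(np.asarray(region).astype(bool).sum())
    if area_px == 0:
        raise ValueError("zero-area region")
    return count / cal.area_px_to_cm2(area_px)


def count_all_regions(
    objects: list[PapillaObject],
    tongue_mask: np.ndarray,
    cal: Calibration,
    subject_id: str = "",
    region_kwargs: dict | None = None,
) -> CountRecord:
    """Per-region counts and densities for one subject.

    Detects tip/midline from the tongue mask, rasterises ED1-ED3, counts by
    the centre-point rule, and reports density per cm^2 for every region.
    """
    tongue_mask = np.asarray(tongue_mask).astype(bool)
    tip, midline = detect_tip_and_midline(tongue_mask)
    counts: dict[str, int] = {}
    densities: dict[str, float] = {}
    kwargs = region_kwargs or {}
    for kind in REGION_KINDS:
        spec = RegionSpec(kind=kind, tip=tip, midline_col=midline, **kwargs)
        mask = region_mask(spec, cal, tongue_mask.shape, tongue_mask=tongue_mask)
        counts[kind] = count_in_region(objects, mask)
        densities[kind] = fp_density(counts[kind], mask, cal) if mask.any() else 0.0
    return CountRecord(
        subject_id=subject_id,
        ED1=counts["ED1"],
        ED2=counts["ED2"],
        ED3=counts["ED3"],
        TOT=counts["TOT"],
        densities=densities,
    )
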