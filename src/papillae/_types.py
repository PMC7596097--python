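"""Shared domain containers.

Masks and images are plain numpy arrays throughout the package:

* image      -- float32 ``(V, H, 3)`` RGB in [0, 1] with a pixels-per-mm
                calibration carried alongside,
* binary mask -- bool ``(V, H)``,
* probability map -- float32 ``(V, H)`` in [0, 1],
* weight map -- float32 ``(V, H)`` with entries >= 1.

The dataclasses below carry the per-object and per-subject records the
counting and statistics layers exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Calibration:
    """Image scale in pixels per millimetre (from the ruler in the frame)."""

    px_per_mm: float

    def __post_init__(self) -> None:
        if not (self.px_per_mm > 0) or self.px_per_mm != self.px_per_mm:
            raise ValueError(f"px_per_mm must be finite and > 0, got {self.px_per_mm}")

    @property
    def px_per_cm(self) -> float:
        return 10.0 * self.px_per_mm

    def area_px_to_mm2(self, area_px: float) -> float:
        return area_px / self.px_per_mm**2

    def area_px_to_cm2(self, area_px: float) -> float:
        return area_px / self.px_per_cm**2


@dataclass
class PapillaObject:
    """One connected component of the papillae mask."""

    label: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    area_mm2: float | None = None


@dataclass
class CountRecord:
    """Per-subject papilla counts for the three literature regions.

    ED1: three 6 mm circles at the anterior tip; ED2: two 6 mm circles at
    0.5 cm from tip and midline; ED3: a 1 cm^2 square bisected by the
    midline; TOT: the whole imaged tongue area.  Densities are counts per
    cm^2 of region area.
    """

    subject_id: str
    ED1: int = 0
    ED2: int = 0
    ED3: int = 0
    TOT: int = 0
    densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("ED1", "ED2", "ED3", "TOT"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {
            "subject_id": self.subject_id,
            "ED1": self.ED1,
            "ED2": self.ED2,
            "ED3": self.ED3,
            "TOT": self.TOT,
        }
        for k, v in self.densities.items():
            out[f"density_{k}"] = v
        return out


VALID_GENDERS = ("F", "M")
VALID_PROP_STATUS = ("NT", "MT", "ST")


@dataclass
class SubjectRecord:
    """Counts plus the metadata used by the cohort-statistics layer.

    ``prop_rating`` is the PROP bitterness intensity on the generalized
    Labeled Magnitude Scale (gLMS, 0-100); ``prop_status`` the derived
    non-/medium-/supertaster class.
    """

    subject_id: str
    gender: str
    prop_status: str
    prop_rating: float
    counts: CountRecord

    def __post_init__(self) -> None:
        if self.gender not in VALID_GENDERS:
            raise ValueError(f"gender must be one of {VALID_GENDERS}")
        if self.prop_status not in VALID_PROP_STATUS:
            raise ValueError(f"prop_status must be one of {VALID_PROP_STATUS}")
        if not (0.0 <= self.prop_rating <= 100.0):
            raise ValueError("prop_rating must lie on the gLMS scale [0, 100]")
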