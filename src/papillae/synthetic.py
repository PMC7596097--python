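"""Synthetic stained-tongue image generator with known ground truth.

Real stained-tongue photographs show an elliptical tongue bordered by a lip
band, with fungiform papillae appearing as pale round-ish blobs (FP resist
the blue food dye) of roughly 0.3-1.05 mm diameter on the darker stained
surface.  This module emulates that appearance at a known pixels-per-mm
calibration and, crucially, records the exact ground truth: the papillae
mask, the tongue and lip masks, every papilla object, and the per-region
counts (ED1-ED3, TOT).  That makes the whole detection-and-counting
pipeline testable end-to-end without the original photographs.

Rendering model, in order: flat background, tongue ellipse with a smooth
texture, lip band hugging the lower tongue boundary, papilla highlight
ellipses, additive Gaussian pixel noise, Gaussian blur.  The tongue is
drawn tip-down so the tip/midline detector has a fixed convention.

Papilla placement is rejection sampling: centres are drawn uniformly inside
the margin-eroded tongue and accepted only if at least
``min_center_separation_mm`` from every accepted centre; a bounded retry
budget per papilla turns an infeasible request into an explicit
:class:`OvercrowdedSpecError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from ._types import Calibration, CountRecord, PapillaObject, SubjectRecord
from .postprocess import label_and_count
from .regions import count_all_regions

logger = logging.getLogger(__name__)

# default colours (RGB in [0,1]) for the stained-tongue appearance
BACKGROUND_RGB = (0.13, 0.13, 0.18)
TONGUE_RGB = (0.25, 0.35, 0.65)
LIP_RGB = (0.55, 0.30, 0.32)

MAX_PLACEMENT_RETRIES = 1000  # per papilla


class OvercrowdedSpecError(RuntimeError):
    """Raised when the requested papilla count cannot be placed."""


@dataclass(frozen=True)
class TongueSpec:
    """Parameters of one synthetic tongue image.

    Geometry is in millimetres wherever it describes anatomy and in pixels
    where it describes the raster; ``px_per_mm`` links the two.
    """

    image_height_px: int = 768
    image_width_px: int = 1152
    px_per_mm: float = 10.0
    n_papillae: int = 150
    papilla_diameter_range_mm: tuple[float, float] = (0.30, 1.05)
    papilla_eccentricity_range: tuple[float, float] = (0.0, 0.5)
    min_center_separation_mm: float = 1.3
    noise_sigma: float = 0.03
    blur_sigma_px: float = 1.0
    papilla_contrast: float = 0.45
    tongue_width_frac: float = 0.36  # tongue semi-axis / image width
    tongue_height_frac: float = 0.35  # tongue semi-axis / image height
    lip_thickness_mm: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        dmin, dmax = self.papilla_diameter_range_mm
        if not dmin < dmax:
            raise ValueError("papilla diameter range must satisfy min < max")
        if dmin <= 0:
            raise ValueError("papilla diameters must be positive")
        emin, emax = self.papilla_eccentricity_range
        if not (0.0 <= emin <= emax < 1.0):
            raise ValueError("eccentricity range must lie in [0, 1)")
        if self.n_papillae < 0:
            raise ValueError("n_papillae must be >= 0")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if self.min_center_separation_mm <= 0:
            raise ValueError("min_center_separation_mm must be > 0")
        if self.noise_sigma < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise/blur sigmas must be >= 0")

    @property
    def calibration(self) -> Calibration:
        return Calibration(px_per_mm=self.px_per_mm)


def default_spec(**overrides) -> TongueSpec:
    """Full-size preset: 768x1152 px at 10 px/mm (2x2 training patches)."""
    return TongueSpec(**overrides)


def easy_spec(**overrides) -> TongueSpec:
    """High-contrast, well-separated preset used for pipeline validation.

    Papillae are at least 0.55 mm across at 20 px/mm, so every object
    comfortably survives the morphological clean-up, and centres are at
    least 1.6 mm apart so no two objects ever merge.
    """
    params = dict(
        image_height_px=512,
        image_width_px=768,
        px_per_mm=20.0,
        n_papillae=50,
        papilla_diameter_range_mm=(0.55, 0.95),
        papilla_eccentricity_range=(0.0, 0.3),
        min_center_separation_mm=1.6,
        noise_sigma=0.01,
        blur_sigma_px=0.6,
        papilla_contrast=0.5,
    )
    params.update(overrides)
    return TongueSpec(**params)


@dataclass
class SyntheticSample:
    """A rendered tongue with its full ground truth."""

    image: np.ndarray  # (V, H, 3) float32 in [0, 1]
    papillae_mask: np.ndarray  # (V, H) bool
    tongue_mask: np.ndarray  # (V, H) bool
    lip_mask: np.ndarray  # (V, H) bool
    objects: list[PapillaObject]
    true_counts: CountRecord
    spec: TongueSpec


def _tongue_geometry(spec: TongueSpec) -> tuple[float, float, float, float]:
    """(center_row, center_col, semi_axis_row, semi_axis_col) of the tongue."""
    v, h = spec.image_height_px, spec.image_width_px
    ry = spec.tongue_height_frac * v
    rx = spec.tongue_width_frac * h
    center_row = 0.88 * v - ry  # tip (bottom vertex) at 88 % of the frame height
    center_col = h / 2.0
    return center_row, center_col, ry, rx


def _render_masks(spec: TongueSpec) -> tuple[np.ndarray, np.ndarray]:
    v, h = spec.image_height_px, spec.image_width_px
    cr, cc, ry, rx = _tongue_geometry(spec)
    rr, hh = np.ogrid[:v, :h]
    tongue = ((rr - cr) / ry) ** 2 + ((hh - cc) / rx) ** 2 <= 1.0
    # lip: a band around the lower tongue boundary (rows below the centre)
    thick = spec.lip_thickness_mm * spec.px_per_mm
    outer = ((rr - cr) / (ry + thick)) ** 2 + ((hh - cc) / (rx + thick)) ** 2 <= 1.0
    lip = outer & ~tongue & (rr >= cr)
    return tongue, lip


def _place_papillae(
    spec: TongueSpec, tongue: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample centres; returns (rows, cols, semi_a, semi_b, thetas)."""
    ppm = spec.px_per_mm
    dmin, dmax = spec.papilla_diameter_range_mm
    emin, emax = spec.papilla_eccentricity_range
    # worst-case semi-axis, used as a placement margin so blobs stay on-tongue
    max_a = (dmax / 2.0 * ppm) / (1.0 - emax**2) ** 0.25
    margin = int(np.ceil(max_a)) + 2
    allowed = ndimage.binary_erosion(tongue, iterations=margin) if margin else tongue
    coords = np.argwhere(allowed)
    if spec.n_papillae > 0 and coords.size == 0:
        raise OvercrowdedSpecError("tongue too small for any papilla at this size")

    min_sep = spec.min_center_separation_mm * ppm
    centers: list[tuple[float, float]] = []
    for k in range(spec.n_papillae):
        for _ in range(MAX_PLACEMENT_RETRIES):
            r, c = coords[rng.integers(len(coords))]
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in centers):
                centers.append((float(r), float(c)))
                break
        else:
            raise OvercrowdedSpecError(
                f"could not place papilla {k + 1}/{spec.n_papillae} after "
                f"{MAX_PLACEMENT_RETRIES} attempts; spec is overcrowded"
            )
    n = len(centers)
    rows = np.array([p[0] for p in centers])
    cols = np.array([p[1] for p in centers])
    diam = rng.uniform(dmin, dmax, size=n)
    ecc = rng.uniform(emin, emax, size=n)
    theta = rng.uniform(0.0, np.pi, size=n)
    radius = diam / 2.0 * ppm
    # semi-axes chosen so the ellipse area equals pi*r^2 at any eccentricity
    shape_factor = (1.0 - ecc**2) ** 0.25
    semi_a = radius / shape_factor
    semi_b = radius * shape_factor
    return rows, cols, semi_a, semi_b, theta


def generate_sample(spec: TongueSpec) -> SyntheticSample:
    """Render one synthetic tongue; deterministic for a fixed spec/seed."""
    rng = np.random.default_rng(spec.seed)
    v, h = spec.image_height_px, spec.image_width_px
    cr, _, ry, _ = _tongue_geometry(spec)
    if cr - ry < 0 or cr + ry > v:
        raise ValueError("tongue ellipse does not fit inside the frame")

    tongue, lip = _render_masks(spec)
    rows, cols, semi_a, semi_b, theta = _place_papillae(spec, tongue, rng)

    papillae = np.zeros((v, h), dtype=bool)
    for r, c, a, b, t in zip(rows, cols, semi_a, semi_b, theta):
        rr, cc = draw_ellipse(r, c, a, b, shape=(v, h), rotation=t)
        papillae[rr, cc] = True
    papillae &= tongue

    image = np.empty((v, h, 3), dtype=np.float32)
    image[:] = BACKGROUND_RGB
    image[tongue] = TONGUE_RGB
    image[lip] = LIP_RGB
    # smooth multiplicative texture on the tongue surface
    texture = ndimage.gaussian_filter(rng.standard_normal((v, h)), 8.0)
    texture *= 0.04 / max(texture.std(), 1e-9)
    image[tongue] *= 1.0 + texture[tongue, None]
    image[papillae] = np.asarray(TONGUE_RGB) + spec.papilla_contrast
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape).astype(np.float32)
    if spec.blur_sigma_px > 0:
        image = ndimage.gaussian_filter(image, (spec.blur_sigma_px, spec.blur_sigma_px, 0.0))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    _, objects = label_and_count(papillae, spec.calibration)
    true_counts = count_all_regions(
        objects, tongue, spec.calibration, subject_id=f"seed{spec.seed}"
    )
    return SyntheticSample(
        image=image,
        papillae_mask=papillae,
        tongue_mask=tongue,
        lip_mask=lip,
        objects=objects,
        true_counts=true_counts,
        spec=spec,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Group structure of a synthetic cohort.

    Per-subject papilla totals are drawn from a normal distribution whose
    mean depends on gender; PROP status and gLMS rating are drawn
    independently of the counts (so the cohort is null for PROP by
    construction unless ``prop_count_shift`` is set).
    """

    gender_proportions: dict[str, float] = field(
        default_factory=lambda: {"F": 0.77, "M": 0.23}
    )
    mean_count: dict[str, float] = field(default_factory=lambda: {"F": 80.0, "M": 65.0})
    count_sd: float = 12.0
    taster_shares: dict[str, float] = field(
        default_factory=lambda: {"NT": 0.30, "MT": 0.45, "ST": 0.25}
    )
    prop_rating_mean: dict[str, float] = field(
        default_factory=lambda: {"NT": 12.0, "MT": 35.0, "ST": 65.0}
    )
    prop_rating_sd: float = 8.0
    prop_count_shift: dict[str, float] = field(
        default_factory=lambda: {"NT": 0.0, "MT": 0.0, "ST": 0.0}
    )
    base_spec: TongueSpec | None = None  # geometry template for rendering

    def group_mean(self, gender: str, prop_status: str) -> float:
        return self.mean_count[gender] + self.prop_count_shift[prop_status]


def _cohort_base_spec() -> TongueSpec:
    # reduced frame so a full cohort renders in seconds
    return easy_spec(
        image_height_px=384,
        image_width_px=576,
        n_papillae=0,
        min_center_separation_mm=1.2,
    )


def generate_cohort(
    n_subjects: int,
    config: CohortConfig | None = None,
    seed: int = 0,
    render: bool = True,
) -> list[tuple[SyntheticSample | None, SubjectRecord]]:
    """Draw a cohort of subjects with group labels and ground-truth counts.

    With ``render=True`` every subject gets a rendered
    :class:`SyntheticSample` whose ground-truth regional counts populate the
    record.  With ``render=False`` (record-only mode, used for statistical
    calibration studies) the drawn total is used directly and regional
    counts are apportioned by typical region/tongue area fractions.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)

    genders = list(config.gender_proportions)
    g_probs = np.array([config.gender_proportions[g] for g in genders], dtype=float)
    g_probs /= g_probs.sum()
    tasters = list(config.taster_shares)
    t_probs = np.array([config.taster_shares[t] for t in tasters], dtype=float)
    t_probs /= t_probs.sum()

    base = config.base_spec or _cohort_base_spec()
    out: list[tuple[SyntheticSample | None, SubjectRecord]] = []
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(int(subject_seeds[i]))
        gender = genders[sub_rng.choice(len(genders), p=g_probs)]
        status = tasters[sub_rng.choice(len(tasters), p=t_probs)]
        rating = float(
            np.clip(
                sub_rng.normal(config.prop_rating_mean[status], config.prop_rating_sd),
                0.0,
                100.0,
            )
        )
        n_pap = int(round(sub_rng.normal(config.group_mean(gender, status), config.count_sd)))
        if n_pap < 0:
            logger.warning("drawn papilla count %d clipped to 0 (subject %d)", n_pap, i)
            n_pap = 0
        subject_id = f"S{i:03d}"
        if render:
            spec = replace(base, n_papillae=n_pap, seed=int(subject_seeds[i]))
            sample = generate_sample(spec)
            counts = replace_subject_id(sample.true_counts, subject_id)
        else:
            sample = None
            counts = _apportioned_counts(subject_id, n_pap, sub_rng)
        out.append(
            (
                sample,
                SubjectRecord(
                    subject_id=subject_id,
                    gender=gender,
                    prop_status=status,
                    prop_rating=rating,
                    counts=counts,
                ),
            )
        )
    return out


def replace_subject_id(counts: CountRecord, subject_id: str) -> CountRecord:
    return CountRecord(
        subject_id=subject_id,
        ED1=counts.ED1,
        ED2=counts.ED2,
        ED3=counts.ED3,
        TOT=counts.TOT,
        densities=dict(counts.densities),
    )


# typical region/tongue area fractions on the reduced cohort frame, used only
# in record-only mode to give the ED columns plausible magnitudes
_ED_AREA_FRACTIONS = {"ED1": 0.14, "ED2": 0.09, "ED3": 0.17}


def _apportioned_counts(
    subject_id: str, total: int, rng: np.random.Generator
) -> CountRecord:
    ed = {k: int(rng.binomial(total, f)) for k, f in _ED_AREA_FRACTIONS.items()}
    return CountRecord(subject_id=subject_id, TOT=total, **ed)


def cohort_group_values(
    records: list[SubjectRecord], group_by: str, region: str = "TOT"
) -> dict[str, np.ndarray]:
    """Split a cohort's counts into groups (by ``gender`` or ``prop_status``)."""
    groups: dict[str, list[float]] = {}
    for rec in records:
        key = getattr(rec, group_by)
        groups.setdefault(key, []).append(float(getattr(rec.counts, region)))
    return {k: np.asarray(v) for k, v in groups.items()}
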