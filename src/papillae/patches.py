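"""Patch extraction and training-time augmentation.

Images are cut into non-overlapping patches (reflect-padded at the
borders) so training memory stays bounded; patches with no tongue coverage
cannot contain papillae and are discarded from the training set.

Augmentation draws a random combination of rotation, horizontal/vertical
mirroring, shearing, zooming and intensity adjustment.  The identical
geometric transform is applied to the image and to every mask/weight map;
masks are warped with nearest-neighbour interpolation so they stay binary,
and intensity changes touch the image only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    weight: np.ndarray | None = None,
    tongue_mask: np.ndarray | None = None,
    patch_size: tuple[int, int] = (384, 576),
    min_tongue_coverage: float = 0.0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Tile an image and its masks into (image, mask, weight) patches.

    Patches whose tongue coverage is not above ``min_tongue_coverage``
    (default: any tongue pixel at all) are left out when a tongue mask is
    supplied.  Raises if the image is smaller than one patch.
    """
    pv, ph = patch_size
    v, h = image.shape[:2]
    if v < pv or h < ph:
        raise ValueError(
            f"image {v}x{h} smaller than patch {pv}x{ph}; resize the input first"
        )
    if weight is None:
        weight = np.ones(image.shape[:2], dtype=np.float32)

    pad_v = (-v) % pv
    pad_h = (-h) % ph

    def pad(a: np.ndarray) -> np.ndarray:
        widths = ((0, pad_v), (0, pad_h)) + ((0, 0),) * (a.ndim - 2)
        return np.pad(a, widths, mode="reflect")

    img_p, mask_p, w_p = pad(image), pad(np.asarray(mask)), pad(weight)
    tongue_p = pad(np.asarray(tongue_mask)) if tongue_mask is not None else None

    out = []
    for r0 in range(0, img_p.shape[0], pv):
        for c0 in range(0, img_p.shape[1], ph):
            sl = (slice(r0, r0 + pv), slice(c0, c0 + ph))
            if tongue_p is not None:
                cov = float(tongue_p[sl].mean())
                if cov <= min_tongue_coverage:
                    continue
            out.append((img_p[sl], mask_p[sl], w_p[sl]))
    return out


def downscale_training_image(
    image: np.ndarray,
    mask: np.ndarray,
    weight: np.ndarray | None = None,
    factor: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Downscale a whole image with its mask/weights for tongue training.

    The tongue occupies most of the frame, so the tongue model trains on
    whole downscaled images rather than patches.  The image is block-mean
    reduced; mask and weights are subsampled (nearest) so they keep their
    discrete values.  Trailing rows/cols are cropped to a multiple of
    ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    v = image.shape[0] - image.shape[0] % factor
    h = image.shape[1] - image.shape[1] % factor
    img = image[:v, :h].reshape(v // factor, factor, h // factor, factor, -1)
    img = img.mean(axis=(1, 3)).astype(np.float32)
    half = factor // 2
    mask_s = np.asarray(mask)[half:v:factor, half:h:factor]
    if weight is None:
        weight = np.ones(image.shape[:2], dtype=np.float32)
    weight_s = np.asarray(weight)[half:v:factor, half:h:factor]
    return img, mask_s, weight_s


@dataclass(frozen=True)
class AugmentParams:
    """One concrete augmentation draw (identity by default)."""

    rotation_deg: float = 0.0
    shear_deg: float = 0.0
    zoom: float = 1.0
    mirror_h: bool = False
    mirror_v: bool = False
    intensity_gain: float = 1.0
    intensity_bias: float = 0.0

    @property
    def is_identity_geometry(self) -> bool:
        return (
            self.rotation_deg == 0.0
            and self.shear_deg == 0.0
            and self.zoom == 1.0
            and not self.mirror_h
            and not self.mirror_v
        )


def sample_augment_params(
    rng: np.random.Generator,
    max_rotation_deg: float = 15.0,
    max_shear_deg: float = 8.0,
    zoom_range: tuple[float, float] = (0.9, 1.1),
    mirror: bool = True,
    max_intensity_gain: float = 0.2,
    max_intensity_bias: float = 0.1,
) -> AugmentParams:
    return AugmentParams(
        rotation_deg=float(rng.uniform(-max_rotation_deg, max_rotation_deg)),
        shear_deg=float(rng.uniform(-max_shear_deg, max_shear_deg)),
        zoom=float(rng.uniform(*zoom_range)),
        mirror_h=bool(mirror and rng.random() < 0.5),
        mirror_v=bool(mirror and rng.random() < 0.5),
        intensity_gain=float(rng.uniform(1 - max_intensity_gain, 1 + max_intensity_gain)),
        intensity_bias=float(rng.uniform(-max_intensity_bias, max_intensity_bias)),
    )


def _geometry_transform(params: AugmentParams, shape: tuple[int, int]) -> AffineTransform:
    v, h = shape
    center = np.array([(h - 1) / 2.0, (v - 1) / 2.0])  # (x, y)
    to_origin = AffineTransform(translation=-center)
    core = AffineTransform(
        rotation=np.deg2rad(params.rotation_deg),
        shear=np.deg2rad(params.shear_deg),
        scale=(params.zoom, params.zoom),
    )
    flip = AffineTransform(
        scale=(-1 if params.mirror_h else 1, -1 if params.mirror_v else 1)
    )
    back = AffineTransform(translation=center)
    return to_origin + core + flip + back


def apply_augment(
    image: np.ndarray,
    masks: list[np.ndarray],
    params: AugmentParams,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Apply one augmentation draw to an image and its masks/weight maps.

    Boolean masks come back boolean (nearest-neighbour warp, re-binarised);
    float maps (e.g. loss weights) are warped nearest-neighbour as well so
    discrete weight levels are preserved.  An identity draw returns the
    inputs unchanged.
    """
    if params.is_identity_geometry:
        img = image
        out_masks = list(masks)
    else:
        tf = _geometry_transform(params, image.shape[:2])
        img = warp(
            image.astype(np.float64), tf.inverse, order=1, mode="reflect", preserve_range=True
        ).astype(np.float32)
        out_masks = []
        for m in masks:
            cval = 0.0 if m.dtype == bool else 1.0  # weight maps pad with 1
            warped = warp(
                m.astype(np.float64), tf.inverse, order=0, mode="constant",
                cval=cval, preserve_range=True,
            )
            out_masks.append(warped > 0.5 if m.dtype == bool else warped.astype(np.float32))
    if params.intensity_gain != 1.0 or params.intensity_bias != 0.0:
        img = np.clip(
            np.asarray(img, dtype=np.float32) * params.intensity_gain + params.intensity_bias,
            0.0,
            1.0,
        )
    return img, out_masks


def augment(
    image: np.ndarray,
    masks: list[np.ndarray],
    seed: int | np.random.Generator,
    **kwargs,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Random augmentation: draw parameters, then apply them."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return apply_augment(image, masks, sample_augment_params(rng, **kwargs))
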