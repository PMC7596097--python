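"""Reading and writing images, masks, weight maps and count tables.

Conventions: RGB images as 8-bit PNG or TIFF; binary masks as single-
channel PNG with values 0/255; float weight maps as single-channel float32
TIFF; per-subject counts and object tables as CSV; the calibration and seed
travel in a JSON sidecar next to each image.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from ._types import CountRecord, PapillaObject, SubjectRecord
from .synthetic import SyntheticSample


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Float [0,1] RGB -> 8-bit PNG/TIFF (by extension)."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    u8 = (arr * 255).round().astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u8)
    else:
        iio.imwrite(path, u8)


def read_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    return arr.astype(np.float32) / 255.0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_weight_map(path: str | Path, weights: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(weights, dtype=np.float32))


def read_weight_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float32)


def write_sidecar(path: str | Path, px_per_mm: float, seed: int, **extra) -> None:
    payload = {"px_per_mm": px_per_mm, "seed": seed, **extra}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def objects_to_frame(objects: list[PapillaObject]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": o.label,
                "area_px": o.area_px,
                "area_mm2": o.area_mm2,
                "centroid_row": o.centroid[0],
                "centroid_col": o.centroid[1],
            }
            for o in objects
        ],
        columns=["label", "area_px", "area_mm2", "centroid_row", "centroid_col"],
    )


def frame_to_objects(df: pd.DataFrame) -> list[PapillaObject]:
    return [
        PapillaObject(
            label=int(r.label),
            area_px=int(r.area_px),
            centroid=(float(r.centroid_row), float(r.centroid_col)),
            area_mm2=None if pd.isna(r.area_mm2) else float(r.area_mm2),
        )
        for r in df.itertuples()
    ]


COUNTS_COLUMNS = [
    "subject_id", "ED1", "ED2", "ED3", "TOT", "gender", "prop_status", "prop_rating",
]


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id,
            "ED1": rec.counts.ED1,
            "ED2": rec.counts.ED2,
            "ED3": rec.counts.ED3,
            "TOT": rec.counts.TOT,
            "gender": rec.gender,
            "prop_status": rec.prop_status,
            "prop_rating": rec.prop_rating,
        }
        for k, v in rec.counts.densities.items():
            row[f"density_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    out = []
    for r in df.itertuples():
        counts = CountRecord(
            subject_id=str(r.subject_id),
            ED1=int(r.ED1), ED2=int(r.ED2), ED3=int(r.ED3), TOT=int(r.TOT),
        )
        out.append(
            SubjectRecord(
                subject_id=str(r.subject_id),
                gender=str(r.gender),
                prop_status=str(r.prop_status),
                prop_rating=float(r.prop_rating),
                counts=counts,
            )
        )
    return out


def write_sample(sample: SyntheticSample, out_dir: str | Path, subject_id: str) -> None:
    """Persist one synthetic sample: image, three masks, sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / f"{subject_id}_image.png", sample.image)
    write_mask(out / f"{subject_id}_papillae.png", sample.papillae_mask)
    write_mask(out / f"{subject_id}_tongue.png", sample.tongue_mask)
    write_mask(out / f"{subject_id}_lip.png", sample.lip_mask)
    write_sidecar(
        out / f"{subject_id}_meta.json",
        px_per_mm=sample.spec.px_per_mm,
        seed=sample.spec.seed,
        n_papillae=sample.spec.n_papillae,
    )
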