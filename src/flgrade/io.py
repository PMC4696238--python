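"""File formats: raster images, the CSV dialects, and JSON serialization.

CSV dialects used across the pipeline:

* candidates: ``grid_row,grid_col,r0,c0,r1,c1,positive_fraction``
* centroblast annotations: ``image_id,row,col``
* training set: ``w00..w63,label``
* reader scores: ``reader_id,case_id,modality,score``
* case truth: ``case_id,grade``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .cb_classifier import CentroblastAnnotation, TrainingSet
from .hpf_detection import HpfCandidate
from .registration import RgbImage, RigidTransform, _as_pixels

Image.MAX_IMAGE_PIXELS = None  # whole-slide crops exceed PIL's default bomb check


def read_image(path: str | Path, pixel_size_um: float | None = None,
               magnification_label: str = "40x") -> RgbImage:
    """Read a PNG/TIFF file as an RGB image."""
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    kwargs = {} if pixel_size_um is None else {"pixel_size_um": pixel_size_um}
    return RgbImage(px, magnification_label=magnification_label, **kwargs)


def write_image(path: str | Path, image: "RgbImage | np.ndarray") -> None:
    px = _as_pixels(image)
    Image.fromarray(np.asarray(px)).save(path)


def candidates_to_frame(candidates: Sequence[HpfCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"grid_row": c.grid_row, "grid_col": c.grid_col,
          "r0": c.bbox[0], "c0": c.bbox[1], "r1": c.bbox[2], "c1": c.bbox[3],
          "positive_fraction": c.positive_fraction} for c in candidates],
        columns=["grid_row", "grid_col", "r0", "c0", "r1", "c1", "positive_fraction"])


def frame_to_candidates(df: pd.DataFrame) -> list[HpfCandidate]:
    return [HpfCandidate(grid_row=int(r.grid_row), grid_col=int(r.grid_col),
                         bbox=(int(r.r0), int(r.c0), int(r.r1), int(r.c1)),
                         positive_fraction=float(r.positive_fraction))
            for r in df.itertuples()]


def write_candidates(path: str | Path, candidates: Sequence[HpfCandidate]) -> None:
    candidates_to_frame(candidates).to_csv(path, index=False)


def read_candidates(path: str | Path) -> list[HpfCandidate]:
    return frame_to_candidates(pd.read_csv(path))


def write_training_set(path: str | Path, ts: TrainingSet) -> None:
    df = pd.DataFrame(ts.features, columns=[f"w{i:02d}" for i in range(64)])
    df["label"] = ts.labels
    df.to_csv(path, index=False)


def read_training_set(path: str | Path) -> TrainingSet:
    df = pd.read_csv(path)
    cols = [f"w{i:02d}" for i in range(64)]
    return TrainingSet(features=df[cols].to_numpy(dtype=float),
                       labels=df["label"].to_numpy())


def read_annotations(path: str | Path) -> list[CentroblastAnnotation]:
    df = pd.read_csv(path)
    return [CentroblastAnnotation(image_id=str(r.image_id), row=int(r.row),
                                  col=int(r.col)) for r in df.itertuples()]


def write_annotations(path: str | Path,
                      annotations: Sequence[CentroblastAnnotation]) -> None:
    pd.DataFrame([vars(a) for a in annotations]).to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"reader_id": str, "case_id": str})


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"case_id": str})


def write_transform(path: str | Path, tf: RigidTransform) -> None:
    Path(path).write_text(json.dumps(tf.to_dict(), indent=2))


def read_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))
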