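"""Instance-mask stage: a pluggable source of per-body binary masks.

The measurement pipeline only needs ``masks + scores + boxes`` from its
first stage.  In production that stage is a learned instance segmenter fed
through :func:`load_external_masks`; for synthetic scenes a deliberately
classical stand-in (:func:`segment_instances`: background-difference
threshold, speckle removal, distance-transform watershed splitting of
touching bodies) provides the same contract.  Stand-in scores are
normalized component areas and are not calibrated confidences.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from . import cocoio


@dataclasses.dataclass
class DetectionResult:
    masks: list[np.ndarray]          # each (H, W) uint8 {0,1}
    scores: list[float]              # in [0, 1]
    boxes: list[tuple[int, int, int, int]]  # (r0, c0, r1, c1) half-open

    def __len__(self) -> int:
        return len(self.masks)


@dataclasses.dataclass(frozen=True)
class SegmenterParams:
    """Settings of the classical stand-in segmenter."""

    threshold: float | None = None      # None -> Otsu on |image - median|
    smooth_sigma: float = 1.0           # presmoothing of the difference map
    min_area_frac: float = 1e-4         # speckle filter, fraction of frame
    split_touching: bool = True
    min_peak_distance: int = 12         # watershed marker separation, px
    split_area_factor: float = 1.6      # split only blobs this many times
                                        # larger than the median blob


def mask_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open bounding box (r0, c0, r1, c1) of a nonempty mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def _split_component(comp: np.ndarray, params: SegmenterParams) -> list[np.ndarray]:
    """Split one foreground blob into bodies by distance-transform watershed."""
    dist = ndimage.distance_transform_edt(comp)
    peaks = peak_local_max(
        dist, min_distance=params.min_peak_distance, labels=comp, exclude_border=False
    )
    if len(peaks) < 2:
        return [comp.astype(np.uint8)]
    markers = np.zeros(comp.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks):
        markers[r, c] = i + 1
    labels = watershed(-dist, markers, mask=comp)
    return [
        (labels == lab).astype(np.uint8)
        for lab in range(1, labels.max() + 1)
        if (labels == lab).any()
    ]


def segment_instances(
    image: np.ndarray, params: SegmenterParams = SegmenterParams()
) -> DetectionResult:
    """Classical stand-in segmenter for top-down scenes on a plain container.

    Foreground is where the per-pixel distance from the median background
    color exceeds a threshold (Otsu-selected when not given).  Components
    much larger than the median body are split by watershed on the distance
    transform; components below the minimum-area filter are dropped.  An
    empty result is a valid return.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    img = image.astype(float)
    bg = np.median(img.reshape(-1, 3), axis=0)
    diff = np.linalg.norm(img - bg, axis=2)
    if params.smooth_sigma > 0:
        # Translucent bodies sit barely above the noise floor; smoothing
        # the difference map keeps each body a single thresholded blob.
        diff = ndimage.gaussian_filter(diff, params.smooth_sigma)
    thr = params.threshold
    if thr is None:
        thr = float(threshold_otsu(diff)) if diff.max() > 0 else np.inf
    fg = diff > thr
    fg = ndimage.binary_fill_holes(fg)

    min_area = params.min_area_frac * fg.size
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    comps = [
        (labels == i) for i in range(1, n + 1) if np.count_nonzero(labels == i) >= min_area
    ]

    masks: list[np.ndarray] = []
    if comps:
        areas = np.array([c.sum() for c in comps], dtype=float)
        median_area = np.median(areas)
        for comp, area in zip(comps, areas):
            if params.split_touching and area > params.split_area_factor * median_area:
                parts = _split_component(comp, params)
            else:
                parts = [comp.astype(np.uint8)]
            masks.extend(p for p in parts if p.sum() >= min_area)

    if not masks:
        return DetectionResult(masks=[], scores=[], boxes=[])
    areas = np.array([m.sum() for m in masks], dtype=float)
    scores = (areas / areas.max()).tolist()
    boxes = [mask_box(m) for m in masks]
    return DetectionResult(masks=masks, scores=scores, boxes=boxes)


def load_external_masks(path: str | Path) -> DetectionResult:
    """Load a COCO-style annotation/prediction file as a DetectionResult.

    Decodes polygon or RLE segmentations; preserves ``score`` fields when
    present, else assigns 1.0.  This is the integration point for a real
    instance segmenter.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read COCO JSON {path}: {exc}") from exc
    sizes = {
        img["id"]: (img["height"], img["width"]) for img in doc.get("images", [])
    }
    masks, scores = [], []
    for ann in doc.get("annotations", doc.get("predictions", [])):
        shape = sizes.get(ann.get("image_id"))
        if shape is None:
            seg = ann["segmentation"]
            if isinstance(seg, dict):
                shape = tuple(seg["size"])
            else:
                raise ValueError(
                    f"{path}: annotation {ann.get('id')} has polygon "
                    "segmentation but no declared image size"
                )
        masks.append(cocoio.decode_segmentation(ann["segmentation"], shape))
        scores.append(float(ann.get("score", 1.0)))
    boxes = [mask_box(m) if m.any() else (0, 0, 0, 0) for m in masks]
    return DetectionResult(masks=masks, scores=scores, boxes=boxes)
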