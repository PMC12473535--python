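"""Minimal COCO-style mask codec (uncompressed RLE and polygons).

Only the dialects the pipeline exchanges are supported: uncompressed
column-major RLE objects ``{"size": [h, w], "counts": [int, ...]}`` and
polygon lists ``[[x0, y0, x1, y1, ...], ...]`` in pixel coordinates.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon as draw_polygon


def encode_rle(mask: np.ndarray) -> dict:
    """Encode a binary mask as uncompressed column-major (Fortran) RLE.

    The counts list alternates runs of 0s and 1s, starting with 0s (a
    leading zero-length run when the mask starts with foreground).
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    flat = (mask > 0).flatten(order="F").astype(np.int8)
    # Run boundaries.
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": counts}


def decode_rle(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    if sum(counts) != h * w:
        raise ValueError(
            f"RLE counts sum to {sum(counts)}, expected {h * w} for size {h}x{w}"
        )
    flat = np.zeros(h * w, dtype=np.uint8)
    pos = 0
    val = 0
    for run in counts:
        if val:
            flat[pos : pos + run] = 1
        pos += run
        val ^= 1
    return flat.reshape((h, w), order="F")


def decode_polygons(polys: list, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize COCO polygon segmentation (x, y interleaved) to a mask."""
    mask = np.zeros(shape, dtype=np.uint8)
    for poly in polys:
        xy = np.asarray(poly, dtype=float).reshape(-1, 2)
        rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=shape)
        mask[rr, cc] = 1
    return mask


def decode_segmentation(seg, shape: tuple[int, int]) -> np.ndarray:
    """Decode either RLE or polygon segmentation to a binary mask."""
    if isinstance(seg, dict):
        mask = decode_rle(seg)
        if mask.shape != tuple(shape):
            raise ValueError(
                f"RLE size {mask.shape} does not match image size {tuple(shape)}"
            )
        return mask
    if isinstance(seg, list):
        return decode_polygons(seg, shape)
    raise ValueError(f"unsupported segmentation type: {type(seg).__name__}")


def mask_bbox_xywh(mask: np.ndarray) -> list[float]:
    """Tight COCO bbox [x, y, w, h] of a mask (zeros for an empty mask)."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return [0.0, 0.0, 0.0, 0.0]
    r0, r1 = rows[0], rows[-1]
    c0, c1 = cols[0], cols[-1]
    return [float(c0), float(r0), float(c1 - c0 + 1), float(r1 - r0 + 1)]
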