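"""Synthetic top-down shrimp scenes with exact ground truth.

Emulates the study conditions the measurement pipeline is built for: a
container imaged from above at 848x480, holding 10-18 curved, translucent,
elongated bodies of 4-11 cm equivalent length.  Each instance carries its
generating centerline polyline and exact arc length, so every downstream
stage (instance masks, centerline prediction, thinning, calibration) can be
tested without any external data.

Bodies are built by sweeping a disk of varying radius along a smooth random
spline; the radius tapers toward both ends (head/tail) and the body is
alpha-blended over the background to emulate the semi-transparency of real
shrimp.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.interpolate import CubicSpline

from . import cocoio

#: Calibration used for synthetic scenes, in mm per pixel.  Matches the
#: study geometry implied by the px/mm error ratios of the reference setup
#: (10.23 mm / 19.44 px).
DEFAULT_MM_PER_PX = 10.23 / 19.44


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    ``curvature_range`` bounds the total absolute heading change (radians)
    accumulated along a body's spine; 0 gives straight capsules, values
    around 2-3 give strongly curled bodies.
    """

    image_height: int = 480
    image_width: int = 848
    n_instances: int = 12
    body_length_range_mm: tuple[float, float] = (40.0, 110.0)
    body_width_px_range: tuple[float, float] = (7.0, 15.0)
    curvature_range: tuple[float, float] = (0.3, 2.2)
    mm_per_px: float = DEFAULT_MM_PER_PX
    allow_overlap: bool = False
    background_style: str = "plain"
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        lo, hi = self.body_length_range_mm
        if not (0 < lo <= hi):
            raise ValueError("invalid body_length_range_mm")
        if self.background_style not in ("plain", "textured"):
            raise ValueError("background_style must be 'plain' or 'textured'")


@dataclasses.dataclass
class InstanceTruth:
    """Ground truth for one body: mask, spine polyline and exact lengths."""

    mask: np.ndarray                 # (H, W) uint8 in {0, 1}
    centerline_polyline: np.ndarray  # (P, 2) float (row, col)
    true_length_px: float
    true_length_mm: float


@dataclasses.dataclass
class Scene:
    image: np.ndarray  # (H, W, 3) uint8
    instances: list[InstanceTruth]
    config: SceneConfig


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline as the sum of Euclidean segment lengths."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _spine_polyline(
    rng: np.random.Generator,
    length_px: float,
    curvature: float,
    n_ctrl: int,
    heading0: float,
    step_px: float = 0.5,
) -> np.ndarray:
    """Smooth spine of exactly ``length_px`` arc length, via a cubic spline
    through control points laid down by a heading walk of total absolute
    turn ``curvature`` radians."""
    # Heading walk: split total bend into n_ctrl-1 turns of random sign
    # pattern but smooth progression (single-lobe or S depending on draw).
    turns = rng.normal(size=n_ctrl - 1)
    if np.sum(np.abs(turns)) > 0:
        turns *= curvature / np.sum(np.abs(turns))
    headings = heading0 + np.concatenate([[0.0], np.cumsum(turns)])
    seg = length_px / (n_ctrl - 1)
    steps = np.stack([np.sin(headings) * seg, np.cos(headings) * seg], axis=1)
    ctrl = np.concatenate([[[0.0, 0.0]], np.cumsum(steps[:-1], axis=0)], axis=0)
    # Chord-length parameterized cubic spline through control points.
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))]
    )
    if chord[-1] == 0:
        raise ValueError("degenerate spine")
    spline = CubicSpline(chord, ctrl, axis=0)
    n_samples = max(int(np.ceil(chord[-1] / step_px)), 8)
    pts = spline(np.linspace(0.0, chord[-1], n_samples))
    # Rescale so the sampled polyline's arc length is exactly length_px.
    cur = polyline_length(pts)
    pts = pts[0] + (pts - pts[0]) * (length_px / cur)
    return pts


def _radius_profile(r_max: float, n: int) -> np.ndarray:
    """Tapered half-width along the spine: r(t) = r_max*(0.35+0.65*sin(pi t))."""
    t = np.linspace(0.0, 1.0, n)
    return r_max * (0.35 + 0.65 * np.sin(np.pi * t))


def rasterize_swept_body(
    polyline: np.ndarray, radii: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Binary mask of a disk of radius ``radii[i]`` swept along ``polyline``.

    Consecutive samples are closer than the minimum radius, so the union of
    stamped disks is a single 8-connected region containing the polyline.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    for (r, c), rad in zip(polyline, radii):
        r0 = max(int(np.floor(r - rad)), 0)
        r1 = min(int(np.ceil(r + rad)) + 1, h)
        c0 = max(int(np.floor(c - rad)), 0)
        c1 = min(int(np.ceil(c + rad)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= ((yy - r) ** 2 + (xx - c) ** 2 <= rad**2).astype(
            np.uint8
        )
    return mask


def build_instance(
    polyline: np.ndarray,
    r_max: float,
    shape: tuple[int, int],
    mm_per_px: float,
) -> InstanceTruth:
    """Construct an :class:`InstanceTruth` from an explicit spine polyline.

    Exposed so tests and experiments can build bodies of prescribed shape
    (straight capsules, S-curves) rather than random ones.
    """
    polyline = np.asarray(polyline, dtype=float)
    radii = _radius_profile(r_max, len(polyline))
    mask = rasterize_swept_body(polyline, radii, shape)
    lpx = polyline_length(polyline)
    return InstanceTruth(
        mask=mask,
        centerline_polyline=polyline,
        true_length_px=lpx,
        true_length_mm=lpx * mm_per_px,
    )


def _make_background(rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    h, w = cfg.image_height, cfg.image_width
    base = np.full((h, w, 3), 185.0)
    if cfg.background_style == "textured":
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.normal(size=(h, w)), sigma=8.0)
        tex = 25.0 * tex / (np.abs(tex).max() + 1e-12)
        base += tex[..., None]
    return base


def generate_scene(config: SceneConfig) -> Scene:
    """Generate one seeded scene with full ground truth.

    Raises ``RuntimeError`` if ``n_instances`` non-overlapping bodies cannot
    be placed within a bounded number of attempts.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    background = _make_background(rng, config)
    image = background.copy()
    occupied = np.zeros((h, w), dtype=bool)
    instances: list[InstanceTruth] = []

    max_attempts = 60 * config.n_instances
    attempts = 0
    while len(instances) < config.n_instances:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_instances} non-overlapping bodies "
                f"after {max_attempts} attempts; reduce n_instances or set "
                "allow_overlap=True"
            )
        attempts += 1
        length_mm = rng.uniform(*config.body_length_range_mm)
        length_px = length_mm / config.mm_per_px
        width_px = rng.uniform(*config.body_width_px_range)
        r_max = width_px / 2.0
        curvature = rng.uniform(*config.curvature_range)
        heading0 = 0.0 if curvature == 0 else rng.uniform(0.0, 2.0 * np.pi)
        n_ctrl = int(rng.integers(4, 7))
        spine = _spine_polyline(rng, length_px, curvature, n_ctrl, heading0)
        # Place: shift so the spine (plus margin) fits inside the frame.
        margin = r_max + 2.0
        lo = spine.min(axis=0)
        hi = spine.max(axis=0)
        span = hi - lo
        if span[0] + 2 * margin >= h or span[1] + 2 * margin >= w:
            continue  # too large for the frame at this pose; redraw
        off_r = rng.uniform(margin - lo[0], h - margin - hi[0])
        off_c = rng.uniform(margin - lo[1], w - margin - hi[1])
        spine = spine + np.array([off_r, off_c])

        inst = build_instance(spine, r_max, (h, w), config.mm_per_px)
        body = inst.mask.astype(bool)
        if not config.allow_overlap and (body & occupied).any():
            continue
        occupied |= body
        instances.append(inst)

        # Render: semi-translucent body over current image.
        alpha = rng.uniform(0.5, 0.9)
        color = np.array(
            [
                rng.uniform(150, 185),
                rng.uniform(110, 140),
                rng.uniform(95, 125),
            ]
        )
        image[body] = (1 - alpha) * image[body] + alpha * color

    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return Scene(image=image, instances=instances, config=config)


# ---------------------------------------------------------------------------
# Export / import


def export_scene(scene: Scene, out_dir: str | Path, scene_id: str = "scene") -> dict:
    """Write a scene as PNG + COCO-style JSON + centerline sidecar JSON.

    Returns a manifest dict with the paths written.  Round-trip via
    :func:`load_scene` reproduces every mask bit-exactly (masks are stored
    as uncompressed column-major RLE).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        img_path = out_dir / f"{scene_id}.png"
        Image.fromarray(scene.image).save(img_path)

        h, w = scene.image.shape[:2]
        annotations = []
        sidecar = []
        for i, inst in enumerate(scene.instances):
            rle = cocoio.encode_rle(inst.mask)
            annotations.append(
                {
                    "id": i + 1,
                    "image_id": 1,
                    "category_id": 1,
                    "segmentation": rle,
                    "area": int(inst.mask.sum()),
                    "bbox": cocoio.mask_bbox_xywh(inst.mask),
                    "iscrowd": 0,
                }
            )
            sidecar.append(
                {
                    "instance_id": i + 1,
                    "polyline": inst.centerline_polyline.tolist(),
                    "length_px": inst.true_length_px,
                    "length_mm": inst.true_length_mm,
                }
            )
        coco = {
            "images": [
                {"id": 1, "height": h, "width": w, "file_name": img_path.name}
            ],
            "annotations": annotations,
            "categories": [{"id": 1, "name": "shrimp"}],
        }
        coco_path = out_dir / f"{scene_id}_coco.json"
        coco_path.write_text(json.dumps(coco))
        side_path = out_dir / f"{scene_id}_centerlines.json"
        side_path.write_text(
            json.dumps(
                {"mm_per_px": scene.config.mm_per_px, "instances": sidecar}
            )
        )
    except OSError as exc:
        raise OSError(f"failed writing scene to {out_dir}: {exc}") from exc
    return {
        "image": str(img_path),
        "coco": str(coco_path),
        "centerlines": str(side_path),
    }


def load_scene(manifest: dict) -> Scene:
    """Reload a scene exported by :func:`export_scene` (config defaults)."""
    image = np.asarray(Image.open(manifest["image"]).convert("RGB"))
    coco = json.loads(Path(manifest["coco"]).read_text())
    side = json.loads(Path(manifest["centerlines"]).read_text())
    h = coco["images"][0]["height"]
    w = coco["images"][0]["width"]
    by_id = {rec["instance_id"]: rec for rec in side["instances"]}
    instances = []
    for ann in coco["annotations"]:
        mask = cocoio.decode_segmentation(ann["segmentation"], (h, w))
        rec = by_id[ann["id"]]
        instances.append(
            InstanceTruth(
                mask=mask,
                centerline_polyline=np.asarray(rec["polyline"], dtype=float),
                true_length_px=float(rec["length_px"]),
                true_length_mm=float(rec["length_mm"]),
            )
        )
    cfg = SceneConfig(
        image_height=h,
        image_width=w,
        n_instances=len(instances),
        mm_per_px=float(side["mm_per_px"]),
    )
    return Scene(image=image, instances=instances, config=cfg)
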