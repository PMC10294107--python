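"""Deterministic synthetic seed-scene generator with per-seed ground truth.

Emulates the photographs the pipeline targets: bright convex soybean-hued
blobs (rotated ellipses) scattered on a dark background, a controllable
fraction of seed pairs joined by thin "tiny contact" bridges, a smooth
illumination gradient and additive pixel noise. Every scene is fully
determined by its RNG seed, and ground truth (per-seed masks, designated
touching pairs, union foreground) is returned alongside, so each pipeline
stage can be tested without any external data.

Scenes default to 1024x683 px, a 3:2 scale-down of the 3072x2048 camera
frames the pipeline is designed for; full size is available via config.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from .enhance import read_scene, write_scene
from .errors import CapacityError, ParameterError
from .segment import SeedBox

__all__ = [
    "GenConfig",
    "SeedTruth",
    "SceneTruth",
    "generate_scene",
    "generate_scenes",
    "make_benchmark",
    "load_benchmark",
    "rle_encode",
    "rle_decode",
]


@dataclass(frozen=True)
class GenConfig:
    """Scene-generation parameters.

    ``touching_fraction`` of the seeds are placed in designated pairs whose
    boundaries are joined by a drawn bridge of ``bridge_width`` px; all
    other seeds keep at least ``min_gap`` px of clear background between
    them. ``floor(touching_fraction * n_seeds / 2)`` pairs are produced.
    """

    width: int = 1024
    height: int = 683
    n_seeds: int = 40
    touching_fraction: float = 0.2
    bridge_width: int = 3
    #: min/max ellipse semi-axes in px (defaults scale the ~200 px soybean
    #: diameter of the full-resolution frames down by the same 1/3 factor
    #: as the canvas)
    seed_axes_range: tuple[float, float] = (22.0, 34.0)
    base_color: tuple[float, float, float] = (190.0, 158.0, 96.0)
    color_jitter: float = 18.0
    bg_color: tuple[float, float, float] = (30.0, 28.0, 26.0)
    noise_sigma: float = 4.0
    #: max relative brightness ramp across the scene (multiplicative)
    illum_gradient: float = 0.15
    rng_seed: int = 12345
    #: background gap between the boundaries of a designated pair, spanned
    #: by the bridge
    bridge_len: float = 8.0
    #: minimum separation between non-designated seeds
    min_gap: float = 4.0
    max_place_tries: int = 300

    def __post_init__(self) -> None:
        if not (0.0 <= self.touching_fraction <= 1.0):
            raise ParameterError("touching_fraction must be in [0, 1]")
        if self.bridge_width < 1:
            raise ParameterError("bridge_width must be >= 1")
        lo, hi = self.seed_axes_range
        if lo <= 0 or hi < lo:
            raise ParameterError("seed_axes_range must be positive and ordered")
        if self.n_seeds < 0:
            raise ParameterError("n_seeds must be >= 0")

    @property
    def n_touch_pairs(self) -> int:
        return int(self.touching_fraction * self.n_seeds / 2)


@dataclass(frozen=True)
class SeedTruth:
    """Ground truth for one seed: ellipse parameters plus its pixel mask.

    The mask is stored bbox-local to keep 40-seed truths compact; ``bbox``
    places it in scene coordinates.
    """

    center: tuple[float, float]  # (cx, cy)
    axes: tuple[float, float]    # semi-axes (a >= b)
    rotation: float              # radians, major axis vs +x
    bbox: SeedBox
    mask_local: NDArray[np.bool_]

    def full_mask(self, shape: tuple[int, int]) -> NDArray[np.bool_]:
        m = np.zeros(shape, dtype=bool)
        b = self.bbox
        m[b.y : b.y + b.h, b.x : b.x + b.w] = self.mask_local
        return m


@dataclass
class SceneTruth:
    """Per-scene ground truth emitted by the generator."""

    width: int
    height: int
    seeds: list[SeedTruth]
    touching_pairs: list[tuple[int, int]]
    union_mask: NDArray[np.bool_]

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)


def _ellipse_radius(a: float, b: float, rotation: float, phi: float) -> float:
    """Radius of the ellipse boundary along scene direction ``phi``."""
    psi = phi - rotation
    return a * b / math.hypot(b * math.cos(psi), a * math.sin(psi))


def _ellipse_mask(
    cx: float, cy: float, a: float, b: float, rot: float, shape: tuple[int, int]
) -> tuple[SeedBox, NDArray[np.bool_]]:
    """Rasterize a rotated ellipse; returns its tight bbox and local mask."""
    h, w = shape
    ex = math.sqrt((a * math.cos(rot)) ** 2 + (b * math.sin(rot)) ** 2)
    ey = math.sqrt((a * math.sin(rot)) ** 2 + (b * math.cos(rot)) ** 2)
    x0 = max(0, int(math.floor(cx - ex)))
    x1 = min(w, int(math.ceil(cx + ex)) + 1)
    y0 = max(0, int(math.floor(cy - ey)))
    y1 = min(h, int(math.ceil(cy + ey)) + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - cx
    dy = ys - cy
    u = dx * math.cos(rot) + dy * math.sin(rot)
    v = -dx * math.sin(rot) + dy * math.cos(rot)
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # tighten the bbox to the rasterized pixels
    rows = np.flatnonzero(local.any(axis=1))
    cols = np.flatnonzero(local.any(axis=0))
    local = local[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    box = SeedBox(
        x=x0 + int(cols[0]),
        y=y0 + int(rows[0]),
        w=int(cols[-1] - cols[0] + 1),
        h=int(rows[-1] - rows[0] + 1),
    )
    return box, local


def _stadium_mask(
    p1: tuple[float, float], p2: tuple[float, float], half_width: float, shape: tuple[int, int]
) -> NDArray[np.bool_]:
    """Pixels within ``half_width`` of the segment p1-p2 (a bridge strip)."""
    h, w = shape
    x0 = max(0, int(math.floor(min(p1[0], p2[0]) - half_width)) - 1)
    x1 = min(w, int(math.ceil(max(p1[0], p2[0]) + half_width)) + 2)
    y0 = max(0, int(math.floor(min(p1[1], p2[1]) - half_width)) - 1)
    y1 = min(h, int(math.ceil(max(p1[1], p2[1]) + half_width)) + 2)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    vx, vy = p2[0] - p1[0], p2[1] - p1[1]
    seg_len2 = vx * vx + vy * vy
    t = ((xs - p1[0]) * vx + (ys - p1[1]) * vy) / max(seg_len2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    dist = np.hypot(xs - (p1[0] + t * vx), ys - (p1[1] + t * vy))
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = dist <= half_width
    return out


class _Placer:
    """Dart-throwing placement with conservative bounding-circle gaps."""

    def __init__(self, config: GenConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.circles: list[tuple[float, float, float]] = []  # (cx, cy, r)

    def _clear(self, cx: float, cy: float, r: float, skip: set[int]) -> bool:
        cfg = self.cfg
        if not (r + cfg.min_gap <= cx <= cfg.width - r - cfg.min_gap):
            return False
        if not (r + cfg.min_gap <= cy <= cfg.height - r - cfg.min_gap):
            return False
        for i, (ox, oy, orr) in enumerate(self.circles):
            if i in skip:
                continue
            if math.hypot(cx - ox, cy - oy) < r + orr + cfg.min_gap:
                return False
        return True

    def sample_axes(self) -> tuple[float, float]:
        lo, hi = self.cfg.seed_axes_range
        a = self.rng.uniform(lo, hi)
        b = self.rng.uniform(lo, a)
        return a, b

    def place_single(self) -> tuple[float, float, float, float, float]:
        cfg = self.cfg
        for _ in range(cfg.max_place_tries):
            a, b = self.sample_axes()
            rot = self.rng.uniform(0.0, math.pi)
            cx = self.rng.uniform(0, cfg.width)
            cy = self.rng.uniform(0, cfg.height)
            if self._clear(cx, cy, a, skip=set()):
                self.circles.append((cx, cy, a))
                return cx, cy, a, b, rot
        raise CapacityError("could not place a seed; reduce n_seeds or seed size")

    def place_pair(self):
        cfg = self.cfg
        for _ in range(cfg.max_place_tries):
            a1, b1 = self.sample_axes()
            rot1 = self.rng.uniform(0.0, math.pi)
            a2, b2 = self.sample_axes()
            rot2 = self.rng.uniform(0.0, math.pi)
            phi = self.rng.uniform(0.0, 2.0 * math.pi)
            r1 = _ellipse_radius(a1, b1, rot1, phi)
            r2 = _ellipse_radius(a2, b2, rot2, phi + math.pi)
            d = r1 + r2 + cfg.bridge_len
            cx1 = self.rng.uniform(0, cfg.width)
            cy1 = self.rng.uniform(0, cfg.height)
            cx2 = cx1 + d * math.cos(phi)
            cy2 = cy1 + d * math.sin(phi)
            n = len(self.circles)
            if not self._clear(cx1, cy1, a1, skip={n}):
                continue
            self.circles.append((cx1, cy1, a1))
            if self._clear(cx2, cy2, a2, skip={n}):
                self.circles.append((cx2, cy2, a2))
                return (cx1, cy1, a1, b1, rot1), (cx2, cy2, a2, b2, rot2), phi
            self.circles.pop()
        raise CapacityError("could not place a touching pair; scene too crowded")


def generate_scene(config: GenConfig | None = None) -> tuple[NDArray[np.uint8], SceneTruth]:
    """Render one synthetic seed scene plus its ground truth.

    Seeds are rotated ellipses placed by dart-throwing with gap
    constraints; each designated pair is joined by a drawn bridge of
    ``bridge_width`` px spanning the gap between the two boundaries. The
    scene is shaded with a linear illumination ramp, perturbed by Gaussian
    pixel noise, and quantized to 8-bit. Fully determined by ``rng_seed``.
    """
    config = config or GenConfig()
    cfg = config
    shape = (cfg.height, cfg.width)
    lo, hi = cfg.seed_axes_range
    if cfg.n_seeds * math.pi * hi * hi > 0.4 * cfg.width * cfg.height:
        raise CapacityError(
            f"{cfg.n_seeds} seeds with semi-axes up to {hi} px exceed 40% of the canvas"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    placer = _Placer(cfg, rng)

    ellipses: list[tuple[float, float, float, float, float]] = []
    pairs: list[tuple[int, int]] = []
    bridges: list[tuple[tuple[float, float], tuple[float, float]]] = []

    n_pairs = cfg.n_touch_pairs
    for _ in range(n_pairs):
        e1, e2, phi = placer.place_pair()
        i = len(ellipses)
        ellipses += [e1, e2]
        pairs.append((i, i + 1))
        # bridge endpoints: slightly inside each ellipse so the strip
        # overlaps both masks and guarantees connectivity
        cx1, cy1, a1, b1, rot1 = e1
        cx2, cy2, a2, b2, rot2 = e2
        r1 = _ellipse_radius(a1, b1, rot1, phi)
        r2 = _ellipse_radius(a2, b2, rot2, phi + math.pi)
        p1 = (cx1 + (r1 - 2.0) * math.cos(phi), cy1 + (r1 - 2.0) * math.sin(phi))
        p2 = (cx2 - (r2 - 2.0) * math.cos(phi), cy2 - (r2 - 2.0) * math.sin(phi))
        bridges.append((p1, p2))
    for _ in range(cfg.n_seeds - 2 * n_pairs):
        ellipses.append(placer.place_single())

    img = np.empty((*shape, 3), dtype=np.float64)
    img[:] = cfg.bg_color
    union = np.zeros(shape, dtype=bool)
    seeds: list[SeedTruth] = []
    colors = []
    for cx, cy, a, b, rot in ellipses:
        box, local = _ellipse_mask(cx, cy, a, b, rot, shape)
        color = np.clip(
            np.asarray(cfg.base_color) + rng.uniform(-cfg.color_jitter, cfg.color_jitter, 3),
            0,
            255,
        )
        colors.append(color)
        region = img[box.y : box.y + box.h, box.x : box.x + box.w]
        region[local] = color
        union[box.y : box.y + box.h, box.x : box.x + box.w] |= local
        seeds.append(
            SeedTruth(center=(cx, cy), axes=(a, b), rotation=rot, bbox=box, mask_local=local)
        )

    for (i, j), (p1, p2) in zip(pairs, bridges):
        strip = _stadium_mask(p1, p2, cfg.bridge_width / 2.0, shape)
        new = strip & ~union
        img[new] = (colors[i] + colors[j]) / 2.0
        union |= strip

    if cfg.illum_gradient > 0:
        psi = rng.uniform(0.0, 2.0 * math.pi)
        ys, xs = np.mgrid[0 : cfg.height, 0 : cfg.width]
        proj = xs * math.cos(psi) + ys * math.sin(psi)
        t = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
        img *= (1.0 - cfg.illum_gradient / 2.0 + cfg.illum_gradient * t)[:, :, None]
    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, img.shape)

    scene = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = SceneTruth(
        width=cfg.width,
        height=cfg.height,
        seeds=seeds,
        touching_pairs=pairs,
        union_mask=union,
    )
    return scene, truth


def _scene_seeds(master_seed: int, n_scenes: int) -> list[int]:
    """Per-scene child seeds derived deterministically from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_scenes, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def generate_scenes(
    n_scenes: int, config: GenConfig | None = None
) -> list[tuple[NDArray[np.uint8], SceneTruth]]:
    """Generate ``n_scenes`` scenes with per-scene seeds derived from
    ``config.rng_seed``, without touching disk."""
    config = config or GenConfig()
    return [
        generate_scene(replace(config, rng_seed=s))
        for s in _scene_seeds(config.rng_seed, n_scenes)
    ]


# ---------------------------------------------------------------------------
# benchmark I/O: PNG scenes + JSON truth sidecars with RLE-encoded masks


def rle_encode(mask: NDArray[np.bool_]) -> list[int]:
    """Run-length encode a flattened boolean mask.

    Alternating run lengths starting with a background run (possibly 0).
    """
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: list[int], shape: tuple[int, int]) -> NDArray[np.bool_]:
    """Inverse of :func:`rle_encode`."""
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    val = False
    for r in runs:
        if val:
            flat[pos : pos + r] = True
        pos += r
        val = not val
    if pos != flat.size:
        raise ParameterError("RLE length does not match mask shape")
    return flat.reshape(shape)


def _truth_to_json(truth: SceneTruth) -> dict:
    return {
        "width": truth.width,
        "height": truth.height,
        "touching_pairs": [list(p) for p in truth.touching_pairs],
        "union_mask_rle": rle_encode(truth.union_mask),
        "seeds": [
            {
                "center": list(s.center),
                "axes": list(s.axes),
                "rotation": s.rotation,
                "bbox": [s.bbox.x, s.bbox.y, s.bbox.w, s.bbox.h],
                "mask_rle": rle_encode(s.mask_local),
            }
            for s in truth.seeds
        ],
    }


def _truth_from_json(d: dict) -> SceneTruth:
    seeds = []
    for s in d["seeds"]:
        x, y, w, h = s["bbox"]
        seeds.append(
            SeedTruth(
                center=tuple(s["center"]),
                axes=tuple(s["axes"]),
                rotation=s["rotation"],
                bbox=SeedBox(x=x, y=y, w=w, h=h),
                mask_local=rle_decode(s["mask_rle"], (h, w)),
            )
        )
    return SceneTruth(
        width=d["width"],
        height=d["height"],
        seeds=seeds,
        touching_pairs=[tuple(p) for p in d["touching_pairs"]],
        union_mask=rle_decode(d["union_mask_rle"], (d["height"], d["width"])),
    )


def config_hash(config) -> str:
    """Short stable hash of a dataclass config, recorded in manifests."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_benchmark(n_scenes: int, config: GenConfig | None = None, out: Path | str = "bench") -> Path:
    """Write a benchmark directory: PNG scenes, JSON truth sidecars, manifest."""
    config = config or GenConfig()
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _scene_seeds(config.rng_seed, n_scenes)
    entries = []
    for i, s in enumerate(seeds):
        scene, truth = generate_scene(replace(config, rng_seed=s))
        scene_name = f"scene_{i:03d}.png"
        truth_name = f"scene_{i:03d}.truth.json"
        write_scene(out / scene_name, scene)
        (out / truth_name).write_text(json.dumps(_truth_to_json(truth)))
        entries.append({"scene": scene_name, "truth": truth_name, "rng_seed": s})
    manifest = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "n_scenes": n_scenes,
        "scenes": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_benchmark(path: Path | str) -> list[tuple[NDArray[np.uint8], SceneTruth]]:
    """Load a benchmark directory written by :func:`make_benchmark`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    out = []
    for entry in manifest["scenes"]:
        scene = read_scene(path / entry["scene"])
        truth = _truth_from_json(json.loads((path / entry["truth"]).read_text()))
        out.append((scene, truth))
    return out
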