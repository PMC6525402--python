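"""Synthetic retroillumination-like scenes with per-pixel ground truth.

Real post-cataract retroillumination photographs are not redistributable, so
this module renders labelled stand-ins: a bright pupil disc carrying patches
of the six opacification textures (clear capsule, honeycomb A/B, fibrotic
plate, pearl plate, Elschnig pearls), optional saturated Purkinje-reflex
spots, and repeat images for the repeatability experiment (exact 90-degree
rotations, and re-rendered "consecutive" exposures with fresh photon noise,
a small translation and a gain change).

The texture recipes are phenomenological: they reproduce the coarse visual
attributes that drive the texture features (cell size and border contrast
for honeycomb, directional streaks for fibrotic plates, blob density and
contrast for pearls) rather than the optics of the imaging system.  Every
scene records the exact class map it was rendered from; its ground-truth
severity is, by construction, the rescaled weighted-mean score of that map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .image import AnalysisMask, GrayImage, make_roi_mask
from .model import MASKED_LABEL, N_CLASSES, ClassMap
from .scoring import ClassWeights, aqua_score

DEFAULT_SIZE: tuple[int, int] = (160, 160)
#: photon-noise standard deviation added at render time
NOISE_SD = 0.01
#: textures are kept below the reflex saturation threshold
TEXTURE_CLIP = (0.01, 0.96)


def child_seed(master_seed: int, *indices: int) -> int:
    """Deterministic per-item seed derived from a master seed.

    Mixing rule: SeedSequence entropy ``[master_seed, *indices]``; the first
    generated state word, reduced below 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SyntheticScene:
    """A rendered image plus the class map it was rendered from."""

    image: GrayImage
    truth_map: ClassMap
    truth_severity: float
    seed: int
    params: dict


# ---------------------------------------------------------------------------
# texture recipes
# ---------------------------------------------------------------------------

def _gradient(shape, rng, amplitude: float) -> np.ndarray:
    h, w = shape
    gy, gx = rng.uniform(-1, 1, size=2)
    rows = np.linspace(-0.5, 0.5, h)[:, None]
    cols = np.linspace(-0.5, 0.5, w)[None, :]
    return amplitude * (gy * rows + gx * cols)

def _cells(shape, rng, spacing: float, thickness: float) -> np.ndarray:
    """Borderness field of a jittered-grid cell tessellation in [0, 1]."""
    h, w = shape
    ys = np.arange(spacing / 2, h + spacing, spacing)
    xs = np.arange(spacing / 2, w + spacing, spacing)
    pts = np.array([(y, x) for y in ys for x in xs], dtype=np.float64)
    pts += rng.uniform(-0.35 * spacing, 0.35 * spacing, size=pts.shape)
    tree = cKDTree(pts)
    grid = np.stack(
        np.meshgrid(np.arange(h), np.arange(w), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    d, _ = tree.query(grid, k=2)
    margin = (d[:, 1] - d[:, 0]).reshape(h, w)  # ~0 on cell borders
    return np.exp(-((margin / thickness) ** 2))

def _blobs(shape, rng, density: float, sigma: float) -> np.ndarray:
    """Normalized field of overlapping round blobs (unit peak scale)."""
    impulses = (rng.random(shape) < density) * rng.uniform(0.5, 1.0, shape)
    f = gaussian_filter(impulses, sigma)
    peak = f.max()
    return f / peak if peak > 0 else f

def _streaks(shape, rng, sigma_along: float, sigma_across: float) -> np.ndarray:
    """Anisotropic smooth noise with a random streak direction, unit sd."""
    horizontal = rng.random() < 0.5
    sig = (sigma_across, sigma_along) if horizontal else (sigma_along, sigma_across)
    f = gaussian_filter(rng.standard_normal(shape), sig)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_texture(
    class_id: int,
    size: tuple[int, int] = DEFAULT_SIZE,
    seed: int = 0,
    noise_seed: int | None = None,
    noise_sd: float = NOISE_SD,
) -> np.ndarray:
    """Full-frame texture patch for one class, deterministic given seeds.

    ``seed`` drives the texture structure; ``noise_seed`` (derived from
    ``seed`` when omitted) drives the additive photon noise, so repeat
    exposures of the same structure can be rendered.
    """
    if not 0 <= class_id < N_CLASSES:
        raise ValueError(f"class_id must be in [0, {N_CLASSES})")
    if min(size) < 32:
        raise ValueError("texture patches must be at least 32x32")
    rng = np.random.default_rng(seed)
    h, w = size
    if class_id == 0:  # clear capsule: smooth bright field
        img = 0.72 + _gradient(size, rng, 0.02)
        img += 0.015 * gaussian_filter(rng.standard_normal(size), 8.0)
    elif class_id == 1:  # honeycomb A: large faint cells
        img = 0.70 + _gradient(size, rng, 0.02)
        img -= 0.12 * _cells(size, rng, spacing=15.0, thickness=1.3)
    elif class_id == 2:  # honeycomb B: smaller, crisper cells
        img = 0.64 + _gradient(size, rng, 0.02)
        img -= 0.26 * _cells(size, rng, spacing=8.0, thickness=1.1)
    elif class_id == 3:  # fibrotic plate: directional streaks on a smooth sheet
        img = 0.56 + _gradient(size, rng, 0.02)
        f = _streaks(size, rng, sigma_along=8.0, sigma_across=1.0)
        img += 0.05 * f
        img -= 0.16 / (1.0 + np.exp(-(f - 1.1) / 0.15))  # darken streak crests
    elif class_id == 4:  # pearl plate: mid-density overlapping small blobs
        img = 0.48 + _gradient(size, rng, 0.02)
        img += 0.18 * _blobs(size, rng, density=0.02, sigma=2.0)
    else:  # Elschnig pearls: dense high-contrast round blobs
        img = 0.30 + _gradient(size, rng, 0.02)
        img += 0.55 * _blobs(size, rng, density=0.03, sigma=2.4)
    if noise_sd > 0:
        nrng = np.random.default_rng(
            child_seed(seed, 1) if noise_seed is None else noise_seed
        )
        img = img + noise_sd * nrng.standard_normal(size)
    return np.clip(img, *TEXTURE_CLIP)


# ---------------------------------------------------------------------------
# scene structure and rendering
# ---------------------------------------------------------------------------

_WEIGHTS = np.asarray(ClassWeights().values)


def _partition_regions(shape, rng, n_regions: int = 24, sigma: float = 12.0):
    """Blob-shaped partition of the grid: argmax of smoothed noise fields."""
    fields = np.stack(
        [gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(n_regions)]
    )
    return np.argmax(fields, axis=0)

def _assign_classes(rng, region_areas: np.ndarray, target_raw: float) -> np.ndarray:
    """Class per region so the area-weighted mean weight approaches target."""
    n = len(region_areas)
    if target_raw <= 0:
        return np.zeros(n, dtype=np.int64)
    if target_raw >= _WEIGHTS[-1]:
        return np.full(n, N_CLASSES - 1, dtype=np.int64)
    frac = region_areas / region_areas.sum()
    u = np.clip(target_raw + rng.normal(0.0, 1.2, size=n), 0.0, _WEIGHTS[-1])
    classes = np.abs(u[:, None] - _WEIGHTS[None, :]).argmin(axis=1)
    # greedy repair: best single-region change until close to the target
    for _ in range(300):
        realized = float(frac @ _WEIGHTS[classes])
        err = realized - target_raw
        if abs(err) <= 0.08:
            break
        deltas = (_WEIGHTS[None, :] - _WEIGHTS[classes][:, None]) * frac[:, None]
        cand_err = np.abs(err + deltas)
        r, c = np.unravel_index(np.argmin(cand_err), cand_err.shape)
        if cand_err[r, c] >= abs(err) - 1e-12:
            break
        classes[r] = c
    return classes


def _scene_structure(severity, size, reflexes, seed, roi_diameter):
    h, w = size
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    roi = make_roi_mask(size, center, roi_diameter)
    rng = np.random.default_rng(child_seed(seed, 0))
    regions = _partition_regions(size, rng)
    areas = np.bincount(regions[roi.inside], minlength=regions.max() + 1).astype(float)
    keep = areas > 0
    target_raw = severity / 25.0
    classes = np.zeros(len(areas), dtype=np.int64)
    classes[keep] = _assign_classes(rng, areas[keep], target_raw)
    label_img = classes[regions]
    tex_seeds = [child_seed(seed, 10 + c) for c in range(N_CLASSES)]
    reflex_spots = []
    radius_lim = roi_diameter / 2.0 - 8.0
    for _ in range(int(reflexes)):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, max(radius_lim, 1.0))
        reflex_spots.append(
            (
                center[0] + rad * np.sin(ang),
                center[1] + rad * np.cos(ang),
                rng.uniform(3.0, 6.0),
            )
        )
    return {
        "roi": roi,
        "label_img": label_img,
        "tex_seeds": tex_seeds,
        "reflex_spots": reflex_spots,
        "classes_present": np.unique(label_img),
    }


def _render(structure, size, noise_seed, shift=(0, 0), gain=1.0) -> np.ndarray:
    h, w = size
    pad = 2
    big = (h + 2 * pad, w + 2 * pad)
    nrng = np.random.default_rng(noise_seed)
    canvas = np.zeros(big)
    # labels on the enlarged canvas: nearest-edge extension of the region map
    lab_big = np.pad(structure["label_img"], pad, mode="edge")
    for c in structure["classes_present"]:
        patch = generate_texture(
            int(c), big, structure["tex_seeds"][int(c)], noise_sd=0.0
        )
        canvas[lab_big == c] = patch[lab_big == c]
    dr, dc = shift
    view = canvas[pad + dr : pad + dr + h, pad + dc : pad + dc + w]
    img = view * gain + NOISE_SD * nrng.standard_normal(size)
    img = np.clip(img, *TEXTURE_CLIP)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for cr, cc, rad in structure["reflex_spots"]:
        disc = (rows - cr) ** 2 + (cols - cc) ** 2 <= rad**2
        img[disc] = 1.0
    return img


def generate_scene(
    severity: float,
    size: tuple[int, int] = DEFAULT_SIZE,
    reflexes: int = 0,
    seed: int = 0,
    roi_diameter: float | None = None,
) -> SyntheticScene:
    """Render one labelled scene with the requested global severity (0-100).

    The ROI is partitioned into blob-shaped regions and classes are assigned
    so that the rescaled weighted-mean score of the truth map falls within
    +/-5 of the request (exactly 0 or 100 at the endpoints).  The recorded
    ``truth_severity`` is always the exact score of the realized truth map.
    """
    if not 0.0 <= severity <= 100.0:
        raise ValueError("severity must be in [0, 100]")
    roi_diameter = roi_diameter or 0.85 * min(size)
    structure = _scene_structure(severity, size, reflexes, seed, roi_diameter)
    img = _render(structure, size, noise_seed=child_seed(seed, 1))
    roi: AnalysisMask = structure["roi"]
    labels = np.where(roi.inside, structure["label_img"], MASKED_LABEL)
    truth = ClassMap(labels.astype(np.int16), roi)
    truth_severity = aqua_score(truth).scaled
    return SyntheticScene(
        image=GrayImage(img),
        truth_map=truth,
        truth_severity=truth_severity,
        seed=int(seed),
        params={
            "severity": float(severity),
            "size": tuple(size),
            "reflexes": int(reflexes),
            "roi_diameter": float(roi_diameter),
        },
    )


def generate_repeat_pair(
    scene: SyntheticScene, mode: str, seed: int = 0
) -> GrayImage:
    """Second exposure of a scene for the repeatability experiment.

    ``rotated``: exact 90-degree rotation of the image (square scenes; the
    circular ROI is rotation symmetric).  ``consecutive``: re-render of the
    identical truth map with a fresh photon-noise draw, a translation of up
    to 2 px, and a +/-5% illumination gain change.
    """
    if mode == "rotated":
        return GrayImage(np.rot90(scene.image.pixels).copy(),
                         mm_per_pixel=scene.image.mm_per_pixel)
    if mode == "consecutive":
        p = scene.params
        structure = _scene_structure(
            p["severity"], p["size"], p["reflexes"], scene.seed, p["roi_diameter"]
        )
        rng = np.random.default_rng(child_seed(scene.seed, 2, seed))
        shift = tuple(rng.integers(-2, 3, size=2))
        gain = 1.0 + rng.uniform(-0.05, 0.05)
        img = _render(
            structure,
            p["size"],
            noise_seed=child_seed(scene.seed, 3, seed),
            shift=shift,
            gain=gain,
        )
        return GrayImage(img, mm_per_pixel=scene.image.mm_per_pixel)
    raise ValueError(f"unknown repeat mode {mode!r}")


def generate_dataset(
    n: int,
    severity_spread: str = "even",
    seed: int = 0,
    size: tuple[int, int] = DEFAULT_SIZE,
    reflexes: int = 0,
    roi_diameter: float | None = None,
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """A manifest-backed dataset of scenes with evenly spread severities."""
    if n < 6:
        raise ValueError("need at least 6 scenes (one per severity bin)")
    if severity_spread != "even":
        raise ValueError("only the 'even' severity spread is implemented")
    severities = np.linspace(0.0, 100.0, n)
    scenes = []
    rows = []
    for i, sev in enumerate(severities):
        s = generate_scene(
            float(sev), size=size, reflexes=reflexes,
            seed=child_seed(seed, 100, i), roi_diameter=roi_diameter,
        )
        scenes.append(s)
        rows.append(
            {
                "id": f"scene_{i:04d}",
                "seed": s.seed,
                "requested_severity": float(sev),
                "truth_severity": s.truth_severity,
            }
        )
    return scenes, pd.DataFrame(rows)
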