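"""Per-pixel local texture features.

Four feature families are computed for a square window centered on every
pixel of the image (reflect padding at the borders, so every pixel receives
a full feature vector):

1. gray-level co-occurrence matrix (GLCM) statistics — energy, entropy,
   contrast, homogeneity and correlation of a windowed co-occurrence matrix
   accumulated over a set of displacement vectors;
2. first-order statistics of the raw window intensities — mean, standard
   deviation, skewness, excess kurtosis, and histogram entropy;
3. Gabor filter-bank responses — locally averaged response magnitude and
   its local standard deviation per (frequency, orientation) channel;
4. local fractal dimension by differential box counting.

Design notes that matter for correctness:

* The windowed GLCM counts a pair for every *anchor* pixel of the window and
  every displacement in both signed directions, with the partner pixel read
  from the reflect-padded image.  Together with the default 4-direction
  offset set this makes the GLCM planes exactly equivariant under 90-degree
  image rotation, which the rotated-repeat experiment relies on.
* Box counts for the fractal dimension are summed over the four
  corner-anchored cell tilings of the window; the counts are integers, so
  the plane is bit-exactly equivariant under quarter turns as well.
* Gabor kernels for orientations >= 90 degrees are exact array rotations of
  the corresponding (theta - 90 deg) kernel, closing the default bank under
  quarter turns.
* 0*log(0) is taken as 0 in every entropy; statistics of a zero-variance
  window (skewness, kurtosis, GLCM correlation) are defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy.signal import fftconvolve
from scipy.special import xlogy
from skimage.filters import gabor_kernel

from .errors import ConfigError, SchemaError
from .image import GrayImage

_LN2 = math.log(2.0)
_VAR_EPS = 1e-12  # variance below this is treated as exactly zero

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
DEFAULT_FREQUENCIES: tuple[float, ...] = (0.08, 0.16, 0.32)
DEFAULT_ORIENTATIONS: tuple[float, ...] = (
    0.0,
    math.pi / 4,
    math.pi / 2,
    3 * math.pi / 4,
)
DEFAULT_BOX_SIZES: tuple[int, ...] = (2, 3, 5, 9)


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the local texture-feature computation.

    Parameters
    ----------
    window_size : odd int >= 3
        Side of the square neighbourhood analysed around each pixel.
    glcm_levels : int >= 2
        Number of gray levels the image is quantized to for the GLCM and
        the windowed histogram entropy.
    glcm_offsets : displacement vectors (drow, dcol)
        Accumulated into one co-occurrence matrix per window, both signed
        directions of each vector.
    gabor_frequencies : cycles/pixel, each in (0, 0.5)
    gabor_orientations : radians
    fractal_box_sizes : ints >= 2, each < window_size; at least 3 for the
        log-log slope fit.
    """

    window_size: int = 17
    glcm_levels: int = 16
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    gabor_frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    gabor_orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    fractal_box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES

    def __post_init__(self) -> None:
        w = self.window_size
        if w < 3 or w % 2 == 0:
            raise ConfigError("window_size must be an odd integer >= 3")
        if self.glcm_levels < 2:
            raise ConfigError("glcm_levels must be >= 2")
        if not self.glcm_offsets:
            raise ConfigError("at least one GLCM offset is required")
        for d in self.glcm_offsets:
            if len(d) != 2 or d == (0, 0):
                raise ConfigError(f"invalid GLCM offset {d!r}")
        for f in self.gabor_frequencies:
            if not 0 < f < 0.5:
                raise ConfigError("gabor frequencies must lie in (0, 0.5)")
        if len(self.fractal_box_sizes) < 3:
            raise ConfigError("need at least 3 fractal box sizes for the fit")
        for s in self.fractal_box_sizes:
            if s < 2 or s >= w:
                raise ConfigError("fractal box sizes must satisfy 2 <= s < window")
        # normalize to tuples so the config hashes/serializes consistently
        object.__setattr__(self, "glcm_offsets", tuple(map(tuple, self.glcm_offsets)))
        object.__setattr__(self, "gabor_frequencies", tuple(self.gabor_frequencies))
        object.__setattr__(self, "gabor_orientations", tuple(self.gabor_orientations))
        object.__setattr__(self, "fractal_box_sizes", tuple(self.fractal_box_sizes))

    # -- naming ---------------------------------------------------------
    @property
    def glcm_names(self) -> tuple[str, ...]:
        return tuple(
            f"glcm_{s}" for s in ("energy", "entropy", "contrast", "homogeneity",
                                  "correlation")
        )

    @property
    def first_order_names(self) -> tuple[str, ...]:
        return ("fo_mean", "fo_sd", "fo_skewness", "fo_kurtosis", "fo_hist_entropy")

    @property
    def gabor_names(self) -> tuple[str, ...]:
        names = []
        for f in self.gabor_frequencies:
            for t in self.gabor_orientations:
                deg = round(math.degrees(t)) % 360
                names.append(f"gabor_f{f:g}_t{deg}_mean")
                names.append(f"gabor_f{f:g}_t{deg}_sd")
        return tuple(names)

    @property
    def fractal_names(self) -> tuple[str, ...]:
        return ("fractal_dimension",)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return (
            self.glcm_names
            + self.first_order_names
            + self.gabor_names
            + self.fractal_names
        )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "window_size": self.window_size,
            "glcm_levels": self.glcm_levels,
            "glcm_offsets": [list(d) for d in self.glcm_offsets],
            "gabor_frequencies": list(self.gabor_frequencies),
            "gabor_orientations": list(self.gabor_orientations),
            "fractal_box_sizes": list(self.fractal_box_sizes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "glcm_offsets" in kwargs:
            kwargs["glcm_offsets"] = tuple(tuple(x) for x in kwargs["glcm_offsets"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# replace() convenience re-export for configs
def with_options(cfg: FeatureConfig, **kwargs) -> FeatureConfig:
    return replace(cfg, **kwargs)


@dataclass
class FeatureStack:
    """A named stack of per-pixel feature planes over one image grid."""

    planes: np.ndarray  # (n_features, H, W)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        self.names = tuple(self.names)
        if self.planes.ndim != 3 or self.planes.shape[0] != len(self.names):
            raise ValueError("planes must be (n_features, H, W) matching names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.planes)):
            raise ValueError("feature planes contain non-finite values")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]  # type: ignore[return-value]

    def plane(self, name: str) -> np.ndarray:
        try:
            return self.planes[self.names.index(name)]
        except ValueError as exc:
            raise SchemaError(f"no feature plane named {name!r}") from exc

    def select(self, names: list[str] | tuple[str, ...]) -> "FeatureStack":
        idx = []
        for n in names:
            if n not in self.names:
                raise SchemaError(f"no feature plane named {n!r}")
            idx.append(self.names.index(n))
        return FeatureStack(self.planes[idx], tuple(names))

    def matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Feature vectors as (n_pixels, n_features); optionally mask-selected."""
        flat = self.planes.reshape(len(self.names), -1).T
        if mask is None:
            return flat
        return self.planes[:, np.asarray(mask, bool)].T

    def to_tiff(self, path: str | Path) -> None:
        """Export as a multi-page float32 TIFF (one page per feature)."""
        tifffile.imwrite(
            Path(path),
            self.planes.astype(np.float32),
            metadata={"axes": "CYX", "feature_names": list(self.names)},
        )


# ---------------------------------------------------------------------------
# windowed-sum machinery
# ---------------------------------------------------------------------------

def _box_sum(padded: np.ndarray, window: int) -> np.ndarray:
    """Sums over all window x window blocks of `padded` (anchored top-left).

    For input of shape (H + window - 1, W + window - 1) the output has shape
    (H, W); output[r, c] = padded[r:r+window, c:c+window].sum().  Uses an
    integral image; exact for integer-valued inputs.
    """
    hp, wp = padded.shape
    s = np.zeros((hp + 1, wp + 1), dtype=np.float64)
    np.cumsum(padded, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    w = window
    return s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w]


def quantize(img: GrayImage, levels: int) -> np.ndarray:
    """Map unit intensities to integer bins floor(I * levels), clamped."""
    if levels < 2:
        raise ConfigError("levels must be >= 2")
    q = np.floor(img.pixels * levels).astype(np.int64)
    np.clip(q, 0, levels - 1, out=q)
    return q


# ---------------------------------------------------------------------------
# family 1: GLCM
# ---------------------------------------------------------------------------

def glcm_window_features(qimg: np.ndarray, cfg: FeatureConfig) -> FeatureStack:
    """Windowed Haralick-style GLCM statistics.

    For every pixel, a co-occurrence matrix is accumulated over all window
    anchors and both signed directions of every configured offset (partner
    pixels come from the reflect-padded image), then normalized; energy,
    entropy (bits), contrast, homogeneity and correlation are derived.
    """
    qimg = np.asarray(qimg)
    h, w = qimg.shape
    win = cfg.window_size
    if win > min(h, w):
        raise ConfigError("window larger than image")
    levels = cfg.glcm_levels
    if qimg.min() < 0 or qimg.max() >= levels:
        raise ValueError("image is not quantized to cfg.glcm_levels")
    half = win // 2
    offsets = [(dr, dc) for d in cfg.glcm_offsets for dr, dc in (d, (-d[0], -d[1]))]
    maxoff = max(max(abs(dr), abs(dc)) for dr, dc in offsets)
    pad = half + maxoff
    q = np.pad(qimg, pad, mode="reflect")

    # anchor grid: every pixel that falls inside some window
    a0, a1 = pad - half, pad + half  # inclusive extents relative to image
    codes = []
    for dr, dc in offsets:
        anchor = q[a0 : a0 + h + 2 * half, a0 : a0 + w + 2 * half]
        partner = q[
            a0 + dr : a0 + dr + h + 2 * half, a0 + dc : a0 + dc + w + 2 * half
        ]
        codes.append(anchor * levels + partner)
    total = float(win * win * len(offsets))

    present = np.unique(np.concatenate([c.ravel() for c in codes]))
    energy = np.zeros((h, w))
    entropy = np.zeros((h, w))
    contrast = np.zeros((h, w))
    homog = np.zeros((h, w))
    si = np.zeros((h, w))
    sj = np.zeros((h, w))
    sii = np.zeros((h, w))
    sjj = np.zeros((h, w))
    sij = np.zeros((h, w))
    for code in present:
        occ = np.zeros(codes[0].shape, dtype=np.float64)
        for c in codes:
            occ += c == code
        p = _box_sum(occ, win) / total
        i, j = divmod(int(code), levels)
        energy += p * p
        entropy -= xlogy(p, p)
        d2 = float((i - j) ** 2)
        contrast += d2 * p
        homog += p / (1.0 + d2)
        si += i * p
        sj += j * p
        sii += (i * i) * p
        sjj += (j * j) * p
        sij += (i * j) * p
    entropy /= _LN2
    var_i = np.clip(sii - si * si, 0.0, None)
    var_j = np.clip(sjj - sj * sj, 0.0, None)
    denom = np.sqrt(var_i * var_j)
    cov = sij - si * sj
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > _VAR_EPS, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return FeatureStack(
        np.stack([energy, entropy, contrast, homog, corr]), cfg.glcm_names
    )


# ---------------------------------------------------------------------------
# family 2: first-order statistics
# ---------------------------------------------------------------------------

def first_order_features(img: GrayImage, cfg: FeatureConfig) -> FeatureStack:
    """Windowed mean, sd, skewness, excess kurtosis and histogram entropy.

    Moments are computed on globally mean-centered intensities (numerically
    stabler; central moments are shift-invariant).  Histogram entropy uses
    ``cfg.glcm_levels`` bins and is reported in bits.
    """
    win = cfg.window_size
    h, w = img.shape
    if win > min(h, w):
        raise ConfigError("window larger than image")
    half = win // 2
    n = float(win * win)
    mu_g = float(img.pixels.mean())
    p = np.pad(img.pixels - mu_g, half, mode="reflect")
    m1 = _box_sum(p, win) / n
    m2 = _box_sum(p * p, win) / n
    m3 = _box_sum(p**3, win) / n
    m4 = _box_sum(p**4, win) / n
    var = np.clip(m2 - m1 * m1, 0.0, None)
    sd = np.sqrt(var)
    mu3 = m3 - 3.0 * m1 * m2 + 2.0 * m1**3
    mu4 = m4 - 4.0 * m1 * m3 + 6.0 * m1 * m1 * m2 - 3.0 * m1**4
    ok = var > _VAR_EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(ok, mu3 / np.where(ok, sd**3, 1.0), 0.0)
        kurt = np.where(ok, mu4 / np.where(ok, var**2, 1.0) - 3.0, 0.0)

    q = np.pad(quantize(img, cfg.glcm_levels), half, mode="reflect")
    hist_ent = np.zeros((h, w))
    for level in range(cfg.glcm_levels):
        pk = _box_sum((q == level).astype(np.float64), win) / n
        hist_ent -= xlogy(pk, pk)
    hist_ent /= _LN2

    return FeatureStack(
        np.stack([m1 + mu_g, sd, skew, kurt, hist_ent]), cfg.first_order_names
    )


# ---------------------------------------------------------------------------
# family 3: Gabor filter bank
# ---------------------------------------------------------------------------

def _quarter_turn(kernel: np.ndarray) -> np.ndarray:
    return np.rot90(kernel)


def gabor_bank(cfg: FeatureConfig) -> dict[tuple[float, float], np.ndarray]:
    """DC-free complex Gabor kernels, one per (frequency, orientation).

    Orientations theta >= pi/2 are realized as exact array rotations of the
    theta - pi/2 kernel so that banks containing both members of a quarter-
    turn pair are exactly closed under 90-degree rotation.
    """
    kernels: dict[tuple[float, float], np.ndarray] = {}
    base_cache: dict[tuple[float, float], np.ndarray] = {}
    for f in cfg.gabor_frequencies:
        for theta in cfg.gabor_orientations:
            t = theta % math.pi
            quarter = t >= math.pi / 2 - 1e-12
            tb = t - math.pi / 2 if quarter else t
            key = (f, round(tb, 12))
            if key not in base_cache:
                k = np.asarray(gabor_kernel(f, theta=tb))
                base_cache[key] = k - k.mean()  # zero response to constants
            k = base_cache[key]
            kernels[(f, theta)] = _quarter_turn(k) if quarter else k
    return kernels


def gabor_features(img: GrayImage, cfg: FeatureConfig) -> FeatureStack:
    """Locally averaged Gabor response magnitude and its local sd.

    The image is convolved (FFT) with each DC-corrected complex kernel; the
    response magnitude is then summarized by its window mean and window
    standard deviation.
    """
    win = cfg.window_size
    h, w = img.shape
    half = win // 2
    n = float(win * win)
    planes = []
    for (f, theta), k in gabor_bank(cfg).items():
        kh, kw = k.shape
        ph, pw = kh // 2, kw // 2
        padded = np.pad(img.pixels, ((ph, kh - 1 - ph), (pw, kw - 1 - pw)),
                        mode="reflect")
        resp = fftconvolve(padded, k, mode="valid")
        mag = np.abs(resp)
        magp = np.pad(mag, half, mode="reflect")
        g1 = _box_sum(magp, win) / n
        g2 = _box_sum(magp * magp, win) / n
        gsd = np.sqrt(np.clip(g2 - g1 * g1, 0.0, None))
        planes.append(g1)
        planes.append(gsd)
    return FeatureStack(np.stack(planes), cfg.gabor_names)


# ---------------------------------------------------------------------------
# family 4: fractal dimension
# ---------------------------------------------------------------------------

def _corner_box_counts(pixels: np.ndarray, win: int, s: int) -> np.ndarray:
    """Differential box counts N_s per window for the top-left tiling.

    The window is tiled by s x s cells anchored at its top-left corner; the
    trailing cells are clipped.  The intensity column over each cell is
    covered by boxes of height s/win (in unit-intensity terms), so a cell
    contributes floor(max * win / s) - floor(min * win / s) + 1 boxes.
    """
    from scipy.ndimage import maximum_filter, minimum_filter

    h, w = pixels.shape
    half = win // 2
    g = np.floor(np.pad(pixels, half, mode="reflect") * (win / s))
    k = -(-win // s)  # ceil
    rem = win - s * (k - 1)
    sizes = sorted({(a, b) for a in (s, rem) for b in (s, rem)})
    # centered filters; reading at index anchor + size//2 yields the
    # reduction over the block [anchor, anchor + size)
    contrib = {}
    for a, b in sizes:
        gmax = maximum_filter(g, size=(a, b))
        gmin = minimum_filter(g, size=(a, b))
        contrib[(a, b)] = gmax - gmin + 1.0
    counts = np.zeros((h, w), dtype=np.float64)
    for k1 in range(k):
        a = s if k1 < k - 1 else rem
        r0 = s * k1
        for k2 in range(k):
            b = s if k2 < k - 1 else rem
            c0 = s * k2
            counts += contrib[(a, b)][
                r0 + a // 2 : r0 + a // 2 + h, c0 + b // 2 : c0 + b // 2 + w
            ]
    return counts


def fractal_features(img: GrayImage, cfg: FeatureConfig) -> FeatureStack:
    """Local fractal dimension by differential box counting.

    Box counts are summed over the four corner-anchored tilings of the
    window (making the plane exactly symmetric under quarter turns), and
    the dimension is the least-squares slope of log N(s) against
    log(1/s), clamped to the surface range [2, 3].
    """
    win = cfg.window_size
    h, w = img.shape
    if win > min(h, w):
        raise ConfigError("window larger than image")
    sizes = cfg.fractal_box_sizes
    x = np.array([math.log(1.0 / s) for s in sizes])
    coeff = (x - x.mean()) / np.sum((x - x.mean()) ** 2)
    dim = np.zeros((h, w))
    for s, c in zip(sizes, coeff):
        n_s = np.zeros((h, w))
        for flip_r in (False, True):
            for flip_c in (False, True):
                p = img.pixels
                if flip_r:
                    p = p[::-1, :]
                if flip_c:
                    p = p[:, ::-1]
                counts = _corner_box_counts(p, win, s)
                if flip_r:
                    counts = counts[::-1, :]
                if flip_c:
                    counts = counts[:, ::-1]
                n_s += counts
        dim += c * np.log(n_s)
    return FeatureStack(np.clip(dim, 2.0, 3.0)[None, :, :], cfg.fractal_names)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_feature_stack(img: GrayImage, cfg: FeatureConfig | None = None) -> FeatureStack:
    """All four feature families, concatenated in the documented order
    (GLCM, first-order, Gabor, fractal).  The default configuration yields
    5 + 5 + 2*(3*4) + 1 = 35 planes."""
    cfg = cfg or FeatureConfig()
    q = quantize(img, cfg.glcm_levels)
    parts = [
        glcm_window_features(q, cfg),
        first_order_features(img, cfg),
        gabor_features(img, cfg),
        fractal_features(img, cfg),
    ]
    return FeatureStack(
        np.concatenate([p.planes for p in parts], axis=0),
        tuple(n for p in parts for n in p.names),
    )


class TextureFeatureExtractor:
    """Stateless transformer view of :func:`extract_feature_stack`.

    Follows the scikit-learn transformer protocol loosely: ``fit`` is a
    no-op, ``transform`` maps a GrayImage (or a list of them) to feature
    stacks.  Exposed so the feature step can sit in pipeline-style code.
    """

    def __init__(self, config: FeatureConfig | None = None):
        self.config = config or FeatureConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "TextureFeatureExtractor":
        for k, v in params.items():
            if k != "config":
                raise ValueError(f"unknown parameter {k!r}")
            self.config = v
        return self

    def fit(self, X=None, y=None) -> "TextureFeatureExtractor":
        return self

    def transform(self, X):
        if isinstance(X, GrayImage):
            return extract_feature_stack(X, self.config)
        return [extract_feature_stack(img, self.config) for img in X]
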