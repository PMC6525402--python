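"""Naive per-window reference implementations used as independent oracles.

Each function recomputes a feature plane (or score) by explicit enumeration
over windows/pixels, sharing only the published definitions with the
production code, not its vectorized computation path.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import convolve as nd_convolve

from pcotex.features import FeatureConfig, gabor_bank

_VAR_EPS = 1e-12


def _signed_offsets(cfg: FeatureConfig):
    return [(dr, dc) for d in cfg.glcm_offsets for dr, dc in (d, (-d[0], -d[1]))]


def glcm_oracle(qimg: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """(5, H, W) planes: energy, entropy, contrast, homogeneity, correlation."""
    levels = cfg.glcm_levels
    w = cfg.window_size
    half = w // 2
    offsets = _signed_offsets(cfg)
    maxoff = max(max(abs(dr), abs(dc)) for dr, dc in offsets)
    pad = half + maxoff
    q = np.pad(qimg, pad, mode="reflect")
    h, wd = qimg.shape
    out = np.zeros((5, h, wd))
    ii, jj = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    for r in range(h):
        for c in range(wd):
            m = np.zeros((levels, levels))
            anchors = q[pad + r - half : pad + r + half + 1,
                        pad + c - half : pad + c + half + 1]
            for dr, dc in offsets:
                partners = q[pad + r - half + dr : pad + r + half + 1 + dr,
                             pad + c - half + dc : pad + c + half + 1 + dc]
                np.add.at(m, (anchors.ravel(), partners.ravel()), 1.0)
            p = m / m.sum()
            nz = p[p > 0]
            energy = float((p * p).sum())
            entropy = float(-(nz * np.log2(nz)).sum())
            contrast = float(((ii - jj) ** 2 * p).sum())
            homog = float((p / (1.0 + (ii - jj) ** 2)).sum())
            mi = float((ii * p).sum())
            mj = float((jj * p).sum())
            vi = float((ii**2 * p).sum()) - mi * mi
            vj = float((jj**2 * p).sum()) - mj * mj
            denom = math.sqrt(max(vi, 0.0) * max(vj, 0.0))
            cov = float((ii * jj * p).sum()) - mi * mj
            corr = cov / denom if denom > _VAR_EPS else 0.0
            out[:, r, c] = (energy, entropy, contrast, homog, corr)
    return out


def first_order_oracle(pixels: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """(5, H, W): mean, sd, skewness, excess kurtosis, histogram entropy."""
    w = cfg.window_size
    half = w // 2
    levels = cfg.glcm_levels
    p = np.pad(pixels, half, mode="reflect")
    q = np.clip(np.floor(p * levels), 0, levels - 1).astype(int)
    h, wd = pixels.shape
    out = np.zeros((5, h, wd))
    for r in range(h):
        for c in range(wd):
            v = p[r : r + w, c : c + w].ravel()
            m = v.mean()
            var = v.var()
            sd = math.sqrt(var)
            if var > _VAR_EPS:
                skew = float(((v - m) ** 3).mean() / sd**3)
                kurt = float(((v - m) ** 4).mean() / var**2 - 3.0)
            else:
                skew = kurt = 0.0
            counts = np.bincount(q[r : r + w, c : c + w].ravel(), minlength=levels)
            pk = counts[counts > 0] / counts.sum()
            ent = float(-(pk * np.log2(pk)).sum())
            out[:, r, c] = (m, sd, skew, kurt, ent)
    return out


def gabor_oracle(pixels: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """(2 * n_channels, H, W): window mean and sd of response magnitude.

    Uses direct spatial convolution (true convolution, mirrored borders) and
    explicit per-window statistics.
    """
    w = cfg.window_size
    half = w // 2
    planes = []
    for (_, _), k in gabor_bank(cfg).items():
        resp = (
            nd_convolve(pixels, k.real, mode="mirror")
            + 1j * nd_convolve(pixels, k.imag, mode="mirror")
        )
        mag = np.abs(resp)
        mp = np.pad(mag, half, mode="reflect")
        h, wd = pixels.shape
        gm = np.zeros((h, wd))
        gs = np.zeros((h, wd))
        for r in range(h):
            for c in range(wd):
                v = mp[r : r + w, c : c + w]
                gm[r, c] = v.mean()
                gs[r, c] = v.std()
        planes.append(gm)
        planes.append(gs)
    return np.stack(planes)


def fractal_oracle(pixels: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """(H, W) local box-counting dimension by explicit cell enumeration."""
    w = cfg.window_size
    half = w // 2
    p = np.pad(pixels, half, mode="reflect")
    sizes = cfg.fractal_box_sizes
    x = np.array([math.log(1.0 / s) for s in sizes])
    h, wd = pixels.shape
    out = np.zeros((h, wd))
    for r in range(h):
        for c in range(wd):
            win = p[r : r + w, c : c + w]
            ys = []
            for s in sizes:
                k = -(-w // s)
                rem = w - s * (k - 1)
                n = 0.0
                for fr in (False, True):
                    for fc in (False, True):
                        wv = win[::-1] if fr else win
                        wv = wv[:, ::-1] if fc else wv
                        g = np.floor(wv * (w / s))
                        for k1 in range(k):
                            a = s if k1 < k - 1 else rem
                            for k2 in range(k):
                                b = s if k2 < k - 1 else rem
                                cell = g[s * k1 : s * k1 + a, s * k2 : s * k2 + b]
                                n += cell.max() - cell.min() + 1.0
                ys.append(math.log(n))
            slope = np.polyfit(x, ys, 1)[0]
            out[r, c] = min(max(slope, 2.0), 3.0)
    return out


def roi_oracle(shape, center, diameter) -> np.ndarray:
    """Strict open-disc membership by per-pixel enumeration."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    for r in range(h):
        for c in range(w):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 < (diameter / 2.0) ** 2:
                out[r, c] = True
    return out


def score_oracle(labels: np.ndarray, mask: np.ndarray, weights) -> float:
    """Per-pixel accumulation of the weighted-mean score."""
    num = 0.0
    den = 0
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            if mask[r, c]:
                num += weights[labels[r, c]]
                den += 1
    if den == 0:
        raise ZeroDivisionError
    return num / den
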