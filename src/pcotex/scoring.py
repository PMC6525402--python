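"""Global opacification score and color-coded qualitative output.

The global score is the class-weighted mean over scored pixels,

    score = sum_n p_n * w_n / sum_n p_n,

where ``p_n`` is the number of pixels assigned class ``n`` and ``w_n`` the
class weight (clear 0, honeycomb A 0.8, honeycomb B 1, plate 2, pearl plate
3, Elschnig pearls 4).  Masked pixels contribute to neither sum.  For
reporting, the raw score is rescaled linearly to 0-100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import EmptyMaskError
from .model import CLASS_NAMES, MASKED_LABEL, N_CLASSES, ClassMap

DEFAULT_WEIGHTS: tuple[float, ...] = (0.0, 0.8, 1.0, 2.0, 3.0, 4.0)

#: color legend of the qualitative output, indexed by class
CLASS_COLORS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),        # clear - black
    (0, 255, 255),    # honeycomb A - cyan
    (0, 0, 255),      # honeycomb B - blue
    (0, 255, 0),      # plate - green
    (255, 255, 0),    # pearl plate - yellow
    (255, 0, 0),      # Elschnig pearls - red
)
MASKED_COLOR: tuple[int, int, int] = (128, 128, 128)


@dataclass(frozen=True)
class ClassWeights:
    """Severity weights per class, in fixed class order."""

    values: tuple[float, ...] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.values)
        if len(v) != N_CLASSES:
            raise ValueError(f"exactly {N_CLASSES} weights required")
        if any(x < 0 for x in v):
            raise ValueError("weights must be non-negative")
        if any(b < a for a, b in zip(v, v[1:])):
            raise ValueError("weights must be non-decreasing in class order")
        object.__setattr__(self, "values", v)

    @property
    def max_weight(self) -> float:
        return self.values[-1]


@dataclass
class PCOScore:
    """Result of scoring one class map."""

    raw: float
    scaled: float
    class_pixel_counts: tuple[int, ...]
    n_valid: int

    def to_dict(self) -> dict:
        d = {"raw": self.raw, "scaled": self.scaled, "n_valid": self.n_valid}
        d.update(
            {f"n_{name}": c for name, c in zip(CLASS_NAMES, self.class_pixel_counts)}
        )
        return d


def aqua_score(classmap: ClassMap, weights: ClassWeights | None = None) -> PCOScore:
    """Weighted-mean global score of a class map (masked pixels excluded)."""
    weights = weights or ClassWeights()
    counts = classmap.class_counts()
    n_valid = int(counts.sum())
    if n_valid == 0:
        raise EmptyMaskError("class map has no scored pixels")
    raw = float(np.dot(counts, weights.values) / n_valid)
    return PCOScore(
        raw=raw,
        scaled=rescale_score(raw, weights),
        class_pixel_counts=tuple(int(c) for c in counts),
        n_valid=n_valid,
    )


def rescale_score(raw: float, weights: ClassWeights | None = None) -> float:
    """Linear conversion of a raw score onto the 0-100 reporting scale."""
    weights = weights or ClassWeights()
    if not 0.0 <= raw <= weights.max_weight:
        raise ValueError(f"raw score {raw} outside [0, {weights.max_weight}]")
    return raw * (100.0 / weights.max_weight)


def render_classmap(classmap: ClassMap) -> np.ndarray:
    """RGB rendering of a class map under the fixed color legend.

    Scored pixels get their class color; masked pixels are mid-gray.
    Returns a (H, W, 3) uint8 array.
    """
    lut = np.array(CLASS_COLORS + (MASKED_COLOR,), dtype=np.uint8)
    idx = classmap.labels.copy()
    idx[idx == MASKED_LABEL] = N_CLASSES
    return lut[idx]


def save_classmap_png(classmap: ClassMap, path: str | Path) -> None:
    iio.imwrite(Path(path), render_classmap(classmap))


def classmap_labels_from_rgb(rgb: np.ndarray) -> np.ndarray:
    """Invert :func:`render_classmap` (the legend colors are unique)."""
    rgb = np.asarray(rgb)
    labels = np.full(rgb.shape[:2], MASKED_LABEL, dtype=np.int16)
    for c, color in enumerate(CLASS_COLORS):
        labels[(rgb == np.array(color, dtype=rgb.dtype)).all(axis=-1)] = c
    return labels


def scores_to_csv(rows: list[tuple[str, PCOScore]], path: str | Path) -> None:
    """Write (image id, raw, scaled, class counts, n_valid) rows as CSV."""
    import pandas as pd

    recs = [{"id": rid, **score.to_dict()} for rid, score in rows]
    pd.DataFrame(recs).to_csv(Path(path), index=False)


def score_to_json(score: PCOScore, path: str | Path) -> None:
    Path(path).write_text(json.dumps(score.to_dict(), indent=1))
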