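"""Validity and repeatability statistics for paired grading scores.

Validity is quantified by the Pearson correlation between automated scores
and a reference severity.  Repeatability of paired measurements follows the
Bland-Altman convention: for differences ``d = first - second``,

* mean difference            ``mean(d)``
* 95% CI halfwidth           ``z * sd(d) / sqrt(n)``   (z = 1.96)
* coefficient of repeatability  ``CR = z * sd(d)``

with the sample standard deviation (n-1 denominator).  Note the exact
identity ``CR / halfwidth = sqrt(n)``.  A t-quantile variant is available
for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as _sps


@dataclass
class PairedScores:
    """Two repeat measurements per subject, on the 0-100 reporting scale."""

    first: np.ndarray
    second: np.ndarray
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=np.float64)
        self.second = np.asarray(self.second, dtype=np.float64)
        if self.first.ndim != 1 or self.first.shape != self.second.shape:
            raise ValueError("first and second must be equal-length 1-D arrays")
        if len(self.first) < 2:
            raise ValueError("at least 2 pairs required")
        if self.ids is not None and len(self.ids) != len(self.first):
            raise ValueError("ids length mismatch")

    def __len__(self) -> int:
        return len(self.first)


@dataclass
class AgreementReport:
    mean_difference: float
    ci_halfwidth: float
    coefficient_of_repeatability: float
    n: int
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference,
            "ci_halfwidth": self.ci_halfwidth,
            "coefficient_of_repeatability": self.coefficient_of_repeatability,
            "n": self.n,
            "level": self.level,
        }


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Requires equal lengths >= 3 and nonzero variance in both arguments.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(_sps.pearsonr(x, y).statistic)


def _quantile(level: float, n: int, use_t: bool) -> float:
    if use_t:
        return float(_sps.t.ppf(0.5 + level / 2.0, df=n - 1))
    if level == 0.95:
        return 1.96  # conventional reporting quantile
    return float(_sps.norm.ppf(0.5 + level / 2.0))


def repeatability(
    pairs: PairedScores, level: float = 0.95, use_t: bool = False
) -> AgreementReport:
    """Bland-Altman agreement of two repeat measurements.

    Parameters
    ----------
    pairs : PairedScores
    level : confidence level of the CI (and of the quantile in CR).
    use_t : use the Student-t quantile (df = n - 1) instead of the normal
        1.96; the normal form is the default used in clinical reporting.
    """
    d = pairs.first - pairs.second
    n = len(d)
    sd = float(np.std(d, ddof=1))
    z = _quantile(level, n, use_t)
    return AgreementReport(
        mean_difference=float(np.mean(d)),
        ci_halfwidth=z * sd / np.sqrt(n),
        coefficient_of_repeatability=z * sd,
        n=n,
        level=level,
    )


def bland_altman_plot(pairs: PairedScores, path: str | Path,
                      level: float = 0.95) -> None:
    """Difference-vs-mean plot with mean difference and CR limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = repeatability(pairs, level=level)
    mean = (pairs.first + pairs.second) / 2.0
    diff = pairs.first - pairs.second
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18)
    ax.axhline(rep.mean_difference, color="k", lw=1)
    for lim in (
        rep.mean_difference - rep.coefficient_of_repeatability,
        rep.mean_difference + rep.coefficient_of_repeatability,
    ):
        ax.axhline(lim, color="r", ls="--", lw=1)
    ax.set_xlabel("mean of pair (0-100)")
    ax.set_ylabel("difference (0-100)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
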