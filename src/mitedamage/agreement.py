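"""Method-comparison statistics: Bland–Altman, repeatability, CCC, Spearman.

Two damage-quantification methods are compared on paired per-rosette
measurements.  The Bland–Altman analysis summarises the paired differences
d_i (absolute, or as a percentage of the pairwise mean) by their mean
(bias) and the 95% limits of agreement bias ± 1.96·sd.  The coefficient of
repeatability CR = 1.96·sd(d) is the value under which the absolute
difference of two repeated measurements falls with 95% probability; its
confidence interval follows from the chi-square distribution of the
variance.  Lin's concordance correlation coefficient

    ccc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)     (population 1/n moments)

penalises location and scale shifts on top of imperfect correlation, so a
method with a constant bias scores lower on CCC than on Pearson/Spearman
even when the two track each other perfectly.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PairedSample",
    "AgreementReport",
    "QuotientResult",
    "bland_altman",
    "repeatability",
    "lin_ccc",
    "spearman",
    "damage_quotient",
    "agreement_report",
    "bland_altman_plot",
    "concordance_plot",
]

Z95 = 1.96


@dataclasses.dataclass
class PairedSample:
    """Per-rosette measurements by two methods, aligned by id.

    Pairs where either side is missing (NaN/None) are excluded at
    construction and counted in ``n_excluded``.
    """

    ids: list
    x: np.ndarray
    y: np.ndarray
    labels: Optional[Dict[str, str]] = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(
            [np.nan if v is None else float(v) for v in self.x], dtype=np.float64
        )
        self.y = np.asarray(
            [np.nan if v is None else float(v) for v in self.y], dtype=np.float64
        )
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise ValueError("ids, x and y must have equal length")
        complete = ~(np.isnan(self.x) | np.isnan(self.y))
        self.n_excluded += int((~complete).sum())
        self.ids = [i for i, ok in zip(self.ids, complete) if ok]
        self.x = self.x[complete]
        self.y = self.y[complete]

    def __len__(self) -> int:
        return len(self.ids)


@dataclasses.dataclass
class AgreementReport:
    """Agreement summary for one method-pair comparison."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int
    mode: str
    cr: Optional[float] = None
    cr_ci: Optional[Tuple[float, float]] = None
    ccc: Optional[float] = None
    ccc_ci: Optional[Tuple[float, float]] = None
    rho: Optional[float] = None
    rho_p: Optional[float] = None
    pearson: Optional[float] = None
    n_excluded: int = 0


def _differences(sample: PairedSample, mode: str) -> np.ndarray:
    if mode == "absolute":
        return sample.x - sample.y
    if mode == "percent":
        means = (sample.x + sample.y) / 2.0
        if np.any(means == 0):
            raise ValueError("percent mode undefined where the pair mean is 0")
        return (sample.x - sample.y) / means
    raise ValueError(f"mode must be 'absolute' or 'percent', got {mode!r}")


def bland_altman(sample: PairedSample, mode: str = "absolute") -> AgreementReport:
    """Bias and 95% limits of agreement of the paired differences."""
    if len(sample) < 2:
        raise ValueError(f"need >= 2 complete pairs, got {len(sample)}")
    d = _differences(sample, mode)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        bias=bias, sd_diff=sd,
        loa_low=bias - Z95 * sd, loa_high=bias + Z95 * sd,
        n_pairs=len(sample), mode=mode, n_excluded=sample.n_excluded,
    )


def repeatability(sample: PairedSample, mode: str = "absolute") -> Tuple[float, Tuple[float, float]]:
    """Coefficient of repeatability 1.96·sd(d) with a chi-square 95% CI."""
    if len(sample) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(sample)}")
    d = _differences(sample, mode)
    n = len(d)
    sd = float(d.std(ddof=1))
    cr = Z95 * sd
    dof = n - 1
    lo = Z95 * sd * np.sqrt(dof / stats.chi2.ppf(0.975, dof))
    hi = Z95 * sd * np.sqrt(dof / stats.chi2.ppf(0.025, dof))
    return cr, (float(lo), float(hi))


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> Tuple[float, Tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z 95% CI.

    Uses population (1/n) moments, matching Lin's original estimator; the
    CI standard error follows Lin's large-sample formula on the z scale.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need >= 3 aligned pairs")
    sx2 = float(x.var())  # ddof=0
    sy2 = float(y.var())
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance in x or y")
    sxy = float(((x - x.mean()) * (y - y.mean())).mean())
    dmean = float(x.mean() - y.mean())
    ccc = 2.0 * sxy / (sx2 + sy2 + dmean ** 2)
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-12 or r == 0:
        return float(ccc), (float(ccc), float(ccc))
    u2 = dmean ** 2 / np.sqrt(sx2 * sy2)
    one_m = 1.0 - ccc ** 2
    se_z2 = (
        (1 - r ** 2) * ccc ** 2 / (one_m * r ** 2)
        + 2 * ccc ** 3 * (1 - ccc) * u2 / (r * one_m ** 2)
        - ccc ** 4 * u2 ** 2 / (2 * r ** 2 * one_m ** 2)
    ) / (n - 2)
    se_z = np.sqrt(max(se_z2, 0.0))
    z = np.arctanh(ccc)
    lo, hi = np.tanh(z - Z95 * se_z), np.tanh(z + Z95 * se_z)
    return float(ccc), (float(lo), float(hi))


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 3 or len(y) != len(x):
        raise ValueError("need >= 3 aligned pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclasses.dataclass
class QuotientResult:
    """Ratio of group mean corrected damage, with attrition bookkeeping."""

    ratio: float
    n_a: int
    n_b: int
    dropped_a: int
    dropped_b: int


def damage_quotient(
    group_a: Sequence[Optional[float]], group_b: Sequence[Optional[float]]
) -> QuotientResult:
    """mean(a) / mean(b) over non-missing corrected areas.

    Missing (dropped) values are excluded and counted; an empty surviving
    group or a zero denominator raises with the attrition report in the
    message — those are the blank cells of a quotient table.
    """
    a = np.array([v for v in group_a if v is not None and not np.isnan(v)], dtype=np.float64)
    b = np.array([v for v in group_b if v is not None and not np.isnan(v)], dtype=np.float64)
    dropped_a = len(group_a) - len(a)
    dropped_b = len(group_b) - len(b)
    if len(a) == 0 or len(b) == 0 or b.mean() == 0:
        raise ValueError(
            "damage quotient undefined: "
            f"n_a={len(a)} (dropped {dropped_a}), n_b={len(b)} (dropped {dropped_b})"
        )
    return QuotientResult(
        ratio=float(a.mean() / b.mean()),
        n_a=len(a), n_b=len(b), dropped_a=dropped_a, dropped_b=dropped_b,
    )


def agreement_report(sample: PairedSample, mode: str = "absolute") -> AgreementReport:
    """Full agreement panel: B&A fields plus CR, CCC, Spearman and Pearson."""
    report = bland_altman(sample, mode)
    if len(sample) >= 3:
        try:
            report.cr, report.cr_ci = repeatability(sample, mode)
        except ValueError:
            pass
        try:
            report.ccc, report.ccc_ci = lin_ccc(sample.x, sample.y)
            sx = sample.x.std()
            sy = sample.y.std()
            sxy = float(((sample.x - sample.x.mean()) * (sample.y - sample.y.mean())).mean())
            report.pearson = sxy / (sx * sy)
        except ValueError:
            pass
        try:
            report.rho, report.rho_p = spearman(sample.x, sample.y)
        except ValueError:
            pass
    return report


def bland_altman_plot(sample: PairedSample, path: str, mode: str = "absolute",
                      title: str = "") -> AgreementReport:
    """Write a Bland–Altman plot (mean-difference line, ±1.96 sd lines)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = bland_altman(sample, mode)
    d = _differences(sample, mode)
    means = (sample.x + sample.y) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, d, s=14, alpha=0.8)
    ax.axhline(report.bias, color="k")
    ax.axhline(report.loa_low, color="k", linestyle="--")
    ax.axhline(report.loa_high, color="k", linestyle="--")
    ax.set_xlabel("pair mean (mm²)")
    ax.set_ylabel("difference" + (" (fraction of mean)" if mode == "percent" else " (mm²)"))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return report


def concordance_plot(sample: PairedSample, path: str, title: str = "") -> Tuple[float, Tuple[float, float]]:
    """Write a concordance plot (45° identity line plus best linear fit)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ccc, ci = lin_ccc(sample.x, sample.y)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(sample.x, sample.y, s=14, alpha=0.8)
    lim = [0, max(sample.x.max(), sample.y.max()) * 1.05]
    ax.plot(lim, lim, "k-", label="concordance")
    slope, intercept = np.polyfit(sample.x, sample.y, 1)
    ax.plot(lim, [slope * v + intercept for v in lim], "k:", label="best fit")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel("method A (mm²)")
    ax.set_ylabel("method B (mm²)")
    ax.legend(loc="upper left", fontsize=8)
    ax.set_title(title or f"CCC = {ccc:.3f} [{ci[0]:.3f}, {ci[1]:.3f}]")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return ccc, ci
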