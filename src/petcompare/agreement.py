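"""Agreement statistics for paired measurements and visual-score cross-tabs.

Quantitative side (paired per-lesion metrics on two reconstructions):
relative differences (tabulation convention: reference = reconstruction A;
Bland-Altman convention: denominator = pair mean), Bland-Altman bias and
limits of agreement, a single-measure two-way intraclass correlation
testing absolute agreement, and paired tests (Student t / Wilcoxon
signed-rank).

Qualitative side (4-point visual malignancy scores, 1 = definitely benign ..
4 = definitely malignant, cross-tabulated reconstruction A x B): Cohen's
kappa (optionally on scores dichotomized 1-2 vs 3-4) and a score-transition
analysis counting nodes that cross the 2|3 boundary, the cut that changes
nodal staging and treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "ScoreCrossTab",
    "relative_differences",
    "bland_altman",
    "icc_absolute_agreement",
    "paired_tests",
    "wilcoxon_signed_rank",
    "cohen_kappa",
    "transition_analysis",
    "TransitionSummary",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired values of one metric on reconstructions A and B, by lesion id."""

    ids: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        ids = tuple(self.ids)
        if not (len(ids) == len(a) == len(b)):
            raise ValueError("ids, a and b must have equal lengths")
        if len(a) < 2:
            raise ValueError("paired series needs at least 2 pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired series contains non-finite values")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.a)

    @classmethod
    def from_values(cls, a: Sequence[float], b: Sequence[float]) -> "PairedSeries":
        return cls(tuple(range(len(list(a)))), np.asarray(a, float), np.asarray(b, float))


def relative_differences(series: PairedSeries, mode: str = "reference_a") -> np.ndarray:
    """Per-pair relative difference of B vs A, in percent.

    ``reference_a``: 100 * (b - a) / a  (the tabulation convention, differences
    in reference to reconstruction A).  ``mean_of_pair``: 100 * (b - a) /
    ((a + b) / 2) (the Bland-Altman convention).
    """
    if mode == "reference_a":
        denom = series.a
    elif mode == "mean_of_pair":
        denom = (series.a + series.b) / 2.0
    else:
        raise ValueError(f"mode must be 'reference_a' or 'mean_of_pair', got {mode!r}")
    bad = np.asarray(series.ids, dtype=object)[denom == 0]
    if bad.size:
        raise ValueError(f"zero denominator for ids: {list(bad)}")
    return 100.0 * (series.b - series.a) / denom


def bland_altman(series: PairedSeries) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement on relative differences.

    Differences are taken relative to the pair mean; limits are
    bias +/- 1.96 * sample SD (ddof=1).  Returns (bias, lower, upper) in %.
    """
    rel = relative_differences(series, mode="mean_of_pair")
    bias = float(np.mean(rel))
    sd = float(np.std(rel, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc_absolute_agreement(series: PairedSeries, alpha: float = 0.05):
    """Single-measure two-way ICC testing absolute agreement, with 95% CI.

    From the two-way ANOVA mean squares with n subjects and k = 2 raters
    (the reconstructions)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the rows (subjects), columns (raters) and
    residual mean squares.  This penalizes a systematic offset between the
    reconstructions, unlike a consistency ICC.  The confidence interval is
    the standard F-based interval for this coefficient.

    Returns ``(icc, (lower, upper))``.
    """
    x = np.column_stack([series.a, series.b])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2) / (
        (n - 1) * (k - 1)
    )
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    if mse == 0:  # perfect agreement: interval collapses
        return float(icc), (float(icc), float(icc))
    a_ = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a_):
        return float(icc), (float(icc), float(icc))
    b_ = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a_ * msc + b_ * mse) ** 2 / (
        (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def _wilcoxon_exact_two_sided(w_plus: float, ranks: np.ndarray) -> float:
    # null distribution of W+ over all 2^n sign assignments, by convolution;
    # mid-ranks are multiples of 1/2, so doubled ranks are exact integers
    scaled = np.rint(2 * ranks).astype(np.int64)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(ranks)
    w2 = int(np.rint(2 * w_plus))
    p_low = dist[: w2 + 1].sum()
    p_high = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(series: PairedSeries, exact_max_n: int = 25):
    """Two-sided Wilcoxon signed-rank test on paired differences b - a.

    Zero differences are discarded; ties get mid-ranks.  The null is exact
    (full 2^n sign distribution, computed by convolution) for n <= 25 and a
    tie-corrected normal approximation beyond.  Returns (W+, p).
    """
    d = series.b - series.a
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: Wilcoxon test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _wilcoxon_exact_two_sided(w_plus, ranks)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = float(2 * stats.norm.sf(abs(z)))
    return w_plus, p


def paired_tests(series: PairedSeries, test: str = "wilcoxon"):
    """Paired comparison of B vs A: ``test`` is ``"t"`` or ``"wilcoxon"``.

    Returns (statistic, two-sided p).  The choice between the two is a
    configuration decision (by distributional assumption), not automated.
    """
    if test == "t":
        res = stats.ttest_rel(series.b, series.a)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        return wilcoxon_signed_rank(series)
    raise ValueError(f"test must be 't' or 'wilcoxon', got {test!r}")


# ---------------------------------------------------------------------------
# visual-score cross-tabulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreCrossTab:
    """4x4 counts of visual scores: rows = score on A, columns = score on B."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (4, 4):
            raise ValueError(f"expected a 4x4 table, got shape {c.shape}")
        if np.any(c < 0) or not np.all(c == np.rint(c)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def dichotomized(self) -> np.ndarray:
        """Collapse scores {1,2} vs {3,4} into a 2x2 table (the staging cut)."""
        c = self.counts
        return np.array(
            [
                [c[:2, :2].sum(), c[:2, 2:].sum()],
                [c[2:, :2].sum(), c[2:, 2:].sum()],
            ]
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.counts,
            index=[f"score_{i}" for i in range(1, 5)],
            columns=[f"score_{i}" for i in range(1, 5)],
        )
        df.to_csv(path, index_label="a\\b")

    @classmethod
    def from_csv(cls, path) -> "ScoreCrossTab":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy())


def cohen_kappa(tab, dichotomize: bool = False) -> float:
    """Cohen's kappa for a square contingency table of paired ratings.

    ``tab`` may be a :class:`ScoreCrossTab` or any square count matrix.
    With ``dichotomize=True`` a 4x4 score table is collapsed to {1,2} vs
    {3,4} first.
    """
    if isinstance(tab, ScoreCrossTab):
        counts = tab.dichotomized() if dichotomize else tab.counts
    else:
        counts = np.asarray(tab, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("kappa requires a square table")
        if dichotomize:
            raise ValueError("dichotomize is only defined for a 4x4 ScoreCrossTab")
    counts = counts.astype(float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    p_o = np.trace(counts) / n
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0)) / n**2)
    if p_e == 1.0:
        raise ValueError("degenerate marginals: expected agreement is 1, kappa undefined")
    return float((p_o - p_e) / (1 - p_e))


@dataclass(frozen=True)
class TransitionSummary:
    """Row-conditional score transitions and 2|3-boundary crossings."""

    row_proportions: np.ndarray  # counts[i][j] / rowsum[i]; NaN rows where rowsum = 0
    upstaged: int  # scored 1-2 on A, 3-4 on B
    downstaged: int  # scored 3-4 on A, 1-2 on B
    grand_total: int
    empty_rows: tuple


def transition_analysis(tab: ScoreCrossTab) -> TransitionSummary:
    """Per-row transition proportions plus counts crossing the 2|3 boundary.

    Rows with zero total are reported as undefined (NaN proportions), not as
    zeros.
    """
    c = tab.counts.astype(float)
    row_sums = c.sum(axis=1)
    props = np.full((4, 4), np.nan)
    nonempty = row_sums > 0
    props[nonempty] = c[nonempty] / row_sums[nonempty, None]
    d = tab.dichotomized()
    return TransitionSummary(
        row_proportions=props,
        upstaged=int(d[0, 1]),
        downstaged=int(d[1, 0]),
        grand_total=tab.grand_total,
        empty_rows=tuple(int(i + 1) for i in np.flatnonzero(~nonempty)),
    )
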