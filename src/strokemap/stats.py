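"""Core statistics shared by all voxel-level analyses.

Implements the unequal-variance (Welch) t statistic, Spearman and Pearson
correlation, the two-sided add-one permutation p-value, Benjamini-Hochberg
FDR and Bonferroni corrections, correlation-strength bands, and the
structure-volume vs behaviour correlation table.

These primitives are written out explicitly because the permutation/FDR
machinery is the inferential core of the mapping analyses; scipy and
statsmodels equivalents serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class PermutationConfig:
    """Settings for permutation-based significance testing.

    All permutation tests are two-sided on the magnitude of the statistic.
    ``pool_across_voxels`` enables the pooled-null strategy used by the
    morphometry group comparison, where every permutation contributes the
    statistics of all in-mask voxels to one common null distribution.
    """

    n_permutations: int = 1000
    seed: int = 0
    pool_across_voxels: bool = False

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class FDRConfig:
    """False-discovery-rate level for voxelwise multiplicity correction."""

    q: float = 0.05

    def __post_init__(self):
        if not 0 < self.q <= 1:
            raise ValueError("q must lie in (0, 1]")


def welch_t(a, b) -> tuple[float, float]:
    """Unequal-variance two-sample t statistic with Welch-Satterthwaite df.

    Returns ``(t, df)`` where ``t = (mean(a) - mean(b)) / sqrt(va/na + vb/nb)``
    with sample variances (n-1 denominator).  If both group variances are
    zero the statistic is undefined and ``(nan, nan)`` is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return float("nan"), float("nan")
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; ``nan`` for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    xm = x - x.mean()
    ym = y - y.mean()
    denom = math.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xm @ ym) / denom, -1.0, 1.0))


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson r of the average-ranked variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched inputs of length >= 3")
    return pearson_r(_average_ranks(x), _average_ranks(y))


def permutation_p(observed: float, null) -> float:
    """Two-sided add-one permutation p-value.

    ``p = (1 + #{|null| >= |observed|}) / (1 + n_null)``; always in (0, 1].
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    count = int(np.sum(np.abs(null) >= abs(observed)))
    return (1 + count) / (1 + null.size)


def fdr_bh(p, cfg: FDRConfig | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR decision at level ``cfg.q``.

    NaN entries (untested voxels) are excluded from the comparison count m
    and are never declared significant.  Returns a boolean array aligned
    with the input.
    """
    cfg = cfg or FDRConfig()
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    sorted_p = pv[order]
    thresh = cfg.q * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    rej = np.zeros(m, dtype=bool)
    if below.size:
        rej[order[: below[-1] + 1]] = True
    out[valid] = rej
    return out


def bonferroni(p, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni decision: reject where ``p <= alpha / m`` (m = finite p)."""
    p = np.asarray(p, dtype=float)
    valid = np.isfinite(p)
    m = int(valid.sum())
    out = np.zeros(p.shape, dtype=bool)
    if m:
        out[valid] = p[valid] <= alpha / m
    return out


#: |r| band edges: below 0.3 weak, 0.3 to below 0.7 medium, 0.7 and above strong.
CORRELATION_BANDS = (0.3, 0.7)


def classify_correlation(r: float) -> str:
    """Band a correlation magnitude as weak / medium / strong.

    Boundaries go to the upper band: |r| in [0, 0.3) weak, [0.3, 0.7)
    medium, [0.7, 1] strong.
    """
    a = abs(r)
    if a > 1:
        raise ValueError("|r| must be <= 1")
    if a < CORRELATION_BANDS[0]:
        return "weak"
    if a < CORRELATION_BANDS[1]:
        return "medium"
    return "strong"


def _pearson_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the exact t transform."""
    if not np.isfinite(r) or n < 4:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), n - 2))


def roi_behaviour_correlations(
    volumes: pd.DataFrame,
    behaviour: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate structure volumes with behavioural scores across subjects.

    ``volumes`` has one row per subject (indexed by subject id) and one
    column per ROI volume (mm^3); ``behaviour`` likewise with score columns
    (ffl, ffr, gsl, gsr).  For every (ROI, score) cell the Pearson r, its
    two-sided p (t transform, df = n-2), the strength band and a Bonferroni
    significance flag over all cells are reported.  Cells with fewer than
    four paired observations are flagged missing.
    """
    common = volumes.index.intersection(behaviour.index)
    vols = volumes.loc[common]
    beh = behaviour.loc[common]
    records = []
    for roi in vols.columns:
        for score in beh.columns:
            pair = pd.concat([vols[roi], beh[score]], axis=1).dropna()
            n = len(pair)
            if n < 4:
                records.append((roi, score, np.nan, np.nan, n, "missing"))
                continue
            r = pearson_r(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            p = _pearson_p(r, n)
            band = classify_correlation(r) if np.isfinite(r) else "missing"
            records.append((roi, score, r, p, n, band))
    table = pd.DataFrame(
        records, columns=["roi", "score", "r", "p", "n", "band"]
    )
    table["significant"] = bonferroni(table["p"].to_numpy(), alpha)
    return table


# ---------------------------------------------------------------------------
# Vectorised kernels shared by the voxelwise analyses.  Shapes: values are
# (n_subjects, n_voxels); group indicators are boolean over subjects.
# ---------------------------------------------------------------------------

def welch_t_matrix(values: np.ndarray, group1: np.ndarray) -> np.ndarray:
    """Welch t per column of ``values`` between group1 and its complement.

    Columns where either group has fewer than two members, or where the
    pooled standard error is zero, come back NaN.
    """
    g = np.asarray(group1, dtype=bool)
    x1 = values[g]
    x0 = values[~g]
    n1, n0 = x1.shape[0], x0.shape[0]
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least two subjects")
    m1 = x1.mean(axis=0)
    m0 = x0.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v0 = x0.var(axis=0, ddof=1)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
    t[se2 == 0] = np.nan
    return t


def welch_t_permuted(values: np.ndarray, group1_matrix: np.ndarray) -> np.ndarray:
    """Welch t for many group-1 indicator rows at once.

    ``group1_matrix`` is (P, n) of 0/1 floats; returns a (P, V) array of t
    statistics, one row per permutation.  Uses sufficient statistics so the
    whole sweep is a pair of matrix products.
    """
    G = np.ascontiguousarray(group1_matrix, dtype=np.float64)
    X = np.ascontiguousarray(values, dtype=np.float64)
    X2 = X * X
    n = X.shape[0]
    n1 = G.sum(axis=1, keepdims=True)
    n0 = n - n1
    tot = X.sum(axis=0, keepdims=True)
    tot2 = X2.sum(axis=0, keepdims=True)
    s1 = G @ X
    q1 = G @ X2
    s0 = tot - s1
    q0 = tot2 - q1
    m1 = s1 / n1
    m0 = s0 / n0
    v1 = (q1 - s1 * m1) / (n1 - 1)
    v0 = (q0 - s0 * m0) / (n0 - 1)
    # guard tiny negative values from cancellation
    np.maximum(v1, 0.0, out=v1)
    np.maximum(v0, 0.0, out=v0)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
    t[se2 == 0] = np.nan
    return t


def rank_columns(values: np.ndarray) -> np.ndarray:
    """Average ranks of each column of a (n, V) array, down the rows."""
    return sps.rankdata(values, method="average", axis=0)


def pearson_r_matrix(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of a vector x against every column of Y; NaN where Y is constant."""
    x = np.asarray(x, dtype=float)
    xm = x - x.mean()
    xn = math.sqrt(xm @ xm)
    Ym = Y - Y.mean(axis=0, keepdims=True)
    yn = np.sqrt((Ym * Ym).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xm @ Ym) / (xn * yn)
    r[yn == 0] = np.nan
    return np.clip(r, -1.0, 1.0)
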