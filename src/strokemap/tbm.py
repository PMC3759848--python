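"""Tensor-based morphometry (TBM) statistics on log-Jacobian maps.

Group comparison: a two-tailed unequal-variance t statistic between lesion
and sham log-Jacobian values at every in-mask voxel, with significance from
label permutations.  Because the group design is identical at every voxel,
the null statistics of all voxels can be pooled across permutations into
one common null distribution, multiplying the effective number of null
samples by the voxel count and sharpening the attainable p-values — the
minimum number of null samples needed to support an FDR threshold q over
V voxels is about V / q (e.g. 42,000 voxels at q = 0.05 need 840,000).

Behavioural correlation: the Spearman rank correlation between a score and
the log-Jacobian value across subjects at every voxel, with score
permutations providing the null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .stats import (
    FDRConfig,
    PermutationConfig,
    fdr_bh,
    pearson_r_matrix,
    rank_columns,
    welch_t_matrix,
    welch_t_permuted,
)

logger = logging.getLogger(__name__)


@dataclass
class TBMConfig:
    """One of ``group_a``/``group_b`` comparison or ``score`` correlation."""

    permutation: PermutationConfig = field(
        default_factory=lambda: PermutationConfig(pool_across_voxels=True)
    )
    fdr: FDRConfig = field(default_factory=FDRConfig)


@dataclass
class TBMResult:
    stat_map: np.ndarray           # Welch t or Spearman rho; NaN where untested
    tested: np.ndarray
    config: TBMConfig
    p_map: np.ndarray | None = None
    significant: np.ndarray | None = None
    n_permutations_used: int | None = None
    pooled_null_size: int | None = None
    exhaustive: bool = False


def required_permutations(n_voxels: int, q: float) -> int:
    """Minimum pooled-null size supporting an FDR threshold q over n voxels.

    ``ceil(n_voxels / q)``: the smallest attainable add-one p must not
    exceed the per-voxel threshold implied by the FDR level.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    return math.ceil(n_voxels / q)


def _valid_voxels(logjac: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """In-mask voxels where every subject has a finite log-Jacobian.

    Voxels with a non-positive determinant in any subject carry NaN in the
    log map and are excluded from the statistics rather than clamped.
    """
    finite = np.isfinite(logjac).all(axis=0)
    return np.asarray(brain_mask, dtype=bool) & finite


def tbm_group_map(
    logjac: np.ndarray,
    labels: np.ndarray,
    brain_mask: np.ndarray,
    group1: str = "lesion",
    cfg: TBMConfig | None = None,
) -> TBMResult:
    """Welch t map (group1 minus the rest) over valid in-mask voxels."""
    cfg = cfg or TBMConfig()
    logjac = np.asarray(logjac, dtype=float)
    labels = np.asarray(labels)
    g1 = labels == group1
    if g1.sum() < 2 or (~g1).sum() < 2:
        raise ValueError("each group needs at least two subjects")
    tested = _valid_voxels(logjac, brain_mask)
    n_excluded = int(np.asarray(brain_mask, dtype=bool).sum() - tested.sum())
    if n_excluded:
        logger.info("excluded %d in-mask voxels with invalid Jacobians", n_excluded)
    X = logjac.reshape(logjac.shape[0], -1)[:, tested.ravel()]
    t_cols = welch_t_matrix(X, g1)
    t_map = np.full(tested.size, np.nan)
    t_map[tested.ravel()] = t_cols
    return TBMResult(
        stat_map=t_map.reshape(tested.shape), tested=tested, config=cfg
    )


def _label_permutations(
    n: int, n1: int, n_requested: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """(P, n) group-1 indicator rows; exhaustive if the design is small.

    When the number of distinct group assignments is at most the requested
    count, all of them are enumerated instead of sampled.
    """
    n_distinct = math.comb(n, n1)
    if n_distinct <= n_requested:
        G = np.zeros((n_distinct, n), dtype=np.float64)
        for i, idx in enumerate(combinations(range(n), n1)):
            G[i, list(idx)] = 1.0
        logger.info(
            "requested %d permutations but only %d distinct assignments; "
            "using exhaustive enumeration", n_requested, n_distinct,
        )
        return G, True
    G = np.zeros((n_requested, n), dtype=np.float64)
    for i in range(n_requested):
        G[i, rng.permutation(n)[:n1]] = 1.0
    return G, False


def tbm_pooled_inference(
    result: TBMResult,
    logjac: np.ndarray,
    labels: np.ndarray,
    group1: str = "lesion",
    cfg: TBMConfig | None = None,
    return_null: bool = False,
):
    """Pooled-null permutation p-values and FDR decisions for a TBM t map.

    Each label permutation contributes the t statistics of *all* tested
    voxels to one common null (size P x V), assuming cross-voxel
    exchangeability of null statistics; the per-voxel two-sided p is the
    add-one tail of that pooled null.  When the group sizes admit fewer
    distinct label assignments than requested, the enumeration is
    exhaustive and logged.
    """
    cfg = cfg or result.config
    logjac = np.asarray(logjac, dtype=float)
    labels = np.asarray(labels)
    g1 = labels == group1
    n = logjac.shape[0]
    tested = result.tested
    X = logjac.reshape(n, -1)[:, tested.ravel()]
    t_obs = result.stat_map.ravel()[tested.ravel()]

    rng = np.random.default_rng(cfg.permutation.seed)
    G, exhaustive = _label_permutations(
        n, int(g1.sum()), cfg.permutation.n_permutations, rng
    )
    T = welch_t_permuted(X, G)

    abs_null = np.abs(T[np.isfinite(T)]).ravel()
    abs_null.sort()
    pooled_size = abs_null.size
    if cfg.permutation.pool_across_voxels:
        # count of null |t| >= observed |t| via a sorted search
        count = pooled_size - np.searchsorted(abs_null, np.abs(t_obs), side="left")
        p_cols = (1 + count) / (1 + pooled_size)
    else:
        with np.errstate(invalid="ignore"):
            count = (np.abs(T) >= np.abs(t_obs)[None, :]).sum(axis=0)
        p_cols = (1 + count) / (1 + T.shape[0])
    p_cols = np.where(np.isfinite(t_obs), p_cols, np.nan)

    p_map = np.full(tested.size, np.nan)
    p_map[tested.ravel()] = p_cols
    p_map = p_map.reshape(tested.shape)
    sig = fdr_bh(p_map.ravel(), cfg.fdr).reshape(tested.shape)

    out = TBMResult(
        stat_map=result.stat_map,
        tested=tested,
        config=cfg,
        p_map=p_map,
        significant=sig,
        n_permutations_used=T.shape[0],
        pooled_null_size=pooled_size if cfg.permutation.pool_across_voxels else None,
        exhaustive=exhaustive,
    )
    if return_null:
        return out, T
    return out


def tbm_behaviour_correlation(
    logjac: np.ndarray,
    scores: np.ndarray,
    brain_mask: np.ndarray,
    cfg: TBMConfig | None = None,
    return_null: bool = False,
):
    """Voxelwise Spearman correlation between a score and log-Jacobian.

    At each valid voxel the rank correlation of the behavioural score with
    the subjects' log-Jacobian values is computed; the null is built by
    permuting the scores across subjects, two-sided add-one p-values follow,
    and FDR is applied over tested voxels.  Voxels with constant
    log-Jacobian across subjects are untested.
    """
    cfg = cfg or TBMConfig(
        permutation=PermutationConfig(pool_across_voxels=False)
    )
    logjac = np.asarray(logjac, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = logjac.shape[0]
    if n < 5:
        raise ValueError("behavioural correlation maps need >= 5 subjects")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite for all subjects")

    tested = _valid_voxels(logjac, brain_mask)
    X = logjac.reshape(n, -1)[:, tested.ravel()]
    RX = rank_columns(X)
    rs = rank_columns(scores[:, None])[:, 0]
    rho_cols = pearson_r_matrix(rs, RX)   # NaN where log J constant

    rng = np.random.default_rng(cfg.permutation.seed)
    P = cfg.permutation.n_permutations
    # permuting the score ranks is equivalent to permuting the scores
    RXc = RX - RX.mean(axis=0, keepdims=True)
    xnorm = np.sqrt((RXc * RXc).sum(axis=0))
    rsc = rs - rs.mean()
    snorm = math.sqrt(rsc @ rsc)
    S = np.empty((P, n))
    for i in range(P):
        S[i] = rsc[rng.permutation(n)]
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (S @ RXc) / (snorm * xnorm)[None, :]

    if cfg.permutation.pool_across_voxels:
        abs_null = np.abs(T[np.isfinite(T)]).ravel()
        abs_null.sort()
        count = abs_null.size - np.searchsorted(
            abs_null, np.abs(rho_cols), side="left"
        )
        p_cols = (1 + count) / (1 + abs_null.size)
        pooled_size = abs_null.size
    else:
        with np.errstate(invalid="ignore"):
            count = np.nansum(np.abs(T) >= np.abs(rho_cols)[None, :], axis=0)
        p_cols = (1 + count) / (1 + P)
        pooled_size = None
    p_cols = np.where(np.isfinite(rho_cols), p_cols, np.nan)

    rho_map = np.full(tested.size, np.nan)
    rho_map[tested.ravel()] = rho_cols
    p_map = np.full(tested.size, np.nan)
    p_map[tested.ravel()] = p_cols
    rho_map = rho_map.reshape(tested.shape)
    p_map = p_map.reshape(tested.shape)
    # voxels with constant log J are untested, not merely non-significant
    tested = tested & np.isfinite(rho_map)
    sig = fdr_bh(p_map.ravel(), cfg.fdr).reshape(tested.shape)

    out = TBMResult(
        stat_map=rho_map,
        tested=tested,
        config=cfg,
        p_map=p_map,
        significant=sig,
        n_permutations_used=P,
        pooled_null_size=pooled_size,
    )
    if return_null:
        return out, T
    return out
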