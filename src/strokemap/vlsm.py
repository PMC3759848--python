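"""Voxel lesion-symptom mapping (VLSM).

At every brain voxel, subjects are split into a lesion-present and a
lesion-absent group according to their binary lesion masks, and the two
groups' behavioural scores are compared with an unequal-variance two-tailed
t-test.  Because group membership and size differ from voxel to voxel, a
minimum group size (default five per side) gates which voxels are testable;
untested voxels are reported separately from non-significant ones.
Significance is assessed by permuting the behavioural scores across
subjects (the lesion masks stay fixed), recomputing the t statistic at each
permutation to build a per-voxel null, and correcting the resulting
two-sided p-values with the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import FDRConfig, PermutationConfig, fdr_bh


@dataclass
class VLSMConfig:
    min_group_size: int = 5
    behaviour_score: str = "ffl"
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    fdr: FDRConfig = field(default_factory=FDRConfig)

    def __post_init__(self):
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")


@dataclass
class VLSMResult:
    """Voxelwise VLSM statistics on the reference grid.

    ``t_map`` holds the Welch t (lesion minus no-lesion) at tested voxels
    and NaN elsewhere; ``n_lesion``/``n_nolesion`` the per-voxel group
    sizes; ``tested`` the voxels meeting the minimum group size inside the
    brain mask.  After inference, ``p_map`` holds two-sided permutation
    p-values and ``significant`` the FDR-corrected decision mask (FDR is
    computed over tested voxels only).
    """

    t_map: np.ndarray
    n_lesion: np.ndarray
    n_nolesion: np.ndarray
    tested: np.ndarray
    config: VLSMConfig
    p_map: np.ndarray | None = None
    significant: np.ndarray | None = None
    n_permutations_used: int | None = None


def vlsm_tmap(
    lesion_masks: np.ndarray,
    scores: np.ndarray,
    brain_mask: np.ndarray,
    cfg: VLSMConfig | None = None,
) -> VLSMResult:
    """Per-voxel lesion-present vs lesion-absent Welch t map.

    ``lesion_masks`` is an (n_subjects, X, Y, Z) boolean stack and
    ``scores`` the matching behavioural values.  Voxels where either group
    is smaller than ``cfg.min_group_size`` are untested.
    """
    cfg = cfg or VLSMConfig()
    masks = np.asarray(lesion_masks).astype(bool)
    scores = np.asarray(scores, dtype=float)
    brain = np.asarray(brain_mask).astype(bool)
    n = masks.shape[0]
    if scores.shape != (n,):
        raise ValueError("scores must have one value per subject")
    if n < 2 * cfg.min_group_size:
        raise ValueError(
            f"need at least {2 * cfg.min_group_size} subjects for "
            f"min_group_size={cfg.min_group_size}"
        )

    flat_masks = masks.reshape(n, -1)
    brain_flat = brain.ravel()
    n_lesion = flat_masks.sum(axis=0)
    n_nolesion = n - n_lesion
    tested_flat = (
        brain_flat
        & (n_lesion >= cfg.min_group_size)
        & (n_nolesion >= cfg.min_group_size)
    )
    if not tested_flat.any():
        raise ValueError(
            "no voxel satisfies the minimum group size anywhere in the brain"
        )

    cols = np.flatnonzero(tested_flat)
    M = flat_masks[:, cols].astype(np.float64)
    t_cols = _vlsm_t_columns(M, scores)

    shape = masks.shape[1:]
    t_map = np.full(brain.size, np.nan)
    t_map[cols] = t_cols
    return VLSMResult(
        t_map=t_map.reshape(shape),
        n_lesion=n_lesion.reshape(shape),
        n_nolesion=n_nolesion.reshape(shape),
        tested=tested_flat.reshape(shape),
        config=cfg,
    )


def _vlsm_t_columns(M: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Welch t (lesion minus no-lesion) for each column of a 0/1 matrix M."""
    n = M.shape[0]
    s = scores
    s2 = s * s
    n1 = M.sum(axis=0)
    n0 = n - n1
    sum1 = s @ M
    q1 = s2 @ M
    sum0 = s.sum() - sum1
    q0 = s2.sum() - q1
    m1 = sum1 / n1
    m0 = sum0 / n0
    v1 = np.maximum((q1 - sum1 * m1) / (n1 - 1), 0.0)
    v0 = np.maximum((q0 - sum0 * m0) / (n0 - 1), 0.0)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
    t[se2 == 0] = np.nan
    return t


def vlsm_inference(
    result: VLSMResult,
    lesion_masks: np.ndarray,
    scores: np.ndarray,
    cfg: VLSMConfig | None = None,
    return_null: bool = False,
):
    """Permutation p-values and FDR significance for a VLSM t map.

    Behaviour scores are permuted across subjects while the lesion masks
    (and hence the per-voxel group splits) stay fixed; the null is built
    per voxel because group composition differs between voxels.  Two-sided
    add-one p-values are corrected by Benjamini-Hochberg FDR over the
    tested voxels.  With ``return_null`` the (P, V_tested) permutation t
    array is returned as well, e.g. to feed cluster enhancement.
    """
    cfg = cfg or result.config
    masks = np.asarray(lesion_masks).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n = masks.shape[0]
    cols = np.flatnonzero(result.tested.ravel())
    M = masks.reshape(n, -1)[:, cols].astype(np.float64)
    t_obs = result.t_map.ravel()[cols]

    rng = np.random.default_rng(cfg.permutation.seed)
    P = cfg.permutation.n_permutations
    S = np.empty((P, n), dtype=np.float64)
    for i in range(P):
        S[i] = scores[rng.permutation(n)]
    # Welch t for all permutations at once via sufficient statistics
    T = _vlsm_t_permuted(M, S)

    abs_obs = np.abs(t_obs)
    with np.errstate(invalid="ignore"):
        count = (np.abs(T) >= abs_obs[None, :]).sum(axis=0)
    p_cols = (1 + count) / (1 + P)
    p_cols[~np.isfinite(t_obs)] = np.nan

    p_map = np.full(result.t_map.size, np.nan)
    p_map[cols] = p_cols
    p_map = p_map.reshape(result.t_map.shape)

    sig = fdr_bh(p_map.ravel(), cfg.fdr).reshape(result.t_map.shape)
    out = VLSMResult(
        t_map=result.t_map,
        n_lesion=result.n_lesion,
        n_nolesion=result.n_nolesion,
        tested=result.tested,
        config=cfg,
        p_map=p_map,
        significant=sig,
        n_permutations_used=P,
    )
    if return_null:
        return out, T
    return out


def _vlsm_t_permuted(M: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Welch t for every (permuted score row, voxel column) pair.

    ``M`` is (n, V) of 0/1 lesion indicators, ``S`` is (P, n) of permuted
    scores.  Returns (P, V).  Uses two matrix products: group-1 sums of the
    scores and their squares.
    """
    n, _ = M.shape
    n1 = M.sum(axis=0)[None, :]
    n0 = n - n1
    sum1 = S @ M
    q1 = (S * S) @ M
    tot = S.sum(axis=1, keepdims=True)
    tot2 = (S * S).sum(axis=1, keepdims=True)
    sum0 = tot - sum1
    q0 = tot2 - q1
    m1 = sum1 / n1
    m0 = sum0 / n0
    v1 = np.maximum((q1 - sum1 * m1) / (n1 - 1), 0.0)
    v0 = np.maximum((q0 - sum0 * m0) / (n0 - 1), 0.0)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (m1 - m0) / np.sqrt(se2)
    # zero pooled variance under a permutation: treat as an extreme draw
    T[se2 == 0] = np.inf
    return T
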