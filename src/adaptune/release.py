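"""Similarity-tuning regression, TFCE, and sign-flip permutation inference.

Inside the adaptation mask, each voxel's four deviant betas (SC, C, D, SD;
Identity excluded) are regressed on the ordinal similarity rank 1..4.  The
per-subject explained-variance (R^2) maps — or, optionally, the signed
slope maps — enter a one-sample group test whose null distribution is
built by randomly sign-flipping subject maps, with threshold-free cluster
enhancement (TFCE) applied to the voxel-wise t map and familywise error
controlled through the permutation distribution of the maximum TFCE score.
Voxels surviving at the requested level are finally intersected with a
positive group-mean slope, because the hypothesis is an *increase* in
release from SC to SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .glm import BetaMaps, StatMap, one_sample_t
from .norms import BIN_LABELS


@dataclass
class ReleaseMaps:
    """One subject's similarity-tuning maps inside the adaptation mask."""

    r2: np.ndarray     # 3D, NaN outside mask
    slope: np.ndarray  # 3D, NaN outside mask
    mask: np.ndarray


@dataclass
class TFCEParams:
    """TFCE settings: the FSL-randomise conventions H=2, E=0.5, 26-connectivity,
    and a step of max/100 unless ``dh`` is given explicitly."""

    H: float = 2.0
    E: float = 0.5
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.H <= 0 or self.E <= 0:
            raise ValueError("TFCE exponents must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("non-positive dh")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


@dataclass
class PermutationResult:
    t_map: np.ndarray            # observed group statistic (3D, NaN outside mask)
    tfce_map: np.ndarray         # TFCE of the observed map
    p_map: np.ndarray            # voxel-wise FWE-corrected p (3D, NaN outside mask)
    null_max: np.ndarray         # max-TFCE permutation distribution
    n_permutations: int
    significant: np.ndarray      # p < alpha mask
    alpha: float
    seed: int | None = None


def voxelwise_release_regression(
    betas: BetaMaps,
    mask: np.ndarray,
    conditions: tuple[str, ...] = BIN_LABELS,
    similarity_x: np.ndarray | None = None,
) -> ReleaseMaps:
    """Per-voxel OLS of deviant betas on similarity rank (or on measured
    similarity values via ``similarity_x``), for one subject.

    slope = cov(x, beta) / var(x); R^2 = 1 - SSE/SST, with R^2 defined as 0
    where the four betas are constant (SST = 0).  The Identity condition
    must not be among ``conditions``.
    """
    if "I" in conditions:
        raise ValueError("the Identity condition is excluded from the release analysis")
    if tuple(conditions) != tuple(BIN_LABELS):
        raise ValueError(f"expected the four deviant bins {BIN_LABELS}, got {conditions}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty release-analysis mask")
    x = np.arange(1.0, 5.0) if similarity_x is None else np.asarray(similarity_x, float)
    if x.shape != (4,):
        raise ValueError("similarity predictor must have one value per deviant bin")
    xc = x - x.mean()
    sxx = float(xc @ xc)

    Y = np.stack([betas.beta(c)[mask] for c in conditions])  # 4 x v
    yc = Y - Y.mean(axis=0)
    slope = (xc @ yc) / sxx
    sst = np.einsum("ij,ij->j", yc, yc)
    ssr = slope ** 2 * sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, ssr / sst, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    shape = mask.shape
    r2_map = np.full(shape, np.nan)
    slope_map = np.full(shape, np.nan)
    r2_map[mask] = r2
    slope_map[mask] = slope
    return ReleaseMaps(r2=r2_map, slope=slope_map, mask=mask)


def tfce(stat: StatMap | np.ndarray, params: TFCEParams | None = None,
         mask: np.ndarray | None = None) -> StatMap:
    """Threshold-free cluster enhancement of a (one-sided) statistic map.

    TFCE(v) = sum over heights h of e(h, v)^E * h^H * dh, where e(h, v) is
    the voxel count of the connected suprathreshold (value >= h) component
    containing v.  Negative values contribute nothing.
    """
    params = params or TFCEParams()
    if isinstance(stat, StatMap):
        values, mask = stat.values, stat.mask if mask is None else mask
    else:
        values = np.asarray(stat, dtype=float)
        mask = np.ones(values.shape, bool) if mask is None else np.asarray(mask, bool)
    out = np.zeros(values.shape)
    pos = np.where(mask & np.isfinite(values) & (values > 0), values, 0.0)
    hmax = float(pos.max())
    if hmax > 0:
        dh = params.dh if params.dh is not None else hmax / params.n_steps
        n_steps = int(np.floor(hmax / dh + 1e-9))
        structure = params.structure
        # crop to the bounding box of positive values: labeling cost scales
        # with array size, and everything outside contributes nothing
        bbox = ndimage.find_objects((pos > 0).astype(np.int8))[0]
        sub = pos[bbox]
        acc = np.zeros(sub.shape)
        for i in range(1, n_steps + 1):
            h = i * dh
            supra = sub >= h
            labels, n = ndimage.label(supra, structure=structure)
            if n == 0:
                break
            sizes = np.bincount(labels.ravel())
            acc[supra] += sizes[labels[supra]] ** params.E * h ** params.H * dh
        out[bbox] = acc
    out[~mask] = 0.0
    return StatMap(values=out, kind="tfce", dof=np.nan, mask=mask)


def permutation_one_sample(
    subject_maps: list[np.ndarray] | np.ndarray,
    mask: np.ndarray,
    n_perm: int = 5000,
    params: TFCEParams | None = None,
    alpha: float = 0.001,
    seed: int | None = None,
) -> PermutationResult:
    """One-sample group test with a sign-flip max-TFCE null distribution.

    The observed voxel-wise one-sample t map is TFCE-enhanced; each
    permutation flips the sign of whole subject maps, recomputes the t map
    and records its maximum TFCE.  FWE-corrected
    p(v) = (1 + #{null max >= TFCE(v)}) / (1 + n_perm).
    """
    params = params or TFCEParams()
    if n_perm < 1.0 / alpha:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve FWE level {alpha}; need >= {int(1 / alpha)}"
        )
    maps = np.stack(subject_maps)
    n_subj = maps.shape[0]
    if n_subj < 8:
        warnings.warn(f"only {n_subj} subjects; permutation p-values will be coarse",
                      stacklevel=2)
    mask = np.asarray(mask, bool)
    data = maps[:, mask]  # n_subj x v
    shape = mask.shape
    rng = np.random.default_rng(seed)

    def t_of(values: np.ndarray) -> np.ndarray:
        vol = np.zeros(shape)
        vol[mask] = values
        return vol

    t_obs = one_sample_t(data)
    tfce_obs = tfce(t_of(t_obs), params, mask)
    obs = tfce_obs.values[mask]

    # under sign flips the per-voxel sum of squares is invariant, so only
    # the flipped mean needs recomputation
    ssq = np.einsum("ij,ij->j", data, data)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        while (signs == 1.0).all():
            # the unflipped arrangement is already counted by the +1 terms
            # of the p-value; drawing it again would double-count it
            signs = rng.choice([-1.0, 1.0], size=n_subj)
        mean = (signs @ data) / n_subj
        var = (ssq - n_subj * mean ** 2) / (n_subj - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mean / np.sqrt(var / n_subj)
        t_perm = np.nan_to_num(t_perm)
        null_max[p] = tfce(t_of(t_perm), params, mask).values[mask].max()

    exceed = (null_max[None, :] >= obs[:, None]).sum(axis=1)
    p_vox = (1.0 + exceed) / (1.0 + n_perm)

    t_map = np.full(shape, np.nan)
    t_map[mask] = t_obs
    p_map = np.full(shape, np.nan)
    p_map[mask] = p_vox
    significant = np.zeros(shape, bool)
    significant[mask] = p_vox < alpha
    return PermutationResult(
        t_map=t_map, tfce_map=tfce_obs.values, p_map=p_map, null_max=null_max,
        n_permutations=n_perm, significant=significant, alpha=alpha, seed=seed,
    )


def positive_slope_mask(significant: np.ndarray, mean_slope: np.ndarray) -> np.ndarray:
    """Final release mask: significant voxels whose group-mean slope is positive."""
    return np.asarray(significant, bool) & (np.nan_to_num(mean_slope) > 0)
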