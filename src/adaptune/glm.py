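"""FIR and HRF design matrices, voxel-wise OLS, and adaptation contrasts.

The adaptation model is a finite-impulse-response GLM with one stick
regressor per adaptor position (1..9) and one per deviant condition, i.e.
14 regressors of interest, plus 24 nuisance columns (6 motion + 18
physiological) and an intercept.  Because each acquisition during the
stimulus stream carries exactly one stick, the fitted position betas trace
the peristimulus BOLD trajectory; repetition suppression makes this
trajectory peak around the 4th time bin and fall by the 7th, which the
4th > 7th contrast (a repeated-measures F on the single-df difference)
turns into an adaptation mask.

The release model replaces the sticks with six HRF-convolved regressors of
interest — one for all adaptors and one per deviant condition — whose
deviant betas estimate per-condition release amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .niftiio import VolumeSeries
from .simulate import STICK_NAMES, double_gamma_hrf, stick_matrix

HRF_INTEREST_NAMES = ["adaptors", "SC", "C", "D", "SD", "I"]
EXPECTED_NUISANCE = 24


@dataclass
class DesignMatrix:
    values: np.ndarray        # time x regressors
    names: list[str]
    tr: float
    interest: list[str]       # subset of names that are regressors of interest

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.names):
            raise ValueError("design column count does not match names")
        cols = self.values[:, [self.names.index(n) for n in self.interest]]
        dead = [n for n, z in zip(self.interest, (cols != 0).any(axis=0)) if not z]
        if dead:
            raise ValueError(f"all-zero regressor(s) of interest: {dead}")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.tr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names, index=self.frame_times)


@dataclass
class BetaMaps:
    """Per-regressor 3D coefficient maps with residual variance and dof."""

    betas: dict[str, np.ndarray]
    resid_var: np.ndarray
    dof: int
    mask: np.ndarray

    def beta(self, name: str) -> np.ndarray:
        return self.betas[name]

    def stack(self, names: list[str]) -> np.ndarray:
        """len(names) x n_mask_voxels matrix of in-mask betas."""
        return np.vstack([self.betas[n][self.mask] for n in names])


@dataclass
class StatMap:
    values: np.ndarray
    kind: str                 # "t", "F", "R2", "slope", ...
    dof: float
    mask: np.ndarray


def _with_confounds(interest: np.ndarray, interest_names: list[str],
                    nuisance, tr: float) -> DesignMatrix:
    n_vols = interest.shape[0]
    if nuisance is None:
        nuis = np.empty((n_vols, 0))
        nuis_names: list[str] = []
    else:
        nuis = np.asarray(nuisance.to_numpy() if hasattr(nuisance, "to_numpy") else nuisance,
                          dtype=float)
        if nuis.shape[0] != n_vols:
            raise ValueError("nuisance rows do not match the number of volumes")
        if nuis.shape[1] != EXPECTED_NUISANCE:
            warnings.warn(
                f"expected {EXPECTED_NUISANCE} nuisance regressors "
                f"(6 motion + 18 physiological), got {nuis.shape[1]}",
                stacklevel=3,
            )
        nuis_names = (list(nuisance.columns) if hasattr(nuisance, "columns")
                      else [f"nuisance_{j}" for j in range(nuis.shape[1])])
    values = np.column_stack([interest, nuis, np.ones(n_vols)])
    return DesignMatrix(values=values, names=interest_names + nuis_names + ["intercept"],
                        tr=tr, interest=interest_names)


def build_fir_design(events: pd.DataFrame, n_vols: int, tr: float = 1.0,
                     nuisance=None, convolve_hrf: bool = False) -> DesignMatrix:
    """14-regressor FIR design: unit impulses per adaptor position and per
    deviant condition, plus nuisance columns and an intercept.

    With ``convolve_hrf=True`` the impulse columns are convolved with the
    canonical HRF, turning the model into a per-position amplitude
    estimator (useful for recovering planted neural amplitudes); the
    default sticks estimate the peristimulus time course.
    """
    S = stick_matrix(events, n_vols, tr)
    present = S.sum(axis=0) > 0  # positions/conditions absent from the run
    names = [n for n, keep in zip(STICK_NAMES, present) if keep]
    S = S[:, present]
    if convolve_hrf:
        kernel = double_gamma_hrf(tr)
        S = np.apply_along_axis(lambda c: np.convolve(c, kernel)[:n_vols], 0, S)
    return _with_confounds(S, names, nuisance, tr)


def build_hrf_design(events: pd.DataFrame, n_vols: int, tr: float = 1.0,
                     nuisance=None) -> DesignMatrix:
    """Six HRF-convolved regressors of interest: all adaptors pooled, plus
    one per deviant condition (SC, C, D, SD, I)."""
    S = stick_matrix(events, n_vols, tr)
    interest = np.column_stack([S[:, :9].sum(axis=1), S[:, 9], S[:, 10],
                                S[:, 11], S[:, 12], S[:, 13]])
    kernel = double_gamma_hrf(tr)
    X = np.apply_along_axis(lambda c: np.convolve(c, kernel)[:n_vols], 0, interest)
    return _with_confounds(X, list(HRF_INTEREST_NAMES), nuisance, tr)


def fit_glm(vol: VolumeSeries, X: DesignMatrix) -> BetaMaps:
    """Voxel-wise ordinary least squares via a thin QR decomposition.

    beta = R^-1 Q^T y per in-mask voxel; residual variance uses
    dof = n_timepoints - n_regressors.  A rank-deficient design is an
    error naming the collinear columns.
    """
    A = X.values
    n, p = A.shape
    if vol.n_vols != n:
        raise ValueError(f"volume has {vol.n_vols} timepoints but design has {n} rows")
    if not vol.mask.any():
        raise ValueError("empty brain mask")
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    bad = diag < max(n, p) * np.finfo(float).eps * diag.max()
    if bad.any():
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear column(s): "
            f"{[X.names[j] for j in np.flatnonzero(bad)]}"
        )
    Y = vol.masked()                               # n x v
    from scipy.linalg import solve_triangular
    beta = solve_triangular(R, Q.T @ Y)            # p x v
    resid = Y - A @ beta
    dof = n - p
    sse = np.einsum("ij,ij->j", resid, resid)

    shape = vol.mask.shape
    maps = {}
    for j, name in enumerate(X.names):
        m = np.full(shape, np.nan)
        m[vol.mask] = beta[j]
        maps[name] = m
    rv = np.full(shape, np.nan)
    rv[vol.mask] = sse / dof if dof > 0 else np.nan
    return BetaMaps(betas=maps, resid_var=rv, dof=dof, mask=vol.mask.copy())


def one_sample_t(maps: np.ndarray) -> np.ndarray:
    """One-sample t across the first axis (subjects), elementwise."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def adaptation_contrast(
    betas_per_subject: list[BetaMaps],
    alpha: float = 0.001,
    bins: tuple[int, int] = (4, 7),
) -> tuple[StatMap, np.ndarray]:
    """Group adaptation effect: per-subject difference between two FIR time
    bins (default 4th minus 7th), tested with a repeated-measures F.

    For a single-df contrast the repeated-measures F equals the squared
    one-sample t on the per-subject differences.  The returned mask keeps
    voxels with p < alpha whose mean difference is positive (the 4th bin
    responding more than the 7th).
    """
    n = len(betas_per_subject)
    if n < 3:
        raise ValueError("adaptation_contrast needs at least 3 subjects")
    hi, lo = f"adaptor_{bins[0]}", f"adaptor_{bins[1]}"
    mask = np.logical_and.reduce([b.mask for b in betas_per_subject])
    d = np.stack([b.beta(hi) - b.beta(lo) for b in betas_per_subject])
    t = one_sample_t(d)
    F = t ** 2
    p = stats.f.sf(F, 1, n - 1)
    adaptation = mask & (p < alpha) & (d.mean(axis=0) > 0)
    Fmap = np.where(mask, F, np.nan)
    return StatMap(values=Fmap, kind="F", dof=n - 1, mask=mask), adaptation


def deviants_vs_identity(betas_per_subject: list[BetaMaps]) -> StatMap:
    """Sanity contrast: mean(SC, C, D, SD) minus Identity, group one-sample t."""
    for b in betas_per_subject:
        if "I" not in b.betas:
            raise ValueError("Identity betas missing from an HRF-model fit")
    mask = np.logical_and.reduce([b.mask for b in betas_per_subject])
    c = np.stack([
        np.mean([b.beta(k) for k in ("SC", "C", "D", "SD")], axis=0) - b.beta("I")
        for b in betas_per_subject
    ])
    t = np.where(mask, one_sample_t(c), np.nan)
    return StatMap(values=t, kind="t", dof=len(betas_per_subject) - 1, mask=mask)
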