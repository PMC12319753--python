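"""Synthetic behavioral and BOLD data with planted adaptation and release.

The reaction-time generator plants a monotone slowing with adaptor-deviant
similarity (with an optional mid-similarity plateau), subject-level random
intercepts, trial noise, and a miss process.  Defaults mirror the scale of
typical release-from-adaptation RT data: ~417 ms at the most dissimilar
deviant, ~32 ms of slowing at the most similar one, with a plateau at the
two intermediate bins, and an 8.5% base miss rate boosted by 3 points for
the hardest (SC) deviants.

The BOLD generator plants, per voxel, a repetition-suppression sequence —
the neural amplitude of the k-th adaptor is amplitude * max(floor,
decay^(k-1)) — and a similarity-tuned release: the deviant amplitude is
amplitude * w(condition), with two archetypal tuning profiles
(graded-linear and step-like).  The neural impulse train is convolved with
a canonical double-gamma HRF and contaminated with linear drift, AR(1)
noise, and linear loadings on 6 simulated motion and 18 simulated
physiological nuisance regressors (6 cardiac, 8 respiratory, 4
interaction), which are returned for use as GLM confounds.

With rapid 1 s stimulus presentation, the peristimulus BOLD trajectory a
stick-FIR model estimates is the HRF-filtered amplitude sequence: under the
default fast decay it rises to a peak near 4 s after trial onset and falls
toward a plateau before 10 s, which is what the 4th-vs-7th time-bin
adaptation contrast detects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .design import TrialSpec
from .niftiio import VolumeSeries
from .norms import BIN_LABELS

# ---------------------------------------------------------------------------
# Reaction times
# ---------------------------------------------------------------------------

#: similarity level per bin: SC is 3 steps above the SD baseline
_SIM_LEVEL = {"SC": 3.0, "C": 2.0, "D": 1.0, "SD": 0.0}


@dataclass
class RTGenParams:
    """Parameters of the reaction-time generator (all times in ms)."""

    base_rt: float = 416.7        # mean RT at the SD (most dissimilar) deviant
    similarity_slope: float = 10.6  # ms of slowing per similarity step
    plateau: float | None = 0.8   # common C/D level (bins); None = linear levels 3,2,1,0
    subject_sd: float = 30.0      # between-subject intercept sd
    trial_sd: float = 100.0       # within-subject trial noise sd
    miss_base_rate: float = 0.085
    miss_similarity_boost: float = 0.03  # extra miss probability for SC
    n_subjects: int = 22
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.miss_base_rate <= 1 or not 0 <= self.miss_similarity_boost <= 1:
            raise ValueError("miss probabilities must lie in [0, 1]")
        if self.subject_sd < 0 or self.trial_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def level(self, condition: str) -> float:
        lv = _SIM_LEVEL[condition]
        if self.plateau is not None and condition in ("C", "D"):
            return float(self.plateau)
        return lv


def simulate_rt_dataset(design: list[TrialSpec], params: RTGenParams) -> pd.DataFrame:
    """Simulate per-trial RTs for the four change-detection conditions.

    Returns a table (subject, trial, condition, rt_ms, responded); Identity
    trials carry no expected response and are omitted.  Missed trials have
    responded=False and NaN rt_ms.
    """
    rng = np.random.default_rng(params.seed)
    idx = np.array([i for i, t in enumerate(design) if t.deviant_condition in BIN_LABELS])
    conds = np.array([design[i].deviant_condition for i in idx])
    levels = np.array([params.level(c) for c in conds])
    p_miss = params.miss_base_rate + params.miss_similarity_boost * (conds == "SC")
    n = idx.size
    frames = []
    for s in range(params.n_subjects):
        intercept = rng.normal(0.0, params.subject_sd)
        rt = (params.base_rt + params.similarity_slope * levels + intercept
              + rng.normal(0.0, params.trial_sd, n))
        miss = rng.random(n) < p_miss
        frames.append(pd.DataFrame({
            "subject": s, "trial": idx, "condition": conds,
            "rt_ms": np.where(miss, np.nan, rt), "responded": ~miss,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

def double_gamma_hrf(dt: float, length: float = 32.0,
                     peak_delay: float = 5.0, undershoot_delay: float = 16.0,
                     undershoot_ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, peak = 1.

    Difference of two gamma densities: a response gamma with mode at
    ``peak_delay - 1`` seconds and an undershoot gamma with mode near
    ``undershoot_delay - 1``, scaled by 1/undershoot_ratio.  The kernel
    spans ``length`` seconds and is normalized to unit peak.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt)
    h = stats.gamma.pdf(t, peak_delay) - stats.gamma.pdf(t, undershoot_delay) / undershoot_ratio
    return h / h.max()


# ---------------------------------------------------------------------------
# Voxel tuning models
# ---------------------------------------------------------------------------

@dataclass
class VoxelTuningModel:
    """Generative tuning of one voxel population.

    ``adapt_decay``/``adapt_floor`` set the repetition-suppression sequence;
    ``weights`` maps each deviant bin to a release amplitude fraction, and
    ``release_profile`` names the archetype the weights realize.
    """

    amplitude: float = 1.0
    adapt_decay: float = 0.5
    adapt_floor: float = 0.1
    release_profile: str = "graded_linear"
    weights: dict[str, float] = field(
        default_factory=lambda: {"SC": 0.4, "C": 0.6, "D": 0.8, "SD": 1.0}
    )
    identity_weight: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.adapt_decay <= 1:
            raise ValueError("adapt_decay must lie in (0, 1]")
        w = [self.weights[b] for b in BIN_LABELS]
        if any(not 0 <= x <= 1 for x in w):
            raise ValueError("profile weights must lie in [0, 1]")
        if self.amplitude != 0 and self.identity_weight > min(w) + 1e-12:
            raise ValueError("identity_weight must not exceed the deviant weights")
        if self.release_profile == "graded_linear" and not (w[0] < w[1] < w[2] < w[3]):
            raise ValueError("graded_linear requires w(SC) < w(C) < w(D) < w(SD)")
        if self.release_profile == "step_sc" and not (
            w[0] < w[1] and w[1] == w[2] == w[3]
        ):
            raise ValueError("step_sc requires w(SC) < w(C) = w(D) = w(SD)")

    @classmethod
    def graded(cls, **kw) -> "VoxelTuningModel":
        return cls(release_profile="graded_linear",
                   weights={"SC": 0.4, "C": 0.6, "D": 0.8, "SD": 1.0}, **kw)

    @classmethod
    def step(cls, **kw) -> "VoxelTuningModel":
        return cls(release_profile="step_sc",
                   weights={"SC": 0.4, "C": 0.85, "D": 0.85, "SD": 0.85}, **kw)

    @classmethod
    def flat(cls, **kw) -> "VoxelTuningModel":
        kw.setdefault("identity_weight", 0.7)
        return cls(release_profile="flat",
                   weights={"SC": 0.7, "C": 0.7, "D": 0.7, "SD": 0.7}, **kw)

    @classmethod
    def silent(cls) -> "VoxelTuningModel":
        return cls(amplitude=0.0, adapt_decay=1.0, release_profile="flat",
                   weights={"SC": 0.0, "C": 0.0, "D": 0.0, "SD": 0.0},
                   identity_weight=0.0)

    def position_amplitude(self, k: int) -> float:
        """Neural amplitude of the k-th adaptor (1-based)."""
        return self.amplitude * max(self.adapt_floor, self.adapt_decay ** (k - 1))

    def event_amplitudes(self) -> np.ndarray:
        """Amplitude per stick regressor: positions 1..9 then SC, C, D, SD, I."""
        pos = [self.position_amplitude(k) for k in range(1, 10)]
        dev = [self.amplitude * self.weights[b] for b in BIN_LABELS]
        return np.array(pos + dev + [self.amplitude * self.identity_weight])


@dataclass
class TuningGrid:
    """Spatial layout of tuning models: an integer label per voxel."""

    shape: tuple[int, int, int]
    labels: np.ndarray                       # 3D int array, 0 = silent
    models: dict[int, VoxelTuningModel]      # label -> model (label 0 implied silent)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def model_for(self, label: int) -> VoxelTuningModel:
        if label == 0:
            return VoxelTuningModel.silent()
        return self.models[label]


GRADED, STEP = 1, 2


def default_tuning_grid(shape: tuple[int, int, int] = (12, 12, 8),
                        graded: VoxelTuningModel | None = None,
                        step: VoxelTuningModel | None = None) -> TuningGrid:
    """12 x 12 x 8 grid with a graded-linear block, a step-like block and
    a silent (non-responsive) remainder."""
    labels = np.zeros(shape, dtype=int)
    nx, ny, nz = shape
    labels[1:nx // 2, 1:ny // 2, 1:nz // 2] = GRADED
    labels[nx // 2 + 1:nx - 1, ny // 2 + 1:ny - 1, nz // 2:nz - 1] = STEP
    return TuningGrid(
        shape=shape,
        labels=labels,
        models={GRADED: graded or VoxelTuningModel.graded(),
                STEP: step or VoxelTuningModel.step()},
    )


# ---------------------------------------------------------------------------
# Nuisance processes and BOLD synthesis
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    ar1_phi: float = 0.3      # lag-1 autocorrelation of the voxel noise
    sigma: float = 0.25       # marginal noise sd (signal units)
    drift_amp: float = 0.3    # sd of the per-voxel linear drift coefficient
    nuisance_amp: float = 0.1  # sd of per-voxel nuisance loadings


STICK_NAMES = [f"adaptor_{k}" for k in range(1, 10)] + [f"deviant_{c}" for c in
                                                        ("SC", "C", "D", "SD", "I")]


def simulate_nuisance(n_vols: int, tr: float, rng: np.random.Generator,
                      n_motion: int = 6, n_physio: int = 18) -> pd.DataFrame:
    """Simulated confounds: random-walk motion traces plus quasi-periodic
    cardiac/respiratory sinusoids with frequency jitter (6 cardiac, 8
    respiratory, 4 cardio-respiratory interaction columns by default)."""
    t = np.arange(n_vols) * tr
    cols, names = [], []
    for m in range(n_motion):
        walk = np.cumsum(rng.normal(0, 1.0, n_vols))
        cols.append(walk)
        names.append(f"motion_{m}")
    n_card = round(n_physio * 6 / 18)
    n_resp = round(n_physio * 8 / 18)
    n_int = n_physio - n_card - n_resp
    card_phase = np.cumsum(2 * np.pi * (1.05 + rng.normal(0, 0.03, n_vols)) * tr)
    resp_phase = np.cumsum(2 * np.pi * (0.3 + rng.normal(0, 0.01, n_vols)) * tr)
    for h in range(max(1, n_card // 2)):
        cols += [np.sin((h + 1) * card_phase), np.cos((h + 1) * card_phase)]
        names += [f"cardiac_sin{h + 1}", f"cardiac_cos{h + 1}"]
    for h in range(max(1, n_resp // 2)):
        cols += [np.sin((h + 1) * resp_phase), np.cos((h + 1) * resp_phase)]
        names += [f"resp_sin{h + 1}", f"resp_cos{h + 1}"]
    for h in range(max(1, n_int // 2)):
        cols += [np.sin(card_phase + (h + 1) * resp_phase),
                 np.cos(card_phase - (h + 1) * resp_phase)]
        names += [f"interact_sin{h + 1}", f"interact_cos{h + 1}"]
    cols = cols[: n_motion + n_physio]
    names = names[: n_motion + n_physio]
    X = np.column_stack(cols)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    return pd.DataFrame(X, columns=names, index=t)


def stick_matrix(events: pd.DataFrame, n_vols: int, tr: float) -> np.ndarray:
    """n_vols x 14 impulse matrix (adaptor positions 1..9, five deviant
    conditions) from an event table whose onsets lie on the tr grid."""
    S = np.zeros((n_vols, len(STICK_NAMES)))
    idx = {name: j for j, name in enumerate(STICK_NAMES)}
    for onset, role, cond in zip(events["onset"], events["stimulus_role"],
                                 events["condition"]):
        v = onset / tr
        if abs(v - round(v)) > 1e-6:
            raise ValueError(f"event onset {onset} s is off the {tr} s acquisition grid")
        v = int(round(v))
        if v >= n_vols:
            raise ValueError(f"event at {onset} s falls outside the run ({n_vols} vols)")
        col = idx[role if role.startswith("adaptor_") else f"deviant_{cond}"]
        S[v, col] += 1.0
    return S


def _ar1_noise(shape: tuple[int, int], phi: float, sigma: float,
               rng: np.random.Generator) -> np.ndarray:
    innov = rng.standard_normal(shape)
    if phi == 0:
        return sigma * innov
    innov *= sigma * np.sqrt(1 - phi ** 2)
    return sp_signal.lfilter([1.0], [1.0, -phi], innov, axis=-1)


def simulate_bold_run(
    events: pd.DataFrame,
    grid: TuningGrid,
    noise: NoiseParams | None = None,
    tr: float = 1.0,
    seed: int | None = None,
    amplitude_scale: float = 1.0,
    n_motion: int = 6,
    n_physio: int = 18,
) -> tuple[VolumeSeries, pd.DataFrame]:
    """Synthesize one 4D BOLD run plus its nuisance regressor matrix.

    The event impulse train of each voxel, weighted by its tuning model's
    position/deviant amplitudes (times ``amplitude_scale``), is convolved
    with the canonical HRF; linear drift, AR(1) noise and nuisance loadings
    are added on top.  Fully reproducible under ``seed``.
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    duration = float(events.attrs.get("run_duration",
                                      events["onset"].iloc[-1] + 17.0))
    n_vols = int(round(duration / tr))
    S = stick_matrix(events, n_vols, tr)
    kernel = double_gamma_hrf(tr)
    C = np.apply_along_axis(lambda c: np.convolve(c, kernel)[:n_vols], 0, S)

    n_vox = int(np.prod(grid.shape))
    flat_labels = grid.labels.reshape(-1)
    amp = np.zeros((len(STICK_NAMES), n_vox))
    for label in np.unique(flat_labels):
        a = grid.model_for(int(label)).event_amplitudes() * amplitude_scale
        amp[:, flat_labels == label] = a[:, None]
    bold = C @ amp  # n_vols x n_vox

    nuis = simulate_nuisance(n_vols, tr, rng, n_motion=n_motion, n_physio=n_physio)
    if noise.nuisance_amp > 0:
        bold += nuis.to_numpy() @ rng.normal(0, noise.nuisance_amp,
                                             (nuis.shape[1], n_vox))
    if noise.drift_amp > 0:
        ramp = np.linspace(-0.5, 0.5, n_vols)
        bold += np.outer(ramp, rng.normal(0, noise.drift_amp, n_vox))
    if noise.sigma > 0:
        bold += _ar1_noise((n_vox, n_vols), noise.ar1_phi, noise.sigma, rng).T

    data = bold.T.reshape(grid.shape + (n_vols,))
    vol = VolumeSeries(data=data, tr=tr, mask=np.ones(grid.shape, dtype=bool))
    return vol, nuis


def null_tuning_grid(shape: tuple[int, int, int] = (6, 6, 6),
                     amplitude: float = 1.0) -> TuningGrid:
    """Grid of uniformly responsive voxels with no adaptation and flat
    tuning — the null condition for calibration studies.  Every stimulus
    (adaptor, deviant or identity) evokes the same amplitude, so no
    position or condition contrast carries signal."""
    labels = np.ones(shape, dtype=int)
    model = VoxelTuningModel(
        amplitude=amplitude, adapt_decay=1.0, adapt_floor=1.0,
        release_profile="flat",
        weights={"SC": 1.0, "C": 1.0, "D": 1.0, "SD": 1.0}, identity_weight=1.0)
    return TuningGrid(shape=shape, labels=labels, models={1: model})


def scaled_grid(grid: TuningGrid, scale: float) -> TuningGrid:
    """A copy of ``grid`` with every model amplitude multiplied by ``scale``."""
    return TuningGrid(
        shape=grid.shape,
        labels=grid.labels,
        models={k: replace(m, amplitude=m.amplitude * scale)
                for k, m in grid.models.items()},
    )
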