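"""Trial-sequence generation for the behavioral and fMRI adaptation experiments.

A trial is an adaptation sequence — five to nine exemplars of one object
type — followed by a few presentations of a deviant object drawn from one
of five conditions: the four similarity bins (SC, C, D, SD) or the Identity
condition (a different exemplar of the adapted object itself).

The behavioral design fully crosses adaptors x adaptation lengths x deviant
conditions x repetitions (defaults: 10 x 5 x 5 x 2 = 500 trials, so each
deviant condition occurs 100 times).  An fMRI run presents every
adaptor-deviant pair once (50 trials, 10 per deviant condition and 10 per
adaptation length), flanked by 16 s fixation periods, with every stimulus
on screen for 500 ms followed by a 500 ms blank.

Trial order is pseudo-random: a seeded shuffle constrained so the same
adaptor object never occupies two consecutive trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .norms import BIN_LABELS, CONDITIONS, SimilarityBinning

EVENT_COLUMNS = ["onset", "duration", "trial_type", "trial_index", "stimulus_role",
                 "condition", "adaptor_object", "deviant_object"]

DEFAULT_LENGTHS = (5, 6, 7, 8, 9)


@dataclass
class TrialSpec:
    adaptor_object: str
    adaptation_length: int
    deviant_condition: str  # SC, C, D, SD or I
    deviant_object: str
    n_deviant_presentations: int

    def __post_init__(self) -> None:
        if not 5 <= self.adaptation_length <= 9:
            raise ValueError("adaptation_length must lie in [5, 9]")
        if self.deviant_condition not in CONDITIONS:
            raise ValueError(f"unknown deviant condition {self.deviant_condition!r}")
        if self.deviant_condition == "I" and self.deviant_object != self.adaptor_object:
            raise ValueError("Identity deviant must be the adaptor object type")


def _deviant_for(binning: SimilarityBinning, condition: str) -> str:
    if condition == "I":
        return binning.adaptor_id
    return binning.deviants[condition]


def _order_without_adjacent_repeats(trials: list[TrialSpec], rng: np.random.Generator,
                                    max_restarts: int = 200) -> list[TrialSpec]:
    """Seeded shuffle such that consecutive trials never share an adaptor.

    Sequential sampling among admissible remaining trials, restarting on a
    dead end; with balanced designs (each adaptor <= half the trials) the
    expected number of restarts is small.
    """
    if len({t.adaptor_object for t in trials}) <= 1:
        pool = list(trials)
        rng.shuffle(pool)  # type: ignore[arg-type]
        return pool
    for _ in range(max_restarts):
        pool = list(trials)
        rng.shuffle(pool)  # type: ignore[arg-type]
        out: list[TrialSpec] = []
        ok = True
        while pool:
            prev = out[-1].adaptor_object if out else None
            choices = [k for k, t in enumerate(pool) if t.adaptor_object != prev]
            if not choices:
                ok = False
                break
            k = choices[rng.integers(len(choices))]
            out.append(pool.pop(k))
        if ok:
            return out
    raise RuntimeError("could not order trials without adjacent adaptor repeats")


def build_behavioral_design(
    binnings: list[SimilarityBinning],
    n_adaptors: int = 10,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    reps_per_cell: int = 2,
    deviant_reps: int = 3,
    seed: int | None = None,
) -> list[TrialSpec]:
    """Fully crossed behavioral design, pseudo-randomly ordered.

    Yields n_adaptors * len(lengths) * 5 conditions * reps_per_cell trials
    (500 under defaults), each deviant condition appearing
    n_adaptors * len(lengths) * reps_per_cell times (100 under defaults).
    """
    by_adaptor = {b.adaptor_id: b for b in binnings}
    adaptors = list(by_adaptor)[:n_adaptors]
    if len(adaptors) < n_adaptors:
        raise ValueError(
            f"need similarity binnings for {n_adaptors} adaptors, got {len(by_adaptor)}"
        )
    rng = np.random.default_rng(seed)
    trials = [
        TrialSpec(
            adaptor_object=a,
            adaptation_length=length,
            deviant_condition=cond,
            deviant_object=_deviant_for(by_adaptor[a], cond),
            n_deviant_presentations=deviant_reps,
        )
        for a in adaptors
        for length in lengths
        for cond in CONDITIONS
        for _ in range(reps_per_cell)
    ]
    return _order_without_adjacent_repeats(trials, rng)


def events_from_trials(
    trials: list[TrialSpec],
    stim_dur: float = 0.5,
    isi: float = 0.5,
    lead_fix: float = 16.0,
    trail_fix: float = 16.0,
) -> pd.DataFrame:
    """Lay trials out on the time axis as one event row per stimulus."""
    rows = []
    t = float(lead_fix)
    soa = stim_dur + isi
    for idx, trial in enumerate(trials):
        for k in range(1, trial.adaptation_length + 1):
            rows.append((t, stim_dur, f"adaptor_{k}", idx, f"adaptor_{k}",
                         trial.deviant_condition, trial.adaptor_object,
                         trial.deviant_object))
            t += soa
        for _ in range(trial.n_deviant_presentations):
            rows.append((t, stim_dur, f"deviant_{trial.deviant_condition}", idx,
                         "deviant", trial.deviant_condition, trial.adaptor_object,
                         trial.deviant_object))
            t += soa
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events.attrs["run_duration"] = t + trail_fix
    return events


def build_fmri_run(
    binnings: list[SimilarityBinning],
    trials_per_run: int = 50,
    stim_dur: float = 0.5,
    isi: float = 0.5,
    lead_fix: float = 16.0,
    trail_fix: float = 16.0,
    deviant_reps: int = 2,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    seed: int | None = None,
) -> pd.DataFrame:
    """One fMRI run: every adaptor-deviant pair once, lengths balanced.

    Under defaults (10 adaptors): 50 trials, 10 per deviant condition, 10
    per adaptation length, first stimulus at 16.0 s, each stimulus 500 ms +
    500 ms blank, and a trailing 16 s fixation (recorded in
    ``events.attrs['run_duration']``).
    """
    n_cells = len(CONDITIONS) * len(lengths)
    if trials_per_run % n_cells:
        raise ValueError(
            f"trials_per_run={trials_per_run} does not divide into the "
            f"{len(CONDITIONS)}x{len(lengths)} condition-by-length cells"
        )
    reps = trials_per_run // n_cells  # trials per (condition, length) cell
    n_adaptors = trials_per_run // len(CONDITIONS)
    adaptors = [b.adaptor_id for b in binnings][:n_adaptors]
    if len(adaptors) < n_adaptors:
        raise ValueError(f"need {n_adaptors} binnings for {trials_per_run} trials")
    by_adaptor = {b.adaptor_id: b for b in binnings}
    rng = np.random.default_rng(seed)

    trials: list[TrialSpec] = []
    for cond in CONDITIONS:
        # every adaptor is paired with this condition's deviant exactly once
        # (all adaptor-deviant pairs in the run); lengths are balanced within
        # condition so each length appears trials_per_run/len(lengths) times
        cell_lengths = [length for length in lengths for _ in range(reps)]
        rng.shuffle(cell_lengths)
        for a, length in zip(adaptors, cell_lengths):
            trials.append(
                TrialSpec(
                    adaptor_object=a,
                    adaptation_length=length,
                    deviant_condition=cond,
                    deviant_object=_deviant_for(by_adaptor[a], cond),
                    n_deviant_presentations=deviant_reps,
                )
            )
    ordered = _order_without_adjacent_repeats(trials, rng)
    return events_from_trials(ordered, stim_dur, isi, lead_fix, trail_fix)


def design_summary(trials: list[TrialSpec]) -> dict:
    counts_cond: dict[str, int] = {c: 0 for c in CONDITIONS}
    counts_len: dict[int, int] = {}
    for t in trials:
        counts_cond[t.deviant_condition] += 1
        counts_len[t.adaptation_length] = counts_len.get(t.adaptation_length, 0) + 1
    return {
        "n_trials": len(trials),
        "per_condition": counts_cond,
        "per_length": {str(k): v for k, v in sorted(counts_len.items())},
    }


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Write a BIDS-style events table (onset, duration, trial_type, ...)."""
    if len(events) and (events["duration"] <= 0).any():
        raise ValueError("refusing to write events with non-positive durations")
    if len(events) and (np.diff(events["onset"].to_numpy()) <= 0).any():
        raise ValueError("refusing to write events with non-increasing onsets")
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    if len(events) and (np.diff(events["onset"].to_numpy()) <= 0).any():
        raise ValueError(f"non-monotone onsets in {path}")
    return events
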