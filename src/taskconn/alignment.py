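"""Motion censoring and phase-aligned replica-frame stacking.

A widely spaced design separates stimuli by ~20 s, so the 8 frames (TR
2.5 s) following each stimulus onset sample one uncontaminated hemodynamic
response.  Frames occupying the same within-trial position ("replica
frames") across trials of the same stimulus type are concatenated into a
regions x frames stack, one stack per (frame index, stimulus) condition;
connectivity is then estimated per stack.

Censoring removes frames whose frame displacement (FD) exceeds a threshold.
A trial is eligible only if it runs the full 8 frames and the preceding
trial started at least 20 s earlier (catch trials and their successors are
thereby excluded).  Participants enter the group analysis only if every one
of the 16 conditions retains at least 40 usable frames; each stack is then
randomly subsampled to exactly that count so all connectotypes use the same
amount of data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from taskconn.synthetic import STIMULI, ParticipantSession

#: Conventional head radius (mm) used to convert rotations to arc displacement.
HEAD_RADIUS_MM = 50.0


class InsufficientFramesError(ValueError):
    """A condition has fewer usable frames than required; the participant
    (or condition) must be excluded rather than fitted on less data."""


@dataclass
class MotionTrace:
    """Per-frame frame-displacement values (mm) for one run."""

    fd: np.ndarray
    source: str = "precomputed"

    def __post_init__(self):
        self.fd = np.asarray(self.fd, dtype=float)
        if np.any(self.fd < 0):
            raise ValueError("frame displacement must be non-negative")


@dataclass
class FrameStack:
    """Replica frames for one (frame index, stimulus) condition.

    ``provenance[j] = (run, trial, global frame index)`` for column ``j``.
    """

    condition: tuple[int, str]
    data: np.ndarray
    provenance: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]


def compute_fd(six_params) -> MotionTrace:
    """Frame displacement from six rigid-body parameters.

    FD[t] is the absolute sum of the frame-to-frame changes in the three
    translations (mm) and the three rotations, the latter converted to arc
    displacement on a 50 mm sphere.  FD of the first frame is zero.
    """
    arr = np.asarray(six_params, dtype=float)
    if isinstance(six_params, pd.DataFrame):
        arr = six_params.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"expected 6 motion parameter columns, got shape {arr.shape}")
    delta = np.abs(np.diff(arr, axis=0))
    delta[:, 3:] *= HEAD_RADIUS_MM
    fd = np.concatenate([[0.0], delta.sum(axis=1)])
    return MotionTrace(fd=fd, source="six-parameter")


def censor_mask(trace: MotionTrace, threshold_mm: float = 0.3,
                keep_equal: bool = False) -> np.ndarray:
    """Boolean keep-mask: frames with FD below the threshold survive.

    The comparison is strict by default (a frame exactly at the threshold is
    dropped); set ``keep_equal`` to keep it.  The first frame of a run has
    FD 0 and is always kept.
    """
    if threshold_mm <= 0:
        raise ValueError("FD threshold must be positive")
    if keep_equal:
        return trace.fd <= threshold_mm
    return trace.fd < threshold_mm


def eligible_trials(events: pd.DataFrame, tr_seconds: float = 2.5,
                    trial_frames: int = 8, min_gap_seconds: float = 20.0,
                    run_duration_s: float | None = None) -> pd.DataFrame:
    """Trials usable for phase-aligned stacking.

    A trial is eligible iff it has the full ``trial_frames`` frames before
    the next onset (or the run end) *and* the preceding trial started at
    least ``min_gap_seconds`` earlier (no constraint for the first trial).
    Catch trials fail the first test; trials following a catch fail the
    second.  Returns the eligible rows with their original integer position
    in a ``trial`` column.
    """
    onsets = events["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("events must be sorted by onset")
    if run_duration_s is None:
        run_duration_s = events.attrs.get("run_duration_s")
    if run_duration_s is None:
        raise ValueError("run duration required (pass run_duration_s or set events.attrs)")
    tol = 1e-9
    full_length = np.append(np.diff(onsets), run_duration_s - onsets[-1]) \
        >= trial_frames * tr_seconds - tol
    gap_ok = np.concatenate([[True], np.diff(onsets) >= min_gap_seconds - tol])
    keep = full_length & gap_ok
    out = events.loc[keep].copy()
    out["trial"] = np.flatnonzero(keep)
    return out


def stack_replicas(timeseries: np.ndarray, trials: pd.DataFrame, frame_index: int,
                   keep_mask: np.ndarray, tr_seconds: float = 2.5,
                   trial_frames: int = 8, run: int = 0,
                   stimulus: str | None = None) -> FrameStack:
    """Stack the ``frame_index``-th frame of each eligible trial in one run.

    A trial contributes a column iff its frame at that phase survives the
    keep mask; columns never cross trial or run boundaries because trials
    are pre-screened for full length.
    """
    if not 1 <= frame_index <= trial_frames:
        raise ValueError(f"frame_index must be in 1..{trial_frames}, got {frame_index}")
    timeseries = np.asarray(timeseries)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    onsets = trials["onset"].to_numpy(dtype=float)
    trial_ids = trials["trial"].to_numpy() if "trial" in trials else np.arange(len(trials))
    frames = np.rint(onsets / tr_seconds).astype(int) + frame_index - 1
    ok = frames < timeseries.shape[1]
    ok[ok] &= keep_mask[frames[ok]]
    if stimulus is not None:
        ok &= trials["trial_type"].to_numpy() == stimulus
    frames, trial_ids = frames[ok], trial_ids[ok]
    data = timeseries[:, frames] if frames.size else np.empty((timeseries.shape[0], 0))
    prov = [(run, int(t), int(f)) for t, f in zip(trial_ids, frames)]
    return FrameStack(condition=(frame_index, stimulus), data=data, provenance=prov)


def concat_stacks(stacks: list[FrameStack]) -> FrameStack:
    """Concatenate same-condition stacks from different runs."""
    conditions = {s.condition for s in stacks}
    if len(conditions) != 1:
        raise ValueError(f"cannot concatenate stacks of different conditions: {conditions}")
    data = np.concatenate([s.data for s in stacks], axis=1)
    prov = [p for s in stacks for p in s.provenance]
    return FrameStack(condition=stacks[0].condition, data=data, provenance=prov)


def condition_stacks(session: ParticipantSession, keep_masks: list[np.ndarray],
                     trial_frames: int = 8,
                     min_gap_seconds: float = 20.0) -> dict[tuple[int, str], FrameStack]:
    """All (frame, stimulus) stacks for one participant, pooled over runs."""
    tr = session.tr_seconds
    per_run_trials = [
        eligible_trials(ev, tr, trial_frames, min_gap_seconds)
        for ev in session.events
    ]
    stacks = {}
    for f in range(1, trial_frames + 1):
        for stim in STIMULI:
            parts = [
                stack_replicas(session.timeseries[r], per_run_trials[r], f,
                               keep_masks[r], tr, trial_frames, run=r,
                               stimulus=stim)
                for r in range(len(session.timeseries))
            ]
            stacks[(f, stim)] = concat_stacks(parts)
    return stacks


def sample_frames(stack: FrameStack, n: int = 40, seed=0) -> FrameStack:
    """Subsample exactly ``n`` columns uniformly without replacement.

    Selection is random rather than lowest-FD, to avoid biasing conditions
    toward systematically low-motion trials.  Deterministic under ``seed``.
    Raises :class:`InsufficientFramesError` when fewer than ``n`` columns
    are available (the participant/condition must then be excluded).
    """
    if stack.n_frames < n:
        raise InsufficientFramesError(
            f"condition {stack.condition}: {stack.n_frames} usable frames < {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = np.sort(rng.choice(stack.n_frames, size=n, replace=False))
    return FrameStack(condition=stack.condition, data=stack.data[:, idx],
                      provenance=[stack.provenance[i] for i in idx])


def participant_passes(stacks: dict[tuple[int, str], FrameStack],
                       min_frames: int = 40, trial_frames: int = 8) -> bool:
    """True iff every one of the 2 * trial_frames conditions has enough frames."""
    for f in range(1, trial_frames + 1):
        for stim in STIMULI:
            if (f, stim) not in stacks:
                raise KeyError(f"missing condition ({f}, {stim!r})")
    return all(stacks[(f, stim)].n_frames >= min_frames
               for f in range(1, trial_frames + 1) for stim in STIMULI)


def condition_seed(master_seed: int, participant_id: str, frame: int,
                   stimulus: str) -> int:
    """Stable per-(participant, condition) seed for frame subsampling.

    Hash-derived so adding or removing a participant never reshuffles the
    selections of the others.
    """
    digest = hashlib.sha256(
        f"{master_seed}|{participant_id}|{frame}|{stimulus}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_fd(path) -> MotionTrace:
    """Read a precomputed one-column FD trace (TSV, one value per frame)."""
    return MotionTrace(fd=np.loadtxt(path, ndmin=1), source="precomputed")


def load_timeseries(path, drop_first: int = 0) -> np.ndarray:
    """Read a headerless regions x frames TSV; optionally drop the first
    ``drop_first`` steady-state frames (for externally acquired data)."""
    ts = np.loadtxt(path, delimiter="\t", ndmin=2)
    return ts[:, drop_first:] if drop_first else ts
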