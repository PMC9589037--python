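"""Seeded synthetic BOLD cohort generator.

Emulates a widely spaced lexical-decision task fMRI study: TR 2.5 s, each
trial one 2.5 s stimulus frame followed by 17.5 s of fixation (8 frames =
20 s per trial), 10 runs of 24 stimuli (18 pseudowords, 6 words) with 3
randomly placed catch trials per run whose inter-trial interval is shortened
to 5, 7.5 or 10 s.

The signal model is the one the connectotype estimator assumes: at a frame
with within-trial phase f and stimulus s, the region vector satisfies

    x = B(f, s) x + eta,   eta ~ N(hrf(offset) * a * gain_s, sigma^2 I)

i.e. x = (I - B)^-1 eta, where B(f, s) equals a base matrix B0 everywhere
except a planted network-pair block scaled by a profile g(f, s).  With
g == 1 the connectivity is constant across conditions (null configuration);
evoked activity can still differ by stimulus through the gain, which is what
separates co-activation from connectivity change.

Head motion is simulated directly as a frame-displacement-like positive
trace (lognormal body plus occasional spikes); a six-parameter mode exists
to exercise the FD computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from taskconn.parcellation import (
    DEFAULT_INCLUDED_NETWORKS,
    NetworkPair,
    ParcellationSchema,
    enumerate_pairs,
    gordon_schema,
    small_schema,
)

#: Stimulus classes, in canonical order (index 0/1 throughout the package).
STIMULI = ("word", "pseudoword")

BASELINE = 0  # phase code for frames outside any trial window


@dataclass(frozen=True)
class TaskDesign:
    """Timing of the widely spaced lexical-decision design."""

    tr_seconds: float = 2.5
    n_runs: int = 10
    trials_per_run: int = 24
    pseudowords_per_run: int = 18
    words_per_run: int = 6
    catch_per_run: int = 3
    trial_frames: int = 8
    catch_iti_choices_seconds: tuple[float, ...] = (5.0, 7.5, 10.0)

    def __post_init__(self):
        if self.words_per_run + self.pseudowords_per_run != self.trials_per_run:
            raise ValueError("words_per_run + pseudowords_per_run must equal trials_per_run")
        if self.catch_per_run > self.trials_per_run:
            raise ValueError("catch_per_run cannot exceed trials_per_run")

    @property
    def trial_duration_seconds(self) -> float:
        """Stimulus frame plus fixation: trial_frames * TR (20 s by default)."""
        return self.trial_frames * self.tr_seconds

    def as_dict(self) -> dict:
        return {
            "tr_seconds": self.tr_seconds, "n_runs": self.n_runs,
            "trials_per_run": self.trials_per_run,
            "pseudowords_per_run": self.pseudowords_per_run,
            "words_per_run": self.words_per_run,
            "catch_per_run": self.catch_per_run,
            "trial_frames": self.trial_frames,
            "catch_iti_choices_seconds": list(self.catch_iti_choices_seconds),
        }


@dataclass(frozen=True)
class MotionConfig:
    """Parameters of the simulated head-motion trace.

    ``mode="fd"`` draws the frame displacement directly: a lognormal body
    (median ``body_median_mm``, log-sd ``body_sigma``) plus Bernoulli spikes
    of probability ``spike_prob`` and lognormal magnitude around
    ``spike_median_mm``.  ``mode="six"`` draws a six-parameter random walk
    (translations mm, rotations rad) for testing the FD computation.
    """

    mode: str = "fd"
    body_median_mm: float = 0.1
    body_sigma: float = 0.5
    spike_prob: float = 0.05
    spike_median_mm: float = 0.6
    spike_sigma: float = 0.4
    six_step_sd_mm: float = 0.03
    six_step_sd_rad: float = 0.0005

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GroundTruth:
    """Condition-dependent generative connectivity for one cohort."""

    schema: ParcellationSchema
    base_connectivity: np.ndarray          # B0, zero diagonal
    interaction_pair: NetworkPair | None   # block scaled by the profile
    interaction_profile: np.ndarray        # g, shape (trial_frames, 2): word, PW
    activation_map: np.ndarray             # per-region evoked amplitude a
    stim_gain: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 1.0
    subject_sd: float = 0.1                # relative jitter of nonzero B0 cells
    ar_coeff: float = 0.0                  # optional AR(1) innovations within trials

    def __post_init__(self):
        b = np.asarray(self.base_connectivity, dtype=float)
        if b.shape != (self.schema.n_rois, self.schema.n_rois):
            raise ValueError("base_connectivity shape does not match schema")
        if np.any(np.diag(b) != 0):
            raise ValueError("base_connectivity must have a zero diagonal")
        self.base_connectivity = b
        self.interaction_profile = np.asarray(self.interaction_profile, dtype=float)
        self.activation_map = np.asarray(self.activation_map, dtype=float)

    @property
    def trial_frames(self) -> int:
        return self.interaction_profile.shape[0]

    def as_dict(self) -> dict:
        """Hash-stable summary of the configuration."""
        return {
            "n_rois": self.schema.n_rois,
            "b0_sha": hashlib.sha256(self.base_connectivity.tobytes()).hexdigest()[:16],
            "pair": None if self.interaction_pair is None else self.interaction_pair.name,
            "profile": self.interaction_profile.tolist(),
            "activation": self.activation_map.tolist(),
            "stim_gain": list(self.stim_gain),
            "noise_sd": self.noise_sd,
            "subject_sd": self.subject_sd,
            "ar_coeff": self.ar_coeff,
        }


@dataclass
class ParticipantSession:
    """One simulated (or loaded) participant: timeseries + events + motion."""

    participant_id: str
    timeseries: list[np.ndarray]      # per run, regions x frames
    events: list[pd.DataFrame]        # per run: onset, duration, trial_type, is_catch
    fd: list[np.ndarray]              # per run frame displacement (mm)
    run_durations: list[float]        # seconds
    tr_seconds: float
    seed: int | None = None
    six_params: list[pd.DataFrame] | None = None


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def simulate_design(design: TaskDesign, seed) -> list[pd.DataFrame]:
    """Per-run events tables with randomized stimulus order and catch placement.

    Non-catch trials are separated by exactly ``trial_duration_seconds``;
    a catch trial is followed by its shortened ITI instead.  Each table
    carries the run duration in ``attrs["run_duration_s"]`` (the run extends
    one full trial length past the last onset).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    runs = []
    for _ in range(design.n_runs):
        types = np.array(
            ["word"] * design.words_per_run
            + ["pseudoword"] * design.pseudowords_per_run
        )
        rng.shuffle(types)
        catch_idx = rng.choice(design.trials_per_run, size=design.catch_per_run,
                               replace=False)
        is_catch = np.zeros(design.trials_per_run, dtype=bool)
        is_catch[catch_idx] = True
        onsets = np.empty(design.trials_per_run)
        t = 0.0
        for i in range(design.trials_per_run):
            onsets[i] = t
            if is_catch[i]:
                iti = rng.choice(design.catch_iti_choices_seconds)
                t += design.tr_seconds + iti
            else:
                t += design.trial_duration_seconds
        table = pd.DataFrame({
            "onset": onsets,
            "duration": np.full(design.trials_per_run, design.tr_seconds),
            "trial_type": types,
            "is_catch": is_catch,
        })
        table.attrs["run_duration_s"] = float(onsets[-1] + design.trial_duration_seconds)
        runs.append(table)
    return runs


# --------------------------------------------------------------------------
# hemodynamic response
# --------------------------------------------------------------------------

# Double-gamma parameters: response gamma (shape, scale) peaking at 5.4 s,
# undershoot gamma down-weighted by the response/undershoot ratio.
_HRF_RESPONSE = (7.0, 0.9)
_HRF_UNDERSHOOT = (15.0, 0.9)
_HRF_RATIO = 1 / 6


def canonical_hrf(t) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    Peaks between 5 and 7 s after stimulus onset and is back within 5% of
    zero by 20 s, matching the stereotyped BOLD response to a brief event.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("the HRF is only defined for t >= 0")
    a1, b1 = _HRF_RESPONSE
    a2, b2 = _HRF_UNDERSHOOT
    h = sps.gamma.pdf(t, a1, scale=b1) - _HRF_RATIO * sps.gamma.pdf(t, a2, scale=b2)
    grid = np.arange(0, 30, 0.01)
    peak = np.max(sps.gamma.pdf(grid, a1, scale=b1)
                  - _HRF_RATIO * sps.gamma.pdf(grid, a2, scale=b2))
    return h / peak


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def interaction_profile(trial_frames: int = 8, amplitude: float = 1.0,
                        shape=(0.0, 0.25, 1.0, 1.0, 0.25, 0.0, 0.0, 0.0)) -> np.ndarray:
    """Planted g(frame, stimulus): word block scaled up at mid-trial frames.

    g(f, word) = 1 + amplitude * shape[f]; g(f, PW) = 1.  The default shape
    concentrates the word/pseudoword connectivity difference at frames 3-4,
    around the hemodynamic peak.
    """
    shape = np.asarray(shape, dtype=float)
    if shape.shape[0] != trial_frames:
        raise ValueError("profile shape length must equal trial_frames")
    g = np.ones((trial_frames, 2))
    g[:, 0] = 1.0 + amplitude * shape
    return g


def default_ground_truth(
    schema: ParcellationSchema | None = None,
    interaction: tuple[str, str] | None = ("CiP", "FrP"),
    amplitude: float = 1.0,
    spectral_target: float = 0.6,
    trial_frames: int = 8,
    tr_seconds: float = 2.5,
    seed: int = 0,
    **kwargs,
) -> GroundTruth:
    """Build a cohort ground truth with network-structured base connectivity.

    B0 has dense within-network blocks, a sparse random background, and a
    strengthened block at the planted pair, then is rescaled so the largest
    spectral radius over all conditions equals ``spectral_target``.
    """
    if schema is None:
        schema = small_schema()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB0)))
    p = schema.n_rois
    b0 = np.zeros((p, p))
    background = (rng.random((p, p)) < 0.10) * rng.normal(0.0, 0.05, (p, p))
    b0 += background
    for net in schema.network_names:
        idx = schema.indices_of(net)
        block = rng.normal(0.12, 0.03, (len(idx), len(idx)))
        b0[np.ix_(idx, idx)] = block
    pair = None
    if interaction is not None:
        pair = next(
            q for q in enumerate_pairs(schema, list(schema.network_names))
            if (q.target_network, q.source_network) == tuple(interaction)
        )
        conn = np.asarray(pair.connections)
        b0[conn[:, 0], conn[:, 1]] = rng.normal(0.15, 0.03, len(conn))
    np.fill_diagonal(b0, 0.0)

    profile = interaction_profile(trial_frames, amplitude)
    activation = np.full(p, 0.3)
    try:
        activation[schema.included_indices(
            [n for n in DEFAULT_INCLUDED_NETWORKS if n in schema.network_names])] = 1.0
    except KeyError:
        activation[:] = 1.0

    gt = GroundTruth(
        schema=schema, base_connectivity=b0, interaction_pair=pair,
        interaction_profile=profile, activation_map=activation, **kwargs,
    )
    radius = max(
        _spectral_radius(ground_truth_matrix(gt, f, s))
        for f in range(1, trial_frames + 1) for s in STIMULI
    )
    gt.base_connectivity = b0 * (spectral_target / radius)
    return gt


def activation_only_ground_truth(word_gain: float = 1.5, **kwargs) -> GroundTruth:
    """Null-connectivity cohort whose stimuli differ only in evoked amplitude.

    g == 1 everywhere (no connectivity interaction) but words evoke a larger
    mean response; used to check that the pipeline does not mistake
    co-activation for connectivity change.
    """
    gt = default_ground_truth(amplitude=0.0, **kwargs)
    gt.stim_gain = (word_gain, 1.0)
    return gt


def _spectral_radius(b: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(b))))


def random_connectivity(n_regions: int, spectral_radius: float = 0.5,
                        symmetric: bool = True, scale: float = 0.15,
                        seed=0) -> np.ndarray:
    """Dense random connectivity matrix rescaled to a given spectral radius.

    With ``symmetric=True`` the population regression of each region on the
    others recovers the matrix itself (up to a quadratic correction); an
    asymmetric matrix is only identified up to the symmetrization implied
    by the joint precision, so symmetric matrices are the right ground
    truth for parameter-recovery checks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    b = rng.normal(0.0, scale, (n_regions, n_regions))
    if symmetric:
        b = (b + b.T) / 2.0
    np.fill_diagonal(b, 0.0)
    return b * (spectral_radius / _spectral_radius(b))


def ground_truth_matrix(gt: GroundTruth, frame: int, stimulus: str) -> np.ndarray:
    """B(frame, stimulus): B0 with the planted block scaled by g(frame, stimulus)."""
    if not 1 <= frame <= gt.trial_frames:
        raise ValueError(f"frame must be in 1..{gt.trial_frames}, got {frame}")
    s = STIMULI.index(stimulus)
    b = gt.base_connectivity.copy()
    if gt.interaction_pair is not None:
        conn = np.asarray(gt.interaction_pair.connections)
        b[conn[:, 0], conn[:, 1]] *= gt.interaction_profile[frame - 1, s]
    return b


def sample_linear_system(b: np.ndarray, n_frames: int, noise_sd: float = 1.0,
                         mean: np.ndarray | None = None, seed=0) -> np.ndarray:
    """Draw frames x = (I - B)^-1 eta, eta ~ N(mean, noise_sd^2 I).

    Returns a regions x n_frames matrix.  Raises if the implicit system is
    not solvable (spectral radius of B >= 1).
    """
    b = np.asarray(b, dtype=float)
    if _spectral_radius(b) >= 1:
        raise ValueError("spectral radius of B must be < 1 for a solvable system")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = b.shape[0]
    eta = noise_sd * rng.standard_normal((p, n_frames))
    if mean is not None:
        eta += np.asarray(mean, dtype=float)[:, None]
    return np.linalg.solve(np.eye(p) - b, eta)


# --------------------------------------------------------------------------
# session simulation
# --------------------------------------------------------------------------

def _frame_phases(events: pd.DataFrame, n_frames: int, tr: float,
                  trial_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Phase (1..trial_frames, 0 = baseline) and stimulus index per frame."""
    phase = np.zeros(n_frames, dtype=int)
    stim = np.full(n_frames, -1, dtype=int)
    onsets = events["onset"].to_numpy()
    types = events["trial_type"].to_numpy()
    bounds = np.append(onsets, np.inf)
    for i, onset in enumerate(onsets):
        start = int(round(onset / tr))
        stop_t = min(bounds[i + 1], onset + trial_frames * tr)
        stop = min(int(round(stop_t / tr)), n_frames)
        for f, frame in enumerate(range(start, stop), start=1):
            phase[frame] = f
            stim[frame] = STIMULI.index(types[i])
    return phase, stim


def _simulate_fd(n_frames: int, cfg: MotionConfig, rng) -> np.ndarray:
    fd = np.exp(rng.normal(np.log(cfg.body_median_mm), cfg.body_sigma, n_frames))
    spikes = rng.random(n_frames) < cfg.spike_prob
    fd[spikes] += np.exp(rng.normal(np.log(cfg.spike_median_mm), cfg.spike_sigma,
                                    int(spikes.sum())))
    fd[0] = 0.0
    return fd


def _simulate_six_params(n_frames: int, cfg: MotionConfig, rng) -> pd.DataFrame:
    steps = np.column_stack([
        rng.normal(0, cfg.six_step_sd_mm, (n_frames, 3)),
        rng.normal(0, cfg.six_step_sd_rad, (n_frames, 3)),
    ])
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    return pd.DataFrame(params, columns=["trans_x", "trans_y", "trans_z",
                                         "rot_x", "rot_y", "rot_z"])


def simulate_session(
    design: TaskDesign,
    gt: GroundTruth,
    motion: MotionConfig | None = None,
    seed: int = 0,
    participant_id: str = "sub-01",
) -> ParticipantSession:
    """Simulate one participant: timeseries, events and motion for all runs.

    Each acquired frame is assigned a phase (its position within the active
    trial, or baseline) and drawn from the corresponding condition's linear
    system; the evoked mean follows the HRF sampled at the frame offset.
    Baseline frames use B0 and zero mean.  Fully deterministic under
    (seed, configuration).
    """
    if motion is None:
        motion = MotionConfig()
    ss = np.random.SeedSequence(seed)
    design_seed, subj_seed, noise_seed, motion_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    events = simulate_design(design, design_seed)
    subj_rng = np.random.default_rng(np.random.SeedSequence(subj_seed))
    noise_rng = np.random.default_rng(np.random.SeedSequence(noise_seed))
    motion_rng = np.random.default_rng(np.random.SeedSequence(motion_seed))

    # participant-level perturbation of the nonzero base-connectivity cells
    b0 = gt.base_connectivity.copy()
    nz = b0 != 0
    b0[nz] *= 1.0 + gt.subject_sd * subj_rng.standard_normal(int(nz.sum()))
    gt_subj = replace_base(gt, b0)

    p = gt.schema.n_rois
    hrf_at = canonical_hrf(np.arange(design.trial_frames) * design.tr_seconds)

    # pre-factor (I - B) per condition; phase 0 = baseline
    solves: dict[tuple[int, int], np.ndarray] = {}
    for f in range(design.trial_frames + 1):
        for s, _ in enumerate(STIMULI):
            if f == 0:
                b = gt_subj.base_connectivity
            else:
                b = ground_truth_matrix(gt_subj, f, STIMULI[s])
            radius = _spectral_radius(b)
            if radius >= 1:
                cond = "baseline" if f == 0 else f"frame {f}, {STIMULI[s]}"
                raise ValueError(
                    f"spectral radius {radius:.3f} >= 1 for condition {cond}")
            solves[(f, s)] = np.linalg.inv(np.eye(p) - b)
            if f == 0:
                break  # baseline is stimulus-independent; keep only (0, 0)

    timeseries, fd_traces, durations, six_all = [], [], [], []
    for run_events in events:
        duration = run_events.attrs["run_duration_s"]
        n_frames = int(round(duration / design.tr_seconds))
        phase, stim = _frame_phases(run_events, n_frames, design.tr_seconds,
                                    design.trial_frames)
        x = np.zeros((p, n_frames))
        eta = gt.noise_sd * noise_rng.standard_normal((p, n_frames))
        if gt.ar_coeff:
            # AR(1) innovations across consecutive within-trial frames
            rho = gt.ar_coeff
            for t in range(1, n_frames):
                if phase[t] > 1:
                    eta[:, t] = rho * eta[:, t - 1] + np.sqrt(1 - rho**2) * eta[:, t]
        for (f, s), solve in solves.items():
            idx = np.flatnonzero((phase == f) & ((f == 0) | (stim == s)))
            if not idx.size:
                continue
            block = eta[:, idx]
            if f > 0:
                mu = hrf_at[f - 1] * gt.activation_map * gt.stim_gain[s]
                block = block + mu[:, None]
            x[:, idx] = solve @ block
        timeseries.append(x)
        durations.append(duration)
        if motion.mode == "six":
            six = _simulate_six_params(n_frames, motion, motion_rng)
            six_all.append(six)
            from taskconn.alignment import compute_fd
            fd_traces.append(compute_fd(six).fd)
        else:
            fd_traces.append(_simulate_fd(n_frames, motion, motion_rng))

    return ParticipantSession(
        participant_id=participant_id, timeseries=timeseries, events=events,
        fd=fd_traces, run_durations=durations, tr_seconds=design.tr_seconds,
        seed=seed, six_params=six_all or None,
    )


def replace_base(gt: GroundTruth, b0: np.ndarray) -> GroundTruth:
    """Copy of the ground truth with a different base matrix."""
    return GroundTruth(
        schema=gt.schema, base_connectivity=b0,
        interaction_pair=gt.interaction_pair,
        interaction_profile=gt.interaction_profile,
        activation_map=gt.activation_map, stim_gain=gt.stim_gain,
        noise_sd=gt.noise_sd, subject_sd=gt.subject_sd, ar_coeff=gt.ar_coeff,
    )


def simulate_cohort(
    design: TaskDesign,
    gt: GroundTruth,
    motion: MotionConfig | None = None,
    n_participants: int = 15,
    master_seed: int = 0,
    screen: bool = True,
    fd_threshold: float = 0.3,
    frames_per_condition: int = 40,
    max_attempts: int = 200,
) -> list[ParticipantSession]:
    """Simulate a cohort of surviving participants.

    With ``screen=True`` (default) candidates are drawn until
    ``n_participants`` pass the inclusion rule (>= ``frames_per_condition``
    usable replica frames in every condition at ``fd_threshold``), mirroring
    a study that recruits more participants than survive motion censoring;
    ``n_participants`` is the surviving sample size.  Candidate seeds are
    derived per attempt from the master seed, so cohorts are reproducible
    and adding a participant never reshuffles the others.
    """
    from taskconn.alignment import censor_mask, condition_stacks, participant_passes

    if motion is None:
        motion = MotionConfig()
    sessions = []
    attempt = 0
    while len(sessions) < n_participants:
        if attempt >= max_attempts:
            raise RuntimeError(
                f"only {len(sessions)}/{n_participants} participants passed "
                f"screening after {max_attempts} attempts")
        seed = int(np.random.SeedSequence((master_seed, attempt))
                   .generate_state(1)[0] % (2**31))
        sess = simulate_session(design, gt, motion, seed=seed,
                                participant_id=f"sub-{attempt + 1:02d}")
        attempt += 1
        if screen:
            masks = [censor_mask_from(sess, r, fd_threshold) for r in range(len(sess.fd))]
            stacks = condition_stacks(sess, masks, design.trial_frames)
            if not participant_passes(stacks, min_frames=frames_per_condition):
                continue
        sessions.append(sess)
    return sessions


def censor_mask_from(session: ParticipantSession, run: int, threshold: float):
    from taskconn.alignment import MotionTrace, censor_mask
    return censor_mask(MotionTrace(fd=session.fd[run]), threshold)


# --------------------------------------------------------------------------
# fixtures on disk
# --------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_fixture(session: ParticipantSession, out_dir, config: dict | None = None):
    """Write one participant as plain-text files.

    Per run: a headerless TSV timeseries (regions as rows), a BIDS-style
    ``events.tsv`` (onset, duration, trial_type, is_catch) and a one-column
    ``motion.tsv`` of FD values.  A ``manifest.json`` records the seed and a
    configuration hash.  Returns the list of written paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for r, (ts, ev, fd) in enumerate(zip(session.timeseries, session.events,
                                         session.fd), start=1):
        base = out / f"{session.participant_id}_run-{r:02d}"
        ts_path = base.with_name(base.name + "_timeseries.tsv")
        np.savetxt(ts_path, ts, delimiter="\t", fmt="%.6f")
        ev_path = base.with_name(base.name + "_events.tsv")
        ev.to_csv(ev_path, sep="\t", index=False)
        fd_path = base.with_name(base.name + "_motion.tsv")
        np.savetxt(fd_path, fd, delimiter="\t", fmt="%.6f")
        paths.extend([ts_path, ev_path, fd_path])
    manifest = {
        "participant_id": session.participant_id,
        "seed": session.seed,
        "n_runs": len(session.timeseries),
        "tr_seconds": session.tr_seconds,
        "run_durations": [float(d) for d in session.run_durations],
        "config_hash": config_hash(config) if config is not None else None,
    }
    mpath = out / f"{session.participant_id}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    paths.append(mpath)
    return paths


def read_fixture(out_dir, participant_id: str) -> ParticipantSession:
    """Load a participant written by :func:`write_fixture`."""
    from pathlib import Path

    out = Path(out_dir)
    manifest = json.loads((out / f"{participant_id}_manifest.json").read_text())
    timeseries, events, fd = [], [], []
    for r in range(1, manifest["n_runs"] + 1):
        base = out / f"{participant_id}_run-{r:02d}"
        timeseries.append(np.loadtxt(base.with_name(base.name + "_timeseries.tsv"),
                                     delimiter="\t", ndmin=2))
        ev = pd.read_csv(base.with_name(base.name + "_events.tsv"), sep="\t")
        ev["is_catch"] = ev["is_catch"].astype(bool)
        events.append(ev)
        fd.append(np.loadtxt(base.with_name(base.name + "_motion.tsv"), ndmin=1))
    for ev, dur in zip(events, manifest["run_durations"]):
        ev.attrs["run_duration_s"] = dur
    return ParticipantSession(
        participant_id=participant_id, timeseries=timeseries, events=events,
        fd=fd, run_durations=manifest["run_durations"],
        tr_seconds=manifest["tr_seconds"], seed=manifest["seed"],
    )
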