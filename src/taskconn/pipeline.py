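"""End-to-end orchestration: simulate/load -> censor & stack -> fit -> test.

``run_pipeline`` executes the full analysis for one configuration and
returns a :class:`RunReport`; ``robustness_sweep`` repeats it over several
FD thresholds on the same cohort, mirroring the censoring-robustness check
(0.25 / 0.3 / 0.5 mm).  A single master seed fans out to per-participant
and per-condition derived seeds, so reports are byte-identical under the
same (config, seed) and partial re-runs are stable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from taskconn import alignment, connectivity, parcellation, stats, synthetic
from taskconn.parcellation import DEFAULT_INCLUDED_NETWORKS
from taskconn.synthetic import STIMULI


@dataclass
class PipelineConfig:
    """Resolved configuration of one analysis run."""

    schema: str = "small"                  # "gordon", "small", or a label-table path
    estimator: str = "connectotype"        # or "pearson"
    fd_threshold: float = 0.3
    frames_per_condition: int = 40
    trial_frames: int = 8
    min_gap_seconds: float = 20.0
    included_networks: tuple[str, ...] = DEFAULT_INCLUDED_NETWORKS
    family_method: str = "tukey"
    epsilon_method: str = "gg"
    anova_mode: str = "lmm_then_anova"
    alpha: float = 0.05
    # synthetic cohort (ignored when sessions are supplied)
    n_participants: int = 15
    amplitude: float = 0.8
    word_gain: float = 1.0
    noise_sd: float = 1.0
    subject_sd: float = 0.1
    interaction: tuple[str, str] | None = ("CiP", "FrP")
    screen_cohort: bool = True
    # penalty selection
    penalty_grid: tuple[float, ...] = tuple(np.logspace(-4, 4, 13))
    cv_folds: int = 5
    penalty_scope: str = "cohort"          # or "participant" / "condition"
    master_seed: int = 0

    def __post_init__(self):
        if self.estimator not in ("connectotype", "pearson"):
            raise ValueError("estimator must be 'connectotype' or 'pearson'")
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")

    def resolve_schema(self) -> parcellation.ParcellationSchema:
        if self.schema == "gordon":
            return parcellation.gordon_schema()
        if self.schema == "small":
            return parcellation.small_schema()
        return parcellation.load_parcellation(self.schema)

    def snapshot(self) -> dict:
        d = asdict(self)
        d["penalty_grid"] = [float(g) for g in self.penalty_grid]
        return d


@dataclass
class RunReport:
    """Everything one run produced, ready for export as TSV/JSON."""

    results: pd.DataFrame
    pair_results: list[stats.RMANOVAResult]
    marginal: pd.DataFrame
    inclusion: pd.DataFrame
    config: dict
    seed: int

    @property
    def n_included(self) -> int:
        return int(self.inclusion["included"].sum())

    def min_corrected_pair(self) -> str:
        idx = self.results["p_corrected"].idxmin()
        return self.results.loc[idx, "pair"]

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "pair_tests.tsv", sep="\t", index=False)
        self.marginal.to_csv(out / "marginal_means.tsv", sep="\t", index=False)
        self.inclusion.to_csv(out / "inclusion.tsv", sep="\t", index=False)
        (out / "config.json").write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "config_hash": synthetic.config_hash(self.config)}, indent=2))


def default_cohort(config: PipelineConfig) -> list[synthetic.ParticipantSession]:
    """Simulate the configured synthetic cohort (surviving participants)."""
    schema = config.resolve_schema()
    design = synthetic.TaskDesign(trial_frames=config.trial_frames)
    if config.word_gain != 1.0 and config.amplitude == 0.0:
        gt = synthetic.activation_only_ground_truth(
            word_gain=config.word_gain, schema=schema,
            interaction=config.interaction, seed=config.master_seed,
            noise_sd=config.noise_sd, subject_sd=config.subject_sd)
    else:
        gt = synthetic.default_ground_truth(
            schema=schema, interaction=config.interaction,
            amplitude=config.amplitude, seed=config.master_seed,
            noise_sd=config.noise_sd, subject_sd=config.subject_sd)
        gt.stim_gain = (config.word_gain, 1.0)
    return synthetic.simulate_cohort(
        design, gt, n_participants=config.n_participants,
        master_seed=config.master_seed, screen=config.screen_cohort,
        fd_threshold=config.fd_threshold,
        frames_per_condition=config.frames_per_condition)


def prepare_stacks(sessions, config: PipelineConfig):
    """Censor, stack, apply the inclusion rule, and subsample per condition.

    Returns ``(participant stacks, inclusion table)`` where the first is a
    dict participant_id -> {(frame, stimulus): sampled FrameStack} holding
    included participants only, and the table records per-participant frame
    accounting and exclusion reasons.
    """
    prepared: dict[str, dict] = {}
    rows = []
    for sess in sessions:
        masks = [alignment.censor_mask(alignment.MotionTrace(fd),
                                       config.fd_threshold)
                 for fd in sess.fd]
        stacks = alignment.condition_stacks(sess, masks, config.trial_frames,
                                            config.min_gap_seconds)
        counts = {cond: s.n_frames for cond, s in stacks.items()}
        min_cond = min(counts, key=counts.get)
        passes = alignment.participant_passes(
            stacks, config.frames_per_condition, config.trial_frames)
        rows.append({
            "participant": sess.participant_id,
            "included": passes,
            "min_frames": counts[min_cond],
            "limiting_condition": f"frame {min_cond[0]} {min_cond[1]}",
            "reason": "" if passes else (
                f"only {counts[min_cond]} frames in frame {min_cond[0]} "
                f"{min_cond[1]} (< {config.frames_per_condition})"),
        })
        if not passes:
            continue
        sampled = {}
        for (f, stim), stack in stacks.items():
            seed = alignment.condition_seed(config.master_seed,
                                            sess.participant_id, f, stim)
            sampled[(f, stim)] = alignment.sample_frames(
                stack, config.frames_per_condition, seed)
        prepared[sess.participant_id] = sampled
    inclusion = pd.DataFrame(rows)
    if not prepared:
        detail = "; ".join(f"{r['participant']}: {r['reason']}" for r in rows)
        raise RuntimeError(f"no participant passed inclusion — {detail}")
    return prepared, inclusion


def fit_cohort_matrices(prepared: dict, estimator: str,
                        penalty: connectivity.PenaltyConfig,
                        penalty_scope: str = "cohort") -> list[dict]:
    """Connectivity matrices for every included participant and condition.

    The ridge penalty is a property of the stacked-frame geometry (every
    stack has the same 40 frames and region count by construction), so by
    default one lambda is selected on the pooled CV error of all stacks in
    the cohort and applied throughout ("cohort" scope).  Re-selecting it
    per participant or per condition ("participant" / "condition" scopes)
    makes the effective shrinkage — and with it the scale of every beta —
    vary across exactly the units the downstream ANOVA compares, which
    costs calibration; both modes remain available for sensitivity checks.
    """
    if estimator != "connectotype":
        return [
            {cond: connectivity.pearson_matrix(s) for cond, s in stacks.items()}
            for stacks in prepared.values()
        ]
    if penalty_scope not in ("cohort", "participant", "condition"):
        raise ValueError("penalty_scope must be 'cohort', 'participant' or 'condition'")
    mats = []
    if penalty_scope == "cohort" and len(penalty.grid) > 1:
        all_stacks = [s for stacks in prepared.values() for s in stacks.values()]
        lam = connectivity.select_shared_penalty(all_stacks, penalty)
        penalty = connectivity.PenaltyConfig(grid=(lam,), folds=penalty.folds,
                                             sharing=penalty.sharing,
                                             seed=penalty.seed)
    for stacks in prepared.values():
        p_penalty = penalty
        if penalty_scope == "participant" and len(penalty.grid) > 1:
            lam = connectivity.select_shared_penalty(stacks.values(), penalty)
            p_penalty = connectivity.PenaltyConfig(grid=(lam,),
                                                   folds=penalty.folds,
                                                   sharing=penalty.sharing,
                                                   seed=penalty.seed)
        mats.append({cond: connectivity.fit_connectotype(s, p_penalty).beta
                     for cond, s in stacks.items()})
    return mats


def analyze_matrices(cohort_matrices: list[dict], participants: list[str],
                     schema, config: PipelineConfig):
    """Per-pair RM-ANOVA over the cohort's condition matrices."""
    pairs = parcellation.enumerate_pairs(schema, config.included_networks)
    pair_results = []
    for pair in pairs:
        table = stats.build_pair_table(pair, cohort_matrices, participants,
                                       config.trial_frames)
        pair_results.append(stats.rm_anova_pair(table, config.anova_mode,
                                                config.epsilon_method))
    p_adj = stats.correct_family(
        [r.p_uncorrected for r in pair_results], config.family_method,
        df=pair_results[0].df_den)
    for r, pc in zip(pair_results, p_adj):
        r.p_corrected = float(pc)
    results = pd.DataFrame([{
        "pair": r.pair.name,
        "n_connections": r.pair.n_connections,
        "F": r.F_interaction,
        "df_num": r.df_num, "df_den": r.df_den,
        "epsilon": r.epsilon, "mauchly_p": r.mauchly_p,
        "p_unadjusted": r.p_unadjusted,
        "p_uncorrected": r.p_uncorrected,
        "p_corrected": r.p_corrected,
        "significant": r.p_corrected < config.alpha,
    } for r in pair_results])
    marginal = pd.concat([r.marginal_means for r in pair_results],
                         ignore_index=True)
    return results, pair_results, marginal


def run_pipeline(config: PipelineConfig, sessions=None) -> RunReport:
    """Execute the full analysis; deterministic under (config, master_seed).

    When ``sessions`` is omitted, the configured synthetic cohort is
    simulated first.  Excluded participants never contribute to any stack.
    """
    schema = config.resolve_schema()
    if sessions is None:
        sessions = default_cohort(config)
    prepared, inclusion = prepare_stacks(sessions, config)
    penalty = connectivity.PenaltyConfig(
        grid=tuple(config.penalty_grid), folds=config.cv_folds,
        seed=config.master_seed)
    participants = list(prepared)
    cohort_matrices = fit_cohort_matrices(prepared, config.estimator, penalty,
                                          config.penalty_scope)
    results, pair_results, marginal = analyze_matrices(
        cohort_matrices, participants, schema, config)
    return RunReport(results=results, pair_results=pair_results,
                     marginal=marginal, inclusion=inclusion,
                     config=config.snapshot(), seed=config.master_seed)


def robustness_sweep(config: PipelineConfig,
                     thresholds=(0.25, 0.3, 0.5),
                     target_pair: str | None = None,
                     sessions=None) -> dict:
    """One full run per FD threshold on the same cohort.

    The cohort is simulated once (screened at the configured threshold);
    each run then re-applies censoring, inclusion and fitting at its own
    threshold, so stricter thresholds can exclude participants.  Returns
    ``{"reports": {thr: RunReport}, "summary": DataFrame}`` where the
    summary tracks the target pair's marginal-mean trajectory across
    thresholds.
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if sessions is None:
        sessions = default_cohort(config)
    if target_pair is None:
        target_pair = (f"{config.interaction[0]} and {config.interaction[1]}"
                       if config.interaction else None)
    reports = {}
    summaries = []
    for thr in thresholds:
        report = run_pipeline(replace(config, fd_threshold=thr), sessions=sessions)
        reports[thr] = report
        if target_pair is not None:
            track = report.marginal[report.marginal["pair"] == target_pair].copy()
            track.insert(0, "fd_threshold", thr)
            track["n_included"] = report.n_included
            summaries.append(track)
    summary = (pd.concat(summaries, ignore_index=True)
               if summaries else pd.DataFrame())
    return {"reports": reports, "summary": summary}
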