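"""Network-pair statistics: box-cox normalization, repeated-measures ANOVA
on the time-by-stimulus interaction, sphericity handling, family-wise
correction, and per-frame post-hoc tests.

For every functional network pair, the fitted connectivity values form a
complete (participant, connection, frame 1..8, stimulus word/PW) table.
Values are box-cox transformed (with a data-driven shift, since beta
weights can be negative), aggregated to a participant x 16-condition
matrix, and submitted to a classical two-way within-subject ANOVA.  The
quantity of interest is the frame-by-stimulus interaction: a network pair
whose connectivity trajectory over the trial differs between stimuli.

Sphericity of the interaction contrasts is assessed with Mauchly's test and
the interaction p-value is degree-of-freedom adjusted with the
Greenhouse-Geisser epsilon (always applied; the unadjusted p is also
reported).  Across the 36 network pairs, p-values are family-wise corrected
(studentized-range-based by default, Holm / Bonferroni / Sidak available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, special
from scipy import stats as sps

from taskconn.parcellation import NetworkPair, extract_pair_values
from taskconn.synthetic import STIMULI

FAMILY_METHODS = ("tukey", "holm", "bonferroni", "sidak", "none")


@dataclass
class BoxCoxResult:
    """Fitted box-cox exponent and the positivity shift applied before it."""

    lmbda: float
    shift: float
    loglik: float


@dataclass
class PairConditionTable:
    """Connectivity values of one network pair across the whole cohort.

    ``values`` is indexed (participant, connection, frame, stimulus) with
    stimulus order (word, pseudoword); ``transformed`` holds the box-cox
    transformed copy used for testing.
    """

    pair: NetworkPair
    values: np.ndarray
    transformed: np.ndarray | None = None
    boxcox: BoxCoxResult | None = None
    participants: list[str] = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def testing_values(self) -> np.ndarray:
        return self.transformed if self.transformed is not None else self.values


@dataclass
class RMANOVAResult:
    """Interaction test for one network pair.

    ``p_uncorrected`` is the epsilon-adjusted interaction p-value (the
    sphericity-unadjusted one is kept in ``p_unadjusted``);
    ``p_corrected`` is filled in after family-wise correction across pairs.
    """

    pair: NetworkPair
    F_interaction: float
    df_num: float
    df_den: float
    epsilon: float
    mauchly_p: float
    p_unadjusted: float
    p_uncorrected: float
    p_corrected: float = np.nan
    posthoc: np.ndarray | None = None
    marginal_means: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# box-cox
# --------------------------------------------------------------------------

def boxcox_fit(values, shift_eps_frac: float = 1e-3) -> tuple[BoxCoxResult, np.ndarray]:
    """Fit the box-cox exponent by maximum profile likelihood.

    Connectivity values can be negative, so when min(values) <= 0 a shift
    of ``eps - min`` is applied first, with ``eps = shift_eps_frac * range``
    (the transform then sees strictly positive data whose smallest value is
    a small fraction of the spread).  The exponent maximizing the profile
    log-likelihood is found with a gradient-based optimizer (L-BFGS-B on
    the negative log-likelihood); the lambda -> 0 limit is the log
    transform.  Returns the fit and the transformed values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.ptp(v) == 0:
        raise ValueError("all values equal; box-cox transform undefined")
    shift = 0.0
    if v.min() <= 0:
        shift = shift_eps_frac * np.ptp(v) - v.min()
    shifted = v + shift

    def neg_llf(lmb):
        return -sps.boxcox_llf(lmb[0], shifted)

    res = optimize.minimize(neg_llf, x0=[1.0], method="L-BFGS-B",
                            bounds=[(-5.0, 5.0)])
    lmbda = float(res.x[0])
    fit = BoxCoxResult(lmbda=lmbda, shift=shift, loglik=float(-res.fun))
    return fit, special.boxcox(shifted, lmbda)


def boxcox_transform(values, fit: BoxCoxResult) -> np.ndarray:
    """Apply an already-fitted box-cox transform (monotone increasing)."""
    return special.boxcox(np.asarray(values, dtype=float) + fit.shift, fit.lmbda)


def build_pair_table(pair: NetworkPair, cohort_matrices: list[dict],
                     participants: list[str] | None = None,
                     trial_frames: int = 8,
                     transform: bool = True) -> PairConditionTable:
    """Assemble the (participant, connection, frame, stimulus) table for a pair.

    ``cohort_matrices[p][(frame, stimulus)]`` is the region x region
    connectivity matrix of participant ``p`` in that condition.  The
    box-cox transform is fitted per pair over all of the pair's values.
    """
    n_subj = len(cohort_matrices)
    n_conn = pair.n_connections
    values = np.empty((n_subj, n_conn, trial_frames, 2))
    for p, mats in enumerate(cohort_matrices):
        for f in range(1, trial_frames + 1):
            for s, stim in enumerate(STIMULI):
                values[p, :, f - 1, s] = extract_pair_values(mats[(f, stim)], pair)
    table = PairConditionTable(
        pair=pair, values=values,
        participants=participants or [f"p{i}" for i in range(n_subj)],
    )
    if transform:
        fit, flat = boxcox_fit(values)
        table.boxcox = fit
        table.transformed = flat.reshape(values.shape)
    return table


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal within-factor contrasts (normalized Helmert)."""
    return sla.helmert(k, full=True)[1:]


def interaction_contrasts(n_frames: int) -> np.ndarray:
    """Orthonormal contrasts of the frame x stimulus interaction.

    Maps the 16 conditions (frame-major, stimulus within frame) onto the
    (n_frames - 1)-dimensional interaction subspace.
    """
    cf = _orthonormal_contrasts(n_frames)          # (f-1) x f
    cs = np.array([[1.0, -1.0]]) / np.sqrt(2.0)    # 1 x 2
    return np.kron(cf, cs)                          # (f-1) x 2f


def mauchly_epsilon(within: np.ndarray,
                    contrasts: np.ndarray | None = None) -> tuple[float, float]:
    """Mauchly's sphericity test and the Greenhouse-Geisser epsilon.

    ``within`` is a participant x condition matrix; ``contrasts`` the
    orthonormal contrast set defining the within-subject effect (all k-1
    deviations from the mean if omitted).  Epsilon is clamped to
    [1/m, 1] where m is the contrast count.  When the contrast covariance
    is singular (too few participants), the test is inconclusive and the
    lower-bound epsilon is returned with a warning.
    """
    y = np.asarray(within, dtype=float)
    n, k = y.shape
    c = _orthonormal_contrasts(k) if contrasts is None else np.asarray(contrasts)
    m = c.shape[0]
    d = y @ c.T
    s = np.cov(d, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    eigs = np.clip(np.linalg.eigvalsh(s), 0.0, None)
    tr = eigs.sum()
    lower = 1.0 / m
    if tr <= 0 or n - 1 < m or np.any(eigs <= 1e-12 * max(tr, 1.0)):
        warnings.warn("singular within-subject contrast covariance; "
                      "using lower-bound epsilon", RuntimeWarning)
        return np.nan, lower
    epsilon = float(np.clip(tr**2 / (m * (eigs**2).sum()), lower, 1.0))
    w = float(np.prod(eigs) / (tr / m) ** m)
    dfe = n - 1
    f_corr = (2 * m**2 + m + 2) / (6.0 * m * dfe)
    stat = -(dfe) * (1 - f_corr) * np.log(w)
    df = m * (m + 1) / 2 - 1
    mauchly_p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return mauchly_p, epsilon


def huynh_feldt(epsilon_gg: float, n: int, m: int) -> float:
    """Huynh-Feldt epsilon from the Greenhouse-Geisser estimate."""
    num = n * m * epsilon_gg - 2.0
    den = m * (n - 1) - m**2 * epsilon_gg
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, epsilon_gg, 1.0))


def two_way_rm_anova(cells: np.ndarray) -> tuple[float, float, float, float]:
    """Classical two-way within-subject ANOVA interaction test.

    ``cells`` is participant x factorA x factorB.  Returns
    (F_interaction, df_num, df_den, SS_interaction_error) using the
    standard sum-of-squares decomposition with the subject-by-interaction
    mean square as the error term.
    """
    y = np.asarray(cells, dtype=float)
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    fa = y.mean(axis=(0, 2))
    fb = y.mean(axis=(0, 1))
    fab = y.mean(axis=0)
    fsa = y.mean(axis=2)
    fsb = y.mean(axis=1)
    ss_ab = n * ((fab - fa[:, None] - fb[None, :] + grand) ** 2).sum()
    resid = (y
             - fab[None, :, :]
             - fsa[:, :, None] - fsb[:, None, :]
             + fa[None, :, None] + fb[None, None, :] + subj[:, None, None]
             - grand)
    ss_err = (resid**2).sum()
    df_num = (a - 1) * (b - 1)
    df_den = (a - 1) * (b - 1) * (n - 1)
    if ss_err <= 0:
        raise ValueError("rank-deficient design: zero interaction error")
    f_stat = (ss_ab / df_num) / (ss_err / df_den)
    return float(f_stat), float(df_num), float(df_den), float(ss_err)


def _aggregate(table: PairConditionTable, mode: str) -> np.ndarray:
    """Participant x frame x stimulus cell means of the transformed values.

    ``"lmm_then_anova"`` mirrors a fit-then-aggregate two-stage procedure:
    a linear model with participant-level adjustment is fitted on the
    connection-level values and the adjusted values are aggregated per
    cell.  With a complete balanced table this equals subtracting each
    participant's own mean before averaging over connections, so the two
    modes differ only by per-participant constants (which a within-subject
    ANOVA removes); both are kept for transparency.
    """
    y = table.testing_values()                    # subj x conn x frame x stim
    cells = y.mean(axis=1)                        # subj x frame x stim
    if mode == "lmm_then_anova":
        subj_effect = cells.mean(axis=(1, 2), keepdims=True) - cells.mean()
        cells = cells - subj_effect
    elif mode != "participant_mean":
        raise ValueError("mode must be 'lmm_then_anova' or 'participant_mean'")
    return cells


def rm_anova_pair(table: PairConditionTable, mode: str = "lmm_then_anova",
                  epsilon_method: str = "gg") -> RMANOVAResult:
    """Frame x stimulus interaction test for one network pair.

    Two stages: connection-level (transformed) values are adjusted for
    participant effects and aggregated to a participant x 16-condition
    matrix; that matrix is tested with a classical two-way
    repeated-measures ANOVA.  The epsilon-adjusted p (always applied,
    whatever Mauchly's test says) is reported as ``p_uncorrected``;
    family-wise correction across pairs happens separately.
    """
    cells = _aggregate(table, mode)
    n, a, b = cells.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    f_stat, df_num, df_den, _ = two_way_rm_anova(cells)
    p_unadj = float(sps.f.sf(f_stat, df_num, df_den))
    within = cells.reshape(n, a * b)              # frame-major, stimulus inner
    contrasts = interaction_contrasts(a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mauchly_p, eps = mauchly_epsilon(within, contrasts)
    if epsilon_method == "hf":
        eps = huynh_feldt(eps, n, contrasts.shape[0])
    elif epsilon_method != "gg":
        raise ValueError("epsilon_method must be 'gg' or 'hf'")
    p_adj = float(sps.f.sf(f_stat, eps * df_num, eps * df_den))
    return RMANOVAResult(
        pair=table.pair, F_interaction=f_stat, df_num=df_num, df_den=df_den,
        epsilon=eps, mauchly_p=mauchly_p, p_unadjusted=p_unadj,
        p_uncorrected=p_adj, posthoc=posthoc_frames(table),
        marginal_means=marginal_means(table),
    )


# --------------------------------------------------------------------------
# family correction and post-hoc
# --------------------------------------------------------------------------

def correct_family(pvals, method: str = "tukey", df: float = 1e6) -> np.ndarray:
    """Family-wise correction of the per-pair interaction p-values.

    ``"tukey"`` treats the tests as a comparison family of size m via the
    studentized range: each p is converted to an equivalent two-sided
    normal quantile z, and the corrected p is the survival probability of
    q = z * sqrt(2) under the studentized range with m groups.  Holm,
    Bonferroni and Sidak are available as standard alternatives; a family
    of one test is returned unchanged.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method not in FAMILY_METHODS:
        raise ValueError(f"unknown method {method!r}; options: {FAMILY_METHODS}")
    if m <= 1 or method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    # studentized-range family adjustment
    z = sps.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    q = z * np.sqrt(2.0)
    df = np.inf if not np.isfinite(df) or df > 1e6 else df
    return sps.studentized_range.sf(q, m, df)


def posthoc_frames(table: PairConditionTable) -> np.ndarray:
    """Paired t-test of word vs pseudoword participant means at each frame.

    Participant-level means over connections of the transformed values; 8
    two-sided p-values.  A frame with identical word/PW values has t = 0
    and p = 1 by convention.
    """
    y = table.testing_values().mean(axis=1)       # subj x frame x stim
    if y.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    pvals = np.empty(y.shape[1])
    for f in range(y.shape[1]):
        diff = y[:, f, 0] - y[:, f, 1]
        if np.allclose(diff, 0):
            pvals[f] = 1.0
            continue
        pvals[f] = sps.ttest_rel(y[:, f, 0], y[:, f, 1]).pvalue
    return pvals


def marginal_means(table: PairConditionTable, dispersion: str = "std",
                   factor: float = 1.15, transformed: bool = False) -> pd.DataFrame:
    """Mean and dispersion per (frame, stimulus) over participants x connections.

    The dispersion bar is ``factor`` times the chosen spread statistic
    (standard deviation by default; ``"sem"`` divides by sqrt of the count).
    Returns a tidy table with 2 * n_frames rows.
    """
    if dispersion not in ("std", "sem"):
        raise ValueError("dispersion must be 'std' or 'sem'")
    y = table.transformed if transformed else table.values
    rows = []
    for f in range(table.n_frames):
        for s, stim in enumerate(STIMULI):
            vals = y[:, :, f, s].ravel()
            spread = vals.std(ddof=1) if vals.size > 1 else 0.0
            if dispersion == "sem":
                spread = spread / np.sqrt(vals.size)
            rows.append({
                "pair": table.pair.name, "frame": f + 1, "stimulus": stim,
                "mean": vals.mean(), "dispersion": factor * spread,
                "dispersion_type": dispersion,
            })
    return pd.DataFrame(rows)
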