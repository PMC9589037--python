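"""Connectotype estimation: each region as a regularized weighted sum of all others.

For a stack of replica frames X (frames x regions), every region i is
modeled as

    x_i = sum_{j != i} beta_ij x_j + e_i

and the row beta_i minimizes ||x_i - X_{-i} beta_i||^2 + lambda ||beta_i||^2.
The collected rows form a directed region x region connectivity matrix with
a zero diagonal.  The ridge penalty makes the fit well-posed in the
underdetermined regime the analysis lives in (40 frames, hundreds of
regions); lambda is chosen by k-fold cross-validation over frames, which
are exchangeable within a stack because they come from different trials.
No autocorrelation pre-whitening is applied: in phase-aligned task data,
temporal structure across frames is part of the signal, not a nuisance.

Implementation note: all rows are solved together through the regularized
precision matrix.  With M = (X^T X + lambda I)^-1, block inversion gives
the leave-self-out ridge row exactly as beta_ij = -M_ij / M_ii (the lambda
penalty sits on the diagonal, so deleting the target's row/column of the
normal equations is a Schur complement of M), so one p x p solve per
(fold, lambda) yields every region's fit in either the overdetermined or
the 40-frames x hundreds-of-regions regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from taskconn.alignment import FrameStack


@dataclass(frozen=True)
class PenaltyConfig:
    """Ridge penalty grid and cross-validation layout."""

    grid: tuple[float, ...] = tuple(np.logspace(-4, 4, 13))
    folds: int = 5
    sharing: str = "global"     # one lambda per stack, or "per-region"
    seed: int = 0

    def __post_init__(self):
        if len(self.grid) == 0 or any(g <= 0 for g in self.grid):
            raise ValueError("penalty grid must be nonempty and positive")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.sharing not in ("global", "per-region"):
            raise ValueError("sharing must be 'global' or 'per-region'")


@dataclass
class Connectotype:
    """Directed beta-weight matrix for one (frame, stimulus) condition.

    ``beta[i, j]`` is the weight of source region j in the model of target
    region i; the diagonal is exactly zero.  ``penalty`` is the selected
    ridge strength (per-region array when sharing is per-region) and
    ``fit_stats`` the per-region cross-validated prediction MSE at that
    penalty (NaN when no CV was run).
    """

    beta: np.ndarray
    condition: tuple | None = None
    penalty: float | np.ndarray = np.nan
    fit_stats: np.ndarray | None = None
    cv_curve: pd.DataFrame | None = field(default=None, repr=False)


def _standardize(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each region across frames; returns (frames x regions, sd)."""
    x = np.asarray(data, dtype=float).T  # frames x regions
    sd = x.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"constant (zero-variance) region(s): {dead.tolist()[:10]}")
    return (x - x.mean(axis=0)) / sd, sd


def _ridge_betas(x_train: np.ndarray, lam: float) -> np.ndarray:
    """All-rows leave-self-out ridge solution (regions x regions).

    beta_ij = -M_ij / M_ii with M = (X^T X + lambda I)^-1; row i is the
    ridge regression of region i on all the others.
    """
    p = x_train.shape[1]
    m = np.linalg.inv(x_train.T @ x_train + lam * np.eye(p))
    beta = -m / np.diag(m)[:, None]
    np.fill_diagonal(beta, 0.0)
    return beta


def _cv_errors(x: np.ndarray, config: PenaltyConfig) -> np.ndarray:
    """Held-out MSE per (lambda, region), averaged over folds."""
    n = x.shape[0]
    if n < config.folds:
        raise ValueError(f"{n} frames < {config.folds} CV folds")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    order = rng.permutation(n)
    folds = np.array_split(order, config.folds)
    errs = np.zeros((len(config.grid), x.shape[1]))
    for test_idx in folds:
        if len(test_idx) == 0:
            raise ValueError("degenerate CV: empty fold")
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        x_tr, x_te = x[mask], x[test_idx]
        for k, lam in enumerate(config.grid):
            beta = _ridge_betas(x_tr, lam)
            resid = x_te - x_te @ beta.T
            errs[k] += (resid**2).mean(axis=0)
    return errs / config.folds


def _select_from_errs(errs: np.ndarray, grid: np.ndarray, sharing: str):
    """Minimizing penalty (ties toward larger lambda) and its fit stats."""
    if sharing == "per-region":
        idx = np.array([np.flatnonzero(errs[:, r] == errs[:, r].min()).max()
                        for r in range(errs.shape[1])])
        return grid[idx], errs[idx, np.arange(errs.shape[1])]
    total = errs.sum(axis=1)
    best = int(np.flatnonzero(total == total.min()).max())
    return float(grid[best]), errs[best]


def select_penalty(stack: FrameStack, config: PenaltyConfig | None = None):
    """CV-selected ridge penalty and the full CV curve.

    The selected lambda minimizes the held-out prediction MSE summed over
    regions; exact ties break toward the larger (more regularized) value.
    Returns ``(penalty, curve)`` where ``curve`` has one row per grid value.
    """
    config = config or PenaltyConfig()
    x, _ = _standardize(stack.data)
    errs = _cv_errors(x, config)
    grid = np.asarray(config.grid)
    curve = pd.DataFrame({"penalty": grid, "cv_mse": errs.sum(axis=1)})
    penalty, _stats = _select_from_errs(errs, grid, config.sharing)
    return penalty, curve


def select_shared_penalty(stacks, config: PenaltyConfig | None = None) -> float:
    """One penalty for a set of same-sized stacks (pooled CV error).

    Used to share a single lambda across all of a participant's condition
    stacks: re-selecting the penalty per condition makes the effective
    shrinkage — and hence the scale of every beta — vary from condition to
    condition, a batch effect on exactly the contrast the downstream ANOVA
    tests.  Pooling the CV curves keeps the estimator identical across
    conditions while still adapting to the participant's data.
    """
    config = config or PenaltyConfig()
    grid = np.asarray(config.grid)
    total = np.zeros(len(grid))
    for stack in stacks:
        x, _ = _standardize(stack.data)
        total += _cv_errors(x, config).sum(axis=1)
    return float(grid[np.flatnonzero(total == total.min()).max()])


def fit_connectotype(stack: FrameStack, config: PenaltyConfig | None = None) -> Connectotype:
    """Fit the connectotype of one frame stack.

    Regions are z-scored across the stack's frames before fitting (so the
    penalty treats all regions alike); the returned betas are mapped back
    to the input scale (beta_ij * sd_i / sd_j), which leaves exact linear
    relations in the raw data recoverable as their raw coefficients.
    When the penalty grid has a single value no CV is run.
    """
    config = config or PenaltyConfig()
    if stack.n_frames < 2 or stack.n_regions < 2:
        raise ValueError("need at least 2 frames and 2 regions")
    x, sd = _standardize(stack.data)
    if len(config.grid) == 1:
        penalty: float | np.ndarray = float(config.grid[0])
        fit_stats = None
    else:
        errs = _cv_errors(x, config)
        penalty, fit_stats = _select_from_errs(errs, np.asarray(config.grid),
                                               config.sharing)
    if np.isscalar(penalty):
        beta = _ridge_betas(x, float(penalty))
    else:
        beta = np.zeros((x.shape[1], x.shape[1]))
        for lam in np.unique(penalty):
            rows = np.flatnonzero(penalty == lam)
            beta[rows] = _ridge_betas(x, float(lam))[rows]
    beta *= sd[:, None] / sd[None, :]
    if not np.all(np.isfinite(beta)):
        raise FloatingPointError("non-finite betas; input may be degenerate")
    return Connectotype(beta=beta, condition=stack.condition, penalty=penalty,
                        fit_stats=fit_stats)


def export_connectotype(connectotype: Connectotype, roi_ids, path,
                        extra: dict | None = None):
    """Write a connectotype as TSV (roi_id header row/column) + JSON sidecar.

    The sidecar records the condition, the selected penalty and any extra
    provenance (seed, config hash).  Returns the two paths written.
    """
    import json
    from pathlib import Path

    path = Path(path)
    ids = [int(r) for r in roi_ids]
    frame = pd.DataFrame(connectotype.beta, index=ids, columns=ids)
    frame.index.name = "roi_id"
    frame.to_csv(path, sep="\t")
    penalty = connectotype.penalty
    sidecar = {
        "condition": list(connectotype.condition) if connectotype.condition else None,
        "penalty": (penalty.tolist() if isinstance(penalty, np.ndarray)
                    else float(penalty)),
        **(extra or {}),
    }
    side_path = path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=2))
    return path, side_path


def pearson_matrix(stack: FrameStack) -> np.ndarray:
    """Pearson correlation baseline on the identical frames.

    Symmetric with a unit diagonal (the diagonal is excluded from any
    downstream pair extraction); requires at least 3 frames and no
    zero-variance region.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    _standardize(stack.data)  # zero-variance check
    r = np.corrcoef(stack.data)
    return np.clip(r, -1.0, 1.0)


def predict_residuals(connectotype: Connectotype, stack: FrameStack) -> np.ndarray:
    """Per-region residual variance of the fitted model on the given stack."""
    beta = connectotype.beta
    if beta.shape[0] != stack.n_regions:
        raise ValueError(
            f"connectotype has {beta.shape[0]} regions, stack has {stack.n_regions}")
    x = np.asarray(stack.data, dtype=float).T
    xc = x - x.mean(axis=0)
    resid = xc - xc @ beta.T
    return (resid**2).mean(axis=0)
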