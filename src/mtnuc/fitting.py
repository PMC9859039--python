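"""Fitting the saturating nucleation model and condition-level statistics.

``fit_eq1`` estimates the initial nucleation rate ``k`` and capacity
``N_max`` by bounded nonlinear least squares on

    N(t) = N_max * (1 - exp(-k * t / N_max)),

multi-started from three capacity guesses because ``N_max`` is weakly
identified when the trajectory never approaches saturation (near-linear
data).  Replicate rates are aggregated as mean ± SEM, conditions are
normalized to a buffer control, and pairs of conditions are compared with
two-sample unpaired Student's t-tests (significance at p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .kinetics import CountTrajectory, NucleationKinetics, eq1_counts

__all__ = [
    "FitResult",
    "ReplicateSummary",
    "fit_eq1",
    "late_slope",
    "aggregate_replicates",
    "compare_conditions",
    "normalize_condition",
]

logger = logging.getLogger(__name__)

_LOWER_BOUND = 1e-6
ALPHA = 0.05


@dataclass
class FitResult:
    """Recovered saturating-model parameters for one trajectory."""

    k_hat: float
    n_max_hat: float
    residual_norm: float
    converged: bool
    initial_guess: tuple[float, float]
    weakly_identified: bool = False

    def as_kinetics(self) -> NucleationKinetics:
        return NucleationKinetics(k=self.k_hat, n_max=self.n_max_hat)


def _model(t: np.ndarray, k: float, n_max: float) -> np.ndarray:
    return n_max * (-np.expm1(-k * t / n_max))


def fit_eq1(
    traj: CountTrajectory, window: tuple[float, float] = (0.0, 150.0)
) -> FitResult:
    """Bounded multi-start least-squares fit of (k, N_max).

    The rate guess is the first-difference slope at the origin; capacity
    guesses are {max(count), 2 max, 10 max}; the start with the smallest
    residual wins.  Both parameters are bounded below at 1e-6.
    """
    sub = traj.window(*window)
    if len(sub) < 5:
        raise ValueError(f"need >= 5 points in window {window}, got {len(sub)}")
    t, y = sub.times, sub.counts

    nonzero = np.flatnonzero(y > 0)
    if nonzero.size == 0:
        # flat-zero data: any tiny k fits; report the boundary honestly
        return FitResult(
            k_hat=_LOWER_BOUND, n_max_hat=_LOWER_BOUND, residual_norm=0.0,
            converged=True, initial_guess=(_LOWER_BOUND, _LOWER_BOUND),
        )
    i1 = nonzero[0] if nonzero[0] > 0 else 1
    k0 = max(_LOWER_BOUND, (y[i1] - y[0]) / (t[i1] - t[0]))
    y_max = max(float(y.max()), 1.0)

    best: optimize.OptimizeResult | None = None
    best_guess = (k0, y_max)
    for n0 in (y_max, 2.0 * y_max, 10.0 * y_max):
        try:
            res = optimize.least_squares(
                lambda p: _model(t, p[0], p[1]) - y,
                x0=[k0, n0],
                bounds=([_LOWER_BOUND, _LOWER_BOUND], [np.inf, np.inf]),
                method="trf",
            )
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
            best_guess = (k0, n0)
    if best is None:
        logger.warning("nonlinear fit failed from all starts")
        return FitResult(
            k_hat=np.nan, n_max_hat=np.nan, residual_norm=np.nan,
            converged=False, initial_guess=best_guess,
        )
    k_hat, n_max_hat = best.x
    result = FitResult(
        k_hat=float(k_hat),
        n_max_hat=float(n_max_hat),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=True,
        initial_guess=best_guess,
    )
    result.weakly_identified = _n_max_weakly_identified(best, t.size)
    return result


def _n_max_weakly_identified(res: optimize.OptimizeResult, n_obs: int) -> bool:
    """Flag fits whose Hessian-based relative CI on N_max exceeds 100%."""
    dof = n_obs - 2
    if dof <= 0:
        return True
    try:
        jtj = res.jac.T @ res.jac
        # a numerically singular Hessian means the capacity direction is
        # flat regardless of residual size (e.g. noise-free linear data)
        if np.linalg.cond(jtj) > 1e12:
            return True
        cov = np.linalg.inv(jtj) * (2.0 * res.cost / dof)
        se_n_max = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return True
    return not np.isfinite(se_n_max) or 1.96 * se_n_max > abs(res.x[1])


def late_slope(
    traj: CountTrajectory, window: tuple[float, float] = (25.0, 150.0)
) -> float:
    """Ordinary least-squares slope (MTs/s) over the saturation window."""
    sub = traj.window(*window)
    if len(sub) < 3:
        raise ValueError(f"need >= 3 points in window {window}, got {len(sub)}")
    return float(np.polyfit(sub.times, sub.counts, 1)[0])


@dataclass
class ReplicateSummary:
    """Mean nucleation rate across biological replicates."""

    mean_k: float
    sem_k: float | None  # None with a single replicate
    n: int
    k_values: list[float] = field(default_factory=list)


def aggregate_replicates(fits: list[FitResult]) -> ReplicateSummary:
    """Arithmetic mean and SEM (sd/sqrt(n)) of recovered rates."""
    if not fits:
        raise ValueError("no fits to aggregate")
    if not all(f.converged for f in fits):
        raise ValueError("all fits must have converged")
    ks = np.array([f.k_hat for f in fits])
    sem = float(ks.std(ddof=1) / np.sqrt(ks.size)) if ks.size > 1 else None
    return ReplicateSummary(
        mean_k=float(ks.mean()), sem_k=sem, n=ks.size, k_values=ks.tolist()
    )


def compare_conditions(a, b) -> tuple[float, bool]:
    """Two-sample unpaired Student's t-test; returns (p, significant).

    Zero variance in both samples with equal means yields p = 1 by
    convention (no evidence of a difference).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return p, p < ALPHA


def normalize_condition(values, control_values) -> np.ndarray:
    """Fold changes: each value divided by the control mean."""
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    ref = control.mean()
    if not ref > 0:
        raise ValueError(f"control mean must be > 0, got {ref}")
    return values / ref
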